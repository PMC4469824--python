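"""Protein quantification: filters, roll-up, normalization, threshold, calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from omicsbridge import (call_deps, derive_threshold, filter_peptides,
                         normalize_median_ratio, quantify_proteins, ratio_pvalue,
                         replicate_fold_change, replicate_reproducibility)
from omicsbridge.proteome import aggregate_proteins, compute_ratio_pvalues

from conftest import small_config
from omicsbridge import generate_reporter_intensities, generate_truth


def make_peptides(rows):
    """rows: list of (protein, i116, i117, i119, i121[, score])."""
    recs = []
    for i, row in enumerate(rows):
        protein, *intens = row
        score = intens[4] if len(intens) > 4 else 50.0
        recs.append({"protein_id": protein, "peptide_id": f"{protein}_p{i}",
                     "unique": True, "score": score,
                     "i116": intens[0], "i117": intens[1],
                     "i119": intens[2], "i121": intens[3]})
    return pd.DataFrame(recs)


class TestFilter:
    def test_zero_min_score_is_identity(self):
        peps = make_peptides([("A", 1, 1, 1, 1), ("B", 2, 2, 2, 2)])
        out, report = filter_peptides(peps, min_score=0.0)
        assert len(out) == 2 and report == {"retained": 2, "dropped": 0}

    def test_score_boundary_inclusive(self):
        peps = make_peptides([("A", 1, 1, 1, 1, 19.0),
                              ("A", 1, 1, 1, 1, 20.0),
                              ("A", 1, 1, 1, 1, 21.0)])
        out, report = filter_peptides(peps, min_score=20.0)
        assert report["retained"] == 2
        assert set(out["score"]) == {20.0, 21.0}

    def test_counts_match_direct_scan(self):
        rng = np.random.default_rng(0)
        scores = np.concatenate([rng.uniform(0, 20, 40), rng.uniform(20, 80, 60)])
        peps = make_peptides([("P%d" % i, 1, 1, 1, 1, s)
                              for i, s in enumerate(scores)])
        _, report = filter_peptides(peps, min_score=20.0)
        assert report["retained"] == int((scores >= 20).sum()) == 60

    def test_non_unique_dropped(self):
        peps = make_peptides([("A", 1, 1, 1, 1)])
        peps.loc[0, "unique"] = False
        out, _ = filter_peptides(peps, min_score=0.0)
        assert out.empty


class TestAggregate:
    def test_single_peptide_ratios(self):
        quant = aggregate_proteins(make_peptides([("A", 10, 10, 20, 20)]))
        assert quant.loc[0, "ratio_rep1"] == pytest.approx(2.0)
        assert quant.loc[0, "ratio_rep2"] == pytest.approx(2.0)

    def test_channel_sums_drive_ratios(self):
        quant = aggregate_proteins(make_peptides([
            ("A", 10, 10, 10, 10), ("A", 10, 10, 30, 30)]))
        assert quant.loc[0, ["i116", "i117", "i119", "i121"]].tolist() == \
            [20, 20, 40, 40]
        assert quant.loc[0, "ratio_rep1"] == pytest.approx(2.0)
        assert quant.loc[0, "n_unique_peptides"] == 2

    def test_zero_channel_peptide_flagged_not_dropped(self):
        quant = aggregate_proteins(make_peptides([
            ("A", 0, 10, 10, 10), ("A", 10, 10, 10, 10)]))
        assert quant.loc[0, "n_zero_peptides"] == 1
        assert quant.loc[0, "quantifiable"]          # summed channel > 0

    def test_all_zero_denominator_unquantifiable(self):
        quant = aggregate_proteins(make_peptides([("A", 0, 10, 10, 10)]))
        assert not quant.loc[0, "quantifiable"]


class TestMedianNormalization:
    def test_constant_ratios(self):
        np.testing.assert_allclose(normalize_median_ratio([2, 2, 2]), [1, 1, 1])

    def test_small_example(self):
        np.testing.assert_allclose(normalize_median_ratio([1, 2, 4]), [0.5, 1, 2])

    def test_median_exactly_one_and_idempotent(self):
        rng = np.random.default_rng(1)
        ratios = np.exp(rng.normal(0.3, 0.7, 1001))
        out = normalize_median_ratio(ratios)
        assert np.sort(out)[500] == 1.0            # sort-and-check oracle
        np.testing.assert_array_equal(normalize_median_ratio(out), out)

    def test_even_n_lower_middle_median_maps_to_one(self):
        out = normalize_median_ratio([1.0, 2.0, 3.0, 4.0])
        assert np.sort(out)[1] == 1.0

    def test_empty_and_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            normalize_median_ratio([])
        with pytest.raises(ValueError):
            normalize_median_ratio([1.0, -2.0])


class TestFoldChange:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 2.0, 1.0), (1.0, 2.0, 2.0), (2.0, 1.0, 2.0), (0.8, 1.4, 1.75)])
    def test_examples(self, a, b, expected):
        assert replicate_fold_change(a, b) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.01, 100), st.floats(0.01, 100))
    def test_symmetric_and_at_least_one(self, a, b):
        fc = replicate_fold_change(a, b)
        assert fc == replicate_fold_change(b, a)
        assert fc >= 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            replicate_fold_change(0.0, 1.0)


class TestDeriveThreshold:
    def test_constant_distribution(self):
        rep = derive_threshold({"wt": [1.3] * 50}, level=0.95)
        assert rep.chosen_threshold == pytest.approx(1.3)
        for q in (0.90, 0.95, 0.99):
            assert rep.quantile("wt", q) == pytest.approx(1.3)

    def test_boundary_fraction_semantics(self):
        # 95 of 100 fold changes at 1.0: the 95% quantile is 1.0 itself.
        fcs = [1.0] * 95 + [2.0] * 5
        rep = derive_threshold({"wt": fcs}, level=0.95)
        assert rep.quantile("wt", 0.95) == 1.0
        assert rep.quantile("wt", 0.99) == 2.0

    def test_monotone_in_quantile(self):
        rng = np.random.default_rng(2)
        fcs = np.exp(np.abs(rng.normal(0, 0.4, 5000)))
        rep = derive_threshold({"wt": fcs})
        qs = [rep.quantile("wt", q) for q in (0.90, 0.95, 0.99)]
        assert qs == sorted(qs)

    def test_max_over_pairings_and_rounding(self):
        rep = derive_threshold({"a": [1.2] * 10, "b": [1.55] * 10},
                               level=0.95, round_up_to=0.1)
        assert rep.chosen_threshold == pytest.approx(1.6)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            derive_threshold({"wt": [1.0]}, level=1.5)


class TestRatioPvalue:
    def test_exact_null_gives_one(self):
        assert ratio_pvalue([0.0, 0.0, 0.0]) == 1.0

    def test_single_peptide_undefined(self):
        assert np.isnan(ratio_pvalue([1.0]))

    def test_matches_t_test_oracle(self):
        x = [1.0, 1.2, 0.9]
        expected = stats.ttest_1samp(x, 0.0).pvalue
        assert ratio_pvalue(x) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_nonzero_mean_is_degenerate_zero(self):
        assert ratio_pvalue([0.7, 0.7, 0.7]) == 0.0

    def test_batch_path_matches_scalar_op(self):
        cfg = small_config(seed=21)
        peps = generate_reporter_intensities(generate_truth(cfg), cfg)
        quant = compute_ratio_pvalues(aggregate_proteins(peps), peps, center=0.0)
        plr = 0.5 * (np.log2(peps["i119"] / peps["i116"])
                     + np.log2(peps["i121"] / peps["i117"]))
        for pid, group in plr.groupby(peps["protein_id"]):
            expected = ratio_pvalue(group.to_numpy())
            got = float(quant.set_index("protein_id").loc[pid, "p_value"])
            if np.isnan(expected):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expected, rel=1e-9)


class TestCallDeps:
    def quant_row(self, r1, r2, p=0.01, n=3):
        return pd.DataFrame([{
            "protein_id": "A", "n_unique_peptides": n, "ratio_rep1": r1,
            "ratio_rep2": r2, "p_value": p, "quantifiable": True}])

    @pytest.mark.parametrize("r1,r2,p,n,expected", [
        (1.7, 1.8, 0.01, 3, "up"),
        (0.5, 0.55, 0.01, 2, "down"),      # 0.55 <= 1/1.6
        (1.7, 1.4, 0.01, 3, "none"),       # discordant replicates
        (1.7, 1.8, 0.20, 3, "none"),       # p too large
        (1.7, 1.8, 0.01, 1, "none"),       # single peptide
    ])
    def test_call_rule(self, r1, r2, p, n, expected):
        calls, _ = call_deps(self.quant_row(r1, r2, p, n), threshold=1.6)
        assert calls.loc[0, "call"] == expected

    def test_counts_reported(self):
        df = pd.concat([self.quant_row(1.7, 1.8), self.quant_row(0.5, 0.5)],
                       ignore_index=True)
        _, counts = call_deps(df, threshold=1.6)
        assert counts == {"up": 1, "down": 1, "none": 0}


class TestReproducibility:
    def test_identical_replicates(self):
        quant = aggregate_proteins(make_peptides(
            [(f"P{i}", v, v, 2 * v, 2 * v) for i, v in enumerate([1, 5, 9, 20])]))
        r = replicate_reproducibility(quant)
        assert r["WT"] == pytest.approx(1.0)
        assert r["MT"] == pytest.approx(1.0)

    def test_anti_correlated_log_intensities(self):
        quant = aggregate_proteins(make_peptides(
            [(f"P{i}", 2.0 ** v, 2.0 ** (-v), 1, 1) for i, v in enumerate([1, 2, 3])]))
        assert replicate_reproducibility(quant)["WT"] == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        cfg = small_config(sigma_reporter=0.3, seed=13)
        peps = generate_reporter_intensities(generate_truth(cfg), cfg)
        quant, _ = quantify_proteins(peps, min_score=0.0, min_unique_peptides=1)
        r = replicate_reproducibility(quant)
        usable = quant[quant["quantifiable"]]
        x = np.log2(usable["i116"].to_numpy())
        y = np.log2(usable["i117"].to_numpy())
        expected = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert r["WT"] == pytest.approx(expected, rel=1e-9)


class TestQuantifyChain:
    def test_specificity_on_null_data(self):
        # All-null proteome with the auto 95% threshold: DEP fraction must
        # stay near the nominal 5% false-call budget.
        cfg = small_config(n_genes=800, frac_de=0.0, sigma_bio=0.0, seed=17)
        peps = generate_reporter_intensities(generate_truth(cfg), cfg)
        quant, _ = quantify_proteins(peps)
        from omicsbridge import threshold_from_quant
        thr = threshold_from_quant(quant, level=0.95).chosen_threshold
        calls, counts = call_deps(quant, thr)
        n_quant = int(quant["quantifiable"].sum())
        assert (counts["up"] + counts["down"]) / n_quant <= 0.05 + 0.03
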