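"""iTRAQ protein quantification and empirical-threshold DEP calling.

Peptide-level reporter intensities are rolled up to protein channel sums,
mutant/wild-type ratios are median-normalized, and the significance
threshold for calling differentially expressed proteins (DEPs) is derived
empirically: the distribution of max/min fold changes between biological
replicates of the *same* condition is tabulated, and its upper quantile
(default 95%) becomes the between-condition cutoff.  A protein is a DEP
when both replicate MT/WT ratios clear the cutoff on the same side, its
peptide-ratio p-value is below alpha, and it is supported by at least two
unique peptides.

Channel pairings, fixed throughout:

* within wild type  117/116, within mutant 121/119  (replicate null),
* between conditions 119/116 (replicate pair 1) and 121/117 (pair 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

RATIO_COLUMNS = ("ratio_rep1", "ratio_rep2", "ratio_wt", "ratio_mt")
_PAIRINGS = {
    "ratio_rep1": ("i119", "i116"),
    "ratio_rep2": ("i121", "i117"),
    "ratio_wt": ("i117", "i116"),
    "ratio_mt": ("i121", "i119"),
}


def filter_peptides(peptides: pd.DataFrame, min_score: float = 20.0
                    ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep unique peptides with identification score >= ``min_score``.

    The score boundary is inclusive.  Returns the retained records and a
    ``{"retained": ..., "dropped": ...}`` report; an empty result is legal
    (downstream stages warn rather than fail here).
    """
    if min_score < 0:
        raise ValueError("min_score must be >= 0")
    keep = (peptides["score"] >= min_score) & peptides["unique"].astype(bool)
    out = peptides.loc[keep].reset_index(drop=True)
    return out, {"retained": int(keep.sum()), "dropped": int((~keep).sum())}


def aggregate_proteins(peptides: pd.DataFrame) -> pd.DataFrame:
    """Roll peptides up to proteins: channel-wise intensity sums and ratios.

    Per protein: summed channel intensities, the unique-peptide count, the
    two between-condition ratios (119/116, 121/117) and the two
    within-condition replicate ratios (117/116, 121/119).  A protein whose
    denominator channel sums to zero is flagged unquantifiable (ratios NaN)
    rather than dropped.  Peptides containing a zero intensity contribute to
    the sums but are flagged in ``n_zero_peptides``.
    """
    channels = ["i116", "i117", "i119", "i121"]
    grouped = peptides.groupby("protein_id", sort=True)
    quant = grouped[channels].sum()
    quant["n_unique_peptides"] = grouped["peptide_id"].nunique()
    has_zero = (peptides[channels] <= 0).any(axis=1)
    quant["n_zero_peptides"] = has_zero.groupby(peptides["protein_id"]).sum().astype(int)
    for col, (num, den) in _PAIRINGS.items():
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = quant[num] / quant[den]
        quant[col] = np.where((quant[num] > 0) & (quant[den] > 0), ratio, np.nan)
    quant["quantifiable"] = ~quant[list(RATIO_COLUMNS)].isna().any(axis=1)
    quant["normalized"] = False
    return quant.reset_index()


def peptide_log2_ratios(peptides: pd.DataFrame) -> pd.Series:
    """Per-peptide mean MT/WT log2 ratio over the two replicate pairings.

    Peptides with any nonpositive intensity yield NaN (flagged upstream).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        r1 = np.log2(peptides["i119"] / peptides["i116"])
        r2 = np.log2(peptides["i121"] / peptides["i117"])
    out = 0.5 * (r1 + r2)
    out[~np.isfinite(out)] = np.nan
    return out


def ratio_pvalue(log2_ratios: Iterable[float], center: float = 0.0) -> float:
    """Two-sided one-sample t-test of peptide log2 ratios against ``center``.

    Fewer than two ratios: NaN (protein not quantifiable).  Zero variance:
    p = 1 when the common value equals the center exactly, else p = 0 (the
    degenerate limit of the t statistic; flagged by the caller).
    """
    x = np.asarray(list(log2_ratios), dtype=float) - center
    x = x[np.isfinite(x)]
    if len(x) < 2:
        return float("nan")
    if np.ptp(x) == 0.0:
        return 1.0 if x[0] == 0.0 else 0.0
    return float(stats.ttest_1samp(x, 0.0).pvalue)


def compute_ratio_pvalues(quant: pd.DataFrame, peptides: pd.DataFrame,
                          center: float | None = None) -> pd.DataFrame:
    """Attach peptide-ratio p-values (and a quality flag) to ``quant``.

    ``center`` defaults to the median of the per-protein mean peptide log2
    ratios — the peptide-level counterpart of median-ratio normalization,
    so systematic channel biases do not shift every test.
    """
    plr = peptides.assign(_plr=peptide_log2_ratios(peptides))
    plr = plr[np.isfinite(plr["_plr"])]
    per_protein = plr.groupby("protein_id")["_plr"]
    if center is None:
        means = per_protein.mean().dropna()
        center = _lower_median(means.to_numpy()) if len(means) else 0.0

    agg = per_protein.agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1),
                          lo="min", hi="max")
    n = agg["n"].to_numpy(dtype=float)
    mean = agg["mean"].to_numpy(dtype=float) - center
    sd = agg["sd"].to_numpy(dtype=float)
    spread = (agg["hi"] - agg["lo"]).to_numpy(dtype=float)

    # Closed-form two-sided one-sample t-test (identical to ratio_pvalue).
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 1, 1))
    degenerate = (n >= 2) & (spread == 0.0)
    p = np.where(degenerate, np.where(mean == 0.0, 1.0, 0.0), p)
    p = np.where(n < 2, np.nan, p)
    flag = np.where(n < 2, "insufficient_peptides",
                    np.where(degenerate, "degenerate_zero_variance", "ok"))

    out = quant.copy()
    out["p_value"] = out["protein_id"].map(pd.Series(p, index=agg.index))
    out["p_flag"] = out["protein_id"].map(
        pd.Series(flag, index=agg.index)).fillna("insufficient_peptides")
    return out


def _lower_median(values: np.ndarray) -> float:
    """Median as the lower-middle order statistic (an observed value)."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def normalize_median_ratio(ratios: np.ndarray | pd.Series) -> np.ndarray:
    """Divide ratios by their (lower-middle) median; the post-normalization
    median is exactly 1 and re-application changes nothing."""
    arr = np.asarray(ratios, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size == 0:
        raise ValueError("cannot normalize an empty ratio list")
    if np.any(finite <= 0):
        raise ValueError("ratios must be > 0")
    return arr / _lower_median(finite)


def normalize_quant(quant: pd.DataFrame) -> pd.DataFrame:
    """Median-normalize every ratio column of the protein table."""
    out = quant.copy()
    for col in RATIO_COLUMNS:
        out[col] = normalize_median_ratio(out[col])
    out["normalized"] = True
    return out


def replicate_fold_change(a, b):
    """max(a, b) / min(a, b) — the symmetric >= 1 fold change."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("fold change requires positive inputs")
    out = np.maximum(a, b) / np.minimum(a, b)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ThresholdReport:
    """Quantiles of the within-condition replicate fold-change distribution
    and the resulting DEP cutoff."""

    table: pd.DataFrame          # columns: pairing, level, fold_change
    chosen_threshold: float
    chosen_level: float

    def quantile(self, pairing: str, level: float) -> float:
        t = self.table
        row = t[(t["pairing"] == pairing) & (t["level"] == level)]
        return float(row["fold_change"].iloc[0])


def _empirical_quantile(sorted_values: np.ndarray, q: float) -> float:
    """Smallest observed value whose cumulative fraction is >= q."""
    n = len(sorted_values)
    idx = min(max(int(math.ceil(q * n)) - 1, 0), n - 1)
    return float(sorted_values[idx])


def derive_threshold(fold_changes: Mapping[str, Iterable[float]],
                     level: float = 0.95,
                     quantiles: tuple[float, ...] = (0.90, 0.95, 0.99),
                     min_threshold: float = 1.0,
                     round_up_to: float | None = None) -> ThresholdReport:
    """Derive the DEP fold-change cutoff from replicate variation.

    For each within-condition pairing, report the empirical quantile of the
    replicate fold changes at the requested levels; the chosen threshold is
    the maximum across pairings at ``level`` (conservative), floored at
    ``min_threshold`` and optionally rounded up to a multiple of
    ``round_up_to``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    levels = sorted(set(quantiles) | {level})
    rows = []
    at_level = []
    for pairing, fcs in fold_changes.items():
        arr = np.sort(np.asarray(list(fcs), dtype=float))
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            raise ValueError(f"no fold changes for pairing {pairing!r}")
        for q in levels:
            rows.append({"pairing": pairing, "level": q,
                         "fold_change": _empirical_quantile(arr, q)})
        at_level.append(_empirical_quantile(arr, level))
    chosen = max(max(at_level), min_threshold)
    if round_up_to:
        chosen = math.ceil(chosen / round_up_to - 1e-12) * round_up_to
    return ThresholdReport(table=pd.DataFrame(rows),
                           chosen_threshold=float(chosen), chosen_level=level)


def threshold_from_quant(quant: pd.DataFrame, level: float = 0.95,
                         min_threshold: float = 1.0,
                         round_up_to: float | None = None) -> ThresholdReport:
    """Replicate-null threshold from a normalized protein table."""
    usable = quant[quant["quantifiable"]]
    fcs = {
        "117/116": replicate_fold_change(usable["ratio_wt"], 1.0),
        "121/119": replicate_fold_change(usable["ratio_mt"], 1.0),
    }
    return derive_threshold(fcs, level=level, min_threshold=min_threshold,
                            round_up_to=round_up_to)


def call_deps(quant: pd.DataFrame, threshold: float, alpha: float = 0.05,
              min_unique_peptides: int = 2) -> tuple[pd.DataFrame, dict[str, int]]:
    """Call DEPs: both replicate ratios beyond the threshold on the same
    side, p-value < alpha, and enough unique peptides; otherwise ``none``."""
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    out = quant.copy()
    r1 = out["ratio_rep1"].to_numpy(dtype=float)
    r2 = out["ratio_rep2"].to_numpy(dtype=float)
    p = out["p_value"].to_numpy(dtype=float)
    eligible = (out["quantifiable"].to_numpy()
                & (out["n_unique_peptides"].to_numpy() >= min_unique_peptides)
                & np.isfinite(p) & (p < alpha))
    up = eligible & (r1 >= threshold) & (r2 >= threshold)
    down = eligible & (r1 <= 1.0 / threshold) & (r2 <= 1.0 / threshold)
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out, {"up": int(up.sum()), "down": int(down.sum()),
                 "none": int(len(out) - up.sum() - down.sum())}


def replicate_reproducibility(quant: pd.DataFrame) -> dict[str, float]:
    """Pearson r of log2 protein channel intensities between replicates,
    per condition.  Degenerate (constant) vectors give NaN."""
    usable = quant[quant["quantifiable"]]
    if len(usable) < 3:
        raise ValueError("need at least 3 quantified proteins")
    out = {}
    for cond, (a, b) in {"WT": ("i116", "i117"), "MT": ("i119", "i121")}.items():
        x = np.log2(usable[a].to_numpy(dtype=float))
        y = np.log2(usable[b].to_numpy(dtype=float))
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[cond] = float("nan")
        else:
            out[cond] = float(stats.pearsonr(x, y).statistic)
    return out


def quantify_proteins(peptides: pd.DataFrame, min_score: float = 20.0,
                      min_unique_peptides: int = 2
                      ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Full quantification chain: filter, aggregate, normalize, test.

    Returns the normalized protein table (``quantifiable`` additionally
    requires ``min_unique_peptides``) and the peptide filter report.
    """
    kept, report = filter_peptides(peptides, min_score=min_score)
    if kept.empty:
        raise ValueError("no peptides survive the score/uniqueness filter")
    quant = aggregate_proteins(kept)
    quant = normalize_quant(quant)
    quant = compute_ratio_pvalues(quant, kept)
    quant["quantifiable"] = (quant["quantifiable"]
                             & (quant["n_unique_peptides"] >= min_unique_peptides))
    report = dict(report, proteins=len(quant),
                  quantifiable=int(quant["quantifiable"].sum()))
    return quant, report
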