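"""mRNA-protein integration: matching, overlap, and the correlation ladder.

Proteins are matched to cognate transcripts on a canonical locus id
(isoform suffixes stripped).  The mRNA-protein relationship is summarized
as a ladder of four nested comparisons of log2 (mutant/wild-type) ratios —

1. ``stringent_overlap``  DEPs that are also called DEGs,
2. ``dep_vs_cognate``     DEPs vs cognate mRNAs under the relaxed filter
   (|log2 ratio| >= 1, i.e. 2-fold, with no probability bound),
3. ``dep_vs_all``         DEPs vs all expressed mRNAs,
4. ``all_vs_all``         all quantified proteins vs all expressed mRNAs —

plus two direction-restricted correlations (``up_up``, ``down_down``).
Protein ratios are aggregated across the two replicate pairings by
geometric mean; mRNA ratios are the M statistic from condition means.
"""

from __future__ import annotations

import re
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")

LADDER_LEVELS = ("stringent_overlap", "dep_vs_cognate", "dep_vs_all", "all_vs_all")


def canonical_gene_id(identifier: str) -> str:
    """Strip a trailing ``.<integer>`` isoform suffix; idempotent."""
    if not identifier:
        raise ValueError("empty identifier")
    return _ISOFORM_SUFFIX.sub("", identifier)


def protein_log2_table(quant: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Canonical id -> replicate-aggregated protein log2 ratio.

    The aggregate is the mean of the two replicate log2 ratios (geometric
    mean of the ratios).  Proteins with undefined ratios are excluded and
    counted; multiple isoforms of one locus average their log2 ratios.
    """
    usable = quant[quant["quantifiable"]].copy()
    excluded = len(quant) - len(usable)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = 0.5 * (np.log2(usable["ratio_rep1"].to_numpy(dtype=float))
                            + np.log2(usable["ratio_rep2"].to_numpy(dtype=float)))
    usable["gene_id"] = usable["protein_id"].map(canonical_gene_id)
    usable["protein_log2_ratio"] = log2_ratio
    finite = np.isfinite(log2_ratio)
    excluded += int((~finite).sum())
    table = (usable.loc[finite]
             .groupby("gene_id", as_index=False)["protein_log2_ratio"].mean())
    return table, excluded


def mrna_log2_table(deg_results: pd.DataFrame) -> pd.DataFrame:
    """Canonical id -> mRNA log2 ratio (the M statistic)."""
    out = pd.DataFrame({
        "gene_id": deg_results["gene_id"].map(canonical_gene_id),
        "mrna_log2_ratio": deg_results["M"].to_numpy(dtype=float),
    })
    return out[np.isfinite(out["mrna_log2_ratio"])].reset_index(drop=True)


def match_pairs(protein_table: pd.DataFrame, mrna_table: pd.DataFrame,
                protein_ids: Iterable[str] | None = None,
                mrna_ids: Iterable[str] | None = None) -> pd.DataFrame:
    """Inner join of protein and mRNA log2 ratios on canonical id, after
    optionally restricting each side to an id set."""
    prot = protein_table
    mrna = mrna_table
    if protein_ids is not None:
        prot = prot[prot["gene_id"].isin(set(protein_ids))]
    if mrna_ids is not None:
        mrna = mrna[mrna["gene_id"].isin(set(mrna_ids))]
    return prot.merge(mrna, on="gene_id", how="inner")


def pearson_log_ratios(pairs: pd.DataFrame, method: str = "pearson"
                       ) -> tuple[float, int]:
    """Correlation of protein vs mRNA log2 ratios; NaN when fewer than
    three pairs or a vector is constant."""
    n = len(pairs)
    if n < 3:
        return float("nan"), n
    x = pairs["protein_log2_ratio"].to_numpy(dtype=float)
    y = pairs["mrna_log2_ratio"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), n
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic), n
    return float(stats.pearsonr(x, y).statistic), n


def overlap_deps_degs(dep_calls: pd.DataFrame, deg_calls: pd.DataFrame
                      ) -> tuple[int, list[str]]:
    """Canonical ids called on both sides (any direction)."""
    dep_ids = {canonical_gene_id(p) for p, c in
               zip(dep_calls["protein_id"], dep_calls["call"]) if c != "none"}
    deg_ids = {canonical_gene_id(g) for g, c in
               zip(deg_calls["gene_id"], deg_calls["call"]) if c != "none"}
    ids = sorted(dep_ids & deg_ids)
    return len(ids), ids


def correlation_ladder(quant: pd.DataFrame, deg_results: pd.DataFrame,
                       dep_calls: pd.DataFrame,
                       relaxed_mrna_log2: float = 1.0,
                       method: str = "pearson") -> pd.DataFrame:
    """The four-level ladder plus the two directional correlations.

    Returns one row per level: ``level``, ``n_pairs``, ``r``,
    ``n_excluded`` (proteins dropped for undefined ratios).  When the
    filters are nested the pair counts are nondecreasing down the ladder.
    """
    prot, excluded = protein_log2_table(quant)
    mrna = mrna_log2_table(deg_results)

    dep_up = {canonical_gene_id(p) for p, c in
              zip(dep_calls["protein_id"], dep_calls["call"]) if c == "up"}
    dep_down = {canonical_gene_id(p) for p, c in
                zip(dep_calls["protein_id"], dep_calls["call"]) if c == "down"}
    dep_ids = dep_up | dep_down
    deg_ids = {canonical_gene_id(g) for g, c in
               zip(deg_results["gene_id"], deg_results["call"]) if c != "none"}
    m = mrna.set_index("gene_id")["mrna_log2_ratio"]
    relaxed_up = set(m.index[m >= relaxed_mrna_log2])
    relaxed_down = set(m.index[m <= -relaxed_mrna_log2])
    relaxed = relaxed_up | relaxed_down

    selections = {
        "stringent_overlap": (dep_ids, deg_ids),
        "dep_vs_cognate": (dep_ids, relaxed),
        "dep_vs_all": (dep_ids, None),
        "all_vs_all": (None, None),
        "up_up": (dep_up, relaxed_up),
        "down_down": (dep_down, relaxed_down),
    }
    rows = []
    for level, (pids, mids) in selections.items():
        pairs = match_pairs(prot, mrna, protein_ids=pids, mrna_ids=mids)
        r, n = pearson_log_ratios(pairs, method=method)
        rows.append({"level": level, "n_pairs": n, "r": r, "n_excluded": excluded})
    return pd.DataFrame(rows)


def ladder_pairs(quant: pd.DataFrame, deg_results: pd.DataFrame) -> pd.DataFrame:
    """All-vs-all matched pairs (scatter data for the widest ladder level)."""
    prot, _ = protein_log2_table(quant)
    return match_pairs(prot, mrna_log2_table(deg_results))


def go_category_tally(ids: Iterable[str], go_map: pd.DataFrame,
                      ontology: str) -> tuple[pd.DataFrame, int]:
    """Per-category counts and percentages for an id list in one ontology.

    A gene may contribute to several categories; percentages are relative
    to the number of annotated ids in the ontology.  Returns the tally and
    the count of unannotated ids.
    """
    canon = {canonical_gene_id(i) for i in ids}
    sub = go_map[(go_map["ontology"] == ontology)
                 & go_map["gene_id"].map(canonical_gene_id).isin(canon)]
    annotated_ids = set(sub["gene_id"].map(canonical_gene_id))
    unannotated = len(canon - annotated_ids)
    if sub.empty:
        return pd.DataFrame(columns=["term", "count", "percent"]), unannotated
    tally = (sub.groupby("term").size().rename("count").reset_index()
             .sort_values(["count", "term"], ascending=[False, True], ignore_index=True))
    tally["percent"] = 100.0 * tally["count"] / len(annotated_ids)
    return tally, unannotated
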