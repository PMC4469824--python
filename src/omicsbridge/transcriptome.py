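"""DGE tag bookkeeping, TPM normalization, and nonparametric DE calling.

Tag counts per gene and library are normalized to TPM (transcripts per
million mapped-to-gene tags).  Differential expression between the mutant
and wild-type conditions is scored nonparametrically: the signal for each
gene is the pair (M, D) — M the log2 ratio of condition mean TPMs (with a
pseudocount inside the log only) and D the absolute difference of the raw
condition means — and the probability of differential expression is the
fraction of a pooled within-condition replicate "noise" cloud (|M0|, D0)
lying strictly below the gene's (|M|, D).  A gene is called when its
probability reaches ``q_min`` (default 0.8) and |M| reaches ``m_min``
(default 1, i.e. 2-fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import LIBRARIES, MT_LIBRARIES, WT_LIBRARIES

_MAPPING_CATEGORIES = ("to_gene", "to_genome", "unknown")


def summarize_mapping(mapping: pd.DataFrame) -> pd.DataFrame:
    """Percentages of clean tags per mapping category, one row per library.

    Requires ``clean == to_gene + to_genome + unknown`` for every library;
    the error names the offending library.
    """
    rows = []
    for _, rec in mapping.iterrows():
        clean = int(rec["clean"])
        parts = {c: int(rec[c]) for c in _MAPPING_CATEGORIES}
        if sum(parts.values()) != clean:
            raise ValueError(
                f"library {rec['library']}: clean={clean} but categories sum to "
                f"{sum(parts.values())}")
        row = {"library": rec["library"], "clean": clean}
        for cat, value in parts.items():
            row[f"pct_{cat}"] = 100.0 * value / clean
        rows.append(row)
    return pd.DataFrame(rows)


def tpm_normalize(counts: pd.DataFrame,
                  denominators: dict[str, float] | None = None) -> pd.DataFrame:
    """Scale each library to transcripts per million mapped tags.

    ``denominators`` defaults to the per-library column sums (the
    mapped-to-gene totals when the matrix covers all mapped genes); a zero
    denominator is an error.
    """
    out = counts[["gene_id"]].copy()
    for lib in LIBRARIES:
        denom = float(denominators[lib]) if denominators else float(counts[lib].sum())
        if denom <= 0:
            raise ValueError(f"library {lib}: nonpositive TPM denominator {denom}")
        out[lib] = counts[lib].to_numpy(dtype=float) / denom * 1e6
    return out


def saturation_curve(counts: pd.DataFrame, library: str,
                     depths: list[int] | None = None,
                     seed: int = 0, steps: int = 8) -> pd.DataFrame:
    """Detected-gene counts at increasing subsample depths.

    Tags are subsampled without replacement; the subsamples are nested
    (each depth extends the previous draw), so the curve is nondecreasing
    by construction and ends at the full-depth detection count.
    """
    vec = counts[library].to_numpy()
    if np.any(vec < 0):
        raise ValueError("counts must be nonnegative")
    vec = vec.astype(np.int64)
    total = int(vec.sum())
    if depths is None:
        depths = [max(1, round(total * (i + 1) / steps)) for i in range(steps)]
    depths = [int(d) for d in depths]
    if any(b <= a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be strictly increasing")
    if depths[-1] > total:
        raise ValueError(f"depth {depths[-1]} exceeds library total {total}")

    rng = np.random.default_rng(seed)
    remaining = vec.copy()
    drawn = np.zeros_like(vec)
    rows = []
    prev = 0
    for depth in depths:
        take = depth - prev
        sample = rng.multivariate_hypergeometric(remaining, take, method="marginals")
        drawn += sample
        remaining -= sample
        prev = depth
        rows.append({"depth": depth, "detected_genes": int((drawn > 0).sum())})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class NoiseDistribution:
    """Pooled within-condition replicate (|M0|, D0) pairs on the TPM scale."""

    abs_m0: np.ndarray
    d0: np.ndarray

    def __len__(self) -> int:
        return len(self.abs_m0)


def build_noise_distribution(tpm: pd.DataFrame,
                             pseudocount: float = 0.5) -> NoiseDistribution:
    """Replicate-vs-replicate noise cloud from both conditions.

    For every gene and each within-condition pair (W1R vs W2R, M1R vs M2R):
    ``|M0| = |log2((x1+k)/(x2+k))|`` and ``D0 = |x1 - x2|`` (D0 without the
    pseudocount, keeping it on the raw TPM scale).
    """
    pairs = [WT_LIBRARIES, MT_LIBRARIES]
    abs_m0, d0 = [], []
    for a, b in pairs:
        x1 = tpm[a].to_numpy(dtype=float)
        x2 = tpm[b].to_numpy(dtype=float)
        abs_m0.append(np.abs(np.log2((x1 + pseudocount) / (x2 + pseudocount))))
        d0.append(np.abs(x1 - x2))
    dist = NoiseDistribution(np.concatenate(abs_m0), np.concatenate(d0))
    if len(dist) == 0:
        raise ValueError("empty noise distribution")
    return dist


def noiseq_probability(m, d, noise: NoiseDistribution):
    """Fraction of noise points strictly below (|M|, D), per gene.

    Strict inequalities on both coordinates: ties count against
    significance.  Exact counting — a kernel-smoothed variant is
    deliberately not used, so results match an exhaustive oracle bit for
    bit.  Accepts scalars or arrays.
    """
    if len(noise) == 0:
        raise ValueError("empty noise distribution")
    m_arr = np.atleast_1d(np.asarray(m, dtype=float))
    d_arr = np.atleast_1d(np.asarray(d, dtype=float))
    abs_m = np.abs(m_arr)
    nm, nd = noise.abs_m0, noise.d0
    out = np.empty(len(abs_m))
    chunk = max(1, int(2e7) // max(len(nm), 1))
    for i in range(0, len(abs_m), chunk):
        sl = slice(i, min(i + chunk, len(abs_m)))
        below = (nm[None, :] < abs_m[sl, None]) & (nd[None, :] < d_arr[sl, None])
        out[sl] = below.sum(axis=1) / len(nm)
    return float(out[0]) if np.isscalar(m) or np.ndim(m) == 0 else out


def call_degs(results: pd.DataFrame, q_min: float = 0.8,
              m_min: float = 1.0) -> pd.DataFrame:
    """Direction calls from (M, probability): up / down / none."""
    out = results.copy()
    prob = out["probability"].to_numpy(dtype=float)
    m = out["M"].to_numpy(dtype=float)
    up = (prob >= q_min) & (m >= m_min)
    down = (prob >= q_min) & (m <= -m_min)
    out["call"] = np.where(up, "up", np.where(down, "down", "none"))
    return out


def deg_analysis(tpm: pd.DataFrame, q_min: float = 0.8, m_min: float = 1.0,
                 pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-gene (M, D, probability, call) for mutant vs wild type.

    M and D are computed on the condition means of TPM across the two
    replicates; the probability compares each gene against the pooled
    replicate noise cloud.
    """
    wt = tpm[list(WT_LIBRARIES)].mean(axis=1).to_numpy()
    mt = tpm[list(MT_LIBRARIES)].mean(axis=1).to_numpy()
    m = np.log2((mt + pseudocount) / (wt + pseudocount))
    d = np.abs(mt - wt)
    noise = build_noise_distribution(tpm, pseudocount=pseudocount)
    prob = noiseq_probability(m, d, noise)
    results = pd.DataFrame({"gene_id": tpm["gene_id"], "M": m, "D": d,
                            "probability": prob})
    return call_degs(results, q_min=q_min, m_min=m_min)


def replicate_correlation(tpm: pd.DataFrame,
                          pseudocount: float = 0.5) -> dict[str, float]:
    """Pearson r of log2(TPM + k) between replicate libraries, per
    condition.  Constant vectors give NaN."""
    if len(tpm) < 3:
        raise ValueError("need at least 3 genes")
    out = {}
    for cond, (a, b) in {"WT": WT_LIBRARIES, "MT": MT_LIBRARIES}.items():
        x = np.log2(tpm[a].to_numpy(dtype=float) + pseudocount)
        y = np.log2(tpm[b].to_numpy(dtype=float) + pseudocount)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[cond] = float("nan")
        else:
            out[cond] = float(stats.pearsonr(x, y).statistic)
    return out
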