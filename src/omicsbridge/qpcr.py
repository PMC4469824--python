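"""Relative qPCR quantification (2^-ddCt) and transcriptome concordance.

For each gene, dCt per condition group is the mean target Ct minus the
mean reference-gene Ct over that group's replicate wells; ddCt is
dCt(mutant) - dCt(wild type) and the relative quantity is
``rq = 2 ** -ddCt`` (amplification efficiency fixed at 2, the classic
Livak form).  A panel gene is concordant with the sequencing result when
the sign of log2 rq matches the sign of the gene's M statistic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def delta_delta_ct(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-gene dCt (both groups), ddCt, and rq = 2^-ddCt.

    ``measurements`` needs columns gene_id, group (WT/MT), replicate,
    ct_target, ct_reference; a gene missing either group is an error that
    names the gene.
    """
    rows = []
    for gene, sub in measurements.groupby("gene_id", sort=True):
        groups = set(sub["group"])
        missing = {"WT", "MT"} - groups
        if missing:
            raise ValueError(f"gene {gene}: missing group(s) {sorted(missing)}")
        dct = {}
        for group in ("WT", "MT"):
            g = sub[sub["group"] == group]
            dct[group] = float(g["ct_target"].mean() - g["ct_reference"].mean())
        ddct = dct["MT"] - dct["WT"]
        rows.append({"gene_id": gene, "delta_ct_wt": dct["WT"],
                     "delta_ct_mt": dct["MT"], "delta_delta_ct": ddct,
                     "rq": 2.0 ** (-ddct)})
    return pd.DataFrame(rows)


def concordance(rq_table: pd.DataFrame, deg_results: pd.DataFrame,
                panel: list[str]) -> dict:
    """Direction agreement between qPCR and the sequencing M statistic.

    A gene is concordant iff sign(log2 rq) == sign(M); zero against
    nonzero is discordant, zero against zero concordant.  Panel genes
    missing on either side are excluded and reported.  Returns
    ``{"concordant": k, "total": n, "table": per-gene verdicts,
    "missing": [...]}``.
    """
    rq = rq_table.set_index("gene_id")["rq"]
    m = deg_results.set_index("gene_id")["M"]
    rows, missing = [], []
    for gene in panel:
        if gene not in rq.index or gene not in m.index:
            missing.append(gene)
            continue
        log2_rq = float(np.log2(rq[gene]))
        sign_q = int(np.sign(log2_rq))
        sign_m = int(np.sign(m[gene]))
        rows.append({"gene_id": gene, "log2_rq": log2_rq, "M": float(m[gene]),
                     "concordant": sign_q == sign_m})
    table = pd.DataFrame(rows, columns=["gene_id", "log2_rq", "M", "concordant"])
    return {"concordant": int(table["concordant"].sum()) if len(table) else 0,
            "total": len(table), "table": table, "missing": missing}
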