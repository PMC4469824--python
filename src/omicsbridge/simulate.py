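"""Ground-truth simulator for the two-condition, two-replicate design.

Emulates the four inputs of the integrated proteome-transcriptome analysis:

* a peptide-level iTRAQ reporter-intensity table (channels 116/117 = wild
  type, 119/121 = mutant),
* per-library DGE tag counts with mapping-category totals,
* a qPCR Ct panel with a condition-invariant reference gene, and
* an optional GO annotation map (labelled synthetic).

The generative model: each locus has a baseline log2 abundance pair
(mRNA, protein) drawn from a bivariate normal with correlation ``rho``;
a per-locus biological condition effect pair with sd ``sigma_bio`` and the
same correlation ``rho``; and, for the DE fraction, a large effect with
magnitude uniform on ``effect_range`` whose protein counterpart equals the
mRNA effect plus independent jitter.  Measurement layers add lognormal
reporter noise, channel biases, and negative-binomial tag-count noise.

Each generator draws from its own child RNG stream seeded as
``(seed, stage_index)``, in a fixed documented order within each stage, so
identical configurations yield byte-identical tables and each stage is
independently reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    CHANNELS,
    LIBRARIES,
    MT_CHANNELS,
    MT_LIBRARIES,
    REFERENCE_GENE,
    ConfigError,
    SimulationConfig,
)

_STREAMS = {"truth": 0, "peptides": 1, "tags": 2, "qpcr": 3, "go": 4}

#: Small synthetic GO vocabulary per ontology (terms echo the field's usual
#: high-level categories).
GO_TERMS = {
    "biological_process": (
        "cellular process", "metabolic process", "regulation of biological process",
        "stress response", "developmental process", "transport",
        "signal transduction", "biogenesis",
    ),
    "molecular_function": (
        "catalytic activity", "binding", "transporter activity",
        "structural molecule activity", "transcription regulator activity",
        "antioxidant activity",
    ),
    "cellular_component": (
        "cell", "organelle", "membrane", "extracellular region",
        "macromolecular complex", "cell wall",
    ),
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([config.seed, _STREAMS[stage]])


def _gene_ids(n: int) -> list[str]:
    # Rice-style locus identifiers spread over 12 chromosomes.
    return [f"LOC_Os{(i % 12) + 1:02d}g{10000 + 10 * (i // 12):05d}" for i in range(n)]


def generate_truth(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the per-locus ground truth table.

    Columns: ``gene_id``, ``is_de``, ``true_log2fc_mrna``,
    ``true_log2fc_protein``, ``base_log_abundance_mrna``,
    ``base_log_abundance_protein``, ``bio_log2fc_mrna``,
    ``bio_log2fc_protein``.  Non-DE loci have both true effects exactly 0;
    the ``bio_*`` columns hold the rho-correlated biological condition
    effect every locus carries (zero when ``sigma_bio`` is 0).

    Draw order: DE membership, effect signs, effect magnitudes, protein
    jitter, baseline normals, biological-effect normals.
    """
    config.validate()
    rng = _rng(config, "truth") if rng is None else rng
    n = config.n_genes
    n_de = int(round(n * config.frac_de))

    de_idx = np.sort(rng.choice(n, size=n_de, replace=False))
    is_de = np.zeros(n, dtype=bool)
    is_de[de_idx] = True

    signs = np.concatenate([np.ones(n_de - n_de // 2), -np.ones(n_de // 2)])
    signs = rng.permutation(signs)
    low, high = config.effect_range
    magnitude = rng.uniform(low, high, size=n_de)
    jitter = rng.normal(0.0, 1.0, size=n_de) * config.protein_jitter_sd

    true_m = np.zeros(n)
    true_p = np.zeros(n)
    true_m[de_idx] = signs * magnitude
    true_p[de_idx] = true_m[de_idx] + jitter

    rho = config.rho
    mix = np.sqrt(max(0.0, 1.0 - rho * rho))
    z1 = rng.normal(0.0, 1.0, size=n)
    z2 = rng.normal(0.0, 1.0, size=n)
    base_m = config.base_log2_mean_mrna + config.base_log2_sd * z1
    base_p = config.base_log2_mean_protein + config.base_log2_sd * (rho * z1 + mix * z2)

    u1 = rng.normal(0.0, 1.0, size=n)
    u2 = rng.normal(0.0, 1.0, size=n)
    bio_m = config.sigma_bio * u1
    bio_p = config.sigma_bio * (rho * u1 + mix * u2)

    return pd.DataFrame({
        "gene_id": _gene_ids(n),
        "is_de": is_de,
        "true_log2fc_mrna": true_m,
        "true_log2fc_protein": true_p,
        "base_log_abundance_mrna": base_m,
        "base_log_abundance_protein": base_p,
        "bio_log2fc_mrna": bio_m,
        "bio_log2fc_protein": bio_p,
    })


def generate_reporter_intensities(truth: pd.DataFrame, config: SimulationConfig,
                                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Peptide-level reporter intensities for the four iTRAQ channels.

    Per protein, ``1 + Poisson(peptides_mean - 1)`` unique peptides; per
    peptide a shared ionization offset, an identification score, and
    independent lognormal channel noise.  Mutant channels (119, 121) carry
    the realized protein effect (true + biological).  Draw order: peptide
    counts, offsets, scores, channel noise.
    """
    if truth.empty:
        raise ConfigError("truth table is empty")
    rng = _rng(config, "peptides") if rng is None else rng
    n = len(truth)

    k = 1 + rng.poisson(max(config.peptides_mean - 1.0, 0.0), size=n)
    total = int(k.sum())
    gene_idx = np.repeat(np.arange(n), k)
    starts = np.concatenate(([0], np.cumsum(k)[:-1]))
    pep_no = np.arange(total) - np.repeat(starts, k) + 1

    offsets = rng.normal(0.0, 1.0, size=total) * config.peptide_log2_sd
    scores = rng.gamma(4.0, 12.0, size=total)  # mean 48; a tail below 20 feeds the filter
    noise = rng.normal(0.0, 1.0, size=(total, 4)) * config.sigma_reporter

    effect = (truth["true_log2fc_protein"].to_numpy()
              + truth["bio_log2fc_protein"].to_numpy())[gene_idx]
    base = truth["base_log_abundance_protein"].to_numpy()[gene_idx] + offsets

    protein_ids = (truth["gene_id"].astype(str) + ".1").to_numpy()[gene_idx]
    out = pd.DataFrame({
        "protein_id": protein_ids,
        "peptide_id": [f"{p}_pep{j}" for p, j in zip(protein_ids, pep_no)],
        "unique": True,
        "score": scores,
    })
    for ci, ch in enumerate(CHANNELS):
        shift = effect if ch in MT_CHANNELS else 0.0
        out[f"i{ch}"] = config.channel_factors[ci] * 2.0 ** (base + shift + noise[:, ci])
    return out


def generate_tag_counts(truth: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tag-count matrix plus the per-library mapping bookkeeping.

    Counts are negative binomial (Poisson in the zero-dispersion limit,
    expected values in ``exact_counts`` mode) around means proportional to
    ``2**(baseline + realized effect)``, scaled so each library's
    mapped-to-gene total matches ``lib_size * frac_to_gene``.
    """
    if truth.empty:
        raise ConfigError("truth table is empty")
    rng = _rng(config, "tags") if rng is None else rng

    base = truth["base_log_abundance_mrna"].to_numpy()
    effect = (truth["true_log2fc_mrna"].to_numpy()
              + truth["bio_log2fc_mrna"].to_numpy())

    counts = pd.DataFrame({"gene_id": truth["gene_id"].to_numpy()})
    mapping_rows = []
    for lib, size in zip(LIBRARIES, config.lib_sizes):
        shift = effect if lib in MT_LIBRARIES else 0.0
        w = 2.0 ** (base + shift)
        to_gene_target = int(round(size * config.frac_to_gene))
        mu = w / w.sum() * to_gene_target
        if config.exact_counts:
            col = mu
        elif config.nb_dispersion < 1e-12:
            col = rng.poisson(mu).astype(np.int64)
        else:
            r = 1.0 / config.nb_dispersion
            col = rng.negative_binomial(r, r / (r + mu)).astype(np.int64)
        counts[lib] = col

        to_gene = int(round(float(np.sum(col))))
        to_genome = int(round(size * config.frac_to_genome))
        unknown = size - to_gene - to_genome
        if unknown < 0:       # pathological draw; keep the identity intact
            to_genome += unknown
            unknown = 0
        mapping_rows.append({
            "library": lib,
            "raw": int(round(size / config.frac_clean)),
            "clean": int(size),
            "to_gene": to_gene,
            "to_genome": to_genome,
            "unknown": unknown,
        })
    return counts, pd.DataFrame(mapping_rows)


def generate_qpcr_panel(truth: pd.DataFrame, config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Ct table for a panel of DE loci plus the reference gene.

    Ct values are built so that the gene's ddCt equals minus its realized
    mRNA log2 fold change (plus ``N(0, sigma_ct)`` per-well noise); the
    ``actin`` reference row has a condition-invariant dCt expectation.
    """
    rng = _rng(config, "qpcr") if rng is None else rng
    de = truth.loc[truth["is_de"]]
    if config.n_qpcr_genes > len(de):
        raise ConfigError(
            f"n_qpcr_genes={config.n_qpcr_genes} exceeds the {len(de)} available DE genes")
    sel = np.sort(rng.choice(de.index.to_numpy(), size=config.n_qpcr_genes, replace=False))
    panel = truth.loc[sel]

    effect = (panel["true_log2fc_mrna"] + panel["bio_log2fc_mrna"]).to_numpy()
    # Higher-abundance transcripts cross threshold earlier (lower Ct).
    ct_wt = 32.0 - panel["base_log_abundance_mrna"].to_numpy()

    reps = config.qpcr_replicates
    rows: list[dict] = []

    def _well(gene: str, group: str, target_base: float, ref_base: float) -> None:
        for r in range(1, reps + 1):
            rows.append({
                "gene_id": gene,
                "group": group,
                "replicate": f"r{r}",
                "ct_target": target_base + config.sigma_ct * rng.normal(),
                "ct_reference": ref_base + config.sigma_ct * rng.normal(),
            })

    for gene, base_wt, eff in zip(panel["gene_id"], ct_wt, effect):
        _well(gene, "WT", base_wt, 20.0)
        _well(gene, "MT", base_wt - eff, 20.0)
    _well(REFERENCE_GENE, "WT", 20.0, 20.0)
    _well(REFERENCE_GENE, "MT", 20.0, 20.0)
    return pd.DataFrame(rows)


def generate_go_map(truth: pd.DataFrame, config: SimulationConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic GO annotation map (gene_id, ontology, term).

    A stand-in for an externally supplied annotation table: ~80% of loci are
    annotated per ontology, each with 1-3 terms, so multi-category
    membership occurs as it does in real annotation output.
    """
    rng = _rng(config, "go") if rng is None else rng
    rows: list[dict] = []
    genes = truth["gene_id"].to_numpy()
    for ontology, terms in GO_TERMS.items():
        annotated = rng.random(len(genes)) < 0.8
        n_terms = 1 + rng.integers(0, 3, size=len(genes))
        for gene, ann, nt in zip(genes, annotated, n_terms):
            if not ann:
                continue
            for term in rng.choice(terms, size=min(nt, len(terms)), replace=False):
                rows.append({"gene_id": gene, "ontology": ontology, "term": term})
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Generate every pipeline input in the fixed stage order.

    Returns a dict with keys ``truth``, ``peptides``, ``tags``, ``mapping``,
    ``qpcr``, ``go_map``.
    """
    truth = generate_truth(config)
    peptides = generate_reporter_intensities(truth, config)
    tags, mapping = generate_tag_counts(truth, config)
    qpcr = generate_qpcr_panel(truth, config)
    go_map = generate_go_map(truth, config)
    return {"truth": truth, "peptides": peptides, "tags": tags,
            "mapping": mapping, "qpcr": qpcr, "go_map": go_map}
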