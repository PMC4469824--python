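"""Configuration objects for the simulator and the end-to-end pipeline.

Two levels of configuration exist: :class:`SimulationConfig` parametrizes the
synthetic four-channel iTRAQ / four-library DGE dataset, and
:class:`PipelineConfig` wraps it together with every analysis cutoff
(peptide score filter, unique-peptide minimum, ratio p-value alpha,
fold-change threshold policy, DE-probability and log2-ratio bounds,
pseudocount, correlation type).  The analysis defaults are the study's
standard settings: score >= 20, >= 2 unique peptides, alpha = 0.05,
auto-derived fold-change threshold at the 95% replicate quantile,
probability >= 0.8 with |log2 ratio| >= 1, pseudocount 0.5.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

#: DGE library identifiers, in fixed column order: wild type then mutant.
LIBRARIES = ("W1R", "W2R", "M1R", "M2R")
WT_LIBRARIES = ("W1R", "W2R")
MT_LIBRARIES = ("M1R", "M2R")

#: iTRAQ reporter channels in fixed column order.  116/117 label the two
#: wild-type replicates, 119/121 the two mutant replicates.
CHANNELS = ("116", "117", "119", "121")
WT_CHANNELS = ("116", "117")
MT_CHANNELS = ("119", "121")

#: Identifier used for the qPCR internal-control (reference) gene.
REFERENCE_GENE = "actin"


class ConfigError(ValueError):
    """Raised when a configuration value violates its contract."""


def _as_tuple(value: Any, n: int, kind=float) -> tuple:
    t = tuple(kind(v) for v in value)
    if len(t) != n:
        raise ConfigError(f"expected {n} values, got {len(t)}: {value!r}")
    return t


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth generator parameters.

    Parameters
    ----------
    n_genes:
        Number of simulated loci; every locus yields both a transcript and a
        protein (one isoform, ``<gene_id>.1``).
    frac_de:
        Fraction of loci carrying a true differential-expression effect.
    effect_range:
        ``(low, high)`` bounds (log2 units, both positive) for the absolute
        true effect size; signs are split evenly between up and down.
    rho:
        Generative mRNA-protein coupling in [-1, 1].  It is applied at two
        levels: the baseline log-abundance pair of each locus, and the
        per-locus biological condition-effect pair (sd ``sigma_bio``).
    sigma_bio:
        Log2 sd of the per-locus biological condition effect shared by both
        replicates of the mutant condition.  Zero means the two conditions
        differ only at DE loci ("all-null" background).
    sigma_reporter:
        Log2 sd of the per-peptide, per-channel reporter-intensity noise.
    channel_factors:
        Four positive multiplicative channel biases (116, 117, 119, 121);
        removed downstream by median-ratio normalization.
    peptides_mean:
        Mean unique peptides per protein; counts are 1 + Poisson(mean - 1).
    peptide_log2_sd:
        Log2 sd of the per-peptide ionization offset (shared across channels).
    protein_jitter_sd:
        Log2 sd of the independent jitter separating a DE locus's protein
        effect from its mRNA effect.
    base_log2_sd, base_log2_mean_mrna, base_log2_mean_protein:
        Lognormal baseline abundance parameters (log2 scale).
    lib_sizes:
        Clean-tag totals of the four DGE libraries (W1R, W2R, M1R, M2R).
    frac_to_gene, frac_to_genome, frac_clean:
        Mapping bookkeeping: fraction of clean tags mapped to genes and to
        the genome (the remainder is unknown), and clean/raw tag ratio.
    nb_dispersion:
        Negative-binomial dispersion of tag counts (variance =
        mu + dispersion * mu**2); 0 selects the Poisson limit.
    exact_counts:
        Emit expected (real-valued) counts instead of sampling - the
        deterministic noise-free limit used by exact-recovery checks.
    n_qpcr_genes:
        Number of DE loci on the qPCR validation panel (the reference gene
        is always added on top).
    sigma_ct:
        Sd (cycles) of per-well Ct noise.
    qpcr_replicates:
        Ct measurements per gene and condition group.
    seed:
        Root seed; identical configs give byte-identical tables.
    """

    n_genes: int = 4000
    frac_de: float = 0.05
    effect_range: tuple[float, float] = (1.0, 3.0)
    rho: float = 0.35
    sigma_bio: float = 0.5
    sigma_reporter: float = 0.25
    channel_factors: tuple[float, float, float, float] = (1.0, 1.08, 0.95, 1.02)
    peptides_mean: float = 3.0
    peptide_log2_sd: float = 1.0
    protein_jitter_sd: float = 0.25
    base_log2_sd: float = 2.0
    base_log2_mean_mrna: float = 5.0
    base_log2_mean_protein: float = 10.0
    lib_sizes: tuple[int, int, int, int] = (3326656, 3511076, 3343333, 3299843)
    frac_to_gene: float = 0.73
    frac_to_genome: float = 0.14
    frac_clean: float = 0.96
    nb_dispersion: float = 0.02
    exact_counts: bool = False
    n_qpcr_genes: int = 20
    sigma_ct: float = 0.25
    qpcr_replicates: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_range", _as_tuple(self.effect_range, 2))
        object.__setattr__(self, "channel_factors", _as_tuple(self.channel_factors, 4))
        object.__setattr__(self, "lib_sizes", _as_tuple(self.lib_sizes, 4, int))
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if not 0.0 <= self.frac_de <= 1.0:
            raise ConfigError(f"frac_de must lie in [0, 1], got {self.frac_de}")
        low, high = self.effect_range
        if not (0.0 < low < high):
            raise ConfigError(f"effect_range must satisfy 0 < low < high, got {self.effect_range}")
        if not -1.0 <= self.rho <= 1.0:
            raise ConfigError(f"rho must lie in [-1, 1], got {self.rho}")
        for name in ("sigma_bio", "sigma_reporter", "peptide_log2_sd",
                     "protein_jitter_sd", "base_log2_sd", "nb_dispersion", "sigma_ct"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if any(f <= 0 for f in self.channel_factors):
            raise ConfigError("all channel_factors must be > 0")
        if self.peptides_mean < 1:
            raise ConfigError("peptides_mean must be >= 1")
        if any(s <= 0 for s in self.lib_sizes):
            raise ConfigError("all lib_sizes must be > 0")
        if not 0.0 < self.frac_to_gene < 1.0 or not 0.0 < self.frac_to_genome < 1.0:
            raise ConfigError("mapping fractions must lie in (0, 1)")
        if self.frac_to_gene + self.frac_to_genome >= 1.0:
            raise ConfigError("frac_to_gene + frac_to_genome must be < 1")
        if not 0.0 < self.frac_clean <= 1.0:
            raise ConfigError("frac_clean must lie in (0, 1]")
        if self.n_qpcr_genes < 0:
            raise ConfigError("n_qpcr_genes must be >= 0")
        if self.qpcr_replicates < 1:
            raise ConfigError("qpcr_replicates must be >= 1")

    def replace(self, **changes: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("effect_range", "channel_factors", "lib_sizes"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**dict(d))


@dataclass(frozen=True)
class ProteomeParams:
    min_score: float = 20.0
    min_unique_peptides: int = 2
    alpha: float = 0.05
    threshold: float | str = "auto"   # "auto" derives it from replicate variation
    quantile: float = 0.95
    min_threshold: float = 1.0
    round_up_to: float | None = None

    def __post_init__(self) -> None:
        if isinstance(self.threshold, str) and self.threshold != "auto":
            raise ConfigError("threshold must be a positive number or 'auto'")
        if not isinstance(self.threshold, str) and self.threshold < 1:
            raise ConfigError("a fixed threshold must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0.0 < self.quantile < 1.0:
            raise ConfigError("quantile must lie in (0, 1)")


@dataclass(frozen=True)
class TranscriptomeParams:
    q_min: float = 0.8
    m_min: float = 1.0
    pseudocount: float = 0.5
    saturation_steps: int = 8

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_min <= 1.0:
            raise ConfigError("q_min must lie in [0, 1]")
        if self.m_min < 0 or self.pseudocount < 0:
            raise ConfigError("m_min and pseudocount must be >= 0")


@dataclass(frozen=True)
class IntegrationParams:
    correlation: str = "pearson"      # or "spearman"
    relaxed_mrna_log2: float = 1.0    # relaxed mRNA filter: ratio >= 2, no probability bound

    def __post_init__(self) -> None:
        if self.correlation not in ("pearson", "spearman"):
            raise ConfigError("correlation must be 'pearson' or 'spearman'")


@dataclass(frozen=True)
class PipelineConfig:
    """Full pipeline configuration; defaults are the study's printed cutoffs."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    proteome: ProteomeParams = field(default_factory=ProteomeParams)
    transcriptome: TranscriptomeParams = field(default_factory=TranscriptomeParams)
    integration: IntegrationParams = field(default_factory=IntegrationParams)

    @property
    def seed(self) -> int:
        return self.simulation.seed

    def replace_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(self, simulation=self.simulation.replace(seed=seed))

    def to_dict(self) -> dict:
        return {
            "simulation": self.simulation.to_dict(),
            "proteome": dataclasses.asdict(self.proteome),
            "transcriptome": dataclasses.asdict(self.transcriptome),
            "integration": dataclasses.asdict(self.integration),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        known = {"simulation", "proteome", "transcriptome", "integration"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
        return cls(
            simulation=SimulationConfig.from_dict(d.get("simulation", {})),
            proteome=ProteomeParams(**d.get("proteome", {})),
            transcriptome=TranscriptomeParams(**d.get("transcriptome", {})),
            integration=IntegrationParams(**d.get("integration", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
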