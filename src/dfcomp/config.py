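"""Configuration for the synthetic deficiency-panel generator.

The defaults describe a DrosDel-like screen on one chromosome arm: a tiling
panel of hemizygous deletion (Df/+) genotypes assayed in two sexes and two
genetic backgrounds with biological duplicates, negative-binomial counts,
ERCC-style spike-in subpools at known 1:1 / 1:1.5 / 1.5:1 ratios, gene-specific
dosage-compensation coefficients, a female-only compensation boost inside
repressive chromatin, and secondary expression changes propagated through a
gene-interaction network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import yaml


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class MixtureComponent:
    """One component of the true-compensation (c_g) mixture.

    ``kind`` is one of ``point`` (params: value), ``beta`` (params: a, b, lo,
    hi -- a Beta(a, b) draw rescaled to [lo, hi]) or ``uniform`` (params: lo,
    hi).  c_g = 0 means no compensation (one-copy expression is half the
    two-copy level), c_g = 1 full compensation, c_g < 0 anti-compensation and
    c_g > 1 over-compensation.
    """

    weight: float
    kind: str
    params: tuple[float, ...]


DEFAULT_MIXTURE: tuple[MixtureComponent, ...] = (
    MixtureComponent(0.60, "beta", (2.0, 2.0, 0.05, 0.60)),   # broad partial
    MixtureComponent(0.20, "point", (0.0,)),                  # none
    MixtureComponent(0.10, "point", (1.0,)),                  # full
    MixtureComponent(0.05, "uniform", (-0.5, 0.0)),           # anti
    MixtureComponent(0.05, "uniform", (1.0, 1.5)),            # over
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic Df/+ panel.

    Coordinates are 0-based half-open (BED convention) throughout.
    """

    n_genes: int = 2500
    n_intergenic: int = 150
    chrom: str = "2L"
    chrom_length: int = 25_000_000
    n_dfs: int = 40
    df_length_range: tuple[int, int] = (200_000, 1_000_000)
    sexes: Sequence[str] = ("female", "male")
    backgrounds: Sequence[str] = ("isogenic", "hybrid")
    replicates: int = 2
    # natural-log mean/sd of the per-gene baseline expression weight
    base_expression: tuple[float, float] = (4.0, 1.5)
    # intergenic probe weight relative to the mean gene weight
    intergenic_level: float = 0.002
    library_size: int = 10_000_000
    depth_sd: float = 0.1
    dispersion: float = 0.05
    compensation_mixture: tuple[MixtureComponent, ...] = DEFAULT_MIXTURE
    female_repressive_boost: float = 0.5
    repressive_states: Sequence[str] = ("Rep", "LamB")
    sex_biased_fraction: float = 0.2
    sex_effect_log2: float = 1.0
    background_sd: float = 0.1
    propagation_alpha: float = 0.5
    propagation_depth: int = 3
    propagation_noise_sd: float = 0.1
    # preferential-attachment backbone: m edges per new node (m=1 gives a
    # sparse tree-like power-law network typical of high-confidence
    # interaction backbones)
    network_m: int = 1
    # the interaction network spans a genome this many times larger than the
    # profiled arm; unprofiled genes participate in topology only
    network_genome_factor: int = 5
    domain_mean_length: int = 400_000
    spikein_n_per_pool: int = 8
    spikein_total_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_dfs < 1:
            raise ConfigurationError("at least one deletion is required")
        if self.replicates < 2:
            raise ConfigurationError("biological duplicates (>=2) are required")
        lo, hi = self.df_length_range
        if not (0 < lo <= hi):
            raise ConfigurationError("invalid df_length_range")
        if hi >= self.chrom_length:
            raise ConfigurationError(
                "deletions may not be longer than the chromosome arm"
            )
        w = sum(c.weight for c in self.compensation_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ConfigurationError(
                f"compensation mixture weights sum to {w}, expected 1"
            )
        if self.dispersion < 0:
            raise ConfigurationError("dispersion must be >= 0")
        if not 0 <= self.spikein_total_fraction < 1:
            raise ConfigurationError("spikein_total_fraction must be in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "compensation_mixture" in raw:
            raw["compensation_mixture"] = tuple(
                MixtureComponent(c["weight"], c["kind"], tuple(c["params"]))
                for c in raw["compensation_mixture"]
            )
        for key in ("df_length_range", "base_expression"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)
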