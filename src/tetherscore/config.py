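"""Configuration objects for the simulator, estimator and pipeline.

All tunable parameters of the screen live here, with the analysis
thresholds of this screen design as defaults: the 32-read gate filter, the 1,000-read
coverage threshold, the |score| > 1 active set, 75% domain coverage, 90%/50%
similarity collapsing and the q < 0.05 reporting cutoff. Configs round-trip
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml
from scipy.stats import norm

from .errors import ConfigError

__all__ = [
    "LibraryConfig",
    "ScreenConfig",
    "GateBoundaries",
    "EstimatorConfig",
    "EnrichmentConfig",
    "PipelineConfig",
    "load_config",
    "save_config",
]


@dataclass
class GateBoundaries:
    """Three ordered fluorescence cut points (population-z units).

    The four FACS gates are ``(-inf, c1], (c1, c2], (c2, c3], (c3, inf)``,
    ordered low -> high YFP/RFP ratio. The screen sorts at the *empirical*
    quartiles of the pooled population; :meth:`theoretical` exposes the
    standard-normal quartile cuts (-0.6745, 0, +0.6745) for analytic work.
    """

    cut_z: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.cut_z = tuple(float(c) for c in self.cut_z)  # type: ignore[assignment]
        if len(self.cut_z) != 3:
            raise ConfigError("GateBoundaries requires exactly 3 cut points")
        if not (self.cut_z[0] < self.cut_z[1] < self.cut_z[2]):
            raise ConfigError(f"gate cuts must be strictly increasing, got {self.cut_z}")

    @classmethod
    def theoretical(cls) -> "GateBoundaries":
        """Equal-occupancy cuts for a standard-normal population."""
        return cls(tuple(norm.ppf([0.25, 0.5, 0.75])))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.cut_z, dtype=float)


@dataclass
class LibraryConfig:
    """Parameters of the synthetic genome and barcoded fragment library.

    Defaults mirror the screen: ~500 bp fragments (size selection after
    tagmentation), three 25-nt barcodes per fragment on average, and a
    compact intron-free genome with CDSs on both strands. ``n_fragments``
    counts raw tagmentation fragments before in-frame selection (~50,000
    fragments were analyzed in the screen).
    """

    n_fragments: int = 50_000
    fragment_size_mean: float = 500.0
    fragment_size_sd: float = 150.0
    mean_barcodes_per_fragment: float = 3.0
    #: target fraction of in-frame fragments with true activity exactly 0
    frac_null_fragments: float = 0.60
    #: |effect| range (population-z units) for regulatory elements
    effect_size_range: tuple[float, float] = (0.5, 4.2)
    # --- synthetic genome geometry ---
    n_genes: int = 150
    genome_length: int = 260_000
    protein_length_mean: float = 400.0
    protein_length_sd: float = 100.0
    protein_length_min: int = 150
    #: length of an embedded regulatory element, in amino acids
    element_length: int = 60
    #: fraction of an element a fragment must cover to inherit its effect
    element_coverage_threshold: float = 0.75
    #: number of distinct element families (domain-style labels)
    n_element_families: int = 8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.effect_size_range = tuple(float(e) for e in self.effect_size_range)  # type: ignore[assignment]
        if self.n_fragments < 0:
            raise ConfigError("n_fragments must be non-negative")
        for name in ("fragment_size_mean", "mean_barcodes_per_fragment", "n_genes",
                     "genome_length", "protein_length_mean", "element_length"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.fragment_size_sd < 0:
            raise ConfigError("fragment_size_sd must be non-negative")
        if not 0.0 <= self.frac_null_fragments <= 1.0:
            raise ConfigError("frac_null_fragments must lie in [0, 1]")
        lo, hi = self.effect_size_range
        if not 0 <= lo <= hi:
            raise ConfigError("effect_size_range must satisfy 0 <= low <= high")
        if not 0.0 < self.element_coverage_threshold <= 1.0:
            raise ConfigError("element_coverage_threshold must lie in (0, 1]")


@dataclass
class ScreenConfig:
    """Parameters of the pooled sort-seq screen simulation.

    The sort splits the pooled population into four equal-occupancy gates by
    YFP/RFP log-ratio; ~2 million cells per gate were sorted in the screen.
    The default here is desk-scale: cell numbers are reduced far more than
    read numbers so the absolute read-count thresholds of the analysis (32
    per gate, 1,000 total) keep their meaning while counting noise matches
    the between-replicate agreement of the screen (see docs/methods.md).
    """

    n_cells_per_gate: int = 3_600
    n_gates: int = 4
    #: within-fragment fluorescence spread, population-z units (fixed at 1)
    within_fragment_sd: float = 1.0
    reads_total: int = 6_000_000
    per_gate_depth_factors: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    #: Dirichlet concentration per barcode for library abundance skew
    barcode_abundance_dispersion: float = 2.0
    #: replicate-2 activity scale (gamma < 1 compresses/saturates extremes)
    replicate_scale: float = 0.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.per_gate_depth_factors = tuple(float(d) for d in self.per_gate_depth_factors)  # type: ignore[assignment]
        if self.n_gates != 4:
            raise ConfigError("the screen sorts into exactly 4 gates")
        if len(self.per_gate_depth_factors) != 4 or any(d <= 0 for d in self.per_gate_depth_factors):
            raise ConfigError("per_gate_depth_factors must be 4 positive scalars")
        if self.replicate_scale < 0:
            raise ConfigError("replicate_scale must be non-negative")
        if self.within_fragment_sd <= 0:
            raise ConfigError("within_fragment_sd must be positive")
        if self.n_cells_per_gate <= 0 or self.reads_total < 0:
            raise ConfigError("cell and read counts must be non-negative")
        if self.barcode_abundance_dispersion <= 0:
            raise ConfigError("barcode_abundance_dispersion must be positive")


@dataclass
class EstimatorConfig:
    """Parameters of the activity-score estimator and its filters."""

    sigma_w: float = 1.0
    mu_bounds: tuple[float, float] = (-3.0, 3.0)
    pseudocount: float = 1.0
    min_gate_count: int = 32
    min_total_reads_replicate_corr: int = 1_000
    #: '>=32 in some gate' (as implemented) vs '>=32 in every gate'
    gate_filter_mode: str = "any_gate"
    #: cut points used by the estimator; None -> standard-normal quartiles
    boundaries: Optional[GateBoundaries] = None
    #: per-gate depth normalizers; None -> estimated from gate read totals
    depth_factors: Optional[tuple[float, float, float, float]] = None

    def __post_init__(self) -> None:
        self.mu_bounds = tuple(float(b) for b in self.mu_bounds)  # type: ignore[assignment]
        if self.depth_factors is not None:
            self.depth_factors = tuple(float(d) for d in self.depth_factors)  # type: ignore[assignment]
        if self.sigma_w <= 0:
            raise ConfigError("sigma_w must be positive")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be >= 0")
        lo, hi = self.mu_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigError("mu_bounds must be finite and ordered")
        if self.min_gate_count <= 0 or self.min_total_reads_replicate_corr <= 0:
            raise ConfigError("count thresholds must be positive integers")
        if self.gate_filter_mode not in ("any_gate", "every_gate"):
            raise ConfigError("gate_filter_mode must be 'any_gate' or 'every_gate'")


@dataclass
class EnrichmentConfig:
    """Thresholds for the domain/motif/PPI/RBP analyses."""

    active_score_threshold: float = 1.0
    domain_coverage_threshold: float = 0.75
    collapse_similarity_domains: float = 0.9
    collapse_similarity_motifs: float = 0.5
    similarity_metric: str = "jaccard"  # or "containment"
    q_threshold: float = 0.05
    rbp_min_datasets: int = 2
    entropy_threshold_bits: float = 1.5
    ppi_granularity: str = "fragment"  # or "gene"

    def __post_init__(self) -> None:
        if self.similarity_metric not in ("jaccard", "containment"):
            raise ConfigError("similarity_metric must be 'jaccard' or 'containment'")
        if self.ppi_granularity not in ("fragment", "gene"):
            raise ConfigError("ppi_granularity must be 'fragment' or 'gene'")
        for name in ("domain_coverage_threshold", "collapse_similarity_domains",
                     "collapse_similarity_motifs", "q_threshold"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1]")


@dataclass
class PipelineConfig:
    """Top-level configuration tying all stages together."""

    library: LibraryConfig = field(default_factory=LibraryConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    estimator: EstimatorConfig = field(default_factory=EstimatorConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    seed: int = 0
    log_level: str = "INFO"

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Return a copy with the global seed propagated to every stage."""
        new = dataclasses.replace(self)
        new.seed = int(seed)
        new.library = dataclasses.replace(self.library, rng_seed=int(seed))
        new.screen = dataclasses.replace(self.screen, rng_seed=int(seed))
        return new


# ---------------------------------------------------------------------------
# serialization


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


_SECTIONS = {
    "library": LibraryConfig,
    "screen": ScreenConfig,
    "estimator": EstimatorConfig,
    "enrichment": EnrichmentConfig,
}


def config_to_dict(cfg: PipelineConfig) -> dict:
    return _to_plain(cfg)


def config_from_dict(data: dict) -> PipelineConfig:
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = dict(data.get(name, {}))
        if name == "estimator" and section.get("boundaries") is not None:
            section["boundaries"] = GateBoundaries(**section["boundaries"])
        kwargs[name] = cls(**section)
    return PipelineConfig(
        seed=int(data.get("seed", 0)),
        log_level=str(data.get("log_level", "INFO")),
        **kwargs,
    )


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})
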