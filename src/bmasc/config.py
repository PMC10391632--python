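"""Parameter blocks for every pipeline stage.

All thresholds that come from the published analysis protocol are the
dataclass defaults; synthetic-world overrides live in the caller's config,
never here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "QCThresholds",
    "StabilityGrid",
    "MarkerRule",
    "TFParams",
    "LineageParams",
]


class ConfigError(ValueError):
    """Invalid stage configuration."""


# diagnostic markers of non-ASC contaminants: T cells (CD3E), NK cells
# (NKG7, GNLY), monocytes (CD14, FCGR3A/CD16), erythrocytes (HBB),
# B cells (MS4A1/CD20, PAX5, IRF8)
CONTAMINANT_MARKERS = (
    "CD3E", "FCGR3A", "CD14", "NKG7", "GNLY", "HBB", "MS4A1", "PAX5", "IRF8",
)


@dataclass
class SimulationConfig:
    """Stated world of the paired expression + repertoire simulation.

    Negative-binomial UMI counts with cluster-specific marker genes,
    ASC-typical mitochondrial and immunoglobulin UMI fractions, a small
    contaminant admixture, and a clonally structured heavy-chain
    repertoire mutated away from germline at ``v_mutation_rate``.
    """

    n_cells: int = 1000
    n_genes: int = 800
    n_clusters: int = 8
    cluster_proportions: Sequence[float] | None = None  # default: equal
    nb_mean_base: float = 2.0
    nb_dispersion: float = 0.5  # var = mu + dispersion * mu^2
    marker_genes_per_cluster: int = 10
    marker_fold_change: float = 4.0
    # ASCs devote most of their transcriptome to Ig; mito load is modest
    mito_fraction_range: tuple[float, float] = (0.02, 0.15)
    ig_fraction_range: tuple[float, float] = (0.40, 0.80)
    contaminant_fraction: float = 0.02
    n_lineages: int = 200
    lineage_size_power: float = 2.0  # Zipf exponent for lineage sizes
    v_mutation_rate: float = 0.07  # per-base; BM ASC SHM averages ~7%
    within_lineage_divergence: float = 0.04  # per-base CDR3 divergence
    cdr3_length_range: tuple[int, int] = (30, 60)
    vdj_match_rate: float = 0.83  # fraction of cells with a VDJ record
    n_mito_genes: int = 10
    n_ig_genes: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells", "n_genes", "n_clusters", "n_lineages",
                     "marker_genes_per_cluster", "n_mito_genes", "n_ig_genes"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cluster_proportions is None:
            self.cluster_proportions = tuple(
                [1.0 / self.n_clusters] * self.n_clusters)
        props = np.asarray(self.cluster_proportions, dtype=float)
        if props.size != self.n_clusters:
            raise ConfigError("cluster_proportions length != n_clusters")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError("cluster_proportions must sum to 1")
        for name in ("contaminant_fraction", "v_mutation_rate",
                     "within_lineage_divergence", "vdj_match_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for name in ("mito_fraction_range", "ig_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigError(f"{name} must be an interval within [0, 1]")
        lo, hi = self.cdr3_length_range
        if lo < 3 or hi < lo:
            raise ConfigError("cdr3_length_range must span >= 3 nt")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs of the published protocol.

    A cell is removed when mito_fraction >= mito_max, n_genes <=
    genes_min_exclusive, n_umi <= umi_min_exclusive, n_genes >=
    genes_max_inclusive_cut, n_umi >= umi_max_inclusive_cut (doublet
    control), or ig_fraction <= ig_fraction_min (non-ASC admixture).
    """

    mito_max: float = 0.30
    genes_min_exclusive: int = 800
    umi_min_exclusive: int = 1000
    genes_max_inclusive_cut: int = 6000
    umi_max_inclusive_cut: int = 60000
    ig_fraction_min: float = 0.05
    contaminant_markers: tuple[str, ...] = CONTAMINANT_MARKERS
    contaminant_min_umi: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.genes_min_exclusive < self.genes_max_inclusive_cut:
            raise ConfigError("gene thresholds must satisfy 0 < min < max")
        if not 0 < self.umi_min_exclusive < self.umi_max_inclusive_cut:
            raise ConfigError("UMI thresholds must satisfy 0 < min < max")
        for name in ("mito_max", "ig_fraction_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class StabilityGrid:
    """Clustering-parameter grid swept for Rand-Index stability."""

    dims: tuple[int, ...] = (50, 60, 70)
    pcs: tuple[int, ...] = (30, 50, 70)
    resolutions: tuple[float, ...] = (0.2, 0.5, 1.0, 1.5)

    def __post_init__(self) -> None:
        for name in ("dims", "pcs", "resolutions"):
            vals = getattr(self, name)
            if len(vals) == 0 or any(v <= 0 for v in vals):
                raise ConfigError(f"{name} must be non-empty and positive")

    def points(self) -> list[tuple[int, int, float]]:
        return [(d, p, r) for d in self.dims for p in self.pcs
                for r in self.resolutions]


@dataclass
class MarkerRule:
    """Marker-gene significance rule: avgLogFC > lfc_min (natural log)
    and Bonferroni-adjusted p < alpha."""

    lfc_min: float = 0.25
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_min < 0:
            raise ConfigError("lfc_min must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass
class TFParams:
    """Transcription-factor selection and assignment thresholds."""

    min_frac_any_cluster: float = 0.10
    min_frac_assigned: float = 0.20
    distinct_lfc: float = 0.25  # natural log
    min_combined_score: int = 500

    def __post_init__(self) -> None:
        for name in ("min_frac_any_cluster", "min_frac_assigned"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.distinct_lfc < 0:
            raise ConfigError("distinct_lfc must be >= 0")


@dataclass
class LineageParams:
    """Clonal-lineage definition: same V, J, CDR3 length, then
    single-linkage merging at ``lineage_homology`` CDR3 identity;
    identical clones tracked at ``clone_homology``."""

    lineage_homology: float = 0.85
    clone_homology: float = 0.98
    linkage: str = "single"  # or "complete"
    on_amino_acid: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.lineage_homology <= 1.0:
            raise ConfigError("lineage_homology must be in (0, 1]")
        if not self.lineage_homology <= self.clone_homology <= 1.0:
            raise ConfigError("clone_homology must be >= lineage_homology")
        if self.linkage not in ("single", "complete"):
            raise ConfigError("linkage must be 'single' or 'complete'")
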