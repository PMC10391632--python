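"""Cell- and gene-level quality control.

Implements the exact published filters: mitochondrial-fraction,
detected-gene and UMI floors, doublet caps, the immunoglobulin-fraction
floor that removes non-ASC admixture, contaminant-marker flagging, and
the exclusion of Ig genes from variable-feature lists.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .config import QCThresholds

log = logging.getLogger(__name__)

__all__ = [
    "is_mito_gene",
    "is_ig_gene",
    "compute_cell_qc",
    "apply_qc_filters",
    "flag_contaminants",
    "exclude_ig_genes",
]

QC_RULES = ("mito_high", "genes_low", "umi_low",
            "genes_high", "umi_high", "ig_low")

# Ig locus stems followed by a segment/constant-class letter; a naive
# 3-letter prefix would misclassify IGF* growth-factor genes.
_IG_SEGMENT_LETTERS = set("VDJGAMEC")


def is_mito_gene(symbol: str) -> bool:
    return symbol.startswith("MT-")


def is_ig_gene(symbol: str) -> bool:
    """True for immunoglobulin locus genes (IGH/IGK/IGL followed by a
    V/D/J segment or constant-class letter), False for e.g. IGFBP3."""
    if len(symbol) < 4 or symbol[:2] != "IG" or symbol[2] not in "HKL":
        return False
    return symbol[3] in _IG_SEGMENT_LETTERS


def _to_dense_colsum(x, mask: np.ndarray) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x[:, mask].sum(axis=1)).ravel()
    return np.asarray(x[:, mask]).sum(axis=1)


def compute_cell_qc(counts: AnnData) -> pd.DataFrame:
    """Per-cell QC metrics: total UMIs, detected genes, mitochondrial and
    immunoglobulin UMI fractions.

    Cells with zero total UMIs get fractions of 0; they are removed
    downstream by the UMI floor regardless.
    """
    symbols = counts.var_names.to_numpy()
    mito = np.array([is_mito_gene(s) for s in symbols])
    ig = np.array([is_ig_gene(s) for s in symbols])
    x = counts.X
    if sparse.issparse(x):
        n_umi = np.asarray(x.sum(axis=1)).ravel()
        n_genes = np.asarray((x > 0).sum(axis=1)).ravel()
    else:
        n_umi = np.asarray(x).sum(axis=1)
        n_genes = (np.asarray(x) > 0).sum(axis=1)
    total = np.where(n_umi > 0, n_umi, 1.0)
    metrics = pd.DataFrame(
        {
            "n_umi": n_umi.astype(np.int64),
            "n_genes": n_genes.astype(np.int64),
            "mito_fraction": _to_dense_colsum(x, mito) / total,
            "ig_fraction": _to_dense_colsum(x, ig) / total,
        },
        index=counts.obs_names,
    )
    return metrics


def apply_qc_filters(
    metrics: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.Series, dict[str, int]]:
    """Apply the published removal rules to per-cell metrics.

    Returns (keep mask ordered as input, per-rule removal counts). A cell
    is attributed to every rule it violates, so counts may overlap.
    Boundary semantics follow the protocol text literally: values at 800
    genes / 1000 UMIs / 30% mito / 5% Ig are removed (<= or >=), as are
    cells at the 6000-gene / 60000-UMI doublet caps.
    """
    t = thresholds if thresholds is not None else QCThresholds()
    violations = {
        "mito_high": metrics["mito_fraction"] >= t.mito_max,
        "genes_low": metrics["n_genes"] <= t.genes_min_exclusive,
        "umi_low": metrics["n_umi"] <= t.umi_min_exclusive,
        "genes_high": metrics["n_genes"] >= t.genes_max_inclusive_cut,
        "umi_high": metrics["n_umi"] >= t.umi_max_inclusive_cut,
        "ig_low": metrics["ig_fraction"] <= t.ig_fraction_min,
    }
    removed = pd.Series(False, index=metrics.index)
    counts: dict[str, int] = {}
    for rule, mask in violations.items():
        counts[rule] = int(mask.sum())
        removed |= mask
    keep = ~removed
    keep.name = "keep"
    return keep, counts


def flag_contaminants(
    counts: AnnData,
    markers: tuple[str, ...] | list[str] | None = None,
    min_umi: int = 1,
) -> pd.Series:
    """Flag cells expressing any diagnostic non-ASC marker at >= min_umi.

    Markers absent from the annotation are logged and skipped; an empty
    marker list yields no flags (with a warning).
    """
    if markers is None:
        markers = list(QCThresholds().contaminant_markers)
    markers = list(markers)
    if not markers:
        log.warning("empty contaminant marker list: no cells flagged")
        return pd.Series(False, index=counts.obs_names, name="contaminant")
    present = [m for m in markers if m in counts.var_names]
    missing = sorted(set(markers) - set(present))
    if missing:
        log.warning("contaminant markers absent from annotation: %s", missing)
    if not present:
        return pd.Series(False, index=counts.obs_names, name="contaminant")
    idx = counts.var_names.get_indexer(present)
    x = counts.X[:, idx]
    if sparse.issparse(x):
        flagged = np.asarray((x >= min_umi).sum(axis=1)).ravel() > 0
    else:
        flagged = (np.asarray(x) >= min_umi).any(axis=1)
    return pd.Series(flagged, index=counts.obs_names, name="contaminant")


def exclude_ig_genes(symbols: list[str]) -> list[str]:
    """Drop immunoglobulin genes from a symbol list (order preserved),
    as done for highly-variable-feature lists before clustering."""
    return [s for s in symbols if not is_ig_gene(s)]
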