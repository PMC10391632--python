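"""Rand-Index clustering stability over a parameter grid.

The published protocol reclusters the data at every combination of
anchoring dimensions, principal components and resolution, then scores
agreement between every pair of resulting labelings with the plain Rand
Index: the proportion of cell pairs that are either co-clustered in
both labelings or separated in both. Clustering itself is a pluggable
contract; two labelers are bundled (a pass-through for precomputed
label files and a PCA + kNN-graph + greedy-modularity labeler for
synthetic demonstrations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import comb

from .config import StabilityGrid
from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "rand_index",
    "adjusted_rand",
    "stability_grid",
    "StabilityResult",
    "precomputed_labeler",
    "knn_modularity_labeler",
]

GridPoint = tuple[int, int, float]


def _as_labels(x) -> tuple[np.ndarray, np.ndarray | None]:
    if isinstance(x, pd.Series):
        return x.to_numpy(), x.index.to_numpy()
    return np.asarray(x), None


def rand_index(a, b) -> float:
    """Plain (unadjusted) Rand Index between two labelings of the same
    cells: agreeing pairs / all pairs, in [0, 1].

    Series inputs are aligned on their cell index; mismatched cell sets
    or fewer than two cells raise InputError. Symmetric and invariant to
    relabeling.
    """
    av, ai = _as_labels(a)
    bv, bi = _as_labels(b)
    if ai is not None and bi is not None:
        if len(ai) != len(bi) or set(ai) != set(bi):
            raise InputError("labelings cover different cell sets")
        bv = pd.Series(bv, index=bi).reindex(ai).to_numpy()
    if av.size != bv.size:
        raise InputError("labelings have different lengths")
    n = av.size
    if n < 2:
        raise InputError("need at least two cells")
    # contingency-table combinatorics: agreements = C(n,2) - togetherA
    # - togetherB + 2 * togetherBoth
    _, ai_codes = np.unique(av, return_inverse=True)
    _, bi_codes = np.unique(bv, return_inverse=True)
    contingency = pd.crosstab(ai_codes, bi_codes).to_numpy()
    nij2 = comb(contingency, 2).sum()
    a2 = comb(contingency.sum(axis=1), 2).sum()
    b2 = comb(contingency.sum(axis=0), 2).sum()
    total = comb(n, 2)
    return float((total - a2 - b2 + 2 * nij2) / total)


def adjusted_rand(a, b) -> float:
    """Chance-corrected Rand Index (for comparisons against synthetic
    ground truth only; the stability protocol uses the plain RI)."""
    from sklearn.metrics import adjusted_rand_score
    av, _ = _as_labels(a)
    bv, _ = _as_labels(b)
    return float(adjusted_rand_score(av, bv))


@dataclass
class StabilityResult:
    ri_matrix: pd.DataFrame  # grid point x grid point, unit diagonal
    mean_ri: float | None  # arithmetic mean over unordered pairs
    failures: list  # (grid point, error message)


def _point_name(point: GridPoint) -> str:
    d, p, r = point
    return f"dim{d}_pc{p}_res{r:g}"


def stability_grid(labeler: Callable[[GridPoint], pd.Series | np.ndarray],
                   grid: StabilityGrid | None = None) -> StabilityResult:
    """Run the labeler at every grid point and score all unordered pairs
    of labelings with the Rand Index.

    Labeler failures are recorded and their pairs skipped; the mean RI
    is the arithmetic mean over the remaining pairs (None when fewer
    than two labelings succeed, e.g. a single-point grid).
    """
    grid = grid if grid is not None else StabilityGrid()
    points = grid.points()
    labelings: dict[str, np.ndarray | pd.Series] = {}
    failures = []
    for point in points:
        name = _point_name(point)
        try:
            labelings[name] = labeler(point)
        except Exception as exc:  # noqa: BLE001 - contract: record and skip
            log.warning("labeler failed at %s: %s", name, exc)
            failures.append((name, str(exc)))
    names = list(labelings)
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    values = []
    for i, ni in enumerate(names):
        mat.loc[ni, ni] = 1.0
        for nj in names[i + 1:]:
            ri = rand_index(labelings[ni], labelings[nj])
            mat.loc[ni, nj] = mat.loc[nj, ni] = ri
            values.append(ri)
    mean_ri = float(np.mean(values)) if values else None
    if mean_ri is None:
        log.warning("fewer than two labelings; mean RI not applicable")
    return StabilityResult(mat, mean_ri, failures)


def precomputed_labeler(labels_dir: str | Path
                        ) -> Callable[[GridPoint], pd.Series]:
    """Labeler reading one TSV (cell_id, cluster) per grid point from
    ``labels_dir``, named dim{d}_pc{p}_res{r}.tsv."""
    labels_dir = Path(labels_dir)

    def labeler(point: GridPoint) -> pd.Series:
        path = labels_dir / f"{_point_name(point)}.tsv"
        df = pd.read_csv(path, sep="\t")
        return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0])

    return labeler


def knn_modularity_labeler(counts, seed: int = 0
                           ) -> Callable[[GridPoint], pd.Series]:
    """Simple deterministic clusterer for synthetic demonstrations:
    log1p-CPM normalization, PCA to the grid point's PC count, a
    k-nearest-neighbour graph (k derived from the dims parameter), and
    greedy modularity communities at the grid point's resolution.
    """
    import networkx as nx
    from sklearn.decomposition import PCA
    from sklearn.neighbors import kneighbors_graph
    from scipy import sparse as sp

    x = counts.X if hasattr(counts, "X") else np.asarray(counts)
    x = np.asarray(x.todense()) if sp.issparse(x) else np.asarray(x, float)
    libsize = np.clip(x.sum(axis=1, keepdims=True), 1, None)
    norm = np.log1p(x / libsize * 1e4)
    index = (counts.obs_names if hasattr(counts, "obs_names")
             else pd.RangeIndex(len(norm)))

    def labeler(point: GridPoint) -> pd.Series:
        dims, pcs, res = point
        pcs = min(pcs, norm.shape[1] - 1, norm.shape[0] - 1)
        emb = PCA(n_components=pcs, random_state=seed).fit_transform(norm)
        k = max(5, dims // 5)
        graph = nx.from_scipy_sparse_array(
            kneighbors_graph(emb, n_neighbors=k, mode="connectivity"))
        communities = nx.community.greedy_modularity_communities(
            graph, resolution=res)
        labels = np.empty(len(emb), dtype=int)
        for ci, members in enumerate(communities):
            labels[list(members)] = ci
        return pd.Series(labels, index=index)

    return labeler
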