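"""Transcription-factor cluster assignment and interaction filtering.

Candidate TFs (highly variable features, markers, or maturation DEGs)
expressed in at least 10% of some cluster are assigned to the cluster
with the highest mean normalized expression; a TF is "cluster distinct"
when the natural-log fold change between its top and second clusters
reaches 0.25. Protein-protein interaction edges are kept only when the
combined score exceeds 500 and both endpoints are assigned to the same
cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse

from .config import TFParams
from .errors import InputError

log = logging.getLogger(__name__)

__all__ = ["select_tfs", "assign_tf_clusters", "filter_interactions"]

_PSEUDOCOUNT = 1e-9  # for log fold changes of normalized means


def _expr_frame(expr) -> pd.DataFrame:
    if isinstance(expr, pd.DataFrame):
        return expr
    x = expr.X
    x = np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)
    return pd.DataFrame(x, index=expr.obs_names, columns=expr.var_names)


def select_tfs(expr, labels: pd.Series, tf_universe: list[str],
               candidate_flags: pd.Series | None = None,
               params: TFParams | None = None) -> list[str]:
    """TFs passing the candidate gate and expressed (normalized value
    > 0) in at least ``min_frac_any_cluster`` of some cluster."""
    params = params if params is not None else TFParams()
    if not tf_universe:
        log.warning("empty TF universe")
        return []
    df = _expr_frame(expr)
    present = [g for g in tf_universe if g in df.columns]
    if candidate_flags is not None:
        present = [g for g in present if bool(candidate_flags.get(g, False))]
    if not present:
        return []
    frac = (df[present] > 0).groupby(labels.reindex(df.index),
                                     observed=True).mean()
    keep = frac.max(axis=0) >= params.min_frac_any_cluster
    return [g for g in present if keep[g]]


def assign_tf_clusters(expr, labels: pd.Series, tfs: list[str],
                       params: TFParams | None = None) -> pd.DataFrame:
    """Assign each TF to its highest-mean-expression cluster.

    Columns: assigned cluster, expressed fraction there, log fold
    changes top-vs-second and top-vs-bottom, the cluster-distinct flag
    (top-vs-second lfc >= 0.25), and the visualization gate (expressed
    fraction >= 0.20 in the assigned cluster and top-vs-bottom lfc
    >= 0.25). Ties go to the smaller cluster id (logged). With a single
    cluster the distinct flag is not applicable (NaN).
    """
    params = params if params is not None else TFParams()
    df = _expr_frame(expr)
    aligned = labels.reindex(df.index)
    means = df[tfs].groupby(aligned, observed=True).mean()  # cluster x tf
    frac = (df[tfs] > 0).groupby(aligned, observed=True).mean()
    clusters = means.index.to_numpy()
    single = len(clusters) < 2
    rows = []
    for tf_gene in tfs:
        m = means[tf_gene]
        order = m.sort_values(ascending=False, kind="mergesort")
        top = order.index[0]
        if (m == m.max()).sum() > 1:
            top = m[m == m.max()].index.min()
            log.info("TF %s tied across clusters; assigned to %s",
                     tf_gene, top)
        if single:
            lfc2 = lfc_bottom = np.nan
            distinct = np.nan
        else:
            rest = m.drop(top)
            second, bottom = rest.max(), m.min()
            lfc2 = float(np.log((m[top] + _PSEUDOCOUNT)
                                / (second + _PSEUDOCOUNT)))
            lfc_bottom = float(np.log((m[top] + _PSEUDOCOUNT)
                                      / (bottom + _PSEUDOCOUNT)))
            distinct = bool(lfc2 >= params.distinct_lfc)
        frac_top = float(frac.loc[top, tf_gene])
        viz = (frac_top >= params.min_frac_assigned
               and (not single) and lfc_bottom >= params.distinct_lfc)
        rows.append({
            "tf": tf_gene, "cluster": top, "expressed_fraction": frac_top,
            "lfc_top_second": lfc2, "lfc_top_bottom": lfc_bottom,
            "distinct": distinct, "viz_pass": bool(viz),
        })
    return pd.DataFrame(rows)


def filter_interactions(edges: pd.DataFrame, assignments: pd.DataFrame,
                        params: TFParams | None = None,
                        within: str = "both") -> pd.DataFrame:
    """Keep edges with combined_score > 500 whose endpoints lie within
    the assigned cluster.

    ``within='both'`` (default) requires both endpoints assigned to the
    same cluster; ``within='either'`` requires assignment of both
    endpoints but only score filtering otherwise. Edges touching
    unassigned proteins are dropped (counted in the log).
    """
    params = params if params is not None else TFParams()
    if within not in ("both", "either"):
        raise InputError("within must be 'both' or 'either'")
    cluster_of = assignments.set_index("tf")["cluster"]
    known = (edges["protein_a"].isin(cluster_of.index)
             & edges["protein_b"].isin(cluster_of.index))
    if (~known).any():
        log.info("%d edges with unassigned endpoints dropped",
                 int((~known).sum()))
    df = edges[known].copy()
    df["cluster_a"] = df["protein_a"].map(cluster_of)
    df["cluster_b"] = df["protein_b"].map(cluster_of)
    keep = df["combined_score"] > params.min_combined_score
    if within == "both":
        keep &= df["cluster_a"] == df["cluster_b"]
    out = df[keep].reset_index(drop=True)
    out["cluster"] = out["cluster_a"].where(
        out["cluster_a"] == out["cluster_b"], other=pd.NA)
    return out.drop(columns=["cluster_a", "cluster_b"])
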