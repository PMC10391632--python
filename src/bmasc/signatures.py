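"""Marker thresholding, preranked enrichment, and pathway scores.

Markers are significantly up-regulated genes (avgLogFC > 0.25,
Bonferroni-adjusted p < 0.05); the prerank statistic is the negative
log10 p times the sign of the fold change; enrichment uses the weighted
Kolmogorov-Smirnov running sum of preranked GSEA; pathway activity per
cell is the mean normalized expression of the pathway's
maturation-associated genes ("multivariate U score" averaging), then
summarized per cluster with optional row-z or min-max scaling.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .config import MarkerRule
from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "filter_markers",
    "prerank_statistic",
    "preranked_es",
    "preranked_significance",
    "maturation_deg_union",
    "ustat_pathway_score",
    "summarize_scores",
    "rank_sum_de",
]


def filter_markers(de: pd.DataFrame, rule: MarkerRule | None = None,
                   n_tests: int | None = None,
                   top_deg: bool = False) -> pd.DataFrame:
    """Apply the marker rule to a DE table (columns gene, avgLogFC,
    p_raw).

    Bonferroni adjustment: p_adj = min(1, p_raw * n_tests), defaulting
    n_tests to the row count (with a warning if a smaller n_tests is
    passed). Markers are up-regulated only; ``top_deg=True`` also keeps
    down-regulated genes with avgLogFC < -lfc_min.
    """
    rule = rule if rule is not None else MarkerRule()
    if n_tests is None:
        n_tests = len(de)
    elif n_tests < len(de):
        log.warning("n_tests=%d smaller than table size %d", n_tests, len(de))
    out = de.copy()
    out["p_adj"] = np.minimum(1.0, out["p_raw"] * n_tests)
    up = (out["avgLogFC"] > rule.lfc_min) & (out["p_adj"] < rule.alpha)
    if top_deg:
        down = (out["avgLogFC"] < -rule.lfc_min) & (out["p_adj"] < rule.alpha)
        return out[up | down].reset_index(drop=True)
    return out[up].reset_index(drop=True)


def prerank_statistic(de: pd.DataFrame,
                      p_floor: float = 1e-300) -> pd.DataFrame:
    """Rank genes by NLP x sign(avgLogFC), descending.

    NLP = -log10(max(p_raw, p_floor)); sign(0) = 0. Ties break by
    |avgLogFC| descending, then gene symbol ascending, so the order is
    total and reproducible.
    """
    genes = de["gene"].astype(str)
    if genes.duplicated().any():
        raise InputError("duplicate genes in DE table")
    score = (-np.log10(np.maximum(de["p_raw"].to_numpy(float), p_floor))
             * np.sign(de["avgLogFC"].to_numpy(float)))
    ranked = pd.DataFrame({
        "gene": genes.to_numpy(),
        "score": score,
        "_abs_lfc": np.abs(de["avgLogFC"].to_numpy(float)),
    })
    ranked = ranked.sort_values(
        ["score", "_abs_lfc", "gene"], ascending=[False, False, True],
        kind="mergesort").drop(columns="_abs_lfc").reset_index(drop=True)
    return ranked


def preranked_es(ranked: pd.DataFrame, gene_set,
                 exponent: float = 1.0) -> tuple[float, list[str]]:
    """Weighted-KS enrichment score of a gene set against a ranked list.

    Hits increment the running sum by |score|^exponent over the total
    hit weight; misses decrement by 1/(N - N_set). The ES is the
    running-sum value of maximal absolute deviation (signed); the
    leading edge is the set members at or before the extremum for a
    positive ES, at or after it for a negative ES. Returns (nan, [])
    when the set does not overlap the list.
    """
    genes = ranked["gene"].to_numpy()
    scores = ranked["score"].to_numpy(float)
    hit = np.isin(genes, list(gene_set))
    n, n_hit = genes.size, int(hit.sum())
    if n_hit == 0:
        log.warning("gene set does not overlap the ranked list")
        return np.nan, []
    weights = np.abs(scores) ** exponent
    hit_total = weights[hit].sum()
    steps = np.where(
        hit,
        (weights / hit_total) if hit_total > 0 else (1.0 / n_hit),
        (-1.0 / (n - n_hit)) if n > n_hit else 0.0)
    running = np.cumsum(steps)
    extremum = int(np.argmax(np.abs(running)))
    es = float(running[extremum])
    if es >= 0:
        leading = genes[: extremum + 1][hit[: extremum + 1]]
    else:
        leading = genes[extremum:][hit[extremum:]]
    return es, list(leading)


def preranked_significance(ranked: pd.DataFrame, gene_set, n_perm: int,
                           seed: int | np.random.Generator | None = None,
                           exponent: float = 1.0) -> float:
    """Permutation p for a preranked ES against random same-size sets:
    p = (1 + #{|ES*| >= |ES|}) / (n_perm + 1)."""
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    genes = ranked["gene"].to_numpy()
    members = set(gene_set) & set(genes)
    if len(members) > genes.size:
        raise InputError("gene set larger than ranked list")
    if not members:
        return np.nan
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    es, _ = preranked_es(ranked, members, exponent)
    count = 0
    for _ in range(n_perm):
        rand_set = rng.choice(genes, size=len(members), replace=False)
        es_star, _ = preranked_es(ranked, rand_set, exponent)
        if abs(es_star) >= abs(es):
            count += 1
    return (1 + count) / (n_perm + 1)


def maturation_deg_union(adjacent_pair_de: list[pd.DataFrame],
                         early_vs_late_de: pd.DataFrame | None = None,
                         rule: MarkerRule | None = None) -> set[str]:
    """Union of genes passing the top-DEG rule (either direction) in any
    adjacent-stage comparison or in the early-vs-late comparison."""
    tables = list(adjacent_pair_de)
    if early_vs_late_de is not None:
        tables.append(early_vs_late_de)
    if not tables:
        log.warning("no DE tables supplied; empty maturation set")
        return set()
    out: set[str] = set()
    for table in tables:
        out |= set(filter_markers(table, rule, top_deg=True)["gene"])
    return out


def ustat_pathway_score(norm_expr: pd.DataFrame, pathway_genes,
                        maturation_set) -> pd.Series | None:
    """Per-cell pathway score: mean normalized expression over the genes
    in pathway ∩ maturation set; None when the intersection is empty."""
    genes = [g for g in norm_expr.columns
             if g in set(pathway_genes) & set(maturation_set)]
    if not genes:
        log.warning("pathway has no maturation-associated genes; skipped")
        return None
    return norm_expr[genes].mean(axis=1)


def summarize_scores(scores: pd.DataFrame, labels: pd.Series,
                     scaling: str = "none") -> pd.DataFrame:
    """Cluster-level enrichment panel: pathway x cluster matrix of mean
    member-cell scores, optionally row-z ('rowz') or min-max ('minmax')
    scaled across clusters within each pathway.

    Pathways whose cluster means are constant are returned unscaled
    (zero spread), with a warning.
    """
    if scaling not in ("none", "rowz", "minmax"):
        raise InputError(f"unknown scaling mode {scaling!r}")
    aligned = labels.reindex(scores.index)
    if aligned.isna().any():
        raise InputError("every cell must carry a cluster label")
    panel = scores.groupby(aligned, observed=True).mean().T  # pathway x cluster
    if scaling == "none" or panel.shape[1] < 2:
        if scaling != "none" and panel.shape[1] < 2:
            log.warning("single cluster: %s scaling skipped", scaling)
        return panel
    if scaling == "rowz":
        sd = panel.std(axis=1, ddof=0)
        flat = sd == 0
        if flat.any():
            log.warning("%d pathway rows have zero spread; left unscaled",
                        int(flat.sum()))
        out = panel.sub(panel.mean(axis=1), axis=0)
        out.loc[~flat] = out.loc[~flat].div(sd[~flat], axis=0)
        out.loc[flat] = panel.loc[flat]
        return out
    rng_ = panel.max(axis=1) - panel.min(axis=1)
    flat = rng_ == 0
    if flat.any():
        log.warning("%d pathway rows have zero spread; left unscaled",
                    int(flat.sum()))
    out = panel.sub(panel.min(axis=1), axis=0)
    out.loc[~flat] = out.loc[~flat].div(rng_[~flat], axis=0)
    out.loc[flat] = panel.loc[flat]
    return out


def rank_sum_de(norm_expr, labels: pd.Series, group1,
                group2=None) -> pd.DataFrame:
    """Built-in fallback DE engine: two-group Wilcoxon rank-sum with a
    natural-log fold change of group means (pseudocount 1e-9).

    ``group2=None`` compares group1 against all remaining cells (the
    marker-detection setting). Returns a DE table with gene, avgLogFC,
    p_raw, and expressing fractions; model-based DE tables can be
    supplied instead wherever a DE table is accepted.
    """
    if hasattr(norm_expr, "X"):
        x = norm_expr.X
        x = np.asarray(x.todense()) if sparse.issparse(x) else np.asarray(x)
        genes = norm_expr.var_names
        index = norm_expr.obs_names
    else:
        x = norm_expr.to_numpy(float)
        genes = norm_expr.columns
        index = norm_expr.index
    aligned = labels.reindex(index)
    in1 = (aligned == group1).to_numpy()
    in2 = (~in1 if group2 is None else (aligned == group2).to_numpy())
    if in1.sum() < 1 or in2.sum() < 1:
        raise InputError("both groups need at least one cell")
    x1, x2 = x[in1], x[in2]
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    lfc = np.log((m1 + 1e-9) / (m2 + 1e-9))
    stat = stats.mannwhitneyu(x1, x2, axis=0, alternative="two-sided")
    return pd.DataFrame({
        "gene": genes.to_numpy(),
        "avgLogFC": lfc,
        "p_raw": stat.pvalue,
        "pct_expr_1": (x1 > 0).mean(axis=0),
        "pct_expr_2": (x2 > 0).mean(axis=0),
        "comparison": f"{group1}_vs_{'rest' if group2 is None else group2}",
    })
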