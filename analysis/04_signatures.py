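#!/usr/bin/env python
"""Marker detection, preranked enrichment and pathway score panel.

Runs the fallback rank-sum DE engine per cluster, applies the marker
rule (avgLogFC > 0.25, Bonferroni p < 0.05), builds the NLP x sign
preranked list, scores synthetic hallmark-like gene sets with the
weighted-KS ES, and summarizes per-cell mean-expression pathway scores
into a row-scaled cluster panel.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bmasc.io_formats import read_count_matrix
from bmasc.pipeline import _normalize, _synthetic_gene_sets
from bmasc.signatures import (filter_markers, maturation_deg_union,
                              prerank_statistic, preranked_es, rank_sum_de,
                              summarize_scores, ustat_pathway_score)

DATA = Path("results/data")
OUT = Path("results/signatures")
SEED = 1


def main() -> None:
    counts = read_count_matrix(DATA / "counts")
    labels = pd.read_csv(DATA / "labels.tsv", sep="\t",
                         index_col=0)["cluster"]
    truth = json.loads((DATA / "truth.json").read_text())
    norm = _normalize(counts)
    clusters = sorted(labels.unique())

    de = {c: rank_sum_de(norm, labels, c) for c in clusters}
    markers = pd.concat(
        [filter_markers(t).assign(cluster=c) for c, t in de.items()],
        ignore_index=True)
    adjacent = [rank_sum_de(norm, labels, a, b)
                for a, b in zip(clusters[:-1], clusters[1:])]
    maturation = maturation_deg_union(adjacent)
    ranked = prerank_statistic(de[clusters[-1]])
    gene_sets = _synthetic_gene_sets(
        norm.columns, {int(k): v for k, v in truth["marker_genes"].items()},
        10, np.random.default_rng([SEED, 2]))

    es_rows, scores = [], {}
    for name, members in gene_sets.items():
        es, leading = preranked_es(ranked, members)
        es_rows.append({"pathway": name, "es": es,
                        "n_leading": len(leading)})
        s = ustat_pathway_score(norm, members, maturation)
        if s is not None:
            scores[name] = s
    panel = summarize_scores(pd.DataFrame(scores), labels, "rowz")

    OUT.mkdir(parents=True, exist_ok=True)
    markers.to_csv(OUT / "markers.tsv", sep="\t", index=False)
    ranked.to_csv(OUT / "ranked_list.tsv", sep="\t", index=False)
    pd.DataFrame(es_rows).to_csv(OUT / "preranked_es.tsv", sep="\t",
                                 index=False)
    panel.to_csv(OUT / "es_panel.tsv", sep="\t")

    per_cluster = markers.groupby("cluster")["gene"].count()
    print(f"markers per cluster: {per_cluster.to_dict()}")
    print(f"maturation DEG union: {len(maturation)} genes")
    top = pd.DataFrame(es_rows).nlargest(3, "es")
    print("top enrichment scores:")
    print(top.to_string(index=False))


if __name__ == "__main__":
    main()
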