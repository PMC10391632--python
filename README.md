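# bmasc

Analysis toolkit for single-cell studies of human bone-marrow
antibody-secreting-cell (ASC) maturation. Bone-marrow plasma cells range
from newly minted plasmablasts to long-lived plasma cells; resolving that
maturation axis requires a combination of scRNA-seq processing and BCR
heavy-chain repertoire analysis. This package implements the bespoke
computational stages of such a study as a tested library, driven by a
synthetic-data generator with complete ground truth so every stage is
verifiable without any external download:

- **QC** (`bmasc.qc`) — the exact cell filters: remove cells with
  mitochondrial UMI fraction ≥ 30%, detected genes ≤ 800, UMIs ≤ 1000,
  genes ≥ 6000 or UMIs ≥ 60000 (doublet control), immunoglobulin UMI
  fraction ≤ 5% (non-ASC admixture), plus contaminant flagging by
  diagnostic markers (CD3E, FCGR3A, CD14, NKG7, GNLY, HBB, MS4A1, PAX5,
  IRF8) and Ig-gene exclusion from variable-feature lists.
- **Cluster stability** (`bmasc.stability`) — the plain Rand Index
  RI = (pairs co-clustered in both + pairs separated in both) / C(n, 2),
  swept over a (dims × PCs × resolution) clustering-parameter grid with a
  pluggable clusterer.
- **Signatures** (`bmasc.signatures`) — marker rule (avgLogFC > 0.25,
  Bonferroni-adjusted p < 0.05), the NLP × sign(avgLogFC) prerank
  statistic, the weighted Kolmogorov–Smirnov enrichment score with
  leading edge, permutation significance, and per-cell pathway scores as
  mean normalized expression of maturation-associated genes, summarized
  per cluster with row-z or min-max scaling.
- **TF assignment** (`bmasc.tf`) — transcription factors gated at ≥ 10%
  expressing cells in some cluster, assigned to their highest-expression
  cluster, flagged "cluster distinct" at ≥ 0.25 natural-log fold change
  over the runner-up, and protein-interaction edges kept at combined
  score > 500 within the assigned cluster.
- **Repertoire** (`bmasc.repertoire`) — clonal lineages (same V gene, J
  gene, CDR3 length; single-linkage at ≥ 85% CDR3 identity; identical
  clones at 98%), somatic-hypermutation profiles as non-gap mismatch
  frequencies per FR/CDR region, replacement/silent classification by
  single-substitution codon translation, R/S ratios with the silent
  floor of 1 and the R/S > 2.9 antigen-selection flag, Morisita overlap
  connectivity of lineage abundances across clusters, and a permutation
  test (shuffle frequencies, ANOVA + Tukey HSD per permutation,
  p = #{p\* < p_observed} / n_perm).
- **Synthetic data** (`bmasc.synthetic`) — negative-binomial counts with
  cluster markers, mito/Ig fractions and contaminants; an AIRR
  rearrangement table with known lineage membership and codon-level
  replacement/silent mutation truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the
synthetic world (1,000 cells, 800 genes, 8 clusters, 200 lineages,
7% per-base SHM) and write their tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_qc.py
...
python analysis/06_repertoire.py
```

Output of the repertoire stage (seed 1):

```
200 lineages (641 clones) from 830 records; ARI vs truth = 1.000
37 lineages span >= 2 clusters (18.5%)
mean global SHM frequency: 7.01%
aggregate CDR R/S = 3.24 (selected: True)
mean off-diagonal Morisita: 0.948; after singleton removal: 0.957
ANOVA p = 0.279; 4/28 cluster pairs with permutation p <= 0.05
```

Reading: lineage clustering at 85% CDR3 homology recovers the simulated
clonal partition exactly (adjusted Rand index 1.0); the recovered mean
mutation frequency (7.01%) matches the simulated 7% per-base rate; the
aggregate CDR replacement/silent ratio exceeds the 2.9 selection
threshold (as expected for unselected random substitutions, which are
~3:1 replacement:silent under the genetic code); Morisita overlap near 1
reflects lineages drawn independently of cluster, and rises after
singleton removal; the permutation test finds no cluster difference in
mutation frequency, consistent with a rate shared by all clusters.

The same stages are callable from a thin CLI (`bmasc simulate|qc|
repertoire|run-all`), and `bmasc.pipeline.run_pipeline` runs everything
end to end with one seed and a manifest.

## Acceptance script

`scripts/acceptance.py` recomputes the package's two checkable reference
identities from scratch at run time — the Morisita overlap of a
lineage-abundance profile with itself and the Rand Index of a cluster
labeling with itself — on freshly generated inputs:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
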