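# Methods

## Scope and design

The package implements the bespoke computational stages of a bone-marrow
ASC maturation analysis: cell-level QC, Rand-Index cluster stability,
marker/enrichment statistics, TF cluster assignment, and the BCR
heavy-chain repertoire stage. Upstream heavy machinery is deliberately a
*contract*, not an implementation: clustering labels, model-based DE
tables and germline-annotated alignments can all be supplied as inputs.
Built-in stand-ins (a PCA + kNN-graph + greedy-modularity labeler, a
rank-sum DE engine) exist only so the synthetic pipeline runs end to
end; they make no claim to reproduce SCTransform/CCA/Louvain or
zero-inflated DE models.

## QC filters

A cell is removed when mito fraction ≥ 0.30, detected genes ≤ 800,
UMIs ≤ 1000, genes ≥ 6000, UMIs ≥ 60000, or Ig UMI fraction ≤ 0.05.
Boundary semantics are taken literally from the protocol text (values at
the printed thresholds are removed). Removals are attributed to every
rule a cell violates, so per-rule counts may overlap. Contaminant cells
are flagged when any diagnostic marker reaches `contaminant_min_umi`
(default 1 UMI — the protocol states no threshold; configurable).
Zero-UMI cells get fractions of 0 and fall to the UMI floor.

Ig genes are recognized by locus stem + segment letter
(IGH/IGK/IGL followed by one of V/D/J/G/A/M/E/C), not by naive 3-letter
prefix, so IGF-family genes are never misclassified. The rule does
accept the non-Ig gene IGHMBP2 — a known, documented limitation of
symbol-based matching.

The exploratory "LowGN" (200–800 genes) re-inclusion detour described in
the source protocol is not implemented; the final rule (exclude ≤ 800)
is.

## Rand-Index stability

RI is the *plain* Rand Index (proportion of agreeing cell pairs),
computed from the contingency table in closed form; the adjusted Rand
index is offered separately for synthetic-truth comparisons only. The
grid mean is the arithmetic mean over **all** unordered grid-point
pairs (whether the original protocol averaged all pairs or only
single-parameter neighbours is ambiguous; all-pairs is the documented
default). Labeler failures at grid points are recorded and their pairs
skipped.

## Enrichment

- Prerank statistic: −log10(max(p, 10⁻³⁰⁰)) × sign(avgLogFC). The log
  base is not stated in the protocol; log10 is the GSEA convention.
  Ties break by |avgLogFC| then gene symbol, making the order total.
- Weighted-KS ES: hit increment |score|^p / Σ_hits |score|^p (p = 1),
  miss decrement 1/(N − N_set); ES is the signed maximal deviation of
  the running sum; |ES| ≤ 1 by construction. p = 0 reduces to the
  classic unweighted KS statistic (tested).
- Significance: permutation over random same-size gene sets with the
  add-one estimator (1 + exceedances)/(n_perm + 1); FDR across sets, if
  needed, is Benjamini–Hochberg — the full GSEA v4 NES/FDR estimator is
  out of scope.
- The "multivariate U score" pathway activity is implemented exactly as
  its operational description: the per-cell mean of normalized
  expression over pathway ∩ maturation-associated DEGs. No rank-based
  U statistic is attempted; the function is a seam where variants could
  be slotted in.
- Maturation-associated DEGs default to the union over all supplied
  comparisons (adjacent-stage pairs plus early-vs-late); restriction to
  particular cluster subsets is a caller choice.

## TF assignment

Mean normalized expression per cluster; assignment by argmax, ties to
the smaller cluster id (logged). Log fold changes between cluster means
use a 10⁻⁹ pseudocount (unstated in the protocol). "Exists within the
assigned cell cluster" is read as *both* endpoints sharing the assigned
cluster (`within="either"` available), since the target visualization
draws edges inside cluster-colored groups. The 10%-expression gate and
the candidate (HVF/marker/DEG) gate commute, so their order is
irrelevant.

## Repertoire

- Lineages: partition by (subject, V gene, J gene, CDR3 length), then
  single-linkage merging of CDR3s at ≥ 85% identity (Hamming on
  nucleotides; lengths are equal within a partition by construction).
  Amino-acid comparison and complete linkage are available by flag.
  Lineage ids are canonicalized to the smallest member sequence_id, so
  output is invariant to input order. Clones use the same machinery at
  98% and provably refine the lineage partition.
- SHM: mismatch counting excludes any column gapped in either sequence
  from numerator *and* denominator, per region (FR1/CDR1/FR2/CDR2/FR3,
  composites CDR, FR, and global V). Region coordinates arrive 1-based
  closed (AIRR convention) and are converted at the I/O boundary.
- R/S: each mismatch is classified by translating the germline codon
  with that single substitution applied (one-at-a-time rule for
  multi-hit codons); codons touching gaps or incomplete edge codons are
  "unclassifiable" and excluded from R and S counts. The reading frame
  comes from a `v_frame_offset` column (0 in simulated data).
  R/S = r / max(s, 1) when r > 0 ("silent set to 1" floor); undefined
  when r = s = 0; selection flag strictly > 2.9.
- Morisita: the Morisita–Horn form
  C = 2Σxᵢyᵢ / [(Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y], chosen over the classical
  unbiased estimator because only this form gives exactly 1 for
  identical profiles at finite counts, matching the stated identity.
  Empty clusters yield NaN entries; multi-subject averaging is the
  element-wise mean over subjects where both clusters are non-empty.
- Permutation test: frequencies are shuffled across cells with labels
  fixed; per permutation, one-way ANOVA and Tukey HSD (Tukey–Kramer for
  unequal sizes). The permutation p per cluster pair is
  #{p\* strictly < p_observed}/n_perm, exactly the printed formula
  generalized from 100 to n_perm. Because the Tukey p is strictly
  decreasing in the studentized-range statistic q at fixed group sizes,
  the comparison is performed on q; only observed p-values evaluate the
  studentized-range distribution. The observed ANOVA/Tukey values are
  verified against scipy's `f_oneway` and `tukey_hsd` in the tests (the
  permutation loop itself is this package's own vectorized code). The
  per-pair Tukey comparison is the default referent; an ANOVA-level
  permutation p is also reported. Cells without frequencies are dropped
  listwise; clusters with < 2 cells are excluded with a warning.

## Synthetic world

Defaults state the conditions of the emulated experiment: 1,000 cells,
800 genes, 8 equal clusters; NB counts (variance μ + 0.5μ²) around a
per-gene lognormal baseline of mean ≈ 2; 10 marker genes and one
designated TF per cluster at 4-fold boost; Ig UMI fraction uniform in
[0.40, 0.80] and mito in [0.02, 0.15] (ASCs devote most UMIs to Ig;
package choices, documented here, not protocol values); 2% contaminant
cells spiking one diagnostic marker; 200 lineages with Zipf(2) sizes and
every lineage realized at least once (real repertoires are
singleton-rich); 83% of cells VDJ-matched; per-base V mutation rate 7%
(anchoring the reported ~6.9% mean SHM); CDR3 lengths 30–60 nt;
within-lineage CDR3 divergence 4% per base, capped at half the distance
budget of the 85% threshold so the true partition is recoverable by
single linkage (triangle inequality). Mutation truth is generated by
the same single-substitution-in-germline-context rule the estimator
uses, making truth and estimate commensurable; the estimator itself is
checked against an independent translate-everything oracle.

What the generator does **not** emulate: gene–gene correlation
structure, ambient RNA, real doublets (only count caps), light chains,
class-switch phylogenies, indels in V (mutation statistics are defined
on non-gap mismatches, so substitutions suffice for exact truth). A
green test therefore establishes algorithmic correctness on the stated
world, not biological fidelity of any upstream model.

The QC acceptance fixture is generated at the metrics level
(`simulate_qc_metrics`): a cell violating the ≥ 6000-genes doublet cap
requires a ≥ 6000-gene matrix, and the filter's contract is over
metrics. Full matrices from `simulate_expression` are QC'd end to end in
the pipeline.

The demonstration pipeline uses QC thresholds rescaled to the 800-gene
world (`synthetic_qc_thresholds`) — the published ≤ 800-gene floor would
remove every cell of an 800-gene simulation — and a reduced 8-point
stability grid for the one-CPU time budget; the full 36-point grid is
exercised in unit tests with a cheap labeler.

## Numerical choices

- Homology boundary: similarity ≥ threshold with a 10⁻¹² tolerance, so
  exactly-85% pairs link.
- Rand Index via contingency-table combinatorics (exact in float for
  n ≤ 10⁵ pairs scale); verified against pair enumeration for n ≤ 30.
- Degenerate permutation input (all frequencies equal) gives q = 0,
  Tukey p = 1, permutation p = 0 under the strict "<" — documented
  behaviour, not an error.
- Row scaling of enrichment panels skips zero-spread rows (returned
  unscaled, with a warning) rather than dividing by zero.

## Known limitations

- The headline dataset results of the emulated study (17,347 cells, 15
  clusters, 11,853 lineages, 86.5% mean RI) require the deposited data
  and the full Seurat stack and are out of scope by design; nothing here
  claims to reproduce them.
- Symbol-prefix gene classification is heuristic (see QC above).
- The bundled labeler's stability depends on the simulated separation;
  its mean RI is a qualitative demonstration, not a calibrated value.
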