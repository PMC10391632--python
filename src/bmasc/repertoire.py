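"""BCR heavy-chain repertoire analysis.

Clonal lineages are sets of rearrangements sharing V gene, J gene and
CDR3 length whose CDR3s are linked at >= 85% identity (single linkage);
identical clones are tracked the same way at 98%. Somatic hypermutation
is quantified as non-gap mismatches between the expressed V sequence and
its germline alignment, per framework/CDR region; each mismatch is
classified replacement or silent by applying the single substitution in
germline codon context. Replacement/silent ratios use a silent floor of
1 when replacements are present, and R/S > 2.9 is flagged as suggestive
of antigen selection. Cluster connectivity is measured with the
Morisita(-Horn) overlap of lineage abundance profiles, and differences
in mutation frequency among clusters are assessed with a permutation
test built on one-way ANOVA plus Tukey's HSD.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .config import LineageParams
from .errors import InputError

log = logging.getLogger(__name__)

__all__ = [
    "cluster_lineages",
    "track_clones",
    "classify_substitution",
    "classify_rs",
    "mutation_profile",
    "rs_ratio",
    "RSResult",
    "lineage_cluster_table",
    "morisita",
    "morisita_matrix",
    "average_morisita",
    "mutation_permutation_test",
    "permutation_pvalue",
    "PermutationTestResult",
    "join_vdj_expression",
]

GAP_CHARS = frozenset("-.")
RS_SELECTION_THRESHOLD = 2.9

REGIONS = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3")
REGION_LABELS = {"fwr1": "FR1", "cdr1": "CDR1", "fwr2": "FR2",
                 "cdr2": "CDR2", "fwr3": "FR3"}

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _translate_codon(codon: str) -> str:
    if codon in _STANDARD_TABLE.stop_codons:
        return "*"
    return _STANDARD_TABLE.forward_table[codon]


def classify_substitution(germline_codon: str, pos_in_codon: int,
                          new_base: str) -> str:
    """Classify a single substitution in germline codon context as
    'replacement' or 'silent' under the standard genetic code."""
    germline_codon = germline_codon.upper()
    if len(germline_codon) != 3 or any(b not in "ACGT" for b in germline_codon):
        raise InputError(f"invalid codon {germline_codon!r}")
    if new_base not in "ACGT":
        raise InputError(f"invalid base {new_base!r}")
    mutated = (germline_codon[:pos_in_codon] + new_base
               + germline_codon[pos_in_codon + 1:])
    same = _translate_codon(germline_codon) == _translate_codon(mutated)
    return "silent" if same else "replacement"


# ---------------------------------------------------------------------------
# lineage clustering


def _gene(call: str) -> str:
    """Gene-level identifier from an annotation call: first listed call,
    allele suffix stripped (IGHV3-23*01 -> IGHV3-23)."""
    return str(call).split(",")[0].split("*")[0].strip()


def _cdr3_distance_links(seqs: list[str], threshold: float,
                         method: str) -> np.ndarray:
    """Cluster equal-length CDR3s by normalized Hamming distance at
    1 - threshold; returns integer component labels."""
    n = len(seqs)
    length = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(n, length)
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = (arr != arr[i]).mean(axis=1)
    cutoff = (1.0 - threshold) + 1e-12
    if method == "single":
        adj = dist <= cutoff
        # union-find over the adjacency
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in np.nonzero(adj[i, i + 1:])[0] + i + 1:
                ri, rj = find(i), find(int(j))
                if ri != rj:
                    parent[rj] = ri
        return np.array([find(i) for i in range(n)])
    z = scipy_linkage(squareform(dist, checks=False), method="complete")
    return fcluster(z, t=cutoff, criterion="distance")


def cluster_lineages(records: pd.DataFrame,
                     params: LineageParams | None = None,
                     threshold: float | None = None) -> pd.Series:
    """Assign a clonal-lineage id to each rearrangement.

    Records are first partitioned by (subject, V gene, J gene, CDR3
    length); within a partition, CDR3s are merged by single linkage at
    ``lineage_homology`` identity. Lineage ids are canonicalized to the
    smallest member sequence_id, making them invariant to input order.
    Records without a CDR3 are excluded (and counted in the log).
    """
    params = params if params is not None else LineageParams()
    threshold = params.lineage_homology if threshold is None else threshold
    df = records.copy()
    if "subject_id" not in df.columns:
        log.warning("no subject_id column: treating all records as one subject")
        df["subject_id"] = "S1"
    valid = df["cdr3"].notna() & (df["cdr3"].astype(str).str.len() > 0)
    n_excluded = int((~valid).sum())
    if n_excluded:
        log.warning("%d records lack a CDR3 and were excluded", n_excluded)
    df = df[valid]
    cdr3 = df["cdr3"].astype(str)
    if params.on_amino_acid:
        cdr3 = cdr3.map(lambda s: str(Seq(s[: len(s) - len(s) % 3]).translate()))
    keys = pd.DataFrame({
        "subject": df["subject_id"].astype(str),
        "v_gene": df["v_call"].map(_gene),
        "j_gene": df["j_call"].map(_gene),
        "cdr3_len": cdr3.str.len(),
    }, index=df.index)
    out = pd.Series(index=df["sequence_id"], dtype=object, name="lineage_id")
    for _, idx in keys.groupby(list(keys.columns), sort=False).groups.items():
        seq_ids = df.loc[idx, "sequence_id"].to_numpy()
        seqs = cdr3.loc[idx].tolist()
        comps = _cdr3_distance_links(seqs, threshold, params.linkage)
        for comp in np.unique(comps):
            members = seq_ids[comps == comp]
            out.loc[members] = min(members)
    return out


def track_clones(records: pd.DataFrame,
                 params: LineageParams | None = None) -> pd.Series:
    """Identical-clone assignment: lineage clustering at 98% homology."""
    params = params if params is not None else LineageParams()
    return cluster_lineages(records, params, threshold=params.clone_homology)


# ---------------------------------------------------------------------------
# mutation profiling


def _region_intervals(record) -> dict[str, tuple[int, int]]:
    """0-based half-open alignment intervals from 1-based closed AIRR
    coordinates."""
    out = {}
    for reg in REGIONS:
        start, end = record[f"{reg}_start"], record[f"{reg}_end"]
        if pd.isna(start) or pd.isna(end):
            raise InputError(f"missing {reg} coordinates")
        out[REGION_LABELS[reg]] = (int(start) - 1, int(end))
    return out


def classify_rs(record) -> pd.DataFrame:
    """Per-mutation replacement/silent labels for one rearrangement.

    Walks germline codons (reading frame given by ``v_frame_offset`` on
    the ungapped germline), and classifies each non-gap mismatch by
    translating the germline codon with that single substitution
    applied. Mismatches in codons touching an alignment gap, or in
    incomplete edge codons, are labelled 'unclassifiable'.
    """
    germ = str(record["v_germline_alignment"]).upper()
    obs = str(record["v_sequence_alignment"]).upper()
    if len(germ) != len(obs):
        raise InputError("alignment lengths differ")
    offset = record.get("v_frame_offset", None)
    if offset is None or (isinstance(offset, float) and np.isnan(offset)):
        raise InputError("v_frame_offset is required for R/S classification")
    offset = int(offset)
    if offset not in (0, 1, 2):
        raise InputError("v_frame_offset must be 0, 1 or 2")

    germ_cols = [i for i, b in enumerate(germ) if b not in GAP_CHARS]
    codons: dict[int, list[int]] = {}
    for ungapped_pos, col in enumerate(germ_cols):
        if ungapped_pos < offset:
            continue
        codons.setdefault((ungapped_pos - offset) // 3, []).append(col)

    rows = []
    for _, cols in sorted(codons.items()):
        complete = len(cols) == 3
        gapped = any(obs[c] in GAP_CHARS for c in cols)
        codon = "".join(germ[c] for c in cols) if complete else None
        for k, c in enumerate(cols):
            if obs[c] in GAP_CHARS or obs[c] == germ[c]:
                continue
            if not complete or gapped or any(b not in "ACGT" for b in codon):
                status = "unclassifiable"
            else:
                status = classify_substitution(codon, k, obs[c])
            rows.append((c, germ[c], obs[c], status))
    return pd.DataFrame(
        rows, columns=["alignment_position", "germline_base",
                       "observed_base", "status"])


def mutation_profile(record, classify: bool = True) -> pd.DataFrame:
    """Per-region mutation counts and frequencies for one rearrangement.

    Rows: FR1, CDR1, FR2, CDR2, FR3, the composites CDR (CDR1+CDR2) and
    FR (FR1+FR2+FR3), and V (the whole alignment). Positions where
    either sequence is gapped are excluded from numerator and
    denominator. With ``classify=True`` (requires ``v_frame_offset``),
    replacement/silent counts are included.
    """
    germ = str(record["v_germline_alignment"]).upper()
    obs = str(record["v_sequence_alignment"]).upper()
    if len(germ) != len(obs):
        raise InputError("alignment lengths differ")
    length = len(germ)
    garr = np.frombuffer(germ.encode(), dtype="S1")
    oarr = np.frombuffer(obs.encode(), dtype="S1")
    gap = np.isin(garr, [b"-", b"."]) | np.isin(oarr, [b"-", b"."])
    nongap = ~gap
    mismatch = nongap & (garr != oarr)

    intervals = _region_intervals(record)
    for name, (s, e) in intervals.items():
        if s < 0 or e > length or s >= e:
            raise InputError(
                f"region {name} interval [{s + 1}, {e}] outside alignment of "
                f"length {length} for record "
                f"{record.get('sequence_id', '<unknown>')}")

    rs = None
    if classify:
        labels = classify_rs(record)
        rs = pd.Series("none", index=np.arange(length))
        if len(labels):
            rs.iloc[labels["alignment_position"].to_numpy()] = (
                labels["status"].to_numpy())

    def span_counts(mask: np.ndarray) -> tuple:
        n_mut = int(mismatch[mask].sum())
        n_bases = int(nongap[mask].sum())
        freq = n_mut / n_bases if n_bases else np.nan
        if rs is None:
            return n_mut, n_bases, freq, np.nan, np.nan, np.nan
        sub = rs[mask]
        return (n_mut, n_bases, freq,
                int((sub == "replacement").sum()),
                int((sub == "silent").sum()),
                int((sub == "unclassifiable").sum()))

    masks = {}
    for name, (s, e) in intervals.items():
        m = np.zeros(length, bool)
        m[s:e] = True
        masks[name] = m
    masks["CDR"] = masks["CDR1"] | masks["CDR2"]
    masks["FR"] = masks["FR1"] | masks["FR2"] | masks["FR3"]
    masks["V"] = np.ones(length, bool)

    rows = {name: span_counts(m) for name, m in masks.items()}
    return pd.DataFrame.from_dict(
        rows, orient="index",
        columns=["n_mutations", "n_nongap_bases", "frequency",
                 "n_replacement", "n_silent", "n_unclassifiable"])


@dataclass
class RSResult:
    region: str
    r_count: int
    s_count: int
    s_denominator: float
    ratio: float
    selected: bool


def rs_ratio(profile: pd.DataFrame, region: str) -> RSResult:
    """Replacement/silent ratio for one region of a mutation profile.

    With replacements present but zero silent mutations the silent
    denominator is floored at 1; with neither, the ratio is undefined
    (NaN) and the selection flag is False. The flag marks R/S > 2.9.
    """
    r = int(profile.loc[region, "n_replacement"])
    s = int(profile.loc[region, "n_silent"])
    if r == 0 and s == 0:
        return RSResult(region, r, s, s, np.nan, False)
    denom = max(s, 1) if r > 0 else s
    ratio = r / denom
    return RSResult(region, r, s, denom, ratio,
                    bool(ratio > RS_SELECTION_THRESHOLD))


# ---------------------------------------------------------------------------
# connectivity


def lineage_cluster_table(assignments: pd.DataFrame,
                          cell_labels: pd.Series,
                          remove_singletons: bool = False) -> pd.DataFrame:
    """Lineage x cluster cell-abundance matrix.

    ``assignments`` needs columns cell_id and lineage_id; cells without a
    cluster label are dropped (and counted in the log). Singleton removal
    drops lineages totalling one cell, which enriches for expanded clones.
    """
    df = assignments[["cell_id", "lineage_id"]].copy()
    df["cluster"] = df["cell_id"].map(cell_labels)
    n_unlabeled = int(df["cluster"].isna().sum())
    if n_unlabeled:
        log.warning("%d records without a cell label dropped", n_unlabeled)
        df = df.dropna(subset=["cluster"])
    table = pd.crosstab(df["lineage_id"], df["cluster"])
    if remove_singletons:
        table = table[table.sum(axis=1) > 1]
        if table.empty:
            log.warning("all lineages are singletons; table is empty")
    return table


def morisita(x: np.ndarray, y: np.ndarray) -> float:
    """Morisita(-Horn) overlap of two abundance profiles: 1 for
    identical repertoires, 0 for disjoint ones."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    bx, by = x.sum(), y.sum()
    if bx == 0 or by == 0:
        return np.nan
    num = 2.0 * float(x @ y)
    denom = ((x @ x) / bx**2 + (y @ y) / by**2) * bx * by
    return num / denom


def morisita_matrix(abundance: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Morisita overlap between cluster columns of a
    lineage x cluster abundance matrix. Empty clusters give NaN."""
    clusters = abundance.columns
    empty = [c for c in clusters if abundance[c].sum() == 0]
    if empty:
        log.warning("clusters with zero cells excluded from overlap: %s", empty)
    mat = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    for a, b in itertools.combinations_with_replacement(clusters, 2):
        val = morisita(abundance[a].to_numpy(), abundance[b].to_numpy())
        mat.loc[a, b] = mat.loc[b, a] = val
    return mat


def average_morisita(matrices: list[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise mean of per-subject overlap matrices over subjects
    where both clusters are non-empty (NaN entries ignored)."""
    if not matrices:
        raise InputError("no matrices to average")
    clusters = sorted(set().union(*[m.index for m in matrices]))
    aligned = [m.reindex(index=clusters, columns=clusters) for m in matrices]
    stack = np.stack([m.to_numpy(dtype=float) for m in aligned])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    return pd.DataFrame(mean, index=clusters, columns=clusters)


# ---------------------------------------------------------------------------
# permutation test


def permutation_pvalue(observed_p: float, permuted_ps: np.ndarray) -> float:
    """Permutation p-value exactly as defined by the protocol:
    (number of permutations with p* strictly below the observed p) / n."""
    permuted_ps = np.asarray(permuted_ps, dtype=float)
    return float(np.count_nonzero(permuted_ps < observed_p)
                 / permuted_ps.size)


@dataclass
class PermutationTestResult:
    anova_p: float
    anova_perm_p: float
    pairs: pd.DataFrame  # cluster_a, cluster_b, tukey_p, perm_p
    n_perm: int
    excluded_clusters: list


def _group_stats(values: np.ndarray, onehot: np.ndarray,
                 sizes: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-row one-way ANOVA decomposition; values is (m, n), onehot is
    (n, k)."""
    n = values.shape[1]
    k = sizes.size
    sums = values @ onehot
    means = sums / sizes
    sq = (values**2) @ onehot
    ssw = (sq - sums**2 / sizes).sum(axis=1)
    grand = values.sum(axis=1) / n
    ssb = (sums**2 / sizes).sum(axis=1) - n * grand**2
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stat = (ssb / (k - 1)) / msw
    return means, msw, f_stat


def mutation_permutation_test(freqs: pd.Series, labels: pd.Series,
                              n_perm: int = 100,
                              seed: int | np.random.Generator | None = None
                              ) -> PermutationTestResult:
    """Test whether per-cell mutation frequencies differ among clusters.

    Observed data get a one-way ANOVA and Tukey's HSD for every cluster
    pair. Frequencies are then shuffled across cells ``n_perm`` times
    with labels fixed, and for each pair the permutation p-value is the
    fraction of permutations whose Tukey p falls strictly below the
    observed one. Because the Tukey p is strictly decreasing in the
    studentized-range statistic q (group sizes fixed), the comparison is
    carried out on q, avoiding n_perm * n_pairs distribution-function
    evaluations. An analogous ANOVA-level permutation p is also reported.

    Cells with missing frequencies are dropped listwise; clusters with
    fewer than 2 cells are excluded from the test.
    """
    if n_perm < 1:
        raise InputError("n_perm must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    df = pd.DataFrame({"freq": freqs, "label": labels}).dropna()
    counts = df["label"].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        log.warning("clusters with <2 cells excluded: %s", small)
        df = df[~df["label"].isin(small)]
    groups = sorted(df["label"].unique())
    k = len(groups)
    if k < 2:
        raise InputError("need >= 2 clusters with >= 2 cells each")
    values = df["freq"].to_numpy(dtype=float)
    gidx = df["label"].map({g: i for i, g in enumerate(groups)}).to_numpy()
    n = values.size
    onehot = np.zeros((n, k))
    onehot[np.arange(n), gidx] = 1.0
    sizes = onehot.sum(axis=0)
    dof = n - k

    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    all_vals = np.vstack([values, perms])
    means, msw, f_stat = _group_stats(all_vals, onehot, sizes)

    pair_idx = list(itertools.combinations(range(k), 2))
    q = np.empty((all_vals.shape[0], len(pair_idx)))
    for col, (i, j) in enumerate(pair_idx):
        se = np.sqrt(msw / 2.0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        with np.errstate(divide="ignore", invalid="ignore"):
            q[:, col] = np.abs(means[:, i] - means[:, j]) / se
    q = np.nan_to_num(q, nan=0.0)  # zero-variance data: q = 0, p = 1

    tukey_p = stats.studentized_range.sf(q[0], k, dof)
    anova_p = float(stats.f.sf(f_stat[0], k - 1, dof)) if np.isfinite(
        f_stat[0]) else 1.0
    # p* < p_obs  <=>  q* > q_obs (strict, by monotonicity of the sf)
    perm_p = (q[1:] > q[0]).sum(axis=0) / n_perm
    anova_perm_p = float(np.count_nonzero(f_stat[1:] > f_stat[0]) / n_perm)

    pairs = pd.DataFrame({
        "cluster_a": [groups[i] for i, _ in pair_idx],
        "cluster_b": [groups[j] for _, j in pair_idx],
        "tukey_p": tukey_p,
        "perm_p": perm_p,
    })
    return PermutationTestResult(anova_p, anova_perm_p, pairs, n_perm, small)


# ---------------------------------------------------------------------------
# expression / VDJ join


def join_vdj_expression(barcodes, records: pd.DataFrame,
                        dominance_min_umi: int = 100
                        ) -> tuple[pd.DataFrame, float, pd.Series]:
    """Inner-join rearrangements onto expression barcodes.

    Returns (matched table, match rate over expression cells, per-cell
    dominance flag: consensus-isotype UMI count above
    ``dominance_min_umi``). Duplicate barcodes keep the record with the
    highest duplicate_count.
    """
    barcodes = pd.Index(barcodes)
    df = records.copy()
    dups = df["cell_id"].duplicated(keep=False)
    if dups.any():
        log.info("%d duplicate-barcode records resolved by UMI weight",
                 int(dups.sum()))
        df = (df.sort_values("duplicate_count", ascending=False)
                .drop_duplicates("cell_id", keep="first"))
    matched = df[df["cell_id"].isin(barcodes)].reset_index(drop=True)
    rate = len(matched) / len(barcodes) if len(barcodes) else np.nan
    dominance = pd.Series(
        matched["duplicate_count"].to_numpy() > dominance_min_umi,
        index=matched["cell_id"], name="ig_dominant")
    return matched, rate, dominance
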