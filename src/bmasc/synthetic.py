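"""Paired expression + repertoire simulator with exhaustive ground truth.

The generator states a small synthetic world shaped like a bone-marrow
antibody-secreting-cell (ASC) experiment: negative-binomial UMI counts
with cluster-specific marker genes, high immunoglobulin and modest
mitochondrial UMI fractions, a few contaminant cells spiking a single
diagnostic marker, and a clonally structured heavy-chain repertoire
whose V sequences are mutated away from germline at a known per-base
rate with codon-level replacement/silent truth. Every stochastic choice
flows from one seeded generator, so outputs are a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import sparse

from .config import CONTAMINANT_MARKERS, ConfigError, SimulationConfig
from .errors import InputError
from .repertoire import REGION_LABELS, classify_substitution

__all__ = [
    "GroundTruth",
    "simulate_expression",
    "simulate_repertoire",
    "simulate_qc_metrics",
    "mutate_v_sequence",
    "V_REGION_LAYOUT",
]

_MITO_GENES = ("MT-ND1", "MT-ND2", "MT-CO1", "MT-CO2", "MT-CO3",
               "MT-ATP6", "MT-ATP8", "MT-CYB", "MT-ND3", "MT-ND4")
_IG_CONSTANT = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2",
                "IGHM", "IGHD", "IGHE", "IGKC", "IGLC1", "IGLC2")
# IgG1-dominant isotype distribution typical of BM ASCs
_ISOTYPES = ("IGHG1", "IGHG2", "IGHG3", "IGHG4", "IGHA1", "IGHA2",
             "IGHM", "IGHD", "IGHE")
_ISOTYPE_P = (0.35, 0.14, 0.07, 0.03, 0.18, 0.05, 0.15, 0.02, 0.01)

# 1-based closed intervals on the (ungapped) V alignment, in frame 0;
# lengths are codon multiples and tile the 312 nt template exactly.
V_REGION_LAYOUT = {"fwr1": (1, 75), "cdr1": (76, 99), "fwr2": (100, 150),
                   "cdr2": (151, 174), "fwr3": (175, 312)}
V_LENGTH = 312

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    cluster_labels: pd.Series | None = None  # cell -> cluster id
    lineage_ids: pd.Series | None = None  # sequence_id -> true lineage
    mutation_truth: pd.DataFrame | None = None  # per record x region counts
    contaminant_cells: list = field(default_factory=list)
    qc_fail_cells: dict = field(default_factory=dict)  # rule -> cell ids
    marker_genes: dict = field(default_factory=dict)  # cluster -> symbols
    tf_genes: dict = field(default_factory=dict)  # cluster -> spiked TF


def _rng_for(config: SimulationConfig, stream: int,
             rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng([config.seed, stream])


def _gene_names(config: SimulationConfig) -> tuple[pd.DataFrame, dict, dict]:
    n_mito = min(config.n_mito_genes, len(_MITO_GENES))
    mito = list(_MITO_GENES[:n_mito])
    ig = list(_IG_CONSTANT[:config.n_ig_genes])
    ig += [f"IGHV{1 + i % 7}-{2 + i}" for i in range(len(ig), config.n_ig_genes)]
    markers = {c: [f"MK{c}G{j}" for j in range(config.marker_genes_per_cluster)]
               for c in range(config.n_clusters)}
    tfs = {c: f"TF{c}" for c in range(config.n_clusters)}
    special = (mito + ig + list(CONTAMINANT_MARKERS) + ["IGFBP3"]
               + [g for gs in markers.values() for g in gs]
               + list(tfs.values()))
    n_rest = config.n_genes - len(special)
    if n_rest < 0:
        raise ConfigError(
            f"n_genes={config.n_genes} too small for the "
            f"{len(special)} designated genes")
    names = special + [f"GENE{i:04d}" for i in range(n_rest)]
    var = pd.DataFrame(index=pd.Index(names, name="gene"))
    var["mito"] = var.index.str.startswith("MT-")
    var["ig"] = [g in set(ig) for g in names]
    var["contaminant_marker"] = [g in set(CONTAMINANT_MARKERS) for g in names]
    return var, markers, tfs


def simulate_expression(config: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[AnnData, GroundTruth]:
    """Simulate a cells x genes UMI count matrix with cluster structure.

    Background genes draw from a negative binomial (variance
    mu + dispersion * mu^2) whose mean is boosted ``marker_fold_change``-
    fold for a cluster's marker genes and its designated transcription
    factor. Mitochondrial and Ig gene totals are added per cell to hit a
    target UMI fraction drawn from the configured ranges, and a
    ``contaminant_fraction`` of cells spike one diagnostic non-ASC
    marker. Deterministic under a fixed config/seed.
    """
    rng = _rng_for(config, 0, rng)
    var, markers, tfs = _gene_names(config)
    n_cells, n_genes = config.n_cells, config.n_genes
    names = var.index.to_numpy()

    cluster = rng.choice(config.n_clusters, size=n_cells,
                         p=np.asarray(config.cluster_proportions))
    barcodes = pd.Index([f"CELL{i:05d}-1" for i in range(n_cells)],
                        name="cell_id")

    special = var["mito"] | var["ig"] | var["contaminant_marker"]
    bg_idx = np.flatnonzero(~special.to_numpy())
    gene_pos = {g: i for i, g in enumerate(names)}

    # per-gene baseline means with lognormal spread around nb_mean_base
    base = config.nb_mean_base * rng.lognormal(-0.125, 0.5, size=bg_idx.size)
    mu = np.tile(base, (n_cells, 1))
    boost = {}
    for c in range(config.n_clusters):
        for g in markers[c] + [tfs[c]]:
            boost.setdefault(g, []).append(c)
    bg_pos = {g: j for j, g in enumerate(names[bg_idx])}
    for g, cs in boost.items():
        col = bg_pos[g]
        mu[np.isin(cluster, cs), col] *= config.marker_fold_change

    size = 1.0 / config.nb_dispersion
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)
    counts[:, bg_idx] = rng.negative_binomial(size, size / (size + mu))

    bg_total = counts.sum(axis=1)
    f_m = rng.uniform(*config.mito_fraction_range, size=n_cells)
    f_g = rng.uniform(*config.ig_fraction_range, size=n_cells)
    scale = bg_total / np.clip(1.0 - f_m - f_g, 1e-6, None)
    mito_tot = rng.poisson(scale * f_m)
    ig_tot = rng.poisson(scale * f_g)
    mito_idx = np.flatnonzero(var["mito"].to_numpy())
    ig_idx = np.flatnonzero(var["ig"].to_numpy())
    w_mito = rng.dirichlet(np.full(mito_idx.size, 2.0))
    w_ig = rng.dirichlet(np.full(ig_idx.size, 2.0))
    for i in range(n_cells):
        counts[i, mito_idx] = rng.multinomial(mito_tot[i], w_mito)
        counts[i, ig_idx] = rng.multinomial(ig_tot[i], w_ig)

    n_cont = int(round(config.contaminant_fraction * n_cells))
    cont_cells = (rng.choice(n_cells, size=n_cont, replace=False)
                  if n_cont else np.array([], dtype=int))
    for i in cont_cells:
        marker = CONTAMINANT_MARKERS[rng.integers(len(CONTAMINANT_MARKERS))]
        counts[i, gene_pos[marker]] = 1 + rng.poisson(3)

    adata = AnnData(
        X=sparse.csr_matrix(counts),
        obs=pd.DataFrame({"true_cluster": cluster}, index=barcodes),
        var=var.copy(),
    )
    truth = GroundTruth(
        cluster_labels=pd.Series(cluster, index=barcodes, name="cluster"),
        contaminant_cells=[barcodes[i] for i in sorted(cont_cells)],
        marker_genes=markers,
        tf_genes=tfs,
    )
    return adata, truth


def simulate_qc_metrics(n_per_rule: int = 10, n_clean: int = 50,
                        rng: np.random.Generator | int | None = None
                        ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Per-cell QC metrics with ``n_per_rule`` cells violating exactly
    one published filter each, plus clean cells passing all of them.

    Metric-level (no count matrix) because the doublet caps require
    thousands of genes; the filters operate on these metrics directly.
    """
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    clean = dict(n_umi=5000, n_genes=2000, mito_fraction=0.05,
                 ig_fraction=0.50)
    designs = {
        "mito_high": dict(clean, mito_fraction=0.35),
        "genes_low": dict(clean, n_genes=700),
        "umi_low": dict(n_umi=950, n_genes=900, mito_fraction=0.05,
                        ig_fraction=0.50),
        "genes_high": dict(clean, n_genes=6500, n_umi=20000),
        "umi_high": dict(clean, n_umi=70000, n_genes=5000),
        "ig_low": dict(clean, ig_fraction=0.03),
    }
    rows, index, truth = [], [], {r: [] for r in designs}
    i = 0
    for rule, d in designs.items():
        for _ in range(n_per_rule):
            cid = f"QC{i:04d}"
            rows.append(dict(d))
            index.append(cid)
            truth[rule].append(cid)
            i += 1
    for _ in range(n_clean):
        jitter = dict(
            n_umi=int(clean["n_umi"] + rng.integers(-500, 500)),
            n_genes=int(clean["n_genes"] + rng.integers(-200, 200)),
            mito_fraction=float(rng.uniform(0.01, 0.15)),
            ig_fraction=float(rng.uniform(0.2, 0.8)),
        )
        rows.append(jitter)
        index.append(f"QC{i:04d}")
        i += 1
    metrics = pd.DataFrame(rows, index=pd.Index(index, name="cell_id"))
    return metrics, truth


def mutate_v_sequence(germline: str, rate: float, frame_offset: int = 0,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[str, pd.DataFrame]:
    """Substitution-only point mutation of a germline V sequence.

    Each base mutates independently with probability ``rate`` to one of
    the three other bases. The returned truth table records, per site,
    the 0-based position, germline and new base, and the
    replacement/silent status obtained by translating the affected codon
    with the single substitution applied in germline context (standard
    genetic code; sites outside complete codons of the given frame are
    'unclassifiable').
    """
    if any(b not in "ACGT" for b in germline):
        raise InputError("germline must be over A/C/G/T")
    if frame_offset not in (0, 1, 2):
        raise InputError("frame_offset must be 0, 1 or 2")
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    n = len(germline)
    arr = np.frombuffer(germline.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(n) < rate)
    records = []
    for pos in hits:
        old = arr[pos]
        choices = _BASES[_BASES != old]
        new = choices[rng.integers(3)]
        arr[pos] = new
        codon_i = (pos - frame_offset) // 3 if pos >= frame_offset else -1
        start = frame_offset + 3 * codon_i
        if codon_i < 0 or start + 3 > n:
            status = "unclassifiable"
        else:
            codon = germline[start:start + 3]
            status = classify_substitution(codon, pos - start,
                                           new.decode())
        records.append((int(pos), old.decode(), new.decode(), status))
    truth = pd.DataFrame(
        records, columns=["position", "germline_base", "new_base", "status"])
    return arr.tobytes().decode(), truth


def _region_counts(truth_sites: pd.DataFrame) -> dict[str, tuple[int, int, int]]:
    """Aggregate per-site mutation truth into per-region
    (n_mutations, n_replacement, n_silent) using the fixed V layout."""
    out = {}
    pos = truth_sites["position"].to_numpy()
    status = truth_sites["status"].to_numpy()
    masks = {}
    for reg, (s, e) in V_REGION_LAYOUT.items():
        masks[REGION_LABELS[reg]] = (pos >= s - 1) & (pos < e)
    masks["CDR"] = masks["CDR1"] | masks["CDR2"]
    masks["FR"] = masks["FR1"] | masks["FR2"] | masks["FR3"]
    masks["V"] = np.ones(pos.size, dtype=bool)
    for name, m in masks.items():
        out[name] = (int(m.sum()),
                     int(((status == "replacement") & m).sum()),
                     int(((status == "silent") & m).sum()))
    return out


def simulate_repertoire(config: SimulationConfig, labels: pd.Series,
                        rng: np.random.Generator | None = None,
                        homology_guarantee: float = 0.85
                        ) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an AIRR rearrangement table with known clonal structure.

    A ``vdj_match_rate`` fraction of labelled cells receive one
    heavy-chain record. Lineage sizes follow a Zipf law with exponent
    ``lineage_size_power``; each lineage owns one germline V template,
    one J call and one CDR3 length, and members' CDR3s diverge from the
    lineage founder by at most half the distance budget implied by
    ``homology_guarantee``, so the true partition is recoverable by
    single-linkage clustering at that threshold. V sequences are mutated
    at ``v_mutation_rate`` with codon-level replacement/silent truth.
    """
    lo, hi = config.cdr3_length_range
    if hi - lo < 0 or lo < 3:
        raise ConfigError("cdr3_length_range must span >= 3 nt")
    rng = _rng_for(config, 1, rng)
    cells = labels.index.to_numpy()
    n_vdj = int(round(config.vdj_match_rate * cells.size))
    chosen = rng.choice(cells, size=n_vdj, replace=False)

    k = config.n_lineages
    weights = (np.arange(1, k + 1, dtype=float)
               ** -config.lineage_size_power)
    weights /= weights.sum()
    # every lineage gets at least one record (real repertoires are
    # singleton-rich); extra cells follow the Zipf size law
    if n_vdj <= k:
        lineage_of_cell = rng.permutation(np.arange(n_vdj))
    else:
        lineage_of_cell = rng.permutation(np.concatenate(
            [np.arange(k), rng.choice(k, size=n_vdj - k, p=weights)]))

    # lineage definitions
    n_templates = max(5, k // 10)
    templates = ["".join(rng.choice(list("ACGT"), V_LENGTH))
                 for _ in range(n_templates)]
    v_names = [f"IGHV{1 + i % 7}-{1 + i // 7}*01" for i in range(n_templates)]
    lin_template = rng.integers(n_templates, size=k)
    lin_j = rng.integers(1, 7, size=k)
    lin_len = rng.integers(lo, hi + 1, size=k)
    founders = ["".join(rng.choice(list("ACGT"), lin_len[l]))
                for l in range(k)]

    coord_cols = {}
    for reg, (s, e) in V_REGION_LAYOUT.items():
        coord_cols[f"{reg}_start"] = s
        coord_cols[f"{reg}_end"] = e

    rows, truth_rows, lineage_ids = [], [], {}
    order = np.argsort(chosen)  # deterministic record order by barcode
    for n, i in enumerate(order):
        cell, lin = chosen[i], int(lineage_of_cell[i])
        seq_id = f"seq{n:05d}"
        length = int(lin_len[lin])
        max_div = int(np.floor((1.0 - homology_guarantee) * length / 2))
        n_div = min(int(rng.binomial(length, config.within_lineage_divergence)),
                    max_div)
        cdr3 = np.frombuffer(founders[lin].encode(), dtype="S1").copy()
        if n_div:
            sites = rng.choice(length, size=n_div, replace=False)
            for pos in sites:
                alt = _BASES[_BASES != cdr3[pos]]
                cdr3[pos] = alt[rng.integers(3)]
        germ = templates[lin_template[lin]]
        mutated, sites = mutate_v_sequence(germ, config.v_mutation_rate,
                                           0, rng)
        dup = int(np.round(np.exp(rng.normal(3.5, 1.0)))) + 1
        rows.append({
            "sequence_id": seq_id, "cell_id": cell, "subject_id": "S1",
            "v_call": v_names[lin_template[lin]],
            "j_call": f"IGHJ{lin_j[lin]}*01",
            "c_call": rng.choice(_ISOTYPES, p=_ISOTYPE_P),
            "cdr3": cdr3.tobytes().decode(),
            "v_sequence_alignment": mutated,
            "v_germline_alignment": germ,
            "v_frame_offset": 0,
            "duplicate_count": dup,
            **coord_cols,
        })
        lineage_ids[seq_id] = f"L{lin:04d}"
        for region, (nm, nr, ns) in _region_counts(sites).items():
            truth_rows.append({"sequence_id": seq_id, "region": region,
                               "n_mutations": nm, "n_replacement": nr,
                               "n_silent": ns})

    table = pd.DataFrame(rows)
    truth = GroundTruth(
        cluster_labels=labels,
        lineage_ids=pd.Series(lineage_ids, name="lineage_id"),
        mutation_truth=pd.DataFrame(truth_rows),
    )
    return table, truth
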