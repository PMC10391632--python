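"""Readers and writers for the standard on-disk formats.

Count matrices travel as a 10x-style MatrixMarket triplet (matrix.mtx
stored features x barcodes, plus barcodes.tsv and features.tsv);
rearrangements as AIRR Rearrangement TSV; gene sets as GMT; interaction
edges as a three-column STRING-like TSV. Internal coordinates are
0-based half-open; AIRR columns stay 1-based closed and are converted
only at this boundary.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from anndata import AnnData
from scipy import io as scipy_io
from scipy import sparse

from .errors import FormatError

log = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_airr",
    "write_airr",
    "read_gene_sets",
    "read_interaction_edges",
    "write_report_tables",
    "AIRR_REQUIRED_COLUMNS",
]

AIRR_REQUIRED_COLUMNS = (
    "sequence_id", "cell_id", "v_call", "j_call", "c_call", "cdr3",
    "v_sequence_alignment", "v_germline_alignment", "duplicate_count",
    "fwr1_start", "fwr1_end", "cdr1_start", "cdr1_end",
    "fwr2_start", "fwr2_end", "cdr2_start", "cdr2_end",
    "fwr3_start", "fwr3_end",
)
_REGION_ORDER = ("fwr1", "cdr1", "fwr2", "cdr2", "fwr3")


def read_count_matrix(path: str | Path) -> AnnData:
    """Read a MatrixMarket triplet directory into cells x genes AnnData.

    The matrix file is features x barcodes (10x convention) and is
    transposed on read; counts are kept integer and sparse.
    """
    path = Path(path)
    mat = sparse.csr_matrix(scipy_io.mmread(path / "matrix.mtx").T)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0]
    if mat.shape[0] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[0]} barcodes but barcodes.tsv lists "
            f"{len(barcodes)}")
    if mat.shape[1] != len(features):
        raise FormatError(
            f"matrix has {mat.shape[1]} features but features.tsv lists "
            f"{len(features)}")
    return AnnData(
        X=mat.astype(np.int64),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(features, name="gene")),
    )


def write_count_matrix(adata: AnnData, path: str | Path) -> None:
    """Write cells x genes AnnData as a 10x-style MTX triplet."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    x = adata.X if sparse.issparse(adata.X) else sparse.csr_matrix(adata.X)
    scipy_io.mmwrite(path / "matrix.mtx", sparse.coo_matrix(x.T),
                     field="integer")
    adata.obs_names.to_series().to_csv(path / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
    adata.var_names.to_series().to_csv(path / "features.tsv", sep="\t",
                                       header=False, index=False)


def _validate_airr(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop records violating type invariants; report them by row."""
    problems = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, rec) in enumerate(df.iterrows()):
        row = i + 2  # 1-based, after the header line
        seq = str(rec["v_sequence_alignment"])
        germ = str(rec["v_germline_alignment"])
        if len(seq) != len(germ):
            problems.append(f"row {row}: alignment lengths differ "
                            f"({len(seq)} vs {len(germ)})")
            keep[i] = False
            continue
        prev_end = 0
        for reg in _REGION_ORDER:
            start, end = rec[f"{reg}_start"], rec[f"{reg}_end"]
            if pd.isna(start) or pd.isna(end):
                continue
            if not (prev_end < int(start) <= int(end)):
                problems.append(
                    f"row {row}: region {reg} interval out of order")
                keep[i] = False
                break
            prev_end = int(end)
    return df[keep].reset_index(drop=True), problems


def read_airr(path: str | Path, validate: bool = True
              ) -> tuple[pd.DataFrame, list[str]]:
    """Read an AIRR Rearrangement TSV.

    Returns (table, report): invalid records (unequal alignment lengths,
    out-of-order region intervals) are dropped and listed in the report
    with their row numbers. A missing required column raises FormatError.
    """
    df = pd.read_csv(path, sep="\t", dtype={"cdr3": str})
    missing = [c for c in AIRR_REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required AIRR column(s): {missing}")
    if df.empty or not validate:
        return df, []
    table, problems = _validate_airr(df)
    if problems:
        log.warning("%d invalid AIRR records dropped", len(problems))
    return table, problems


def write_airr(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file into {set name: unique member symbols}."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"line {lineno}: GMT line needs name, description and "
                    f"at least one member")
            sets[fields[0]] = {g for g in fields[2:] if g}
    return sets


def read_interaction_edges(path: str | Path) -> pd.DataFrame:
    """Read a STRING-like edge TSV (protein_a, protein_b,
    combined_score in 0-1000). Self-loops are dropped; duplicate
    undirected edges keep their first occurrence."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise FormatError("edge table needs three columns")
    df = df.iloc[:, :3]
    df.columns = ["protein_a", "protein_b", "combined_score"]
    scores = pd.to_numeric(df["combined_score"], errors="coerce")
    if scores.isna().any() or not np.allclose(scores, scores.round()):
        raise FormatError("combined_score must be integer")
    if ((scores < 0) | (scores > 1000)).any():
        raise FormatError("combined_score must lie in [0, 1000]")
    df["combined_score"] = scores.astype(int)
    df = df[df["protein_a"] != df["protein_b"]]
    lo = df[["protein_a", "protein_b"]].min(axis=1)
    hi = df[["protein_a", "protein_b"]].max(axis=1)
    df = df.assign(protein_a=lo, protein_b=hi)
    df = df.drop_duplicates(["protein_a", "protein_b"]).reset_index(drop=True)
    return df


def write_report_tables(bundle: dict[str, pd.DataFrame], out_dir: str | Path,
                        parameters: dict | None = None,
                        seed: int | None = None) -> dict:
    """Write one TSV per result table plus a JSON manifest recording
    files, parameters and seed. Returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    from . import __version__
    files = []
    for name, table in bundle.items():
        fname = f"{name}.tsv"
        table.to_csv(out_dir / fname, sep="\t")
        files.append(fname)
    manifest = {
        "files": files,
        "parameters": parameters or {},
        "seed": seed,
        "version": __version__,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
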