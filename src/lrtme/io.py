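"""Readers and writers for the delimited-text formats shared by all
modules.

Cell tables travel as TSV (tab separation because marker names may
contain commas), expression matrices as MatrixMarket triplets with
sibling cell/gene annotation TSVs.  Writers prepend ``#``-prefixed header
comments recording the tool version and a parameter digest so every
output is traceable to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from . import __version__
from .panels import SUBTYPE_LABELS
from .phenotyping import CELL_TABLE_COLUMNS
from .sc import lognormalize_adata


class FormatError(ValueError):
    """Input file violates the expected schema."""


def _params_digest(params: Mapping | None) -> str:
    payload = json.dumps(params or {}, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _header_lines(params: Mapping | None) -> str:
    return (
        f"# lrtme v{__version__}\n"
        f"# params_digest={_params_digest(params)}\n"
    )


def write_table(
    df: pd.DataFrame, path: str | Path, params: Mapping | None = None
) -> None:
    """Write a TSV with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_lines(params))
        df.to_csv(fh, sep="\t", index=False)


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a spatial cell table.

    Required columns: ``sample_id, cell_id, x_um, y_um`` plus at least one
    marker column.  Malformed rows (non-numeric coordinates) and duplicate
    ``(sample_id, cell_id)`` pairs are rejected with line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    value_cols = [c for c in df.columns if c not in ("sample_id", "cell_id")]
    if len(value_cols) <= 2:
        raise FormatError(f"{path}: no marker columns found")
    # header comments + column row precede data row 0
    n_header = 1
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_header += 1
            else:
                break
    out = df[["sample_id", "cell_id"]].copy()
    for c in value_cols:
        converted = pd.to_numeric(df[c], errors="coerce")
        bad = converted.isna() & df[c].notna()
        if bad.any():
            lines = [int(i) + n_header + 1 for i in df.index[bad][:5]]
            raise FormatError(
                f"{path}: non-numeric value in column {c!r} at line(s) "
                f"{lines}"
            )
        if converted.isna().any():
            lines = [int(i) + n_header + 1 for i in df.index[converted.isna()][:5]]
            raise FormatError(
                f"{path}: missing value in column {c!r} at line(s) {lines}"
            )
        out[c] = converted
    if not np.isfinite(out[["x_um", "y_um"]].to_numpy()).all():
        raise FormatError(f"{path}: non-finite coordinates")
    dup = out.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        lines = [int(i) + n_header + 1 for i in out.index[dup][:5]]
        raise FormatError(
            f"{path}: duplicate (sample_id, cell_id) at line(s) {lines}"
        )
    return out


def write_cell_table(
    cells: pd.DataFrame, path: str | Path, params: Mapping | None = None
) -> None:
    write_table(cells, path, params)


def write_expression(
    adata: ad.AnnData, prefix: str | Path, params: Mapping | None = None
) -> dict:
    """Write an expression dataset as MTX + annotation TSVs.

    Produces ``<prefix>.mtx`` (raw counts when available, otherwise the
    stored matrix), ``<prefix>.cells.tsv`` (cell_id, sample_id, subtype,
    cluster plus an ``is_counts`` header flag), and ``<prefix>.genes.tsv``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    is_counts = "counts" in adata.layers
    mat = adata.layers["counts"] if is_counts else adata.X
    spio.mmwrite(str(prefix) + ".mtx", sparse.csr_matrix(np.asarray(mat)))
    cells = adata.obs.reset_index(names="cell_id")[
        ["cell_id", "sample_id", "subtype", "cluster"]
    ]
    with open(str(prefix) + ".cells.tsv", "w") as fh:
        fh.write(_header_lines(params))
        fh.write(f"# is_counts={str(is_counts).lower()}\n")
        if "library_size" in adata.uns:
            fh.write(f"# library_size={int(adata.uns['library_size'])}\n")
        cells.to_csv(fh, sep="\t", index=False)
    with open(str(prefix) + ".genes.tsv", "w") as fh:
        fh.write(_header_lines(params))
        pd.DataFrame({"gene": list(adata.var_names)}).to_csv(
            fh, sep="\t", index=False
        )
    return {
        "mtx": str(prefix) + ".mtx",
        "cells": str(prefix) + ".cells.tsv",
        "genes": str(prefix) + ".genes.tsv",
    }


def read_expression(
    mtx_path: str | Path,
    cells_path: str | Path,
    genes_path: str | Path,
) -> ad.AnnData:
    """Read an expression dataset from MTX + annotation TSVs.

    The ``is_counts`` header flag in the cell annotation file declares
    whether the matrix holds raw counts; if so, library-size
    normalization and log2(x+1) are applied on load (the normalized
    matrix lands in ``.X``, the counts in ``.layers['counts']``).
    """
    mat = spio.mmread(str(mtx_path))
    mat = np.asarray(sparse.csr_matrix(mat).todense(), dtype=float)
    flags: dict[str, str] = {}
    with open(cells_path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                flags[k.strip()] = v.strip()
    cells = pd.read_csv(cells_path, sep="\t", comment="#")
    genes = pd.read_csv(genes_path, sep="\t", comment="#")
    if "gene" not in genes.columns:
        raise FormatError(f"{genes_path}: expected a 'gene' column")
    if mat.shape[0] != len(cells):
        raise FormatError(
            f"matrix has {mat.shape[0]} rows but {len(cells)} cell "
            "annotations"
        )
    if mat.shape[1] != len(genes):
        raise FormatError(
            f"matrix has {mat.shape[1]} columns but {len(genes)} gene "
            "annotations"
        )
    required = {"cell_id", "sample_id", "subtype", "cluster"}
    missing = required - set(cells.columns)
    if missing:
        raise FormatError(f"{cells_path}: missing columns {sorted(missing)}")
    unknown = set(cells["subtype"].astype(str)) - set(SUBTYPE_LABELS)
    if unknown:
        raise FormatError(
            f"{cells_path}: unknown subtype label(s) {sorted(unknown)}; "
            f"expected one of {list(SUBTYPE_LABELS)}"
        )
    obs = cells.set_index("cell_id")
    obs.index = obs.index.astype(str)
    obs.index.name = None
    adata = ad.AnnData(
        X=mat, obs=obs, var=pd.DataFrame(index=genes["gene"].astype(str))
    )
    if flags.get("is_counts", "false") == "true":
        adata.layers["counts"] = mat.copy()
        library_size = int(flags.get("library_size", 1000))
        adata.uns["library_size"] = library_size
        lognormalize_adata(adata, library_size)
    return adata
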