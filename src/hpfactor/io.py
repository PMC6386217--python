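"""Count-matrix readers/writers and model serialization.

Counts load from Matrix Market coordinate files (with a companion gene TSV)
or dense whitespace-delimited tables; explicit zeros are dropped with a
warning, duplicates rejected, and orientation normalized to cells x genes.
Fitted models round-trip through a single ``.npz`` archive holding every
variational array plus a JSON manifest block sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

from .core import FittedModel, HyperParams, SparseCountMatrix, VariationalState

__all__ = [
    "load_counts",
    "save_counts",
    "save_model",
    "load_model",
]

logger = logging.getLogger("hpfactor")

FORMAT_VERSION = 1

_STATE_FIELDS = (
    "gamma_shape",
    "gamma_rate",
    "lambda_shape",
    "lambda_rate",
    "kappa_shape",
    "kappa_rate",
    "tau_shape",
    "tau_rate",
)


def _from_coo(
    mat: coo_matrix,
    cell_ids: list[str] | None,
    gene_names: list[str] | None,
) -> SparseCountMatrix:
    data = np.asarray(mat.data)
    if not np.allclose(data, np.rint(data)) or np.any(data < 0):
        raise ValueError("counts must be non-negative integers")
    keep = data != 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} explicit zero entries", stacklevel=2)
    return SparseCountMatrix(
        n_cells=mat.shape[0],
        n_genes=mat.shape[1],
        rows=mat.row[keep],
        cols=mat.col[keep],
        counts=np.rint(data[keep]).astype(np.int64),
        cell_ids=cell_ids or [],
        gene_names=gene_names or [],
    )


def load_counts(
    path: str | Path,
    format: str = "mtx",
    gene_file: str | Path | None = None,
    cells_as_rows: bool = True,
) -> SparseCountMatrix:
    """Load a cells x genes count matrix.

    ``mtx``: 1-based Matrix Market coordinate file; ``gene_file`` is a TSV
    whose first column holds gene names (one per matrix column).
    ``dense_tsv``: whitespace-delimited table with a header row of gene
    names and the first column holding cell ids; set ``cells_as_rows=False``
    if genes are rows.  Duplicate coordinates raise; explicit zeros are
    dropped with a warning.
    """
    path = Path(path)
    if format == "mtx":
        mat = mmread(str(path))
        coo = coo_matrix(mat)
        # scipy sums duplicates silently on conversion; detect them first
        flat = coo.row.astype(np.int64) * coo.shape[1] + coo.col
        if np.unique(flat).size != flat.size:
            raise ValueError("duplicate coordinates in MTX file")
        gene_names = None
        if gene_file is not None:
            gene_names = (
                pd.read_csv(gene_file, sep="\t", header=None)[0].astype(str).tolist()
            )
            if len(gene_names) != coo.shape[1]:
                raise ValueError(
                    f"gene file has {len(gene_names)} entries but matrix has "
                    f"{coo.shape[1]} gene columns"
                )
        return _from_coo(coo, None, gene_names)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep=r"\s+", index_col=0)
        if not cells_as_rows:
            df = df.T
        coo = coo_matrix(df.to_numpy())
        return _from_coo(coo, df.index.astype(str).tolist(), df.columns.astype(str).tolist())
    raise ValueError(f"unknown format {format!r}")


def save_counts(X: SparseCountMatrix, prefix: str | Path) -> dict[str, Path]:
    """Write ``<prefix>.mtx`` plus gene and cell TSVs; returns the paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": prefix.with_suffix(".mtx"),
        "genes": prefix.parent / f"{prefix.name}.genes.tsv",
        "cells": prefix.parent / f"{prefix.name}.cells.tsv",
    }
    mmwrite(str(paths["mtx"]), X.to_coo(), field="integer")
    pd.Series(X.gene_names).to_csv(paths["genes"], sep="\t", index=False, header=False)
    pd.Series(X.cell_ids).to_csv(paths["cells"], sep="\t", index=False, header=False)
    return paths


def save_model(model: FittedModel, path: str | Path, manifest: dict | None = None) -> None:
    """Serialize a fitted model to a single npz archive with a JSON manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h = model.hyper
    meta = {
        "format_version": FORMAT_VERSION,
        "hyper": {
            "K": h.K,
            "a": h.a,
            "a_prime": h.a_prime,
            "b_prime": h.b_prime,
            "c": h.c,
            "c_prime": h.c_prime,
            "d_prime": h.d_prime,
        },
        "converged": bool(model.converged),
        "seed": int(model.seed),
        "n_trials": int(model.n_trials),
        "gene_names": list(model.gene_names),
        "cell_ids": list(model.cell_ids),
        "manifest": manifest or {},
    }
    arrays = {f: getattr(model.state, f) for f in _STATE_FIELDS}
    arrays["loss_history"] = np.asarray(model.loss_history, dtype=np.float64)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path: str | Path) -> FittedModel:
    """Load a model archive written by :func:`save_model`.

    Raises on truncated/corrupt archives and on unknown format versions.
    """
    path = Path(path)
    try:
        with np.load(path) as npz:
            arrays = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise ValueError(f"corrupt or unreadable model archive {path}: {exc}") from exc
    missing = [f for f in (*_STATE_FIELDS, "meta_json") if f not in arrays]
    if missing:
        raise ValueError(f"model archive missing arrays: {missing}")
    meta = json.loads(arrays["meta_json"].tobytes().decode("utf-8"))
    version = meta.get("format_version")
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    state = VariationalState(*(arrays[f] for f in _STATE_FIELDS))
    hyper = HyperParams(**meta["hyper"])
    history = [(int(it), float(v)) for it, v in arrays["loss_history"]]
    return FittedModel(
        hyper=hyper,
        state=state,
        loss_history=history,
        converged=meta["converged"],
        seed=meta["seed"],
        n_trials=meta["n_trials"],
        gene_names=meta["gene_names"],
        cell_ids=meta["cell_ids"],
    )
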