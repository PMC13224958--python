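"""Readers and writers for the standard formats the tool touches.

Input: 10x-style triplet (MatrixMarket matrix + features/barcodes text),
a cell -> sample assignment TSV with optional sample-level covariates, and
GMT gene-set files (with an optional ``gene,weight`` extension for signed
regulons).  Output: a round-trippable model archive (raw .npy blocks plus
a JSON sidecar, deterministic bytes) and delimited result tables.

No reader materializes a dense genes x cells array; the matrix stays in
sparse coordinate/CSC form throughout.
"""
from __future__ import annotations

import gzip
import json
import logging
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .model import (
    DecompositionModel,
    ExpressionDataset,
    FitReport,
    GeneProgramPrior,
    HyperParams,
    SampleDesign,
)

__all__ = [
    "read_10x_triplet",
    "write_dataset",
    "read_sample_table",
    "write_sample_table",
    "read_gene_sets_gmt",
    "write_model",
    "read_model",
    "write_table",
]

logger = logging.getLogger(__name__)

ARCHIVE_VERSION = "1"


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_id_column(path) -> list:
    with _open_text(path) as fh:
        return [line.rstrip("\r\n").split("\t")[0] for line in fh if line.strip()]


def _make_unique(ids: list) -> list:
    seen: dict = {}
    out = []
    for x in ids:
        if x in seen:
            seen[x] += 1
            out.append(f"{x}-{seen[x]}")
        else:
            seen[x] = 0
            out.append(x)
    return out


def read_10x_triplet(matrix_path, features_path, barcodes_path) -> ExpressionDataset:
    """Load a MatrixMarket + features + barcodes triplet as a single-sample dataset.

    Orientation is normalized to genes x cells (the matrix is transposed
    when its header dimensions match barcodes-first).  Duplicate gene ids
    are disambiguated by suffixing.  Non-integer values flag the dataset
    as already normalized.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".gz":
        with gzip.open(matrix_path, "rb") as fh:
            mat = scipy.io.mmread(fh)
    else:
        mat = scipy.io.mmread(matrix_path)
    genes = _read_id_column(features_path)
    cells = _read_id_column(barcodes_path)
    g, c = len(genes), len(cells)
    if mat.shape == (g, c):
        pass
    elif mat.shape == (c, g):
        mat = mat.T
    else:
        raise ValueError(
            f"matrix is {mat.shape[0]}x{mat.shape[1]} but features file has {g} "
            f"lines and barcodes file has {c} lines"
        )
    if mat.nnz == 0:
        warnings.warn("matrix has no nonzero entries", stacklevel=2)
    if len(set(genes)) != g:
        genes = _make_unique(genes)
    values = sp.csc_matrix(mat)
    is_int = np.issubdtype(values.dtype, np.integer) or (
        values.nnz > 0 and np.all(values.data == np.round(values.data))
    ) or values.nnz == 0
    if not is_int:
        logger.info("non-integer matrix values: treating input as normalized expression")
    return ExpressionDataset(
        values=values.astype(np.int64) if is_int else values.astype(np.float64),
        gene_ids=genes,
        cell_ids=_make_unique(cells),
        sample_of_cell=np.zeros(c, dtype=np.int64),
        n_samples=1,
        is_normalized=not is_int,
    )


def write_dataset(data: ExpressionDataset, out_dir) -> dict:
    """Write the 10x triplet (matrix.mtx at full float precision)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "barcodes": out_dir / "barcodes.tsv",
    }
    coo = sp.coo_matrix(data.values)
    field = "integer" if np.issubdtype(coo.dtype, np.integer) else "real"
    scipy.io.mmwrite(paths["matrix"], coo, field=field, precision=17)
    paths["features"].write_text("".join(f"{g}\n" for g in data.gene_ids))
    paths["barcodes"].write_text("".join(f"{c}\n" for c in data.cell_ids))
    return paths


def read_sample_table(path, cell_ids: list):
    """Parse the cell -> sample TSV; returns (sample_of_cell, sample_ids, design).

    Requires ``cell_id`` and ``sample_id`` columns; any remaining columns
    become sample-level covariates (checked constant within sample;
    non-numeric columns are one-hot expanded with the reference level —
    first appearance — dropped).  The map is keyed by cell_id, so the
    table's row order is irrelevant; samples are ordered by first
    appearance in the dataset's cell order.  ``design`` is None when no
    covariate columns are present; otherwise it includes an intercept.
    """
    tab = pd.read_csv(path, sep="\t", dtype={0: str})
    for col in ("cell_id", "sample_id"):
        if col not in tab.columns:
            raise ValueError(f"sample table is missing required column '{col}'")
    tab["cell_id"] = tab["cell_id"].astype(str)
    tab = tab.drop_duplicates(subset="cell_id", keep="first")
    by_cell = tab.set_index("cell_id")
    missing = [c for c in cell_ids if c not in by_cell.index]
    if missing:
        shown = ", ".join(map(str, missing[:10]))
        raise ValueError(
            f"{len(missing)} cells in the matrix are absent from the sample "
            f"table (first {min(10, len(missing))}: {shown})"
        )
    extra = len(by_cell.index.difference(pd.Index(cell_ids)))
    if extra:
        warnings.warn(f"{extra} table rows have no matching cell in the matrix", stacklevel=2)
    aligned = by_cell.loc[cell_ids]
    sample_series = aligned["sample_id"].astype(str)
    sample_ids = list(dict.fromkeys(sample_series))  # first appearance order
    sample_index = {sid: i for i, sid in enumerate(sample_ids)}
    sample_of_cell = sample_series.map(sample_index).to_numpy(dtype=np.int64)

    cov_cols = [c for c in tab.columns if c not in ("cell_id", "sample_id")]
    if not cov_cols:
        return sample_of_cell, sample_ids, None

    per_sample = aligned.assign(_sid=sample_series).groupby("_sid", sort=False)
    for col in cov_cols:
        if per_sample[col].nunique().max() > 1:
            raise ValueError(f"covariate '{col}' varies within a sample")
    first = per_sample.first().loc[sample_ids]

    blocks = [np.ones((len(sample_ids), 1))]
    names = ["intercept"]
    for col in cov_cols:
        vals = first[col]
        if pd.api.types.is_numeric_dtype(vals):
            blocks.append(vals.to_numpy(dtype=np.float64)[:, None])
            names.append(col)
        else:
            levels = list(dict.fromkeys(vals))
            for lev in levels[1:]:  # reference level (first appearance) dropped
                blocks.append((vals == lev).to_numpy(dtype=np.float64)[:, None])
                names.append(f"{col}[{lev}]")
    design = SampleDesign(
        X=np.hstack(blocks), covariate_names=names, intercept_included=True
    )
    return sample_of_cell, sample_ids, design


def write_sample_table(data: ExpressionDataset, path, design: Optional[SampleDesign] = None):
    """Write the cell -> sample TSV (plus non-intercept covariates if given)."""
    cols = {"cell_id": data.cell_ids,
            "sample_id": [data.sample_ids[i] for i in data.sample_of_cell]}
    if design is not None:
        start = 1 if design.intercept_included else 0
        for j in range(start, design.n_covariates):
            cols[design.covariate_names[j]] = design.X[data.sample_of_cell, j]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_gene_sets_gmt(path, gene_ids: list) -> GeneProgramPrior:
    """Parse a GMT file into a sparse signed genes x programs prior.

    Standard GMT: ``name<TAB>description<TAB>gene...``; members may be
    ``gene,weight`` pairs for signed regulons.  Members absent from
    ``gene_ids`` are dropped (count logged per set); sets empty after the
    intersection are dropped with a warning.
    """
    index = {g: i for i, g in enumerate(gene_ids)}
    rows, cols, vals, names = [], [], [], []
    with _open_text(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {ln} has {len(fields)} fields; GMT needs "
                    "name, description and at least one member"
                )
            name = fields[0]
            weights: dict = {}
            for token in fields[2:]:
                if not token:
                    continue
                if "," in token:
                    gene, w = token.split(",", 1)
                    weight = float(w)
                else:
                    gene, weight = token, 1.0
                if gene in index:
                    weights[index[gene]] = weights.get(index[gene], 0.0) + weight
            dropped = len([t for t in fields[2:] if t]) - len(weights)
            if dropped:
                logger.info("gene set '%s': %d members not in dataset", name, dropped)
            if not weights:
                warnings.warn(
                    f"gene set '{name}' has no genes in the dataset; dropped",
                    stacklevel=2,
                )
                continue
            p = len(names)
            names.append(name)
            for gi, w in sorted(weights.items()):
                rows.append(gi)
                cols.append(p)
                vals.append(w)
    if not names:
        raise ValueError(f"{path}: no gene sets overlap the dataset")
    A = sp.csc_matrix((vals, (rows, cols)), shape=(len(gene_ids), len(names)))
    return GeneProgramPrior(A=A, program_names=names)


# ---------------------------------------------------------------------------
# model archive


def write_model(model: DecompositionModel, path, report: Optional[FitReport] = None):
    """Serialize all blocks + metadata to a directory; bitwise round-trippable.

    Blocks are raw .npy files (shape and dtype self-recorded); metadata and
    the fit report go to ``meta.json``.  Wall-clock time lives in a
    separate ``provenance.json`` so archive content is deterministic for a
    given seed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    blocks = {
        "Z": model.Z,
        "B": model.B,
        "o": model.o,
        "s": model.s,
        "delta": np.stack(model.delta) if model.delta else np.zeros((0,) + model.Z.shape),
        "sample_of_cell": model.sample_of_cell,
    }
    if model.D is not None:
        blocks["D"] = model.D
    if model.W is not None:
        blocks["W"] = model.W
        blocks["A"] = model.A
    for name, arr in blocks.items():
        np.save(path / f"{name}.npy", np.ascontiguousarray(arr))
    meta = {
        "format_version": ARCHIVE_VERSION,
        "blocks": {k: {"shape": list(v.shape), "dtype": str(v.dtype)} for k, v in blocks.items()},
        "gene_ids": list(map(str, model.gene_ids)),
        "cell_ids": list(map(str, model.cell_ids)),
        "sample_ids": list(map(str, model.sample_ids)),
        "n_samples": int(model.n_samples),
        "covariate_names": model.covariate_names,
        "program_names": model.program_names,
        "fit_report": None,
    }
    if report is not None:
        rep = report.to_dict()
        wall = rep.pop("wall_seconds")
        meta["fit_report"] = rep
        (path / "provenance.json").write_text(
            json.dumps({"wall_seconds": wall}, sort_keys=True) + "\n"
        )
    (path / "meta.json").write_text(json.dumps(meta, sort_keys=True, indent=1) + "\n")
    return path


def read_model(path):
    """Load an archive written by :func:`write_model`; returns (model, report)."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no model archive at {path} (missing meta.json)")
    meta = json.loads(meta_path.read_text())
    version = meta.get("format_version")
    if version != ARCHIVE_VERSION:
        raise ValueError(
            f"archive format version {version!r} != supported version {ARCHIVE_VERSION!r}"
        )
    arrays = {}
    for name, info in meta["blocks"].items():
        arr = np.load(path / f"{name}.npy")
        if list(arr.shape) != info["shape"]:
            raise ValueError(
                f"block '{name}' has shape {list(arr.shape)}, metadata says {info['shape']}"
            )
        arrays[name] = arr
    report = None
    if meta.get("fit_report"):
        rep = meta["fit_report"]
        prov = path / "provenance.json"
        wall = json.loads(prov.read_text())["wall_seconds"] if prov.exists() else float("nan")
        report = FitReport(
            loss_trajectory=rep["loss_trajectory"],
            converged=rep["converged"],
            n_iter=rep["n_iter"],
            hyperparams=HyperParams(**rep["hyperparams"]),
            wall_seconds=wall,
            loss_initial=rep.get("loss_initial", float("nan")),
        )
    model = DecompositionModel(
        Z=arrays["Z"],
        delta=list(arrays["delta"]),
        B=arrays["B"],
        o=arrays["o"],
        s=arrays["s"],
        gene_ids=meta["gene_ids"],
        cell_ids=meta["cell_ids"],
        sample_of_cell=arrays["sample_of_cell"],
        n_samples=meta["n_samples"],
        sample_ids=meta["sample_ids"],
        D=arrays.get("D"),
        W=arrays.get("W"),
        A=arrays.get("A"),
        covariate_names=meta.get("covariate_names"),
        program_names=meta.get("program_names"),
    )
    model.check_dims()
    return model, report


def write_table(values: np.ndarray, path, row_ids: list, col_ids: list,
                row_label: str = "gene_id") -> None:
    """Write a labeled matrix as TSV, values rounded to 6 significant digits."""
    df = pd.DataFrame(values, index=pd.Index(row_ids, name=row_label), columns=col_ids)
    df.to_csv(path, sep="\t", float_format="%.6g")
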