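"""Core model types, the objective function, and reconstruction equations.

A multi-sample expression matrix is modeled cell-by-cell as

    y_n = o + s_n * 1 + (Z + dZ_i) b_n + noise,      i = sample(n),

where

* ``Z`` (genes x K, orthonormal columns) spans the shared cell-state
  manifold common to all samples,
* ``dZ_i`` (genes x K) is a per-sample additive distortion of those axes,
  capturing batch / condition-specific deformation,
* ``b_n`` (K,) places cell n in the shared latent space,
* ``o`` (genes,) is a per-gene offset and ``s_n`` a per-cell scalar offset
  (the log-space size factor).

``Z b_n`` is the batch-corrected expression of cell n and ``dZ_i b_n`` its
sample-specific deviation.  Distortions may optionally be modeled as linear
functions of sample-level covariates x_i through a map ``D`` (giving
clustering-free differential expression), and the reference axes may be
expressed through a gene-program prior ``A`` as ``Z = A W`` (giving
per-cell program activities ``W b_n``).

The fitted objective is least squares on log-normalized expression:

    L = sum_n || y_n - o - s_n 1 - (Z + dZ_i) b_n ||^2
        + lambda_b  * sum_n ||b_n||^2
        + lambda_delta * sum_i ||dZ_i - D(x_i)||_F^2
        + lambda_d  * ||D||_F^2
        + lambda_w  * ||W||_F^2            (only when a prior is used)
"""
from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._workspace import dense_block

__all__ = [
    "ExpressionDataset",
    "HyperParams",
    "DecompositionModel",
    "SampleDesign",
    "GeneProgramPrior",
    "FitReport",
    "normalize",
    "reconstruct_cell",
    "compute_loss",
    "batch_corrected_expression",
    "sample_distortion",
]


def _as_list(x) -> list:
    return list(x)


@dataclasses.dataclass
class ExpressionDataset:
    """Sparse genes x cells matrix with ids and a cell -> sample map.

    ``values`` holds raw counts (``is_normalized=False``) or expression
    already on the modeling scale (``is_normalized=True``).
    """

    values: "sp.spmatrix | sp.sparray | np.ndarray"
    gene_ids: list
    cell_ids: list
    sample_of_cell: np.ndarray
    n_samples: int
    is_normalized: bool = False
    sample_ids: Optional[list] = None

    def __post_init__(self) -> None:
        self.gene_ids = _as_list(self.gene_ids)
        self.cell_ids = _as_list(self.cell_ids)
        self.sample_of_cell = np.asarray(self.sample_of_cell, dtype=np.int64)
        g, n = self.values.shape
        if len(self.gene_ids) != g:
            raise ValueError(
                f"gene_ids has {len(self.gene_ids)} entries but matrix has {g} rows"
            )
        if len(self.cell_ids) != n:
            raise ValueError(
                f"cell_ids has {len(self.cell_ids)} entries but matrix has {n} columns"
            )
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids are not unique")
        if len(set(self.cell_ids)) != n:
            raise ValueError("cell_ids are not unique")
        if self.sample_of_cell.shape != (n,):
            raise ValueError("sample_of_cell length does not match cell count")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if n and (self.sample_of_cell.min() < 0 or self.sample_of_cell.max() >= self.n_samples):
            raise ValueError("sample_of_cell contains out-of-range sample indices")
        counts = np.bincount(self.sample_of_cell, minlength=self.n_samples)
        if n and (counts == 0).any():
            empty = int(np.flatnonzero(counts == 0)[0])
            raise ValueError(f"sample {empty} has no cells")
        if not self.is_normalized:
            mn = self.values.data.min() if sp.issparse(self.values) and self.values.nnz else (
                self.values.min() if not sp.issparse(self.values) and self.values.size else 0.0
            )
            if mn < 0:
                raise ValueError("count matrix has negative entries")
        if self.sample_ids is None:
            self.sample_ids = [f"sample{i}" for i in range(self.n_samples)]
        self._cells_by_sample: Optional[list] = None

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cells_of_sample(self, i: int) -> np.ndarray:
        if self._cells_by_sample is None:
            order = np.argsort(self.sample_of_cell, kind="stable")
            bounds = np.searchsorted(self.sample_of_cell[order], np.arange(self.n_samples + 1))
            self._cells_by_sample = [
                order[bounds[j]:bounds[j + 1]] for j in range(self.n_samples)
            ]
        return self._cells_by_sample[i]


def normalize(data: ExpressionDataset, scale: float = 1e4) -> ExpressionDataset:
    """Library-size normalize and log-transform raw counts.

    Each column x is mapped to log(1 + scale * x / colsum(x)).  Datasets
    already flagged as normalized are returned unchanged.  Sparsity is
    preserved (log1p(0) = 0).
    """
    if data.is_normalized:
        return data
    if sp.issparse(data.values):
        X = sp.csc_matrix(data.values, copy=True).astype(np.float64)
        colsum = np.asarray(X.sum(axis=0)).ravel()
        safe = np.where(colsum > 0, colsum, 1.0)
        X.data *= np.repeat(scale / safe, np.diff(X.indptr))
        np.log1p(X.data, out=X.data)
    else:
        dense = np.asarray(data.values, dtype=np.float64)
        colsum = dense.sum(axis=0)
        safe = np.where(colsum > 0, colsum, 1.0)
        X = np.log1p(dense * (scale / safe))
    return ExpressionDataset(
        values=X,
        gene_ids=data.gene_ids,
        cell_ids=data.cell_ids,
        sample_of_cell=data.sample_of_cell,
        n_samples=data.n_samples,
        is_normalized=True,
        sample_ids=data.sample_ids,
    )


@dataclasses.dataclass
class HyperParams:
    """Fitting configuration: latent dimension, ridge weights, stopping rule."""

    K: int
    lambda_b: float = 1e-3
    lambda_delta: float = 1.0
    lambda_d: float = 1.0
    lambda_w: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    seed: int = 0
    n_workers: int = 1

    def validate(self, n_genes: Optional[int] = None, n_cells: Optional[int] = None) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if n_genes is not None and n_cells is not None and self.K > min(n_genes, n_cells):
            raise ValueError(
                f"K={self.K} exceeds min(genes, cells)={min(n_genes, n_cells)}"
            )
        for name in ("lambda_b", "lambda_delta", "lambda_d", "lambda_w"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.tol > 0:
            raise ValueError("tol must be > 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class SampleDesign:
    """Samples x covariates matrix used to model distortions as D(x_i)."""

    X: np.ndarray
    covariate_names: list
    intercept_included: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("design matrix must be 2-D (samples x covariates)")
        if self.X.shape[1] != len(self.covariate_names):
            raise ValueError("covariate_names length does not match design columns")
        if not np.isfinite(self.X).all():
            raise ValueError("design matrix contains missing/non-finite values")
        for j, name in enumerate(self.covariate_names):
            col = self.X[:, j]
            if self.X.shape[0] > 1 and np.ptp(col) == 0 and not (
                self.intercept_included and j == 0
            ):
                warnings.warn(
                    f"covariate '{name}' is constant across samples", stacklevel=2
                )

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1]


@dataclasses.dataclass
class GeneProgramPrior:
    """Signed genes x programs membership matrix A (regulons / pathways)."""

    A: "sp.spmatrix | np.ndarray"
    program_names: list

    def __post_init__(self) -> None:
        if self.A.shape[1] != len(self.program_names):
            raise ValueError("program_names length does not match prior columns")
        col_nnz = (
            np.diff(sp.csc_matrix(self.A).indptr)
            if sp.issparse(self.A)
            else (np.asarray(self.A) != 0).sum(axis=0)
        )
        if (np.asarray(col_nnz) == 0).any():
            bad = self.program_names[int(np.flatnonzero(np.asarray(col_nnz) == 0)[0])]
            raise ValueError(f"program '{bad}' has no member genes")

    def dense(self) -> np.ndarray:
        return self.A.toarray() if sp.issparse(self.A) else np.asarray(self.A, dtype=np.float64)


@dataclasses.dataclass
class FitReport:
    """Per-iteration objective values and convergence provenance."""

    loss_trajectory: list
    converged: bool
    n_iter: int
    hyperparams: HyperParams
    wall_seconds: float
    loss_initial: float = math.nan

    def to_dict(self) -> dict:
        return {
            "loss_trajectory": [float(v) for v in self.loss_trajectory],
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "hyperparams": self.hyperparams.to_dict(),
            "wall_seconds": float(self.wall_seconds),
            "loss_initial": float(self.loss_initial),
        }


@dataclasses.dataclass
class DecompositionModel:
    """Fitted parameter blocks plus the metadata needed to use them alone."""

    Z: np.ndarray                       # genes x K, orthonormal after each iteration
    delta: list                         # per sample genes x K distortions
    B: np.ndarray                       # K x cells embeddings
    o: np.ndarray                       # genes offsets
    s: np.ndarray                       # cells offsets (size factors)
    gene_ids: list
    cell_ids: list
    sample_of_cell: np.ndarray
    n_samples: int
    sample_ids: list
    D: Optional[np.ndarray] = None      # covariates x genes x K
    W: Optional[np.ndarray] = None      # programs x K
    A: Optional[np.ndarray] = None      # genes x programs (dense copy of prior)
    covariate_names: Optional[list] = None
    program_names: Optional[list] = None

    @property
    def n_genes(self) -> int:
        return self.Z.shape[0]

    @property
    def K(self) -> int:
        return self.Z.shape[1]

    @property
    def n_cells(self) -> int:
        return self.B.shape[1]

    def cells_of_sample(self, i: int) -> np.ndarray:
        return np.flatnonzero(self.sample_of_cell == i)

    def check_dims(self) -> None:
        g, K = self.Z.shape
        if len(self.delta) != self.n_samples:
            raise ValueError("delta: expected one block per sample")
        for i, dz in enumerate(self.delta):
            if dz.shape != (g, K):
                raise ValueError(f"delta[{i}]: shape {dz.shape} != {(g, K)}")
        if self.B.shape[0] != K:
            raise ValueError(f"B: has {self.B.shape[0]} rows, expected K={K}")
        if self.o.shape != (g,):
            raise ValueError(f"o: shape {self.o.shape} != {(g,)}")
        if self.s.shape != (self.B.shape[1],):
            raise ValueError(f"s: shape {self.s.shape} != {(self.B.shape[1],)}")
        if self.D is not None and self.D.shape[1:] != (g, K):
            raise ValueError(f"D: trailing shape {self.D.shape[1:]} != {(g, K)}")
        if self.W is not None:
            if self.A is None:
                raise ValueError("W: present without a prior matrix A")
            if self.A.shape != (g, self.W.shape[0]):
                raise ValueError(f"A: shape {self.A.shape} incompatible with W")
            if self.W.shape[1] != K:
                raise ValueError(f"W: has {self.W.shape[1]} columns, expected K={K}")

    def predicted_distortion(self, design: Optional[SampleDesign], i: int) -> np.ndarray:
        """D(x_i): the covariate-predicted distortion for sample i (0 if no map)."""
        if self.D is None or design is None:
            return np.zeros_like(self.Z)
        return np.einsum("t,tgk->gk", design.X[i], self.D)

    def copy(self) -> "DecompositionModel":
        return DecompositionModel(
            Z=self.Z.copy(),
            delta=[d.copy() for d in self.delta],
            B=self.B.copy(),
            o=self.o.copy(),
            s=self.s.copy(),
            gene_ids=list(self.gene_ids),
            cell_ids=list(self.cell_ids),
            sample_of_cell=self.sample_of_cell.copy(),
            n_samples=self.n_samples,
            sample_ids=list(self.sample_ids),
            D=None if self.D is None else self.D.copy(),
            W=None if self.W is None else self.W.copy(),
            A=None if self.A is None else self.A.copy(),
            covariate_names=None if self.covariate_names is None else list(self.covariate_names),
            program_names=None if self.program_names is None else list(self.program_names),
        )


def reconstruct_cell(model: DecompositionModel, cell: int) -> np.ndarray:
    """Expected expression o + s_n 1 + (Z + dZ_i) b_n for one cell."""
    model.check_dims()
    if not 0 <= cell < model.n_cells:
        raise IndexError(f"cell index {cell} out of range [0, {model.n_cells})")
    i = int(model.sample_of_cell[cell])
    M = model.Z + model.delta[i]
    return model.o + model.s[cell] + M @ model.B[:, cell]


def _check_finite(model: DecompositionModel) -> None:
    blocks = {"Z": model.Z, "B": model.B, "o": model.o, "s": model.s}
    for i, dz in enumerate(model.delta):
        blocks[f"delta[{i}]"] = dz
    if model.D is not None:
        blocks["D"] = model.D
    if model.W is not None:
        blocks["W"] = model.W
    for name, arr in blocks.items():
        if not np.isfinite(arr).all():
            raise ValueError(f"parameter block '{name}' contains non-finite entries")


def compute_loss(
    model: DecompositionModel,
    data: ExpressionDataset,
    hp: HyperParams,
    design: Optional[SampleDesign] = None,
) -> float:
    """Penalized least-squares objective (see module docstring).

    Samples are reduced in ascending index order so the value is independent
    of any parallel processing order.
    """
    _check_finite(model)
    model.check_dims()
    values = data.values if sp.issparse(data.values) else np.asarray(data.values)
    total = 0.0
    for i in range(data.n_samples):
        idx = data.cells_of_sample(i)
        R = dense_block(values, idx)
        R -= model.o[:, None]
        R -= model.s[idx][None, :]
        R -= (model.Z + model.delta[i]) @ model.B[:, idx]
        total += float(np.dot(R.ravel(), R.ravel()))
    if hp.lambda_b > 0:
        total += hp.lambda_b * float(np.dot(model.B.ravel(), model.B.ravel()))
    if hp.lambda_delta > 0:
        for i in range(data.n_samples):
            P = model.delta[i] - model.predicted_distortion(design, i)
            total += hp.lambda_delta * float(np.dot(P.ravel(), P.ravel()))
    if model.D is not None and hp.lambda_d > 0:
        total += hp.lambda_d * float(np.dot(model.D.ravel(), model.D.ravel()))
    if model.W is not None and hp.lambda_w > 0:
        total += hp.lambda_w * float(np.dot(model.W.ravel(), model.W.ravel()))
    return total


def batch_corrected_expression(
    model: DecompositionModel,
    cells: Optional[Sequence[int]] = None,
    include_offsets: bool = False,
) -> np.ndarray:
    """Z B[:, cells] — expression with sample distortions and size factors removed.

    With ``include_offsets`` the per-gene offsets o are added columnwise.
    Neither the sample distortion dZ_i b_n nor the cell offset s_n is ever
    included: they are precisely the terms batch correction removes.
    """
    idx = np.arange(model.n_cells) if cells is None else np.asarray(cells, dtype=np.int64)
    out = model.Z @ model.B[:, idx]
    if include_offsets:
        out = out + model.o[:, None]
    return out


def sample_distortion(
    model: DecompositionModel, sample: int, cells: Sequence[int]
) -> np.ndarray:
    """dZ_i B[:, cells] — the expression distortion sample i imposes on its cells."""
    if not 0 <= sample < model.n_samples:
        raise IndexError(f"sample index {sample} out of range [0, {model.n_samples})")
    idx = np.asarray(cells, dtype=np.int64)
    wrong = idx[model.sample_of_cell[idx] != sample]
    if wrong.size:
        cid = model.cell_ids[int(wrong[0])]
        raise ValueError(
            f"cell '{cid}' belongs to sample {int(model.sample_of_cell[wrong[0]])}, "
            f"not sample {sample}"
        )
    return model.delta[sample] @ model.B[:, idx]
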