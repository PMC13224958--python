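"""Model setup and latent-variable initialization.

Setup allocates every parameter block at its final size (the workspace
contract: no block changes shape afterwards; the optimizer updates them in
place).  Initialization fills the offsets with row/column means and the
factors (Z, B) with a seeded randomized truncated SVD of the doubly
centered matrix, computed without ever densifying the input: the centering
is applied implicitly through rank-one corrections to the sparse products.
"""
from __future__ import annotations

import warnings
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .model import (
    DecompositionModel,
    ExpressionDataset,
    GeneProgramPrior,
    HyperParams,
    SampleDesign,
)

__all__ = ["setup_model", "initialize_latents"]


def setup_model(
    data: ExpressionDataset,
    hp: HyperParams,
    design: Optional[SampleDesign] = None,
    prior: Optional[GeneProgramPrior] = None,
) -> DecompositionModel:
    """Allocate all parameter blocks (zero-filled) at their final shapes."""
    g, n = data.n_genes, data.n_cells
    hp.validate(g, n)
    if design is not None and design.X.shape[0] != data.n_samples:
        raise ValueError(
            f"design has {design.X.shape[0]} rows but dataset has {data.n_samples} samples"
        )
    if prior is not None and prior.A.shape[0] != g:
        raise ValueError(
            f"prior has {prior.A.shape[0]} genes but dataset has {g}; align genes first"
        )
    if prior is not None and len(prior.program_names) < hp.K:
        raise ValueError(
            f"K={hp.K} exceeds the {len(prior.program_names)} programs in the "
            "prior; Z = A W cannot have full column rank"
        )
    counts = np.bincount(data.sample_of_cell, minlength=data.n_samples)
    small = np.flatnonzero(counts < hp.K)
    if small.size:
        warnings.warn(
            f"samples {small.tolist()} have fewer than K={hp.K} cells; "
            "their distortion estimates will rely on the ridge prior",
            stacklevel=2,
        )
    K = hp.K
    model = DecompositionModel(
        Z=np.zeros((g, K)),
        delta=[np.zeros((g, K)) for _ in range(data.n_samples)],
        B=np.zeros((K, n)),
        o=np.zeros(g),
        s=np.zeros(n),
        gene_ids=list(data.gene_ids),
        cell_ids=list(data.cell_ids),
        sample_of_cell=data.sample_of_cell.copy(),
        n_samples=data.n_samples,
        sample_ids=list(data.sample_ids),
        D=None if design is None else np.zeros((design.n_covariates, g, K)),
        W=None if prior is None else np.zeros((len(prior.program_names), K)),
        A=None if prior is None else prior.dense(),
        covariate_names=None if design is None else list(design.covariate_names),
        program_names=None if prior is None else list(prior.program_names),
    )
    model.check_dims()
    return model


def _centered_matmul(Y, o, s, M):
    """(Y - o 1^T - 1 s^T) @ M without densifying Y."""
    out = Y @ M
    out = np.asarray(out)
    out -= np.outer(o, M.sum(axis=0))
    out -= np.outer(np.ones(Y.shape[0]), s @ M)
    return out


def _centered_rmatmul(Y, o, s, Q):
    """(Y - o 1^T - 1 s^T)^T @ Q without densifying Y."""
    out = Y.T @ Q
    out = np.asarray(out)
    out -= np.outer(np.ones(Y.shape[1]), o @ Q)
    out -= np.outer(s, Q.sum(axis=0))
    return out


def _randomized_svd_centered(
    Y, o, s, K: int, seed: int, n_power: int = 4, oversample: int = 10
):
    """Seeded randomized rank-K SVD of Y - o 1^T - 1 s^T (Halko range finder)."""
    g, n = Y.shape
    ell = min(K + oversample, g, n)
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n, ell))
    Q = np.linalg.qr(_centered_matmul(Y, o, s, G))[0]
    for _ in range(n_power):
        Q = np.linalg.qr(_centered_rmatmul(Y, o, s, Q))[0]
        Q = np.linalg.qr(_centered_matmul(Y, o, s, Q))[0]
    small = _centered_rmatmul(Y, o, s, Q).T  # ell x n
    U2, sv, Vt = np.linalg.svd(small, full_matrices=False)
    Z = Q @ U2[:, :K]
    B = sv[:K, None] * Vt[:K]
    return Z, B


def _fix_signs(Z: np.ndarray, B: np.ndarray) -> None:
    """Make each axis's largest-magnitude gene loading positive (in place).

    np.argmax breaks ties at the lowest gene index, which pins the
    convention and makes determinism tests bitwise.
    """
    for k in range(Z.shape[1]):
        j = int(np.argmax(np.abs(Z[:, k])))
        if Z[j, k] < 0:
            Z[:, k] *= -1.0
            B[k, :] *= -1.0


def initialize_latents(
    model: DecompositionModel, data: ExpressionDataset, hp: HyperParams
) -> DecompositionModel:
    """Fill offsets and (Z, B) in place; distortions stay at zero.

    o is the per-gene mean of the (normalized) data, s the per-cell mean of
    the gene-centered data; (Z, B) come from a seeded randomized rank-K SVD
    of the doubly centered matrix.  Row means of B are absorbed into o so
    the embedding starts in the identifiable gauge.
    """
    Y = data.values
    g, n = Y.shape
    o = np.asarray(Y.mean(axis=1)).ravel()
    s = np.asarray(Y.mean(axis=0)).ravel() - o.mean()
    model.o[...] = o
    model.s[...] = s
    sq = (Y.data ** 2).sum() if sp.issparse(Y) else float((np.asarray(Y) ** 2).sum())
    if sq == 0.0:
        warnings.warn("all-zero expression matrix; using canonical axes", stacklevel=2)
        model.Z[...] = np.eye(g, hp.K)
        model.B[...] = 0.0
        return model
    Z, B = _randomized_svd_centered(Y, o, s, hp.K, hp.seed)
    _fix_signs(Z, B)
    bbar = B.mean(axis=1)
    B -= bbar[:, None]
    model.Z[...] = Z
    model.B[...] = B
    model.o[...] = o + Z @ bbar
    return model
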