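"""Block-coordinate descent fitting.

Each iteration sweeps [cell embeddings -> sample distortions -> covariate
map -> reference axes -> QR re-orthogonalization -> offsets].  Every block
solve is the exact minimizer of its ridge subproblem, so the recorded loss
trajectory is non-increasing.  Sample-specific blocks (embeddings,
distortions) are mutually independent and may run on worker threads;
global reductions always accumulate per-sample partial sums in ascending
sample index, so results are invariant to both the worker count and the
order samples are processed in.

Sparsity contract: the expression matrix is never densified as a whole.
The only dense intermediates are genes x K products of the sparse matrix
(computed via sparse matmul) and, inside the loss, per-sample residual
blocks routed through the tracked scratch allocator.
"""
from __future__ import annotations

import logging
import time
import warnings
from concurrent.futures import ThreadPoolExecutor
from typing import Callable, Optional, Sequence

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .initialization import initialize_latents, setup_model
from .model import (
    DecompositionModel,
    ExpressionDataset,
    FitReport,
    GeneProgramPrior,
    HyperParams,
    SampleDesign,
    compute_loss,
    normalize,
)

__all__ = [
    "update_cell_embeddings",
    "update_sample_distortions",
    "update_covariate_map",
    "update_reference",
    "orthogonalize_reference",
    "update_offsets",
    "fit",
]

logger = logging.getLogger(__name__)


def _map_samples(
    fn: Callable[[int], object],
    n_samples: int,
    n_workers: int = 1,
    order: Optional[Sequence[int]] = None,
) -> list:
    """Run fn over samples (optionally threaded / permuted); results indexed by sample."""
    order = list(range(n_samples)) if order is None else list(order)
    if sorted(order) != list(range(n_samples)):
        raise ValueError("sample order must be a permutation of all samples")
    results: list = [None] * n_samples
    if n_workers > 1 and n_samples > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            for i, res in zip(order, pool.map(fn, order)):
                results[i] = res
    else:
        for i in order:
            results[i] = fn(i)
    return results


def _spmul(Y, M: np.ndarray) -> np.ndarray:
    """Y @ M as an ndarray for sparse or dense Y."""
    return np.asarray(Y @ M)


def update_cell_embeddings(
    model: DecompositionModel,
    data: ExpressionDataset,
    hp: HyperParams,
    order: Optional[Sequence[int]] = None,
) -> DecompositionModel:
    """b_n = (M_i^T M_i + lambda_b I)^-1 M_i^T (y_n - o - s_n 1), M_i = Z + dZ_i.

    The K x K Gram matrix is formed once per sample and shared by all of
    the sample's cells.
    """
    Y = data.values if sp.issparse(data.values) else np.asarray(data.values)
    K = model.K

    def work(i: int) -> np.ndarray:
        idx = data.cells_of_sample(i)
        M = model.Z + model.delta[i]
        G = M.T @ M + hp.lambda_b * np.eye(K)
        rhs = _spmul(Y[:, idx].T, M).T  # K x n_i
        rhs -= np.outer(M.T @ model.o, np.ones(len(idx)))
        rhs -= np.outer(M.sum(axis=0), model.s[idx])
        try:
            c = scipy.linalg.cho_factor(G, check_finite=False)
            return scipy.linalg.cho_solve(c, rhs, check_finite=False)
        except scipy.linalg.LinAlgError:
            warnings.warn(
                f"singular embedding system for sample {i}; using pseudo-inverse",
                stacklevel=2,
            )
            return np.linalg.pinv(G) @ rhs

    results = _map_samples(work, data.n_samples, hp.n_workers, order)
    for i in range(data.n_samples):
        model.B[:, data.cells_of_sample(i)] = results[i]
    return model


def update_sample_distortions(
    model: DecompositionModel,
    data: ExpressionDataset,
    hp: HyperParams,
    design: Optional[SampleDesign] = None,
    order: Optional[Sequence[int]] = None,
) -> DecompositionModel:
    """dZ_i = (R_i B_i^T + lambda_delta D(x_i)) (B_i B_i^T + lambda_delta I)^-1.

    R_i is the sample's residual after offsets and the shared factor part;
    the product R_i B_i^T is assembled from sparse matmuls and rank-one
    corrections, so R_i itself is never materialized here.
    """
    Y = data.values if sp.issparse(data.values) else np.asarray(data.values)
    K = model.K

    def work(i: int) -> np.ndarray:
        idx = data.cells_of_sample(i)
        Dx = model.predicted_distortion(design, i)
        if len(idx) == 0:
            return Dx.copy()
        Bi = model.B[:, idx]
        Cbb = Bi @ Bi.T
        RB = _spmul(Y[:, idx], Bi.T)
        RB -= np.outer(model.o, Bi.sum(axis=1))
        RB -= np.outer(np.ones(model.n_genes), Bi @ model.s[idx])
        RB -= model.Z @ Cbb
        lhs = Cbb + hp.lambda_delta * np.eye(K)
        rhs = RB + hp.lambda_delta * Dx
        try:
            c = scipy.linalg.cho_factor(lhs, check_finite=False)
            return scipy.linalg.cho_solve(c, rhs.T, check_finite=False).T
        except scipy.linalg.LinAlgError:
            warnings.warn(
                f"singular distortion system for sample {i}; using pseudo-inverse",
                stacklevel=2,
            )
            return rhs @ np.linalg.pinv(lhs)

    results = _map_samples(work, data.n_samples, hp.n_workers, order)
    for i in range(data.n_samples):
        model.delta[i][...] = results[i]
    return model


def update_covariate_map(
    model: DecompositionModel, design: SampleDesign, hp: HyperParams
) -> DecompositionModel:
    """One ridge regression of the vectorized distortions on the covariates.

    D = argmin sum_i ||dZ_i - D(x_i)||_F^2 + (lambda_d / lambda_delta) ||D||_F^2.
    Global, synchronized step.
    """
    if model.D is None:
        raise ValueError("model was set up without a design; no covariate map to update")
    if hp.lambda_delta == 0:
        model.D[...] = 0.0
        return model
    X = design.X
    S, T = X.shape
    if hp.lambda_d == 0 and S < T:
        raise ValueError(
            f"{S} samples cannot identify {T} covariate effects with lambda_d=0; "
            "use a positive lambda_d ridge"
        )
    G = X.T @ X + (hp.lambda_d / hp.lambda_delta) * np.eye(T)
    V = np.stack([model.delta[i].ravel() for i in range(model.n_samples)])
    try:
        sol = scipy.linalg.solve(G, X.T @ V, assume_a="pos", check_finite=False)
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError):
        warnings.warn("singular covariate-map system; using least-squares", stacklevel=2)
        sol = np.linalg.lstsq(G, X.T @ V, rcond=None)[0]
    model.D[...] = sol.reshape(T, model.n_genes, model.K)
    return model


def update_reference(
    model: DecompositionModel,
    data: ExpressionDataset,
    hp: HyperParams,
    prior: Optional[GeneProgramPrior] = None,
    order: Optional[Sequence[int]] = None,
) -> DecompositionModel:
    """Z* = C_yb C_bb^-1 from global normal equations (synchronized step).

    C_yb = sum_n (y_n - o - s_n 1 - dZ_i b_n) b_n^T and C_bb = sum_n b_n b_n^T,
    accumulated from per-sample partials in ascending sample order.  With a
    gene-program prior, Z* is projected through it: W = (A^T A + lambda_w I)^-1
    A^T Z*, then Z <- A W.
    """
    Y = data.values if sp.issparse(data.values) else np.asarray(data.values)
    K = model.K

    def work(i: int):
        idx = data.cells_of_sample(i)
        Bi = model.B[:, idx]
        Cbb_i = Bi @ Bi.T
        Cyb_i = _spmul(Y[:, idx], Bi.T)
        Cyb_i -= np.outer(model.o, Bi.sum(axis=1))
        Cyb_i -= np.outer(np.ones(model.n_genes), Bi @ model.s[idx])
        Cyb_i -= model.delta[i] @ Cbb_i
        return Cyb_i, Cbb_i

    parts = _map_samples(work, data.n_samples, hp.n_workers, order)
    Cyb = np.zeros((model.n_genes, K))
    Cbb = np.zeros((K, K))
    for i in range(data.n_samples):  # ascending: deterministic reduction
        Cyb += parts[i][0]
        Cbb += parts[i][1]
    try:
        c = scipy.linalg.cho_factor(Cbb, check_finite=False)
        Zstar = scipy.linalg.cho_solve(c, Cyb.T, check_finite=False).T
    except scipy.linalg.LinAlgError:
        eps = 1e-10 * max(np.trace(Cbb), 1.0)
        warnings.warn(
            f"rank-deficient embedding Gram matrix; adding ridge eps={eps:.3g}",
            stacklevel=2,
        )
        Zstar = scipy.linalg.solve(
            Cbb + eps * np.eye(K), Cyb.T, assume_a="pos", check_finite=False
        ).T
    if model.W is not None:
        A = model.A
        GA = A.T @ A + hp.lambda_w * np.eye(A.shape[1])
        W = scipy.linalg.solve(GA, A.T @ Zstar, assume_a="pos", check_finite=False)
        model.W[...] = W
        Zstar = A @ W
    model.Z[...] = Zstar
    return model


def orthogonalize_reference(model: DecompositionModel) -> np.ndarray:
    """Thin QR gauge fix: Z <- Q, B <- R B (scale absorbed into the embeddings).

    R's diagonal is forced nonnegative (sign flips absorbed into R).  The
    reconstruction Z B is invariant; distortion blocks are left unchanged.
    Returns R so callers can propagate the transform (e.g. to W).
    """
    Q, R = np.linalg.qr(model.Z)
    diag = np.diag(R)
    scale = max(float(np.abs(diag).max()), 1.0)
    bad = np.flatnonzero(np.abs(diag) < 1e-12 * scale)
    if bad.size:
        raise ValueError(
            f"reference axis {int(bad[0])} collapsed (rank-deficient Z); "
            "reduce K or increase regularization"
        )
    sgn = np.where(diag < 0, -1.0, 1.0)
    Q = Q * sgn
    R = sgn[:, None] * R
    model.Z[...] = Q
    model.B[...] = R @ model.B
    if model.W is not None:
        # keep Z = A W exact: W <- W R^-1
        model.W[...] = scipy.linalg.solve_triangular(
            R.T, model.W.T, lower=True, check_finite=False
        ).T
    return R


def update_offsets(
    model: DecompositionModel, data: ExpressionDataset
) -> DecompositionModel:
    """Exact joint (o, s) solve on the factor residual; B rows re-centered first.

    Centering B absorbs the embedding means into o (the gauge convention).
    The offset block's joint minimizer is then closed-form: o takes the
    per-gene residual means (grand mean included, fixing the o+c / s-c
    indeterminacy), s the per-cell residual means minus the grand mean.
    Afterwards both the per-gene and per-cell mean residuals vanish.
    """
    Y = data.values if sp.issparse(data.values) else np.asarray(data.values)
    g, n = Y.shape
    bbar = model.B.mean(axis=1)
    model.o[...] = model.o + model.Z @ bbar
    model.B[...] = model.B - bbar[:, None]
    row_f = np.zeros(g)
    col_f = np.zeros(n)
    for i in range(data.n_samples):
        idx = data.cells_of_sample(i)
        M = model.Z + model.delta[i]
        Bi = model.B[:, idx]
        row_f += M @ Bi.sum(axis=1)
        col_f[idx] = M.sum(axis=0) @ Bi
    row_mean = (np.asarray(Y.sum(axis=1)).ravel() - row_f) / n
    col_mean = (np.asarray(Y.sum(axis=0)).ravel() - col_f) / g
    grand = row_mean.mean()
    model.o[...] = row_mean
    model.s[...] = col_mean - grand
    return model


def _first_nonfinite_block(model: DecompositionModel) -> str:
    for name, arr in [("Z", model.Z), ("B", model.B), ("o", model.o), ("s", model.s)]:
        if not np.isfinite(arr).all():
            return name
    for i, dz in enumerate(model.delta):
        if not np.isfinite(dz).all():
            return f"delta[{i}]"
    if model.D is not None and not np.isfinite(model.D).all():
        return "D"
    if model.W is not None and not np.isfinite(model.W).all():
        return "W"
    return "loss"


def fit(
    data: ExpressionDataset,
    hp: HyperParams,
    design: Optional[SampleDesign] = None,
    prior: Optional[GeneProgramPrior] = None,
    distortions: bool = True,
    sample_order: Optional[Sequence[int]] = None,
):
    """Normalize, set up, initialize, and run BCD to convergence.

    Parameters
    ----------
    data
        Counts (normalized internally as log1p of depth-scaled counts) or
        pre-normalized expression.
    hp
        Latent dimension, ridge weights, stopping rule, seed, worker count.
    design
        Optional sample-level covariates; enables the covariate map D and
        differential-expression vector fields.
    prior
        Optional gene-program matrix; constrains Z = A W and enables
        per-cell program activities.
    distortions
        When False, the per-sample distortion blocks stay at zero (pure
        shared-factor model).
    sample_order
        Processing order for the per-sample blocks; results are invariant
        to it (deterministic ascending reductions) — exposed for testing.

    Returns
    -------
    (DecompositionModel, FitReport)
    """
    t0 = time.perf_counter()
    ds = normalize(data)
    model = setup_model(ds, hp, design, prior)
    loss_initial = compute_loss(model, ds, hp, design)  # all blocks zero
    initialize_latents(model, ds, hp)
    losses = [compute_loss(model, ds, hp, design)]
    logger.info("init: loss=%.6g (baseline %.6g)", losses[0], loss_initial)
    converged = False
    it = 0
    for it in range(1, hp.max_iter + 1):
        update_cell_embeddings(model, ds, hp, order=sample_order)
        if distortions:
            update_sample_distortions(model, ds, hp, design, order=sample_order)
            if design is not None:
                update_covariate_map(model, design, hp)
        update_reference(model, ds, hp, prior, order=sample_order)
        orthogonalize_reference(model)
        update_offsets(model, ds)
        L = compute_loss(model, ds, hp, design)
        if not np.isfinite(L):
            raise RuntimeError(
                f"non-finite loss at iteration {it}; first offending block: "
                f"{_first_nonfinite_block(model)}"
            )
        prev = losses[-1]
        rel = abs(L - prev) / abs(prev) if prev != 0 else 0.0
        losses.append(L)
        logger.info("iter %d: loss=%.10g rel_change=%.3g", it, L, rel)
        if rel < hp.tol:
            converged = True
            break
    report = FitReport(
        loss_trajectory=losses,
        converged=converged,
        n_iter=it,
        hyperparams=hp,
        wall_seconds=time.perf_counter() - t0,
        loss_initial=loss_initial,
    )
    return model, report
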