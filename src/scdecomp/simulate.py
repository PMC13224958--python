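"""Synthetic multi-sample datasets with known ground truth.

The generator emits exactly the structure the model assumes: a shared
orthonormal gene basis, cell states drawn from a small cluster mixture
plus a one-dimensional trajectory (so a continuum of states exists and
clustering-free differential expression is meaningfully testable),
per-sample axis distortions with a covariate-linked component supported
on a planted gene set, per-gene and per-cell offsets, and i.i.d. Gaussian
measurement noise on the log scale.

Truth is returned in the model's identifiable gauge: Z_true orthonormal
with the sign convention applied, B_true rows mean-centered, and the
distortions mean-centered across samples (a common distortion shared by
all samples is indistinguishable from a shift of Z, so the truth places
it in Z).
"""
from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import scipy.sparse as sp

from .model import ExpressionDataset, GeneProgramPrior, SampleDesign

__all__ = ["GroundTruth", "generate", "generate_counts_variant",
           "program_prior_from_truth", "DEFAULTS"]

#: default study conditions used by the package's own test fixtures
DEFAULTS = dict(
    genes=200,
    K=5,
    n_samples=4,
    cells_per_sample=500,
    noise_sd=0.1,
    distortion_scale=0.3,
    covariate_effect=1.0,
    n_de_genes=20,
    seed=7,
)


@dataclasses.dataclass
class GroundTruth:
    """Generating parameters, in the identifiable gauge, for recovery tests."""

    Z_true: np.ndarray
    delta_true: list
    B_true: np.ndarray
    o_true: np.ndarray
    s_true: np.ndarray
    D_true: np.ndarray
    X: np.ndarray
    planted_de_genes: np.ndarray
    program_matrix: Optional[np.ndarray] = None
    program_activities_true: Optional[np.ndarray] = None
    W_true: Optional[np.ndarray] = None


def _orthonormal_signed(M: np.ndarray):
    """QR with the largest-|loading|-positive sign convention; returns (Q, R)."""
    Q, R = np.linalg.qr(M)
    for k in range(Q.shape[1]):
        j = int(np.argmax(np.abs(Q[:, k])))
        if Q[j, k] < 0:
            Q[:, k] *= -1.0
            R[k, :] *= -1.0
    return Q, R


def _latent_states(rng: np.random.Generator, K: int, n: int) -> np.ndarray:
    """Cell states: 3-cluster mixture plus a 1-D trajectory, rows centered."""
    centers = 2.5 * rng.standard_normal((3, K))
    assign = rng.integers(0, 3, size=n)
    B = centers[assign].T + 1.5 * rng.standard_normal((K, n))
    direction = rng.standard_normal(K)
    direction /= np.linalg.norm(direction)
    t = rng.uniform(-2.0, 2.0, size=n)
    B += np.outer(direction, t)
    B -= B.mean(axis=1, keepdims=True)
    return B


def generate(
    genes: int = DEFAULTS["genes"],
    K: int = DEFAULTS["K"],
    n_samples: int = DEFAULTS["n_samples"],
    cells_per_sample: int = DEFAULTS["cells_per_sample"],
    noise_sd: float = DEFAULTS["noise_sd"],
    distortion_scale: float = DEFAULTS["distortion_scale"],
    covariate_effect: float = DEFAULTS["covariate_effect"],
    n_de_genes: int = DEFAULTS["n_de_genes"],
    seed: int = DEFAULTS["seed"],
    n_programs: int = 0,
    genes_per_program: int = 20,
):
    """Draw one multi-sample dataset; returns (dataset, design, truth).

    The binary "disease" covariate is split evenly across samples.  With
    ``n_programs > 0`` the shared axes are driven through a signed
    gene-program matrix (Z_true = A W_true after orthonormalization) and
    the truth records per-cell program activities.
    """
    if genes < 1 or K < 1 or n_samples < 1 or cells_per_sample < 1:
        raise ValueError("all counts must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_de_genes > genes:
        raise ValueError(f"n_de_genes={n_de_genes} exceeds genes={genes}")
    rng = np.random.default_rng(seed)
    n_cells = n_samples * cells_per_sample
    sample_of_cell = np.repeat(np.arange(n_samples), cells_per_sample)

    B = _latent_states(rng, K, n_cells)

    program_matrix = None
    W_gauge = None
    if n_programs > 0:
        A = np.zeros((genes, n_programs))
        for p in range(n_programs):
            members = rng.choice(genes, size=min(genes_per_program, genes), replace=False)
            A[members, p] = rng.choice([-1.0, 1.0], size=len(members))
        W_raw = rng.standard_normal((n_programs, K))
        Z, R = _orthonormal_signed(A @ W_raw)
        W_gauge = np.linalg.solve(R.T, W_raw.T).T  # W_raw R^-1
        program_matrix = A
    else:
        raw = rng.standard_normal((genes, K))
        # gene-centered axes: a gene-mean component of Z B is indistinguishable
        # from the per-cell offsets, so the identifiable gauge excludes it
        raw -= raw.mean(axis=0, keepdims=True)
        Z, _ = _orthonormal_signed(raw)

    # binary disease covariate, even split, with intercept
    disease = (np.arange(n_samples) >= n_samples / 2).astype(float)
    X = np.column_stack([np.ones(n_samples), disease])
    design = SampleDesign(
        X=X, covariate_names=["intercept", "disease"], intercept_included=True
    )

    # covariate-linked distortion supported on the planted genes; the
    # intercept slice centers the predictions so mean_i dZ_i = 0 (gauge)
    planted = rng.choice(genes, size=n_de_genes, replace=False)
    planted.sort()
    D_true = np.zeros((2, genes, K))
    D_true[1, planted, :] = covariate_effect * rng.standard_normal((n_de_genes, K)) / np.sqrt(genes)
    D_true[0] = -disease.mean() * D_true[1]

    noise_blocks = distortion_scale * rng.standard_normal((n_samples, genes, K)) / np.sqrt(genes)
    noise_blocks -= noise_blocks.mean(axis=0, keepdims=True)
    delta = [
        np.einsum("t,tgk->gk", X[i], D_true) + noise_blocks[i] for i in range(n_samples)
    ]

    o = rng.uniform(0.5, 2.5, size=genes)
    s = rng.normal(0.0, 0.2, size=n_cells)

    Y = np.empty((genes, n_cells))
    for i in range(n_samples):
        idx = np.flatnonzero(sample_of_cell == i)
        Y[:, idx] = o[:, None] + s[idx][None, :] + (Z + delta[i]) @ B[:, idx]
    if noise_sd > 0:
        Y += noise_sd * rng.standard_normal(Y.shape)
    else:
        Y[np.abs(Y) < 1e-8] = 0.0

    values = sp.csc_matrix(Y)
    dataset = ExpressionDataset(
        values=values,
        gene_ids=[f"gene{g:04d}" for g in range(genes)],
        cell_ids=[f"cell{c:05d}" for c in range(n_cells)],
        sample_of_cell=sample_of_cell,
        n_samples=n_samples,
        is_normalized=True,
        sample_ids=[f"sample{i}" for i in range(n_samples)],
    )
    truth = GroundTruth(
        Z_true=Z,
        delta_true=delta,
        B_true=B,
        o_true=o,
        s_true=s,
        D_true=D_true,
        X=X,
        planted_de_genes=planted,
        program_matrix=program_matrix,
        program_activities_true=None if W_gauge is None else W_gauge @ B,
        W_true=W_gauge,
    )
    return dataset, design, truth


def program_prior_from_truth(truth: GroundTruth) -> GeneProgramPrior:
    """Wrap the generator's signed program matrix as a model prior."""
    if truth.program_matrix is None:
        raise ValueError("ground truth was generated without programs")
    return GeneProgramPrior(
        A=sp.csc_matrix(truth.program_matrix),
        program_names=[f"program{p}" for p in range(truth.program_matrix.shape[1])],
    )


def generate_counts_variant(mean_depth: float = 5000.0, **params):
    """Integer-count variant exercising the normalization path end to end.

    The Gaussian log-scale values are exponentiated into relative rates and
    sampled as Poisson counts at the requested mean library size.
    """
    if not mean_depth > 0:
        raise ValueError("mean_depth must be > 0")
    dataset, design, truth = generate(**params)
    seed = params.get("seed", DEFAULTS["seed"])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 961748927]))
    M = np.asarray(dataset.values.toarray())
    if M.max() > 80.0:
        raise ValueError(
            "latent means overflow exp(); use smaller effect sizes or offsets"
        )
    rates = np.exp(M)
    rates /= rates.sum(axis=0, keepdims=True)
    counts = rng.poisson(mean_depth * rates).astype(np.int64)
    counts_ds = ExpressionDataset(
        values=sp.csc_matrix(counts),
        gene_ids=dataset.gene_ids,
        cell_ids=dataset.cell_ids,
        sample_of_cell=dataset.sample_of_cell,
        n_samples=dataset.n_samples,
        is_normalized=False,
        sample_ids=dataset.sample_ids,
    )
    return counts_ds, design, truth
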