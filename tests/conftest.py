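import numpy as np
import pytest
import scipy.sparse as sp

from scdecomp import (
    DecompositionModel,
    ExpressionDataset,
    HyperParams,
    SampleDesign,
    fit,
    generate,
    program_prior_from_truth,
)


def make_instance(seed, genes=12, cells=30, K=3, n_samples=3, with_design=True,
                  sparsity=0.4):
    """Small random model + dataset (consistent shapes, arbitrary parameters)."""
    rng = np.random.default_rng(seed)
    sample_of_cell = np.concatenate(
        [np.arange(n_samples), rng.integers(0, n_samples, cells - n_samples)]
    )
    dense = rng.standard_normal((genes, cells))
    dense[rng.random((genes, cells)) < sparsity] = 0.0
    ds = ExpressionDataset(
        values=sp.csc_matrix(dense),
        gene_ids=[f"g{j}" for j in range(genes)],
        cell_ids=[f"c{j}" for j in range(cells)],
        sample_of_cell=sample_of_cell,
        n_samples=n_samples,
        is_normalized=True,
    )
    design = None
    D = None
    if with_design:
        X = np.column_stack([np.ones(n_samples), rng.standard_normal(n_samples)])
        design = SampleDesign(X=X, covariate_names=["intercept", "x1"],
                              intercept_included=True)
        D = 0.2 * rng.standard_normal((2, genes, K))
    Z = np.linalg.qr(rng.standard_normal((genes, K)))[0]
    model = DecompositionModel(
        Z=Z,
        delta=[0.15 * rng.standard_normal((genes, K)) for _ in range(n_samples)],
        B=rng.standard_normal((K, cells)),
        o=rng.standard_normal(genes),
        s=0.3 * rng.standard_normal(cells),
        gene_ids=list(ds.gene_ids),
        cell_ids=list(ds.cell_ids),
        sample_of_cell=sample_of_cell.copy(),
        n_samples=n_samples,
        sample_ids=list(ds.sample_ids),
        D=D,
        covariate_names=None if design is None else list(design.covariate_names),
    )
    hp = HyperParams(K=K, lambda_b=0.37, lambda_delta=0.9, lambda_d=0.53,
                     lambda_w=0.7, seed=seed)
    return model, ds, hp, design


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic fixture: 200 genes, K=5, 4 samples, 2000 cells."""
    return generate()


@pytest.fixture(scope="session")
def default_fit(default_sim):
    ds, design, _ = default_sim
    return fit(ds, HyperParams(K=5, seed=7), design=design)


@pytest.fixture(scope="session")
def program_sim():
    ds, design, truth = generate(n_programs=5)
    return ds, design, truth, program_prior_from_truth(truth)


@pytest.fixture(scope="session")
def program_fit(program_sim):
    ds, design, truth, prior = program_sim
    return fit(ds, HyperParams(K=5, seed=7), design=design, prior=prior)


def model_max_diff(a, b):
    parts = [np.abs(a.Z - b.Z).max(), np.abs(a.B - b.B).max(),
             np.abs(a.o - b.o).max(), np.abs(a.s - b.s).max()]
    parts += [np.abs(x - y).max() for x, y in zip(a.delta, b.delta)]
    if a.D is not None and b.D is not None:
        parts.append(np.abs(a.D - b.D).max())
    return max(float(p) for p in parts)
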