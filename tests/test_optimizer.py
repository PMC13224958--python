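"""Block-coordinate updates against independent oracles, and fit() behavior."""
import numpy as np
import pytest

from conftest import make_instance, model_max_diff
from oracles import (
    oracle_covariate_map,
    oracle_distortions,
    oracle_embeddings,
    oracle_offsets,
    oracle_reference,
)

from scdecomp import (
    HyperParams,
    compute_loss,
    fit,
    generate,
    orthogonalize_reference,
    update_cell_embeddings,
    update_covariate_map,
    update_offsets,
    update_reference,
    update_sample_distortions,
)
from scdecomp._workspace import tracker

SEEDS = range(6)


class TestCellEmbeddings:
    def test_identity_axes_no_ridge_recovers_residual(self):
        model, ds, hp, _ = make_instance(0, genes=3, K=3)
        model.Z[...] = np.eye(3)
        for dz in model.delta:
            dz[...] = 0.0
        hp.lambda_b = 0.0
        update_cell_embeddings(model, ds, hp)
        Y = ds.values.toarray()
        np.testing.assert_allclose(
            model.B, Y - model.o[:, None] - model.s[None, :], atol=1e-10
        )

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_normal_equations_oracle(self, seed):
        model, ds, hp, _ = make_instance(seed)
        expected = oracle_embeddings(
            ds.values.toarray(), model.o, model.s, model.Z, model.delta,
            ds.sample_of_cell, hp.lambda_b,
        )
        update_cell_embeddings(model, ds, hp)
        np.testing.assert_allclose(model.B, expected, atol=1e-10)

    def test_orthonormal_axes_zero_ridge_is_left_inverse(self):
        model, ds, hp, _ = make_instance(1)
        for dz in model.delta:
            dz[...] = 0.0
        hp.lambda_b = 0.0
        update_cell_embeddings(model, ds, hp)
        Y = ds.values.toarray()
        resid = Y - model.o[:, None] - model.s[None, :]
        np.testing.assert_allclose(model.B, model.Z.T @ resid, atol=1e-10)


class TestSampleDistortions:
    def test_huge_ridge_pins_distortions_to_covariate_prediction(self):
        model, ds, hp, design = make_instance(2)
        hp.lambda_delta = 1e12
        update_sample_distortions(model, ds, hp, design)
        for i in range(ds.n_samples):
            np.testing.assert_allclose(
                model.delta[i], model.predicted_distortion(design, i), atol=1e-4
            )

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_dense_ridge_oracle(self, seed):
        model, ds, hp, design = make_instance(seed)
        expected = oracle_distortions(
            ds.values.toarray(), model.o, model.s, model.Z, model.B,
            ds.sample_of_cell, ds.n_samples, hp.lambda_delta, X=design.X, D=model.D,
        )
        update_sample_distortions(model, ds, hp, design)
        for i in range(ds.n_samples):
            np.testing.assert_allclose(model.delta[i], expected[i], atol=1e-10)

    def test_planted_single_factor_distortion_recovered(self):
        """Noiseless data with a known dZ: a near-zero ridge recovers it."""
        ds, design, truth = generate(
            genes=60, K=1, n_samples=2, cells_per_sample=120,
            noise_sd=0.0, distortion_scale=0.25, covariate_effect=0.0, seed=3,
        )
        hp = HyperParams(K=1, lambda_delta=1e-9, lambda_b=0.0)
        model, ds_n, _ = _model_at_truth(ds, truth)
        update_sample_distortions(model, ds, hp, design)
        for i in range(2):
            np.testing.assert_allclose(model.delta[i], truth.delta_true[i], atol=1e-4)


def _model_at_truth(ds, truth):
    """Model object holding the generator's true parameters."""
    from scdecomp import DecompositionModel
    model = DecompositionModel(
        Z=truth.Z_true.copy(), delta=[d.copy() for d in truth.delta_true],
        B=truth.B_true.copy(), o=truth.o_true.copy(), s=truth.s_true.copy(),
        gene_ids=list(ds.gene_ids), cell_ids=list(ds.cell_ids),
        sample_of_cell=ds.sample_of_cell.copy(), n_samples=ds.n_samples,
        sample_ids=list(ds.sample_ids),
    )
    return model, ds, truth


class TestCovariateMap:
    def test_common_distortion_intercept_only(self):
        model, ds, hp, design = make_instance(4)
        import scdecomp
        common = np.random.default_rng(0).standard_normal(model.Z.shape)
        for dz in model.delta:
            dz[...] = common
        design_i = scdecomp.SampleDesign(
            X=np.ones((ds.n_samples, 1)), covariate_names=["intercept"],
            intercept_included=True,
        )
        model.D = np.zeros((1,) + model.Z.shape)
        hp.lambda_d = 0.0
        update_covariate_map(model, design_i, hp)
        np.testing.assert_allclose(model.D[0], common, atol=1e-10)

    def test_exact_linear_model_recovered(self):
        model, ds, hp, design = make_instance(5)
        rng = np.random.default_rng(1)
        Q = rng.standard_normal(model.Z.shape)
        x = rng.standard_normal(ds.n_samples)
        import scdecomp
        design_x = scdecomp.SampleDesign(X=x[:, None], covariate_names=["x"])
        for i in range(ds.n_samples):
            model.delta[i][...] = x[i] * Q
        model.D = np.zeros((1,) + model.Z.shape)
        hp.lambda_d = 0.0
        update_covariate_map(model, design_x, hp)
        np.testing.assert_allclose(model.D[0], Q, atol=1e-10)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_dense_ridge_oracle(self, seed):
        model, ds, hp, design = make_instance(seed)
        expected = oracle_covariate_map(model.delta, design.X, hp.lambda_d / hp.lambda_delta)
        update_covariate_map(model, design, hp)
        np.testing.assert_allclose(model.D, expected, atol=1e-10)

    def test_underdetermined_without_ridge_rejected(self):
        model, ds, hp, design = make_instance(6, n_samples=2)
        import scdecomp
        wide = scdecomp.SampleDesign(
            X=np.random.default_rng(2).standard_normal((2, 4)),
            covariate_names=list("abcd"),
        )
        model.D = np.zeros((4,) + model.Z.shape)
        hp.lambda_d = 0.0
        with pytest.raises(ValueError, match="ridge"):
            update_covariate_map(model, wide, hp)


class TestReference:
    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_normal_equations_oracle(self, seed):
        model, ds, hp, _ = make_instance(seed)
        expected = oracle_reference(
            ds.values.toarray(), model.o, model.s, model.delta, model.B,
            ds.sample_of_cell,
        )
        update_reference(model, ds, hp)
        np.testing.assert_allclose(model.Z, expected, atol=1e-10)

    def test_recovers_svd_subspace_on_noiseless_rank_k_data(self):
        from scipy.linalg import subspace_angles
        ds, _, truth = generate(
            genes=80, K=4, n_samples=1, cells_per_sample=200, noise_sd=0.0,
            distortion_scale=0.0, covariate_effect=0.0, seed=9,
        )
        hp = HyperParams(K=4, lambda_b=0.0)
        model, _, _ = _model_at_truth(ds, truth)
        for dz in model.delta:
            dz[...] = 0.0
        update_reference(model, ds, hp)
        Y = ds.values.toarray()
        Yc = Y - Y.mean(1, keepdims=True)
        Yc -= Yc.mean(0, keepdims=True)
        U = np.linalg.svd(Yc)[0][:, :4]
        assert subspace_angles(model.Z, U).max() < 1e-6

    def test_orthonormal_embedding_rows_give_exact_product(self):
        model, ds, hp, _ = make_instance(7, cells=3, K=3, n_samples=1)
        model.B[...] = np.eye(3)
        model.s[...] = 0.0
        for dz in model.delta:
            dz[...] = 0.0
        update_reference(model, ds, hp)
        resid = ds.values.toarray() - model.o[:, None]
        np.testing.assert_allclose(model.Z, resid @ np.eye(3), atol=1e-10)

    def test_identity_prior_gives_ridge_shrunk_solution(self):
        model, ds, hp, _ = make_instance(8)
        g = model.n_genes
        model.A = np.eye(g)
        model.W = np.zeros((g, model.K))
        model.program_names = [f"p{j}" for j in range(g)]
        unconstrained = oracle_reference(
            ds.values.toarray(), model.o, model.s, model.delta, model.B,
            ds.sample_of_cell,
        )
        update_reference(model, ds, hp)
        np.testing.assert_allclose(model.W, unconstrained / (1 + hp.lambda_w), atol=1e-10)
        np.testing.assert_allclose(model.Z, model.A @ model.W, atol=1e-12)


class TestOrthogonalize:
    def test_already_orthonormal_is_identity_transform(self):
        model, _, _, _ = make_instance(9)
        Z0, B0 = model.Z.copy(), model.B.copy()
        R = orthogonalize_reference(model)
        np.testing.assert_allclose(R, np.eye(model.K), atol=1e-10)
        np.testing.assert_allclose(model.Z, Z0, atol=1e-10)
        np.testing.assert_allclose(model.B, B0, atol=1e-10)

    def test_scaling_absorbed_into_embeddings(self):
        model, _, _, _ = make_instance(10)
        Z0, B0 = model.Z.copy(), model.B.copy()
        model.Z[...] = 2.0 * Z0
        orthogonalize_reference(model)
        np.testing.assert_allclose(model.Z, Z0, atol=1e-10)
        np.testing.assert_allclose(model.B, 2.0 * B0, atol=1e-10)

    @pytest.mark.parametrize("seed", SEEDS)
    def test_qr_identities_and_reconstruction_invariance(self, seed):
        model, _, _, _ = make_instance(seed)
        rng = np.random.default_rng(seed)
        model.Z[...] = rng.standard_normal(model.Z.shape)
        prod = model.Z @ model.B
        Z_raw = model.Z.copy()
        R = orthogonalize_reference(model)
        np.testing.assert_allclose(model.Z @ R, Z_raw, atol=1e-12)
        np.testing.assert_allclose(model.Z.T @ model.Z, np.eye(model.K), atol=1e-12)
        np.testing.assert_allclose(model.Z @ model.B, prod, atol=1e-10)
        assert (np.diag(R) > 0).all()

    def test_rank_deficient_axes_rejected(self):
        model, _, _, _ = make_instance(11)
        model.Z[:, 1] = model.Z[:, 0]
        with pytest.raises(ValueError, match="axis"):
            orthogonalize_reference(model)


class TestOffsets:
    def test_zero_factors_give_row_means(self):
        model, ds, _, _ = make_instance(12)
        model.B[...] = 0.0
        model.s[...] = 0.0
        update_offsets(model, ds)
        np.testing.assert_allclose(
            model.o, np.asarray(ds.values.mean(axis=1)).ravel(), atol=1e-12
        )

    @pytest.mark.parametrize("seed", SEEDS)
    def test_mean_residuals_vanish(self, seed):
        """Normal-equation identity: per-gene and per-cell residual means are 0."""
        model, ds, _, _ = make_instance(seed)
        update_offsets(model, ds)
        Y = ds.values.toarray()
        F = np.column_stack([
            (model.Z + model.delta[model.sample_of_cell[c]]) @ model.B[:, c]
            for c in range(ds.n_cells)
        ])
        resid = Y - model.o[:, None] - model.s[None, :] - F
        assert np.abs(resid.mean(axis=1)).max() < 1e-10
        assert np.abs(resid.mean(axis=0)).max() < 1e-10

    @pytest.mark.parametrize("seed", SEEDS)
    def test_matches_loop_oracle(self, seed):
        model, ds, _, _ = make_instance(seed)
        o_exp, s_exp, B_exp = oracle_offsets(
            ds.values.toarray(), model.o, model.s, model.Z, model.delta, model.B,
            ds.sample_of_cell,
        )
        update_offsets(model, ds)
        np.testing.assert_allclose(model.o, o_exp, atol=1e-10)
        np.testing.assert_allclose(model.s, s_exp, atol=1e-10)
        np.testing.assert_allclose(model.B, B_exp, atol=1e-10)


class TestFit:
    def test_noiseless_rank_k_loss_collapses(self):
        ds, design, _ = generate(noise_sd=0.0, distortion_scale=0.0,
                                 covariate_effect=0.0, cells_per_sample=200)
        hp = HyperParams(K=5, lambda_b=1e-9, lambda_delta=1e-9, lambda_d=1e-9, seed=7)
        model, report = fit(ds, hp, design=design)
        assert report.loss_trajectory[-1] < 1e-6 * report.loss_initial

    def test_infinite_tolerance_runs_exactly_one_iteration(self, default_sim):
        ds, design, _ = default_sim
        hp = HyperParams(K=5, tol=np.inf, seed=7)
        _, report = fit(ds, hp, design=design)
        assert report.n_iter == 1
        assert report.converged

    def test_loss_trajectory_nonincreasing(self, default_fit):
        _, report = default_fit
        L = np.asarray(report.loss_trajectory)
        assert (np.diff(L) <= 1e-9 * np.abs(L[:-1])).all()

    def test_worker_count_does_not_change_results(self, default_sim, default_fit):
        ds, design, _ = default_sim
        m1, _ = default_fit
        m4, _ = fit(ds, HyperParams(K=5, seed=7, n_workers=4), design=design)
        assert model_max_diff(m1, m4) < 1e-10

    def test_sample_processing_order_does_not_change_results(self, default_sim, default_fit):
        ds, design, _ = default_sim
        m1, _ = default_fit
        mp, _ = fit(ds, HyperParams(K=5, seed=7), design=design,
                    sample_order=[2, 0, 3, 1])
        assert model_max_diff(m1, mp) < 1e-10

    def test_gauge_conventions_after_every_fit(self, default_fit):
        model, _ = default_fit
        np.testing.assert_allclose(model.Z.T @ model.Z, np.eye(5), atol=1e-8)
        assert np.abs(model.B.mean(axis=1)).max() < 1e-8

    def test_blocks_updated_in_place(self, default_sim):
        """No parameter block is reallocated between iterations."""
        from scdecomp.initialization import setup_model
        ds, design, _ = default_sim
        hp = HyperParams(K=5, seed=7, max_iter=3, tol=1e-15)
        import scdecomp.optimizer as op
        from scdecomp.model import normalize
        dsn = normalize(ds)
        model = setup_model(dsn, hp, design)
        ids = (id(model.Z), id(model.B), id(model.o), id(model.s),
               tuple(id(d) for d in model.delta), id(model.D))
        from scdecomp.initialization import initialize_latents
        initialize_latents(model, dsn, hp)
        for _ in range(2):
            op.update_cell_embeddings(model, dsn, hp)
            op.update_sample_distortions(model, dsn, hp, design)
            op.update_covariate_map(model, design, hp)
            op.update_reference(model, dsn, hp)
            op.orthogonalize_reference(model)
            op.update_offsets(model, dsn)
        assert ids == (id(model.Z), id(model.B), id(model.o), id(model.s),
                       tuple(id(d) for d in model.delta), id(model.D))

    def test_no_dense_full_matrix_scratch(self):
        """Dense scratch stays at per-sample size, never genes x all-cells."""
        ds, design, _ = generate(genes=80, K=4, n_samples=4, cells_per_sample=60)
        tracker.reset()
        fit(ds, HyperParams(K=4, seed=0, max_iter=3, tol=1e-15), design=design)
        assert tracker.max_elements <= 80 * 60
        assert tracker.max_elements < 80 * 240

    def test_nonfinite_data_aborts_with_block_name(self):
        model, ds, hp, design = make_instance(13)
        import scipy.sparse as sp
        bad = ds.values.toarray()
        bad[0, 0] = np.inf
        from scdecomp import ExpressionDataset
        ds_bad = ExpressionDataset(
            values=sp.csc_matrix(bad), gene_ids=ds.gene_ids, cell_ids=ds.cell_ids,
            sample_of_cell=ds.sample_of_cell, n_samples=ds.n_samples,
            is_normalized=True,
        )
        with pytest.raises((RuntimeError, ValueError)):
            fit(ds_bad, hp, design=design)


class TestSparseDenseEquivalence:
    def test_sparse_and_densified_fits_agree(self):
        from scdecomp import ExpressionDataset
        ds, design, _ = generate(genes=100, K=4, n_samples=3, cells_per_sample=80)
        hp = HyperParams(K=4, seed=1, max_iter=12, tol=1e-15)
        m_sparse, _ = fit(ds, hp, design=design)
        ds_dense = ExpressionDataset(
            values=ds.values.toarray(), gene_ids=ds.gene_ids, cell_ids=ds.cell_ids,
            sample_of_cell=ds.sample_of_cell, n_samples=ds.n_samples,
            is_normalized=True, sample_ids=ds.sample_ids,
        )
        m_dense, _ = fit(ds_dense, hp, design=design)
        assert model_max_diff(m_sparse, m_dense) < 1e-10
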