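import numpy as np
import pytest

from otalign._exceptions import ParameterError, ValidationError
from otalign.core import (
    MappingModel,
    ObjectiveConfig,
    _loss_and_grad,
    _spectral_init,
    fit,
    hyperparameter_search,
    objective,
    transform,
)
from otalign.graph import build_graph
from otalign.kernels import gaussian_gram
from otalign.metrics import foscttm, label_transfer_accuracy
from otalign.simulate import make_pair
from otalign.sinkhorn import extract_plan, sinkhorn_divergence


def toy_model(rng, n_x=7, n_y=6, k=2, **cfg_kwargs):
    x = rng.normal(size=(n_x, 3))
    y = rng.normal(size=(n_y, 4))
    cfg = ObjectiveConfig(k_latent=k, epsilon=0.1, **cfg_kwargs)
    kx, ky = gaussian_gram(x), gaussian_gram(y)
    return MappingModel(
        p_x=rng.normal(size=(n_x, k)),
        p_y=rng.normal(size=(n_y, k)),
        kernel_x=kx,
        kernel_y=ky,
        laplacian_x=build_graph(kx, 2),
        laplacian_y=build_graph(ky, 2),
        config=cfg,
        x_train=x,
        y_train=y,
        epsilon_used=0.1,
    )


class TestObjective:
    def test_zero_weights_isolate_sinkhorn_term(self, rng):
        m = toy_model(rng, lambda_topo=0.0, lambda_ortho=0.0)
        total, comps = objective(m)
        div = sinkhorn_divergence(m.embedding_x, m.embedding_y, 0.1)
        assert total == pytest.approx(div, rel=1e-9)
        assert total == pytest.approx(comps["ot"], rel=1e-12)

    def test_decomposition_exact(self, rng):
        m = toy_model(rng, lambda_topo=0.3, lambda_ortho=0.7)
        total, c = objective(m)
        assert total == pytest.approx(
            c["ot"] + 0.3 * c["topo"] + 0.7 * c["ortho"], rel=1e-9
        )

    def test_spectral_coefficients_zero_ortho_component(self, rng):
        m = toy_model(rng)
        m.p_x = _spectral_init(m.kernel_x, 2)
        _, comps = objective(m)
        # P = U L^{-1/2} makes P'KP = I exactly for the x domain
        assert m.ortho_residual("x") == pytest.approx(0.0, abs=1e-8)

    def test_zero_coefficients_give_2k_ortho(self, rng):
        m = toy_model(rng, k=3)
        m.p_x = np.zeros_like(m.p_x)
        m.p_y = np.zeros_like(m.p_y)
        _, comps = objective(m)
        assert comps["topo"] == pytest.approx(0.0, abs=1e-12)
        assert comps["ortho"] == pytest.approx(6.0)  # ||-I_3||_F^2 per domain

    def test_gradient_matches_finite_differences(self, rng):
        """Analytic gradient of the full objective w.r.t. P_X entries on a
        6-cell toy agrees with central differences."""
        m = toy_model(rng, n_x=6, n_y=6, lambda_topo=0.1, lambda_ortho=0.5)
        cfg = m.config
        args = (
            m.kernel_x.gram, m.kernel_y.gram,
            m.laplacian_x.laplacian, m.laplacian_y.laplacian,
        )

        def loss(px):
            return _loss_and_grad(px, m.p_y, *args, cfg, 0.1, None)[0]

        from dataclasses import replace

        cfg = replace(cfg, sinkhorn_max_iter=20000, sinkhorn_tol=1e-12)
        _, _, grad_px, _, _ = _loss_and_grad(m.p_x, m.p_y, *args, cfg, 0.1, None)
        h = 1e-6
        num = np.zeros_like(m.p_x)
        for i in range(m.p_x.shape[0]):
            for j in range(m.p_x.shape[1]):
                pp, pm = m.p_x.copy(), m.p_x.copy()
                pp[i, j] += h
                pm[i, j] -= h
                num[i, j] = (loss(pp) - loss(pm)) / (2 * h)
        rel = np.abs(num - grad_px).max() / np.abs(num).max()
        assert rel < 1e-3


class TestFit:
    def test_loss_decreases_and_self_alignment(self):
        """Aligning a modality with a copy of itself recovers the identity
        pairing almost perfectly."""
        pair = make_pair("branch", n=100, target_dim=30, seed=2)
        x = pair.domain_x
        model = fit(x, x, ObjectiveConfig(max_epochs=150, seed=0))
        assert model.history[-1]["total"] <= model.history[0]["total"]
        f = foscttm(model.embedding_x, model.embedding_y, np.arange(x.n_cells))
        assert f < 0.05

    def test_same_seed_bitwise_identical(self):
        pair = make_pair("branch", n=60, target_dim=20, seed=1)
        cfg = ObjectiveConfig(max_epochs=40, seed=5)
        m1 = fit(pair.domain_x, pair.domain_y, cfg)
        m2 = fit(pair.domain_x, pair.domain_y, cfg)
        assert np.array_equal(m1.p_x, m2.p_x)
        assert np.array_equal(m1.p_y, m2.p_y)

    def test_random_init_also_deterministic(self):
        pair = make_pair("branch", n=60, target_dim=20, seed=1)
        cfg = ObjectiveConfig(max_epochs=30, seed=5, init="random")
        m1 = fit(pair.domain_x, pair.domain_y, cfg)
        m2 = fit(pair.domain_x, pair.domain_y, cfg)
        assert np.array_equal(m1.p_x, m2.p_x)

    def test_history_records_components(self, small_fit):
        _, model = small_fit
        rec = model.history[0]
        assert {"epoch", "total", "ot", "topo", "ortho", "lr", "epsilon"} <= set(rec)

    def test_ortho_residual_reported(self, small_fit):
        _, model = small_fit
        assert model.ortho_residual("x") >= 0.0


class TestTransform:
    def test_training_points_reproduce_embedding(self, small_fit):
        _, model = small_fit
        got = transform(model, model.x_train, "x")
        assert np.allclose(got, model.embedding_x, atol=1e-10)

    def test_single_duplicated_point(self, small_fit):
        _, model = small_fit
        got = transform(model, model.x_train[4:5], "x")
        assert np.allclose(got[0], model.embedding_x[4], atol=1e-10)

    def test_two_point_toy_closed_form(self):
        x = np.array([[0.0], [2.0]])
        cfg = ObjectiveConfig(k_latent=1, max_epochs=5, epsilon=0.5, k_neighbors=1)
        model = fit(x, x, cfg)
        q = np.array([[1.0]])  # midpoint: kernel value exp(-1/(2*4)) to both
        sigma = model.kernel_x.sigma
        kq = np.exp(-1.0 / (2 * sigma**2))
        expected = kq * model.p_x.sum()
        assert transform(model, q, "x")[0, 0] == pytest.approx(expected, rel=1e-10)

    def test_wrong_dimension_rejected(self, small_fit):
        _, model = small_fit
        with pytest.raises(ValidationError):
            transform(model, np.zeros((2, 3)), "x")


class TestSearch:
    def test_unsupervised_selects_minimum_objective(self):
        pair = make_pair("branch", n=60, target_dim=20, seed=2)
        grids = {"lambda_ortho": [1e-2], "lambda_topo": [1e-3, 1e-4]}
        base = ObjectiveConfig(max_epochs=30, seed=0)
        model, table = hyperparameter_search(
            pair.domain_x, pair.domain_y, grids=grids, base_config=base
        )
        best_row = table.loc[table["objective"].idxmin()]
        final, _ = objective(model, tol=1e-9)
        assert final == pytest.approx(best_row["objective"], rel=1e-6)

    def test_constraint_filters_equal_weights(self):
        pair = make_pair("branch", n=60, target_dim=20, seed=2)
        grids = {"lambda_ortho": [1e-3], "lambda_topo": [1e-3, 1e-4]}
        base = ObjectiveConfig(max_epochs=10, seed=0)
        _, table = hyperparameter_search(
            pair.domain_x, pair.domain_y, grids=grids, base_config=base
        )
        # the (1e-3, 1e-3) pair violates lambda_ortho > lambda_topo
        assert len(table) == 1
        assert table.iloc[0]["lambda_topo"] == 1e-4

    def test_all_filtered_grid_rejected(self):
        pair = make_pair("branch", n=60, target_dim=20, seed=2)
        with pytest.raises(ParameterError):
            hyperparameter_search(
                pair.domain_x, pair.domain_y,
                grids={"lambda_ortho": [1e-4], "lambda_topo": [1e-3]},
            )

    def test_semisupervised_requires_labels(self):
        pair = make_pair("branch", n=60, target_dim=20, seed=2)
        with pytest.raises(ParameterError):
            hyperparameter_search(
                pair.domain_x, pair.domain_y, mode="semisupervised"
            )

    def test_semisupervised_selects_max_lta(self):
        pair = make_pair("branch", n=80, target_dim=20, seed=2)
        grids = {"lambda_ortho": [1e-2, 1e-1], "lambda_topo": [1e-3]}
        base = ObjectiveConfig(max_epochs=60, seed=0)
        model, table = hyperparameter_search(
            pair.domain_x, pair.domain_y, grids=grids, mode="semisupervised",
            labels_x=pair.domain_x.labels, labels_y=pair.domain_y.labels,
            base_config=base,
        )
        assert "lta_val" in table
        best = table["lta_val"].max()
        sel = table.loc[table["lta_val"].idxmax()]
        assert sel["lta_val"] == best


class TestExtractPlan:
    def test_plan_marginals_within_tolerance(self, small_fit):
        _, model = small_fit
        plan = extract_plan(model)
        assert np.abs(plan.plan.sum(axis=1) - plan.marginal_a).max() < 1e-6
        assert np.abs(plan.plan.sum(axis=0) - plan.marginal_b).max() < 1e-6

    def test_aligned_toy_argmax_recovers_partner(self, rng):
        """On perfectly aligned paired clouds the plan's row argmax points
        at the true partner for >= 95% of rows."""
        from otalign.sinkhorn import entropic_ot_cost

        xe = rng.normal(size=(60, 3))
        perm = rng.permutation(60)
        inv = np.argsort(perm)
        ye = xe[perm]  # y row j = x row perm[j]; partner of x i is inv[i]
        _, plan = entropic_ot_cost(xe, ye, epsilon=0.01, max_iter=5000, tol=1e-9)
        hits = np.mean(np.argmax(plan.plan, axis=1) == inv)
        assert hits >= 0.95
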