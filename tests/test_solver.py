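import numpy as np
import pytest

from intergee.correlation import WorkingCorrelationModel, build_V_inv
from intergee.design import GroupMap, LongitudinalDataset, build_design
from intergee.solver import (
    METHODS,
    FitConfig,
    fit_pgee,
    gee_information,
    gee_score,
    lasso_initialize,
    newton_update,
    sparsify,
)
from intergee.simulate import SimulationDesign, simulate_dataset


def _dataset(n, k, p, q, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k, p))
    E = (rng.standard_normal((n, k, q)) > 0).astype(float)
    data = LongitudinalDataset(y=np.zeros((n, k)), X=X, E=E)
    design, groups = build_design(data)
    if beta is None:
        beta = np.zeros(design.d)
    y = (design.Z @ beta).reshape(n, k) + 0.3 * rng.standard_normal((n, k))
    return LongitudinalDataset(y=y, X=X, E=E), design, groups


class TestScoreAndInformation:
    def test_score_zero_at_exact_fit(self):
        data, design, groups = _dataset(6, 3, 2, 2, seed=1)
        beta = np.random.default_rng(2).standard_normal(design.d)
        y = (design.Z @ beta).reshape(6, 3)
        V_inv = np.eye(3)
        U = gee_score(beta, design, V_inv, y.reshape(-1))
        assert np.abs(U).max() < 1e-10

    def test_score_zero_at_ols_under_independence(self):
        data, design, groups = _dataset(20, 3, 3, 2, seed=3)
        y = data.y.reshape(-1)
        beta_ols, *_ = np.linalg.lstsq(design.Z, y, rcond=None)
        U = gee_score(beta_ols, design, np.eye(3), y)
        assert np.abs(U).max() < 1e-8

    def test_score_scalar_case(self):
        data = LongitudinalDataset(y=[[2.0]], X=np.zeros((1, 1, 0)),
                                   E=np.zeros((1, 1, 1)))
        design, _ = build_design(data)
        # d = 2 (intercept + one dummy, dummy is 0); check the intercept entry
        U = gee_score(np.zeros(design.d), design, np.eye(1), np.array([2.0]))
        assert U[0] == pytest.approx(2.0)

    def test_information_is_ZtZ_under_independence(self):
        data, design, groups = _dataset(5, 2, 2, 1, seed=4)
        T = gee_information(design, np.eye(2))
        assert np.allclose(T, design.Z.T @ design.Z)

    def test_information_matches_hand_sum(self):
        data, design, groups = _dataset(4, 2, 1, 1, seed=5)
        V_inv = np.linalg.inv(np.array([[1.0, 0.5], [0.5, 1.0]]))
        expected = sum(Zi.T @ V_inv @ Zi for Zi in design.Z3)
        assert np.allclose(gee_information(design, V_inv), expected)


class TestNewtonUpdate:
    def test_scalar_arithmetic(self):
        # T=2, n=1, W=1, beta=1, U=0 -> beta' = 1 + (1/3)(-1) = 2/3
        beta = newton_update(np.array([1.0]), np.array([0.0]),
                             np.array([[2.0]]), np.array([1.0]), n=1)
        assert beta[0] == pytest.approx(2.0 / 3.0)

    def test_one_step_reaches_ols_from_zero(self):
        data, design, groups = _dataset(15, 2, 2, 1, seed=6)
        y = data.y.reshape(-1)
        U = gee_score(np.zeros(design.d), design, np.eye(2), y)
        T = gee_information(design, np.eye(2))
        beta = newton_update(np.zeros(design.d), U, T, np.zeros(design.d), n=15)
        beta_ols, *_ = np.linalg.lstsq(design.Z, y, rcond=None)
        assert np.allclose(beta, beta_ols, atol=1e-8)

    def test_fixed_point(self):
        beta = np.array([1.0, -2.0])
        out = newton_update(beta, np.zeros(2), np.eye(2), np.zeros(2), n=3)
        assert np.allclose(out, beta)

    def test_one_step_gls_idempotent(self):
        """With W = 0 and V fixed, the second step is a no-op."""
        data, design, groups = _dataset(15, 3, 2, 1, seed=7)
        y = data.y.reshape(-1)
        V_inv = build_V_inv(WorkingCorrelationModel("ar1", 0.4, 1.3, 3))
        T = gee_information(design, V_inv)
        w = np.zeros(design.d)
        b1 = newton_update(np.zeros(design.d), gee_score(np.zeros(design.d), design, V_inv, y), T, w, 15)
        b2 = newton_update(b1, gee_score(b1, design, V_inv, y), T, w, 15)
        assert np.allclose(b1, b2, atol=1e-9)

    def test_singular_system_rejected(self):
        T = np.zeros((2, 2))
        with pytest.raises(np.linalg.LinAlgError):
            newton_update(np.zeros(2), np.ones(2), T, np.zeros(2), n=1)


class TestLassoInit:
    def test_recovers_signal_column(self):
        beta = None
        rng = np.random.default_rng(8)
        n, k, p, q = 60, 2, 6, 1
        X = rng.standard_normal((n, k, p))
        E = (rng.standard_normal((n, k, q)) > 0).astype(float)
        data0 = LongitudinalDataset(y=np.zeros((n, k)), X=X, E=E)
        design, groups = build_design(data0)
        beta = np.zeros(design.d)
        beta[groups.main_cols[2]] = 2.0
        y = (design.Z @ beta).reshape(n, k) + 0.1 * rng.standard_normal((n, k))
        data = LongitudinalDataset(y=y, X=X, E=E)
        b0 = lasso_initialize(data, design, seed=0)
        assert abs(b0[groups.main_cols[2]]) > 1.0
        others = np.delete(np.arange(design.d), [0, 1, groups.main_cols[2]])
        assert np.abs(b0[others]).max() < 0.2

    def test_constant_response(self):
        data = LongitudinalDataset(
            y=np.full((6, 2), 5.0),
            X=np.random.default_rng(0).standard_normal((6, 2, 2)),
            E=np.zeros((6, 2, 1)),
        )
        b0 = lasso_initialize(data)
        assert b0[0] == pytest.approx(5.0, abs=1e-6)
        assert np.abs(b0[2:]).max() < 1e-6

    def test_zero_response(self):
        data = LongitudinalDataset(
            y=np.zeros((6, 2)),
            X=np.random.default_rng(1).standard_normal((6, 2, 2)),
            E=np.zeros((6, 2, 1)),
        )
        b0 = lasso_initialize(data)
        assert np.abs(b0).max() < 1e-10


class TestSparsify:
    def test_tau_zero_is_identity(self):
        groups = GroupMap(p=2, q=1)
        beta = np.random.default_rng(0).standard_normal(groups.d)
        out, sel = sparsify(beta, 0.0, groups)
        assert np.array_equal(out, beta)
        assert sel.size == groups.d

    def test_small_entries_zeroed(self):
        groups = GroupMap(p=2, q=1)
        beta = np.array([0.1, 0.2, 0.0005, 0.5, 0.0001, 0.9])
        out, sel = sparsify(beta, 1e-3, groups)
        assert np.array_equal(out, [0.1, 0.2, 0.0, 0.5, 0.0, 0.9])
        assert set(sel) == {0, 1, 3, 5}

    def test_unpenalized_never_zeroed(self):
        groups = GroupMap(p=1, q=2)
        beta = np.full(groups.d, 1e-9)
        out, sel = sparsify(beta, 1e-3, groups)
        assert np.all(out[: 3] == 1e-9)
        assert np.all(out[3:] == 0.0)


class TestFitPGEE:
    def test_zero_penalty_equals_pooled_ols(self):
        data, design, groups = _dataset(40, 3, 3, 2, seed=9)
        cfg = FitConfig(structure="independence",
                        group_interactions=False, zero_threshold=0.0)
        fit = fit_pgee(data, cfg)
        beta_ols, *_ = np.linalg.lstsq(design.Z, data.y.reshape(-1), rcond=None)
        assert np.abs(fit.beta - beta_ols).max() < 1e-6
        assert fit.converged

    def test_huge_penalty_keeps_only_unpenalized(self, small_sim):
        design_cfg, data, truth = small_sim
        cfg = FitConfig.from_method("A1", lambda1=50.0, lambda2=50.0)
        fit = fit_pgee(data, cfg)
        assert set(fit.selected) == set(range(1 + design_cfg.q))
        assert np.all(fit.beta[1 + design_cfg.q:] == 0.0)

    def test_subject_permutation_invariance(self, small_sim):
        _, data, truth = small_sim
        cfg = FitConfig.from_method("A1", lambda1=0.3, lambda2=0.3, max_iter=30)
        fit = fit_pgee(data, cfg, lasso_seed=0)
        perm = np.random.default_rng(5).permutation(data.n)
        fit_p = fit_pgee(data.subset(perm), cfg, lasso_seed=0)
        assert np.abs(fit.beta - fit_p.beta).max() < 1e-8

    def test_convergence_flag_and_trace(self, small_sim):
        _, data, truth = small_sim
        cfg = FitConfig.from_method("A2", lambda1=0.3, lambda2=0.3)
        fit = fit_pgee(data, cfg)
        assert len(fit.deltas) == fit.n_iter
        if fit.converged:
            assert fit.deltas[-1] < cfg.tol

    def test_method_map(self):
        assert METHODS["A1"] == ("exchangeable", True)
        assert METHODS["A5"] == ("ar1", False)
        cfg = FitConfig.from_method("A3", lambda1=0.1, lambda2=0.2)
        assert cfg.structure == "independence" and cfg.group_interactions
        with pytest.raises(ValueError):
            FitConfig.from_method("A7")
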