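"""Estimator tests: kernel covariance, ADMM vs convex oracle, CV, cv.vote."""

import numpy as np
import pytest

from tvggm.estimator import (
    TimeVaryingGraphicalLasso,
    cv_vote,
    fit_local_group_lasso,
    group_lasso_objective,
    kernel_covariance,
    support_constrained_mle,
)
from tvggm.preprocess import bin_cells
from tvggm.simulate import TVGGMSpec, make_precision_path, sample_cells

from conftest import proximal_gradient_group_glasso


class TestKernelCovariance:
    def test_uniform_weight_limit_equals_sample_covariance(self, rng):
        X = rng.normal(size=(25, 6))
        times = np.linspace(0, 1, 25)
        S = kernel_covariance(X, times, 0.5, h=1e9)
        np.testing.assert_allclose(S, np.cov(X.T, bias=True), atol=1e-8)

    def test_tiny_bandwidth_degenerates_to_zero_matrix(self, rng):
        X = rng.normal(size=(2, 4))
        times = np.array([0.0, 1.0])
        S = kernel_covariance(X, times, 0.0, h=0.01)
        np.testing.assert_allclose(S, 0.0, atol=1e-12)

    def test_matches_naive_double_loop(self, rng):
        X = rng.normal(size=(25, 5))
        times = np.linspace(0, 1, 25)
        t, h = 0.5, 0.2
        S = kernel_covariance(X, times, t, h, kernel="epanechnikov")
        u = (times - t) / h
        w = np.where(np.abs(u) <= 1, 0.75 * (1 - u**2), 0.0)
        w = w / w.sum()
        mu = sum(w[i] * X[i] for i in range(25))
        expected = np.zeros((5, 5))
        for i in range(25):
            d = X[i] - mu
            expected += w[i] * np.outer(d, d)
        np.testing.assert_allclose(S, expected, atol=1e-12)

    def test_all_zero_weights_error(self, rng):
        X = rng.normal(size=(5, 3))
        with pytest.raises(ValueError):
            kernel_covariance(X, np.linspace(0, 0.1, 5), 0.9, h=0.05)

    def test_positive_semidefinite(self, rng):
        X = rng.normal(size=(15, 8))
        S = kernel_covariance(X, np.linspace(0, 1, 15), 0.3, 0.25)
        assert np.linalg.eigvalsh(S)[0] > -1e-10


class TestGroupLassoADMM:
    def test_large_lambda_empties_graph(self, rng):
        Ss = [np.cov(rng.standard_normal((30, 6)).T) for _ in range(3)]
        lam = max(np.abs(S - np.diag(np.diag(S))).max() for S in Ss) * 2
        omegas, supports, _ = fit_local_group_lasso(Ss, lam)
        for sup in supports:
            assert np.triu(sup, k=1).sum() == 0

    def test_matches_convex_oracle_single_time(self, rng):
        X = rng.standard_normal((40, 5))
        S = np.cov(X.T)
        lam = 0.1
        omegas, _, _ = fit_local_group_lasso(
            [S], lam, tol_abs=1e-9, tol_rel=1e-7, max_iter=20000
        )
        obj = group_lasso_objective([S], omegas, lam)
        _, obj_oracle = proximal_gradient_group_glasso([S], lam)
        assert abs(obj - obj_oracle) / abs(obj_oracle) < 1e-4

    def test_matches_convex_oracle_neighborhood(self, rng):
        Ss = [np.cov(rng.standard_normal((25, 4)).T) for _ in range(3)]
        lam = 0.08
        omegas, _, _ = fit_local_group_lasso(
            Ss, lam, tol_abs=1e-9, tol_rel=1e-7, max_iter=20000
        )
        obj = group_lasso_objective(Ss, omegas, lam)
        _, obj_oracle = proximal_gradient_group_glasso(Ss, lam)
        assert abs(obj - obj_oracle) / abs(obj_oracle) < 1e-4

    def test_persistent_edge_survives_small_lambda(self, rng):
        p = 4
        omega = np.eye(p)
        omega[0, 1] = omega[1, 0] = -0.45
        omega[0, 0] = omega[1, 1] = 1.45
        cov = np.linalg.inv(omega)
        Ss = [
            np.cov(rng.multivariate_normal(np.zeros(p), cov, size=300).T)
            for _ in range(3)
        ]
        omegas, supports, _ = fit_local_group_lasso(Ss, 0.02)
        for sup in supports:
            assert sup[0, 1]

    def test_group_support_shared_across_neighborhood(self, rng):
        Ss = [np.cov(rng.standard_normal((20, 5)).T) for _ in range(4)]
        _, supports, _ = fit_local_group_lasso(Ss, 0.05)
        for m in range(1, 4):
            np.testing.assert_array_equal(supports[m], supports[0])

    def test_solutions_symmetric_positive_definite(self, rng):
        Ss = [np.cov(rng.standard_normal((15, 6)).T) for _ in range(2)]
        omegas, _, _ = fit_local_group_lasso(Ss, 0.05)
        for om in omegas:
            np.testing.assert_allclose(om, om.T)
            assert np.linalg.eigvalsh(om)[0] > 0

    def test_lambda_monotonicity_of_edge_counts(self, rng):
        Ss = [np.cov(rng.standard_normal((30, 8)).T) for _ in range(2)]
        smax = max(np.abs(S - np.diag(np.diag(S))).max() for S in Ss)
        counts = []
        warm = None
        for lam in np.geomspace(smax * 1.1, smax / 20, 8):
            _, supports, warm = fit_local_group_lasso(Ss, lam, warm=warm)
            counts.append(int(np.triu(supports[0], 1).sum()))
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestSupportConstrainedMLE:
    def test_full_support_inverts_covariance(self, rng):
        S = np.cov(rng.standard_normal((50, 4)).T)
        om, ok, _ = support_constrained_mle(S, np.ones((4, 4), bool))
        assert ok
        np.testing.assert_allclose(om, np.linalg.inv(S), rtol=1e-3, atol=1e-6)

    def test_empty_support_gives_diagonal(self, rng):
        S = np.cov(rng.standard_normal((50, 4)).T)
        om, ok, _ = support_constrained_mle(S, np.zeros((4, 4), bool))
        assert ok
        np.testing.assert_allclose(om, np.diag(1.0 / np.diag(S)), rtol=1e-3)


class TestCvVote:
    def test_unanimous_edge_retained(self):
        sets = [frozenset({(0, 1)})] * 5
        assert (0, 1) in cv_vote(sets, 0.5)

    def test_minority_edge_dropped(self):
        sets = [frozenset({(0, 1)})] * 2 + [frozenset()] * 3
        assert (0, 1) not in cv_vote(sets, 0.5)

    def test_matches_counting_oracle(self, rng):
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        sets = [
            frozenset(p for p in pairs if rng.random() < 0.4) for _ in range(7)
        ]
        consensus = cv_vote(sets, 0.5)
        for p in pairs:
            count = sum(p in s for s in sets)
            assert (p in consensus) == (count > 3.5)

    def test_needs_two_folds(self):
        with pytest.raises(ValueError):
            cv_vote([frozenset()], 0.5)


@pytest.fixture(scope="module")
def static_small_fit():
    """CV fit on small static synthetic data, shared by selection tests."""
    spec = TVGGMSpec(
        n_genes=8,
        n_cells=2000,
        edge_density_per_phase=(0.15, 0.15, 0.15),
        partial_corr_strength=0.4,
        dropout_rate=0.0,
        shared_support=True,
        seed=2,
    )
    truth = make_precision_path(spec)
    expr, pt = sample_cells(truth, 2000, 0.0, seed=3)
    binned = bin_cells(expr, pt, 100)
    est = TimeVaryingGraphicalLasso(
        h_grid=(0.5, 1.5),
        d_grid=(0.0, 1.0),
        n_lambda=5,
        cv_folds=5,
        eval_times=np.linspace(0, 1, 10),
    )
    est.fit(binned)
    return truth, est


class TestCrossValidation:
    def test_single_point_grid_is_selected(self, rng):
        X = rng.normal(size=(40, 4))
        est = TimeVaryingGraphicalLasso(
            h_grid=(0.5,), d_grid=(0.0,), lambda_grid=[0.1], cv_folds=4,
            eval_times=np.linspace(0, 1, 5),
        )
        est.fit(X, pseudotime=np.linspace(0, 1, 40))
        assert all(p == (0.5, 0.0, 0.1) for p in est.selected_params_)

    def test_static_data_selection_is_time_stable(self, static_small_fit):
        truth, est = static_small_fit
        sets = est.edge_sets_
        true_edges = truth.true_edge_sets[0]
        # no spurious dynamics in the true support: every true edge is
        # recovered at every evaluation time
        for es in sets:
            assert true_edges <= es
        # and the sets themselves stay strongly overlapping over time
        jac = [
            len(sets[i] & sets[j]) / max(len(sets[i] | sets[j]), 1)
            for i in range(len(sets))
            for j in range(i + 1, len(sets))
        ]
        assert np.mean(jac) >= 0.5
        # the majority set over times is close to the truth
        counts = {}
        for es in sets:
            for e in es:
                counts[e] = counts.get(e, 0) + 1
        majority = {e for e, c in counts.items() if c > len(sets) / 2}
        tp = len(majority & true_edges)
        assert 2 * tp / (len(majority) + len(true_edges)) > 0.7

    def test_every_estimate_spd_with_called_edges(self, static_small_fit):
        _, est = static_small_fit
        for e in est.series_.estimates:
            assert np.linalg.eigvalsh(e.omega)[0] > 0
            p = e.omega.shape[0]
            off = np.abs(np.triu(e.omega, 1))
            called = {
                (est.series_.gene_names[i], est.series_.gene_names[j])
                for i, j in zip(*np.nonzero(off > 1e-6))
            }
            assert called == set(e.edge_set)

    def test_changing_support_favors_dynamic_model(self):
        # two-regime data: the best d > 0 CV score is no worse than d = 0
        rng = np.random.default_rng(8)
        p = 6
        om1 = np.eye(p); om1[0, 1] = om1[1, 0] = -0.45; om1[0, 0] = om1[1, 1] = 1.45
        om2 = np.eye(p); om2[2, 3] = om2[3, 2] = -0.45; om2[2, 2] = om2[3, 3] = 1.45
        n = 1500
        times = np.sort(rng.uniform(0, 1, n))
        X = np.empty((n, p))
        for i, t in enumerate(times):
            om = om1 if t < 0.5 else om2
            X[i] = rng.multivariate_normal(np.zeros(p), np.linalg.inv(om))
        binned = bin_cells(X, times, 100)
        est = TimeVaryingGraphicalLasso(
            h_grid=(0.3,), d_grid=(0.0, 0.2), n_lambda=4, cv_folds=5,
            eval_times=np.linspace(0, 1, 9),
        )
        est.cross_validate(binned)
        import pandas as pd

        table = pd.DataFrame(est.cv_table_)
        best = table.groupby("d")["cv_score"].min()
        assert best[0.2] <= best[0.0] + 1e-9


class TestSeriesContainer:
    def test_series_length_matches_eval_times(self, static_small_fit):
        _, est = static_small_fit
        assert len(est.series_) == 10

    def test_graphs_carry_all_genes(self, static_small_fit):
        _, est = static_small_fit
        for g in est.series_.to_graphs():
            assert g.number_of_nodes() == 8
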