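import numpy as np
import pytest

from asteria.design import DesignMatrix, expand_interactions
from asteria.hierlasso import ConvergenceError, HierarchicalLasso

from conftest import random_design
from reference_qp import reference_objective


def _model(n, q, seed, signal=None, noise=0.3):
    d = random_design(n, q, seed)
    idx = expand_interactions(d)
    rng = np.random.default_rng(seed + 1000)
    y = noise * rng.standard_normal(n)
    if signal is not None:
        y = y + idx.matrix() @ signal
    return HierarchicalLasso(y, idx), idx


class TestLambdaPath:
    def test_lambda_max_matches_direct_inner_product(self):
        d = DesignMatrix(
            np.array([[1], [0], [1], [0], [1], [0]]), list("abcdef"), ["A"]
        )
        idx = expand_interactions(d)
        x = idx.main_cols[:, 0].astype(float)
        y = 2.0 * x
        m = HierarchicalLasso(y, idx)
        xc, yc = x - x.mean(), y - y.mean()
        assert m.lambda_max() == pytest.approx(abs(xc @ yc), rel=1e-12)

    def test_grid_definition(self):
        m, _ = _model(12, 3, seed=1)
        lams = m.lambda_path(n_lambda=20, ratio=0.01)
        assert len(lams) == 20
        assert lams[0] == pytest.approx(m.lambda_max())
        assert lams[-1] == pytest.approx(0.01 * m.lambda_max())
        assert (np.diff(lams) < 0).all()

    def test_constant_response_is_an_error(self):
        d = random_design(10, 3, seed=2)
        m = HierarchicalLasso(np.ones(10), expand_interactions(d))
        with pytest.raises(ValueError, match="no variance"):
            m.lambda_path()

    def test_orthogonal_response_is_an_error(self):
        # y orthogonal to every centered column -> lambda_max = 0
        L = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        d = DesignMatrix(L, list("abcd"), ["A", "B"])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        m = HierarchicalLasso(y, expand_interactions(d))
        assert m.lambda_max() == pytest.approx(0.0, abs=1e-12)
        with pytest.raises(ValueError, match="no variance"):
            m.lambda_path()


class TestFit:
    def test_full_shrinkage_at_lambda_max(self):
        m, _ = _model(15, 3, seed=3, signal=None)
        res = m.fit(1.001 * m.lambda_max())
        assert (res.beta == 0).all()
        assert (res.theta == 0).all()
        assert res.beta0 == pytest.approx(m.endog.mean())
        assert res.active_set == []

    def test_soft_threshold_closed_form_single_column(self):
        # orthonormalised single main: beta = sign(z) * max(|z| - lam, 0)
        rng = np.random.default_rng(7)
        x = np.array([1, 0, 1, 1, 0, 0, 1, 0], dtype=float)
        d = DesignMatrix(x.reshape(-1, 1).astype(int), [f"r{i}" for i in range(8)], ["A"])
        idx = expand_interactions(d)
        y = 2.0 * x + 0.1 * rng.standard_normal(8)
        xc = x - x.mean()
        scale = np.linalg.norm(xc)
        # rescale so the centered column has unit norm: fit on y/scale alt.
        # exact closed form in the original scale: beta minimises
        # 0.5*||yc - xc*b||^2 + lam*|b| -> b = soft(xc@yc, lam)/||xc||^2
        m = HierarchicalLasso(y, idx)
        z = xc @ (y - y.mean())
        lam = 0.4 * abs(z)
        res = m.fit(lam, tol=1e-12, max_iter=20000)
        expected = np.sign(z) * max(abs(z) - lam, 0.0) / scale**2
        assert res.beta[0] == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_objective_matches_generic_convex_oracle(self, seed):
        m, idx = _model(12, 3, seed=seed, signal=None, noise=1.0)
        lam = 0.3 * m.lambda_max()
        res = m.fit(lam, tol=1e-11, max_iter=50000)
        ref = reference_objective(m.Xc, m.Zc, idx.pair_index, m.yc, lam)
        assert res.objective <= ref + 1e-5 * max(1.0, abs(ref))

    def test_determinism_byte_identical(self):
        m, _ = _model(20, 4, seed=5, signal=None, noise=0.5)
        lams = m.lambda_path(n_lambda=10)
        p1 = m.fit_path(lambdas=lams)
        p2 = m.fit_path(lambdas=lams)
        for a, b in zip(p1.results, p2.results):
            assert a.beta.tobytes() == b.beta.tobytes()
            assert a.theta.tobytes() == b.theta.tobytes()
        assert p1.entry_order == p2.entry_order

    def test_objective_trace_monotone_nonincreasing(self):
        m, _ = _model(20, 4, seed=6, noise=1.0)
        res = m.fit(0.1 * m.lambda_max(), debug=True)
        trace = res.objective_trace
        assert trace is not None and len(trace) == res.n_iter
        assert (np.diff(trace) <= 1e-12).all()

    def test_theta_exactly_symmetric(self):
        sig = np.zeros(4 + 6)
        sig[0] = 1.2
        sig[1] = 0.8
        sig[4] = 1.0  # first pair column
        m, _ = _model(25, 4, seed=8, signal=sig, noise=0.2)
        res = m.fit(0.05 * m.lambda_max())
        assert (res.theta == res.theta.T).all()
        assert (np.diag(res.theta) == 0).all()

    def test_nonconvergence_raises_with_diagnostics(self):
        m, _ = _model(20, 4, seed=9, noise=1.0)
        with pytest.raises(ConvergenceError) as exc:
            m.fit(0.05 * m.lambda_max(), max_iter=2)
        assert np.isfinite(exc.value.objective)


class TestPath:
    def test_strong_main_enters_first_majority_of_seeds(self):
        wins = 0
        for seed in range(10):
            sig = np.zeros(3 + 3)
            sig[1] = 2.0
            m, _ = _model(20, 3, seed=100 + seed, signal=sig, noise=0.2)
            path = m.fit_path(n_lambda=15)
            assert path.entry_order, "strong signal must enter"
            if path.entry_order[0][0] == "M2":
                wins += 1
        assert wins >= 6

    def test_path_starts_intercept_only_and_entry_unique(self):
        m, _ = _model(20, 4, seed=11, noise=1.0)
        path = m.fit_path(n_lambda=12)
        assert path.results[0].active_set == []
        labels = [lab for lab, _ in path.entry_order]
        assert len(labels) == len(set(labels))

    def test_warm_start_continuity(self):
        sig = np.zeros(4 + 6)
        sig[0] = 1.5
        m, _ = _model(25, 4, seed=12, signal=sig, noise=0.3)
        path = m.fit_path(n_lambda=20)
        for a, b in zip(path.results[:-1], path.results[1:]):
            step = np.linalg.norm(b.beta - a.beta) + np.linalg.norm(b.theta - a.theta)
            assert step < 5.0  # no wild jumps between adjacent grid points


class TestHierarchyEnforcement:
    def _results_with(self, beta, theta_entries, q=3):
        m, _ = _model(12, q, seed=13)
        res = m.fit(1.1 * m.lambda_max())
        res.beta = np.array(beta, dtype=float)
        th = np.zeros((q, q))
        for (j, k), v in theta_entries.items():
            th[j, k] = th[k, j] = v
        res.theta = th
        return res

    def test_orphan_interaction_cleared(self):
        res = self._results_with([0.0, 0.0, 0.0], {(0, 1): 0.3})
        out = res.enforce_hierarchy()
        assert out.theta[0, 1] == 0.0
        assert out.hierarchy_clean

    def test_single_zero_parent_also_clears(self):
        res = self._results_with([1.0, 0.0, 0.0], {(0, 1): 0.3})
        out = res.enforce_hierarchy()
        assert out.theta[0, 1] == 0.0

    def test_valid_interaction_untouched_and_all_zero_identity(self):
        res = self._results_with([1.0, -0.5, 0.0], {(0, 1): 0.3})
        out = res.enforce_hierarchy()
        assert out.theta[0, 1] == 0.3
        res0 = self._results_with([0.0, 0.0, 0.0], {})
        out0 = res0.enforce_hierarchy()
        assert (out0.theta == 0).all() and (out0.beta == 0).all()

    def test_hierarchy_holds_exhaustively_along_path(self):
        sig = np.zeros(4 + 6)
        sig[0], sig[2] = 1.0, -1.2
        sig[4] = 0.8
        m, idx = _model(25, 4, seed=14, signal=sig, noise=0.3)
        path = m.fit_path(n_lambda=15)
        for res in path.results:  # path results are hierarchy-enforced
            for j, k in idx.pair_index:
                if res.theta[j, k] != 0:
                    assert res.beta[j] != 0 and res.beta[k] != 0
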