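"""Axis construction: residualization, group ridge, expression, alignment."""

import numpy as np
import pytest

from neuraxes.axes import (alignment_axis, axis_expression, build_axes,
                           cross_task_correlation, group_ridge_fit,
                           residualize, _loo_residuals, _ridge_beta)


class TestResidualize:
    def test_residual_of_self_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.abs(residualize(y, y)).max() < 1e-12

    def test_orthogonal_covariate_leaves_demeaned_y(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        c = np.array([1.0, 1.0, -1.0, -1.0])
        assert np.allclose(residualize(y, c), y)

    def test_residual_orthogonal_to_covariate(self):
        rng = np.random.default_rng(0)
        y, c = rng.standard_normal(30), rng.standard_normal(30)
        r = residualize(y, c)
        assert abs(np.dot(r, c - c.mean())) < 1e-10

    def test_zero_variance_covariate_warns_and_demeans(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = residualize(y, np.full(3, 5.0))
        assert np.allclose(r, y - y.mean())


class TestGroupRidge:
    def test_single_group_fixed_penalty_equals_closed_form(self):
        rng = np.random.default_rng(1)
        n, p, lam = 25, 10, 5.0
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        ax = group_ridge_fit(X, y, np.array(["net"] * p), n_iter=0,
                             global_grid=[lam],
                             grid_range=(1.0, 1.0), n_grid=1)
        closed = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ y)
        assert np.abs(ax.beta - closed).max() < 1e-8
        assert ax.network_penalties["net"] == pytest.approx(lam)

    def test_vanishing_penalty_recovers_ols_when_p_below_n(self):
        rng = np.random.default_rng(2)
        n, p = 40, 8
        X = rng.standard_normal((n, p))
        y = X @ rng.standard_normal(p) + 0.1 * rng.standard_normal(n)
        ax = group_ridge_fit(X, y, np.array(["a"] * p), n_iter=0,
                             global_grid=[1e-8],
                             grid_range=(1.0, 1.0), n_grid=1)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.abs(ax.beta - ols).max() < 1e-6

    def test_infinite_penalty_shrinks_to_zero(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        ax = group_ridge_fit(X, y, np.array(["a"] * 6), n_iter=0,
                             global_grid=[1e12],
                             grid_range=(1.0, 1.0), n_grid=1)
        assert np.abs(ax.beta).max() < 1e-6
        assert ax.cv_r2 <= 0.0

    def test_loo_residuals_match_brute_force(self):
        rng = np.random.default_rng(4)
        n, p = 15, 25
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        pen = np.full(p, 3.0)
        loo = _loo_residuals(X, y, pen)
        brute = np.empty(n)
        for i in range(n):
            m = np.ones(n, bool)
            m[i] = False
            b = _ridge_beta(X[m], y[m], pen)
            brute[i] = y[i] - X[i] @ b
        assert np.abs(loo - brute).max() < 1e-10

    def test_null_signal_gives_nonpositive_cv_r2(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 40))
        y = rng.standard_normal(30)
        groups = np.repeat(["a", "b", "c", "d"], 10)
        ax = group_ridge_fit(X, y, groups)
        assert ax.cv_r2 < 0.1

    def test_signal_network_gets_smallest_penalty_and_top_roi(self):
        """Planted signal in one network: its multiplier is smallest and
        the top-|beta| ROI is the planted one in >= 90% of 50 replicates."""
        hits_pen, hits_top = 0, 0
        n, p = 40, 40
        groups = np.repeat(["a", "b", "c", "d"], 10)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((n, p))
            y = 1.0 * X[:, 3] + 0.3 * rng.standard_normal(n)
            ax = group_ridge_fit(X, y, groups, n_iter=4)
            pens = ax.network_penalties
            hits_pen += pens["a"] == min(pens.values())
            hits_top += np.argmax(np.abs(ax.beta)) == 3
        assert hits_pen >= 45
        assert hits_top >= 45


class TestBuildAxes:
    def _cohort(self, rng, effect=0.8, n=36, p=24):
        groups = np.repeat(["w", "x", "y", "z"], p // 4)
        explicit = rng.standard_normal(n)
        implicit = rng.standard_normal(n)
        error = rng.standard_normal(n)
        X = 0.3 * rng.standard_normal((n, p))
        X[:, 0] += effect * explicit       # network w
        X[:, 6] += effect * implicit       # network x
        X[:, 12] += effect * (-error)      # network y
        behavior = {"explicit": explicit, "implicit": implicit,
                    "early_error": error}
        return X, behavior, groups

    def test_null_cohort_axes_have_low_cv_r2(self):
        rng = np.random.default_rng(6)
        X, behavior, groups = self._cohort(rng, effect=0.0)
        axes = build_axes(X, behavior, groups, n_iter=3)
        for ax in axes.values():
            assert ax.cv_r2 <= 0.1

    def test_each_axis_top_roi_in_its_planted_set(self):
        rng = np.random.default_rng(7)
        X, behavior, groups = self._cohort(rng)
        axes = build_axes(X, behavior, groups, n_iter=3)
        assert np.argmax(np.abs(axes["explicit"].beta)) == 0
        assert np.argmax(np.abs(axes["implicit"].beta)) == 6
        assert np.argmax(np.abs(axes["performance"].beta)) == 12

    def test_explicit_only_effect_is_specific(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n, p = 36, 24
            groups = np.repeat(["w", "x", "y", "z"], 6)
            explicit = rng.standard_normal(n)
            behavior = {"explicit": explicit,
                        "implicit": rng.standard_normal(n),
                        "early_error": rng.standard_normal(n)}
            X = 0.3 * rng.standard_normal((n, p))
            X[:, 0] += 0.8 * explicit
            axes = build_axes(X, behavior, groups, n_iter=3)
            hits += (axes["explicit"].cv_r2 > axes["implicit"].cv_r2
                     and axes["explicit"].cv_r2 > axes["performance"].cv_r2)
        assert hits >= 18

    def test_missing_behavior_drops_subject(self):
        rng = np.random.default_rng(8)
        X, behavior, groups = self._cohort(rng)
        behavior["explicit"] = np.array(behavior["explicit"])
        behavior["explicit"][0] = np.nan
        with pytest.warns(UserWarning, match="dropping 1 subject"):
            axes = build_axes(X, behavior, groups, n_iter=2)
        assert "explicit" in axes


class TestExpressionAndAlignment:
    def test_expression_of_own_beta_is_one(self):
        rng = np.random.default_rng(9)
        from neuraxes.axes import AxisMap
        beta = rng.standard_normal(20)
        ax = AxisMap(beta, list(range(20)), np.array(["a"] * 20), {}, 0.5)
        assert axis_expression(ax, beta).value == pytest.approx(1.0)
        assert axis_expression(ax, -beta).value == pytest.approx(-1.0)

    def test_expression_affine_invariance(self):
        rng = np.random.default_rng(10)
        from neuraxes.axes import AxisMap
        beta = rng.standard_normal(30)
        conn = rng.standard_normal(30)
        ax = AxisMap(beta, list(range(30)), np.array(["a"] * 30), {}, 0.5)
        r1 = axis_expression(ax, conn).value
        r2 = axis_expression(ax, 3.0 * conn + 7.0).value
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_independent_vectors_rarely_correlate(self):
        rng = np.random.default_rng(11)
        from neuraxes.axes import AxisMap
        p, hits, draws = 100, 0, 400
        beta = rng.standard_normal(p)
        ax = AxisMap(beta, list(range(p)), np.array(["a"] * p), {}, 0.5)
        for _ in range(draws):
            hits += abs(axis_expression(ax, rng.standard_normal(p)).value) < 0.3
        assert hits >= 0.93 * draws

    def test_alignment_identical_betas_is_zero(self):
        from neuraxes.axes import AxisMap
        beta = np.array([0.1, 0.5, -0.2, 0.3])
        a = AxisMap(beta, list(range(4)), np.array(["a"] * 4), {}, 0.5)
        b = AxisMap(beta.copy(), list(range(4)), np.array(["a"] * 4), {}, 0.5)
        assert np.all(alignment_axis(a, b) == 0)

    def test_alignment_reversed_order_spans_extremes(self):
        from neuraxes.axes import AxisMap
        p = 7
        beta = np.arange(p, dtype=float)
        a = AxisMap(beta, list(range(p)), np.array(["a"] * p), {}, 0.5)
        b = AxisMap(beta[::-1].copy(), list(range(p)), np.array(["a"] * p),
                    {}, 0.5)
        d = alignment_axis(a, b)
        assert d.min() == -(p - 1) and d.max() == (p - 1)

    def test_alignment_all_ties_use_average_ranks(self):
        from neuraxes.axes import AxisMap
        p = 5
        a = AxisMap(np.arange(p, dtype=float), list(range(p)),
                    np.array(["a"] * p), {}, 0.5)
        b = AxisMap(np.zeros(p), list(range(p)), np.array(["a"] * p), {}, 0.5)
        d = alignment_axis(a, b)
        assert np.allclose(d, np.arange(1, p + 1) - (p + 1) / 2)


class TestCrossTaskCorrelation:
    def test_perfect_linear_pair(self):
        x = np.arange(10, dtype=float)
        r, t, p = cross_task_correlation(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(0.0)

    def test_t_and_p_at_r_034_n_36(self):
        # construct two vectors with exact correlation 0.34
        rng = np.random.default_rng(12)
        n, r_target = 36, 0.34
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e -= x * np.dot(x, e) / np.dot(x, x)
        e /= e.std()
        y = r_target * x + np.sqrt(1 - r_target**2) * e
        r, t, p = cross_task_correlation(x, y)
        assert r == pytest.approx(0.34, abs=1e-12)
        assert t == pytest.approx(2.108, abs=0.005)
        assert p == pytest.approx(0.0424, abs=0.002)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cross_task_correlation(np.ones(8), np.arange(8.0))
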