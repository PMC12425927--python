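"""Meta-regression, model selection, quadratic summaries, Mantel tests,
and tree-ensemble moderator importance."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from soymeta.effect_sizes import EffectSize
from soymeta.moderator_analysis import (RegressionFit, mantel, meta_regression,
                                        moderator_importance, partial_mantel,
                                        quadratic_summary, select_model)


def _eff(values, variances=None, trait="yield"):
    if variances is None:
        variances = [1e-4] * len(values)
    return [EffectSize(f"o{i}", f"s{i}", trait, float(y), float(v))
            for i, (y, v) in enumerate(zip(values, variances))]


class TestMetaRegression:
    def test_noise_free_linear_interpolation(self):
        x = np.linspace(0, 1, 8)
        fit = meta_regression(_eff(2 * x + 1), x, "linear", tau2=0.0)
        assert fit.coef == pytest.approx([1.0, 2.0], abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_noise_free_quadratic_vertex_recovery(self):
        x = np.linspace(0, 0.5, 9)
        y = -((x - 0.212) ** 2) + 0.04
        fit = meta_regression(_eff(y), x, "quadratic", tau2=0.0)
        assert fit.coef[2] == pytest.approx(-1.0, abs=1e-8)
        assert quadratic_summary(fit).vertex_x == pytest.approx(0.212, abs=1e-8)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(44)
        x = rng.uniform(0, 2, size=30)
        v = rng.uniform(0.01, 0.1, size=30)
        y = 0.3 - 0.5 * x + rng.normal(0, 0.1, size=30)
        tau2 = 0.02
        fit = meta_regression(_eff(y, v), x, "linear", tau2=tau2)
        W = np.diag(1.0 / (v + tau2))
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        assert fit.coef == pytest.approx(beta, abs=1e-10)
        assert fit.cov == pytest.approx(np.linalg.inv(X.T @ W @ X), abs=1e-10)

    def test_missing_moderator_rows_dropped(self):
        x = [0.0, 1.0, 2.0, math.nan, 3.0, 4.0]
        fit = meta_regression(_eff(np.arange(6.0)), x, "linear", tau2=0.0)
        assert fit.k == 5

    def test_rank_deficient_design_errors(self):
        with pytest.raises(ValueError, match="rank"):
            meta_regression(_eff([0.1, 0.2, 0.3, 0.4, 0.5]), [1.0] * 5, "quadratic", tau2=0.0)

    def test_quadratic_r2_at_least_linear(self):
        rng = np.random.default_rng(46)
        x = rng.uniform(0, 1, size=40)
        y = 0.2 * x + rng.normal(0, 0.1, size=40)
        v = rng.uniform(0.005, 0.05, size=40)
        lin = meta_regression(_eff(y, v), x, "linear", tau2=0.01)
        quad = meta_regression(_eff(y, v), x, "quadratic", tau2=0.01)
        assert quad.r2 >= lin.r2 - 1e-12


class TestSelectModel:
    @staticmethod
    def _fit(form, aic, bic, ncoef=2, k=10):
        return RegressionFit(form, np.zeros(ncoef), np.eye(ncoef), 0.5, 0.1,
                             aic, bic, k, 0.01)

    def test_lowest_aic_wins(self):
        assert select_model([self._fit("linear", 10, 12),
                             self._fit("quadratic", 11, 11, 3)]).form == "linear"

    def test_aic_tie_broken_by_bic(self):
        assert select_model([self._fit("linear", 10, 13),
                             self._fit("quadratic", 10, 12, 3)]).form == "quadratic"

    def test_full_tie_prefers_fewer_parameters(self):
        assert select_model([self._fit("quadratic", 10, 12, 3),
                             self._fit("linear", 10, 12, 2)]).form == "linear"

    def test_single_candidate_returned(self):
        fit = self._fit("linear", 3, 4)
        assert select_model([fit]) is fit

    def test_mismatched_k_errors(self):
        with pytest.raises(ValueError, match="different data"):
            select_model([self._fit("linear", 1, 2, k=10),
                          self._fit("quadratic", 2, 3, 3, k=12)])

    def test_linear_truth_selects_linear_at_theoretical_rate(self):
        """Under a true linear model the AIC rule keeps the linear form at
        close to the theoretical P(chi2_1 < 2) ~ 0.84 rate, and the choice
        always equals the direct argmin-AIC oracle."""
        rng = np.random.default_rng(48)
        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            x = rng.uniform(0, 1, size=25)
            v = np.full(25, 0.01)
            y = 0.1 + 0.4 * x + rng.normal(0, np.sqrt(v))
            fits = [meta_regression(_eff(y, v), x, form, tau2=0.0)
                    for form in ("linear", "quadratic")]
            chosen = select_model(fits)
            assert chosen.form == min(fits, key=lambda f: f.aic).form
            wins += chosen.form == "linear"
        assert wins >= 0.75 * n_rep


class TestQuadraticSummary:
    def test_vertex_from_printed_coefficients(self):
        fit = RegressionFit("quadratic", np.array([0.01, 0.424, -1.0]),
                            np.eye(3), 0, 0, 0, 0, 10, 0)
        assert quadratic_summary(fit).vertex_x == pytest.approx(0.212)

    def test_negative_discriminant_concave(self):
        fit = RegressionFit("quadratic", np.array([-1.0, 0.0, -1.0]),
                            np.eye(3), 0, 0, 0, 0, 10, 0)
        s = quadratic_summary(fit)
        assert s.roots == () and s.positive_interval is None and s.vertex_y < 0

    def test_random_concave_roots_match_bisection(self):
        rng = np.random.default_rng(50)
        for _ in range(20):
            b2 = -float(rng.uniform(0.5, 3))
            vx = float(rng.uniform(-2, 2))
            vy = float(rng.uniform(0.1, 2))
            # construct y = b2 (x - vx)^2 + vy: concave with two real roots
            coef = np.array([b2 * vx ** 2 + vy, -2 * b2 * vx, b2])
            fit = RegressionFit("quadratic", coef, np.eye(3), 0, 0, 0, 0, 10, 0)
            s = quadratic_summary(fit)
            poly = lambda x: coef[0] + coef[1] * x + coef[2] * x ** 2
            half = math.sqrt(vy / -b2) + 1.0
            lo = optimize.bisect(poly, vx - half, vx, xtol=1e-12)
            hi = optimize.bisect(poly, vx, vx + half, xtol=1e-12)
            assert s.roots[0] == pytest.approx(lo, abs=1e-9)
            assert s.roots[1] == pytest.approx(hi, abs=1e-9)
            assert s.positive_interval == pytest.approx((lo, hi), abs=1e-9)

    def test_vertex_is_argmax_for_concave(self):
        fit = RegressionFit("quadratic", np.array([0.0, 0.424, -1.0]),
                            np.eye(3), 0, 0, 0, 0, 10, 0)
        s = quadratic_summary(fit)
        poly = lambda x: 0.424 * x - x ** 2
        for eps in (1e-3, 0.1):
            assert poly(s.vertex_x) >= poly(s.vertex_x + eps)
            assert poly(s.vertex_x) >= poly(s.vertex_x - eps)

    def test_zero_curvature_errors(self):
        fit = RegressionFit("quadratic", np.array([0.0, 1.0, 0.0]),
                            np.eye(3), 0, 0, 0, 0, 10, 0)
        with pytest.raises(ValueError, match="linear"):
            quadratic_summary(fit)


def _random_distance(rng, n):
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return d


class TestMantel:
    def test_self_correlation_is_one(self):
        d = _random_distance(np.random.default_rng(52), 6)
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_exhaustive_p_matches_brute_force(self):
        rng = np.random.default_rng(53)
        a, b = _random_distance(rng, 5), _random_distance(rng, 5)
        r, p = mantel(a, b, n_perm=9999, seed=0)
        tri = np.tril_indices(5, k=-1)
        r_obs = np.corrcoef(a[tri], b[tri])[0, 1]
        count = total = 0
        for perm in itertools.permutations(range(5)):
            bp = b[np.ix_(perm, perm)]
            count += np.corrcoef(a[tri], bp[tri])[0, 1] >= r_obs - 1e-12
            total += 1
        assert r == pytest.approx(r_obs, abs=1e-12)
        assert p == pytest.approx(count / total, abs=1e-12)

    def test_r_matches_skbio(self):
        rng = np.random.default_rng(54)
        a, b = _random_distance(rng, 8), _random_distance(rng, 8)
        r, p = mantel(a, b, n_perm=999, seed=1)
        r_sk, p_sk, _ = skbio_mantel(DistanceMatrix(a), DistanceMatrix(b),
                                     method="pearson", permutations=999,
                                     alternative="greater")
        assert r == pytest.approx(r_sk, abs=1e-10)
        assert p == pytest.approx(p_sk, abs=0.1)  # both permutation estimates

    def test_invariant_under_monotone_linear_transform(self):
        rng = np.random.default_rng(56)
        a, b = _random_distance(rng, 7), _random_distance(rng, 7)
        r1, _ = mantel(a, b, n_perm=99, seed=2)
        r2, _ = mantel(a, 3.0 * b + 1.0 - np.diag(np.ones(7)), n_perm=99, seed=2)
        # keep zero diagonal after affine shift
        b2 = 3.0 * b
        r2, _ = mantel(a, b2, n_perm=99, seed=2)
        assert r2 == pytest.approx(r1, abs=1e-12)

    def test_dimension_mismatch_and_constant_errors(self):
        rng = np.random.default_rng(57)
        a = _random_distance(rng, 5)
        with pytest.raises(ValueError):
            mantel(a, _random_distance(rng, 6))
        const = np.ones((5, 5)) - np.eye(5)
        with pytest.raises(ValueError, match="constant"):
            mantel(a, const, n_perm=9)


class TestPartialMantel:
    def test_controlling_for_copy_gives_zero(self):
        rng = np.random.default_rng(58)
        a, b = _random_distance(rng, 7), _random_distance(rng, 7)
        r, _ = partial_mantel(a, b, b, n_perm=99, seed=3)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_control_preserves_r(self):
        rng = np.random.default_rng(59)
        n = 30
        a = _random_distance(rng, n)
        b = a + _random_distance(rng, n) * 0.5
        c = _random_distance(rng, n)
        r_simple, _ = mantel(a, b, n_perm=9, seed=4)
        r_partial, _ = partial_mantel(a, b, c, n_perm=9, seed=4)
        assert r_partial == pytest.approx(r_simple, abs=0.1)

    def test_matches_residual_correlation_oracle(self):
        rng = np.random.default_rng(61)
        a, b, c = (_random_distance(rng, 6) for _ in range(3))
        r, _ = partial_mantel(a, b, c, n_perm=9, seed=5)
        tri = np.tril_indices(6, k=-1)
        ta, tb, tc = a[tri], b[tri], c[tri]

        def resid(x, z):
            slope, intercept = np.polyfit(z, x, 1)
            return x - (slope * z + intercept)

        oracle = np.corrcoef(resid(ta, tc), resid(tb, tc))[0, 1]
        assert r == pytest.approx(oracle, abs=1e-10)


class TestModeratorImportance:
    @staticmethod
    def _frame(rng, n=80, signal=True):
        a = rng.uniform(0, 1, size=n)
        b = rng.uniform(0, 1, size=n)
        c = rng.uniform(0, 1, size=n)
        y = (2.0 * a if signal else np.zeros(n)) + rng.normal(0, 0.05, size=n)
        return pd.DataFrame({"lnrr": y, "A": a, "B": b, "C": c})

    def test_planted_signal_ranks_first(self):
        rng = np.random.default_rng(62)
        wins = 0
        n_rep = 20
        for rep in range(n_rep):
            ranked = moderator_importance(self._frame(rng), "lnrr", ["A", "B", "C"],
                                          seed=rep, n_estimators=60)
            wins += ranked[0][0] == "A"
        assert wins >= 0.9 * n_rep

    def test_pure_noise_gives_small_importances(self):
        rng = np.random.default_rng(63)
        ranked = moderator_importance(self._frame(rng, signal=False), "lnrr",
                                      ["A", "B", "C"], seed=0, n_estimators=60)
        # permutation importance of irrelevant predictors hovers near zero
        assert all(abs(imp) < 0.01 for _, imp in ranked)

    def test_single_predictor_trivially_first(self):
        rng = np.random.default_rng(64)
        ranked = moderator_importance(self._frame(rng), "lnrr", ["A"], seed=0,
                                      n_estimators=30)
        assert ranked[0][0] == "A" and len(ranked) == 1

    def test_all_missing_predictor_dropped(self, caplog):
        rng = np.random.default_rng(65)
        frame = self._frame(rng)
        frame["D"] = np.nan
        with caplog.at_level("WARNING"):
            ranked = moderator_importance(frame, "lnrr", ["A", "B", "C", "D"],
                                          seed=0, n_estimators=30)
        assert "D" not in [name for name, _ in ranked]

    def test_too_few_rows_errors(self):
        rng = np.random.default_rng(66)
        with pytest.raises(ValueError, match="20"):
            moderator_importance(self._frame(rng, n=10), "lnrr", ["A", "B"], seed=0)
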