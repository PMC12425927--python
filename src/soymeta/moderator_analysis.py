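"""Continuous-moderator meta-regression, quadratic dose-response
summaries, Mantel tests, and tree-ensemble moderator importance.

Meta-regression is weighted least squares on lnRR with weights
1/(v_i + tau2), the total heterogeneity tau2 taken from a preliminary
intercept-only multilevel fit and held fixed across candidate forms so
that AIC/BIC comparisons share one weighting.  Candidate forms are linear
and quadratic; the lower-AIC model is selected (ties broken by BIC, then
parsimony).  Concave quadratic fits are summarized by their turning point
and the interval where the fitted lnRR is positive — e.g. the nitrogen
rate beyond which diversity declines, or the Shannon-response range in
which intercropped yield beats monoculture.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance
from sklearn.model_selection import train_test_split

from .effect_sizes import EffectSize
from .meta_model import fit_multilevel_re

logger = logging.getLogger(__name__)

FORMS = ("linear", "quadratic")


@dataclass
class RegressionFit:
    form: str
    coef: np.ndarray        # (intercept, b1[, b2])
    cov: np.ndarray
    r2: float               # weighted R^2
    p_model: float          # Wald chi-square on the slope coefficients
    aic: float
    bic: float
    k: int
    tau2: float             # heterogeneity added to the weights


@dataclass(frozen=True)
class QuadraticSummary:
    vertex_x: float
    vertex_y: float
    roots: tuple[float, ...]                 # real roots of fitted value = 0
    positive_interval: tuple[float, float] | None  # open interval with fitted lnRR > 0


def _design(x: np.ndarray, form: str) -> np.ndarray:
    if form == "linear":
        return np.column_stack([np.ones_like(x), x])
    if form == "quadratic":
        return np.column_stack([np.ones_like(x), x, x ** 2])
    raise ValueError(f"unknown form {form!r}; expected one of {FORMS}")


def meta_regression(effects: Sequence[EffectSize], x: Sequence[float], form: str,
                    tau2: float | None = None) -> RegressionFit:
    """Variance-weighted regression of lnRR on a continuous moderator.

    Rows with missing x are dropped (count logged).  When ``tau2`` is not
    given it is estimated once from an intercept-only multilevel fit
    (study plus observation components summed).
    """
    if len(x) != len(effects):
        raise ValueError("x must align with effects")
    x_arr = np.asarray(x, dtype=float)
    keep = np.isfinite(x_arr)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("meta_regression: dropped %d row(s) with missing moderator", dropped)
    effects = [e for e, m in zip(effects, keep) if m]
    x_arr = x_arr[keep]

    if tau2 is None:
        overall = fit_multilevel_re(effects)
        tau2 = overall.tau2_study + overall.tau2_obs

    y = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])
    X = _design(x_arr, form)
    k, p = X.shape
    if k < p + 1:
        raise ValueError(f"need at least {p + 1} observations for a {form} fit, got {k}")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError(f"rank-deficient design for {form} fit (constant moderator?)")

    w = 1.0 / (v + tau2)
    XtW = X.T * w
    cov = np.linalg.inv(XtW @ X)     # known-variance convention: no residual rescaling
    beta = cov @ (XtW @ y)
    resid = y - X @ beta

    ybar_w = float(np.sum(w * y) / np.sum(w))
    rss = float(np.sum(w * resid ** 2))
    tss = float(np.sum(w * (y - ybar_w) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0

    slopes = beta[1:]
    cov_ss = cov[1:, 1:]
    chi2 = float(slopes @ np.linalg.solve(cov_ss, slopes))
    p_model = float(stats.chi2.sf(chi2, p - 1))

    # Gaussian likelihood with known per-row variances 1/w
    ll = float(-0.5 * np.sum(np.log(2 * math.pi / w) + w * resid ** 2))
    return RegressionFit(
        form=form, coef=beta, cov=cov, r2=r2, p_model=p_model,
        aic=-2 * ll + 2 * p, bic=-2 * ll + p * math.log(k), k=k, tau2=float(tau2),
    )


def select_model(fits: Sequence[RegressionFit]) -> RegressionFit:
    """Pick the candidate with lowest AIC; ties by BIC, then fewer parameters."""
    if not fits:
        raise ValueError("no candidate fits")
    ks = {f.k for f in fits}
    if len(ks) != 1:
        raise ValueError(f"candidates fitted on different data (k = {sorted(ks)})")
    return min(fits, key=lambda f: (f.aic, f.bic, len(f.coef)))


def quadratic_summary(fit: RegressionFit) -> QuadraticSummary:
    """Turning point, real roots, and the interval of positive fitted lnRR."""
    if fit.form != "quadratic":
        raise ValueError("quadratic_summary requires a quadratic fit")
    c0, b1, b2 = (float(c) for c in fit.coef)
    if b2 == 0.0:
        raise ValueError("b2 = 0: use the linear form")
    vx = -b1 / (2 * b2)
    vy = c0 + b1 * vx + b2 * vx ** 2
    disc = b1 ** 2 - 4 * b2 * c0
    if disc > 0:
        r1 = (-b1 - math.sqrt(disc)) / (2 * b2)
        r2 = (-b1 + math.sqrt(disc)) / (2 * b2)
        roots: tuple[float, ...] = tuple(sorted((r1, r2)))
    elif disc == 0:
        roots = (vx,)
    else:
        roots = ()

    positive: tuple[float, float] | None
    if b2 < 0:
        positive = (roots[0], roots[1]) if len(roots) == 2 else None
    else:  # convex: positive region is unbounded, not a single finite interval
        positive = (-math.inf, math.inf) if not roots and vy > 0 else None
    return QuadraticSummary(vertex_x=vx, vertex_y=vy, roots=roots, positive_interval=positive)


def _check_distance_matrix(d: np.ndarray, name: str) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"{name} must be square")
    if d.shape[0] < 4:
        raise ValueError(f"{name} must have dimension >= 4")
    if not np.allclose(d, d.T):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(d), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    return d


def _tri(d: np.ndarray) -> np.ndarray:
    return d[np.tril_indices(d.shape[0], k=-1)]


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant distance triangle: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(dist_a: np.ndarray, dist_b: np.ndarray, n_perm: int = 9999,
           seed: int = 0) -> tuple[float, float]:
    """Mantel test: Pearson correlation of lower triangles with a
    one-sided (greater) permutation p.

    When n! does not exceed the permutation budget the null is
    enumerated exhaustively and the p-value is exact; otherwise
    ``n_perm`` seeded random relabelings are drawn and the add-one
    estimator keeps p strictly positive."""
    a = _check_distance_matrix(dist_a, "dist_a")
    b = _check_distance_matrix(dist_b, "dist_b")
    if a.shape != b.shape:
        raise ValueError("distance matrices must have the same dimension")
    tri_a = _tri(a)
    r_obs = _pearson(tri_a, _tri(b))
    n = a.shape[0]
    if math.factorial(n) <= max(n_perm, 720):
        # exact null: enumerate every relabeling (identity included)
        count = total = 0
        for perm in itertools.permutations(range(n)):
            r_perm = _pearson(tri_a, _tri(b[np.ix_(perm, perm)]))
            count += r_perm >= r_obs - 1e-12
            total += 1
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pearson(tri_a, _tri(b[np.ix_(perm, perm)]))
        if r_perm >= r_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r_obs, p


def partial_mantel(dist_a: np.ndarray, dist_b: np.ndarray, dist_c: np.ndarray,
                   n_perm: int = 9999, seed: int = 0) -> tuple[float, float]:
    """Partial Mantel: correlation of a and b triangles controlling for c.

    Both triangles are residualized on the c triangle; permutations
    relabel b jointly before residualizing, with the add-one estimator.
    """
    a = _check_distance_matrix(dist_a, "dist_a")
    b = _check_distance_matrix(dist_b, "dist_b")
    c = _check_distance_matrix(dist_c, "dist_c")
    if not (a.shape == b.shape == c.shape):
        raise ValueError("distance matrices must have the same dimension")
    ta, tc = _tri(a), _tri(c)

    def residual(x: np.ndarray, z: np.ndarray) -> np.ndarray:
        zc = z - z.mean()
        denom = float(zc @ zc)
        slope = float(zc @ (x - x.mean())) / denom if denom > 0 else 0.0
        return x - x.mean() - slope * zc

    def safe_corr(x: np.ndarray, z: np.ndarray) -> float:
        # a residual can collapse to zero (b fully explained by c): partial r = 0
        if float(np.std(x)) < 1e-14 or float(np.std(z)) < 1e-14:
            return 0.0
        return float(np.corrcoef(x, z)[0, 1])

    ra = residual(ta, tc)
    r_obs = safe_corr(ra, residual(_tri(b), tc))
    rng = np.random.default_rng(seed)
    n = a.shape[0]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        rb = residual(_tri(b[np.ix_(perm, perm)]), tc)
        if safe_corr(ra, rb) >= r_obs - 1e-12:
            count += 1
    return r_obs, (1 + count) / (1 + n_perm)


def moderator_importance(frame, response: str, predictors: Sequence[str], seed: int,
                         n_estimators: int = 200, n_repeats: int = 10,
                         test_size: float = 0.3) -> list[tuple[str, float]]:
    """Rank moderators by out-of-sample permutation importance.

    A random-forest regressor of the lnRR response on the predictors is
    trained on 70% of the complete rows; importance is the mean increase
    in held-out squared error over ``n_repeats`` seeded column
    permutations.  Predictors with no observed values are dropped with a
    warning.  Returns (predictor, importance) sorted descending.
    """
    if len(predictors) < 1:
        raise ValueError("need at least 1 predictor")
    usable = []
    for name in predictors:
        if frame[name].notna().any():
            usable.append(name)
        else:
            logger.warning("moderator_importance: predictor %r is all-missing; dropped", name)
    data = frame[[response, *usable]].dropna()
    if len(data) < 20:
        raise ValueError(f"need >= 20 complete rows, got {len(data)}")
    X = data[usable].to_numpy(dtype=float)
    y = data[response].to_numpy(dtype=float)
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=test_size, random_state=seed)
    model = RandomForestRegressor(n_estimators=n_estimators, random_state=seed)
    model.fit(X_tr, y_tr)
    result = permutation_importance(model, X_te, y_te, n_repeats=n_repeats,
                                    random_state=seed, scoring="neg_mean_squared_error")
    ranked = sorted(zip(usable, result.importances_mean), key=lambda t: -t[1])
    return [(name, float(imp)) for name, imp in ranked]
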