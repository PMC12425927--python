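"""Multilevel random-effects pooling of lnRR effect sizes.

Observations are nested within articles, so the pooling model carries two
random layers above the known sampling error:

    y_ij = mu + b_i + u_ij + e_ij
    b_i  ~ N(0, tau2_study)     article-level heterogeneity
    u_ij ~ N(0, tau2_obs)       residual observation-level heterogeneity
    e_ij ~ N(0, v_ij)           known sampling variance of lnRR

Variance components are estimated by REML via Fisher scoring with
non-negativity enforced by projection; fixed effects by GLS at the
converged components.  Inference is Wald (z): the 95% CI is
mu +/- 1.96 se and an effect is significant when the CI excludes zero.

Subgroup (moderator) analysis replaces the single intercept by level
dummies and tests level-mean equality with an omnibus Wald chi-square
(Q_M, df = levels - 1), followed by single-step max-|z| adjusted pairwise
comparisons (Tukey-style, Monte-Carlo approximated).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_sizes import EffectSize

logger = logging.getLogger(__name__)

Z_95 = 1.96  # Wald 95% critical value, fixed by convention

REML_TOL = 1e-8
REML_MAX_ITER = 200


class ConvergenceError(RuntimeError):
    """REML failed to converge; carries the last iterate and gradient norm."""

    def __init__(self, message: str, tau2: tuple[float, float], grad_norm: float):
        super().__init__(f"{message} (last tau2={tau2}, |grad|={grad_norm:.3e})")
        self.tau2 = tau2
        self.grad_norm = grad_norm


@dataclass
class MetaEstimate:
    """Pooled effect with Wald inference and variance components."""

    mu: float
    se: float
    ci_low: float
    ci_high: float
    tau2_study: float
    tau2_obs: float
    k: int
    n_studies: int
    z: float
    p: float
    q_total: float


@dataclass
class SubgroupResult:
    """Per-level pooled effects plus the Q_M omnibus test."""

    moderator: str
    levels: list[str]
    estimates: dict[str, MetaEstimate]
    qm: float
    df: int
    p_qm: float
    pairwise: list[tuple[str, str, float, float]] = field(default_factory=list)
    # internals needed by the post hoc step
    _coef: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    _cov: np.ndarray = field(default=None, repr=False)   # type: ignore[assignment]


def _build_cov(v: np.ndarray, study_idx: list[np.ndarray],
               tau2_study: float, tau2_obs: float) -> np.ndarray:
    V = np.diag(v + tau2_obs)
    for idx in study_idx:
        V[np.ix_(idx, idx)] += tau2_study
    return V


def _restricted_ll(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Restricted log-likelihood (constant dropped) plus GLS pieces."""
    Vinv = np.linalg.inv(V)
    XtWX = X.T @ Vinv @ X
    C = np.linalg.inv(XtWX)
    beta = C @ (X.T @ (Vinv @ y))
    r = y - X @ beta
    sign1, logdet_v = np.linalg.slogdet(V)
    sign2, logdet_x = np.linalg.slogdet(XtWX)
    if sign1 <= 0 or sign2 <= 0:
        raise np.linalg.LinAlgError("non-PD covariance in REML")
    ll = -0.5 * (logdet_v + logdet_x + float(r @ Vinv @ r))
    return ll, beta, C


def _reml_fit(y: np.ndarray, v: np.ndarray, studies: Sequence[str], X: np.ndarray,
              *, fix_tau2_study: float | None = None, fix_tau2_obs: float | None = None,
              tol: float = REML_TOL, max_iter: int = REML_MAX_ITER):
    """Fisher-scoring REML for (tau2_study, tau2_obs) with projection to >= 0.

    Returns (beta, cov_beta, tau2_study, tau2_obs).  With one observation
    per study the two components are confounded (the study and residual
    design matrices coincide), so the study component is pinned at zero
    and all heterogeneity loads on tau2_obs.
    """
    k = len(y)
    labels = sorted(set(studies))
    study_idx = [np.flatnonzero(np.asarray(studies, dtype=object) == s) for s in labels]

    singleton = all(len(idx) == 1 for idx in study_idx)
    if singleton and fix_tau2_study is None:
        fix_tau2_study = 0.0

    free = [name for name, fx in (("study", fix_tau2_study), ("obs", fix_tau2_obs)) if fx is None]
    tau2 = {
        "study": fix_tau2_study if fix_tau2_study is not None else 0.0,
        "obs": fix_tau2_obs if fix_tau2_obs is not None else 0.0,
    }
    if free:
        # moment-style start: spread the DerSimonian-Laird total evenly
        w = 1.0 / v
        mu_fe = float(np.sum(w * y) / np.sum(w))
        q = float(np.sum(w * (y - mu_fe) ** 2))
        c = float(np.sum(w) - np.sum(w ** 2) / np.sum(w))
        p = X.shape[1]
        tau2_dl = max((q - (k - p)) / c, 0.0) if c > 0 else 0.0
        start = max(tau2_dl / len(free), 1e-4)
        for name in free:
            tau2[name] = start

    V = _build_cov(v, study_idx, tau2["study"], tau2["obs"])
    ll, beta, C = _restricted_ll(y, X, V)
    grad_norm = math.inf

    for _ in range(max_iter):
        if not free:
            break
        Vinv = np.linalg.inv(V)
        WX = Vinv @ X
        P = Vinv - WX @ np.linalg.solve(X.T @ WX, WX.T)
        Py = P @ y

        # derivative matrices of V w.r.t. each free component
        Gs: list[np.ndarray] = []
        for name in free:
            if name == "obs":
                Gs.append(np.eye(k))
            else:
                G = np.zeros((k, k))
                for idx in study_idx:
                    G[np.ix_(idx, idx)] += 1.0
                Gs.append(G)

        score = np.array([
            -0.5 * (np.trace(P @ G) - float(Py @ G @ Py)) for G in Gs
        ])
        cur = np.array([tau2[name] for name in free])
        # active set: components pinned at zero whose score points outward
        active = (cur <= 0.0) & (score <= 0.0)
        if np.all(active):
            break  # KKT conditions hold at the boundary
        inact = ~active
        grad_norm = float(np.linalg.norm(score[inact]))
        if grad_norm < 1e-12:
            break
        info = np.empty((len(free), len(free)))
        PG = [P @ G for G in Gs]
        for a in range(len(free)):
            for b in range(a, len(free)):
                info[a, b] = info[b, a] = 0.5 * np.trace(PG[a] @ PG[b])
        step = np.zeros(len(free))
        try:
            step[inact] = np.linalg.solve(info[np.ix_(inact, inact)], score[inact])
        except np.linalg.LinAlgError:
            step[inact] = score[inact]  # fall back to steepest ascent

        # step-halving with projection onto the non-negative orthant
        improved = False
        for _half in range(30):
            cand = np.maximum(cur + step, 0.0)
            V_new = _build_cov(v, study_idx,
                               cand[free.index("study")] if "study" in free else tau2["study"],
                               cand[free.index("obs")] if "obs" in free else tau2["obs"])
            try:
                ll_new, beta_new, C_new = _restricted_ll(y, X, V_new)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if ll_new >= ll - 1e-12:
                improved = True
                break
            step *= 0.5
        if not improved:
            break  # cannot improve further; treat current point as optimum
        delta = ll_new - ll
        for i, name in enumerate(free):
            tau2[name] = float(cand[i])
        V, ll, beta, C = V_new, ll_new, beta_new, C_new
        if abs(delta) < tol:
            break
    else:
        raise ConvergenceError("REML did not converge", (tau2["study"], tau2["obs"]), grad_norm)

    # exact zeros at the boundary, never epsilon
    for name in free:
        if tau2[name] < 1e-10:
            tau2[name] = 0.0
    V = _build_cov(v, study_idx, tau2["study"], tau2["obs"])
    _, beta, C = _restricted_ll(y, X, V)
    return beta, C, tau2["study"], tau2["obs"]


def _cochran_q(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    return float(np.sum(w * (y - mu_fe) ** 2))


def fit_multilevel_re(effects: Sequence[EffectSize], *,
                      fix_tau2_study: float | None = None,
                      fix_tau2_obs: float | None = None) -> MetaEstimate:
    """Pool effect sizes under the study-nested random-effects model."""
    k = len(effects)
    if k == 0:
        raise ValueError("no effect sizes to pool")
    y = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0 for pooling")
    studies = [e.study_id for e in effects]
    n_studies = len(set(studies))

    if k == 1:
        mu, se = float(y[0]), float(math.sqrt(v[0]))
        t2s, t2o = 0.0, 0.0
    else:
        X = np.ones((k, 1))
        beta, C, t2s, t2o = _reml_fit(y, v, studies, X,
                                      fix_tau2_study=fix_tau2_study,
                                      fix_tau2_obs=fix_tau2_obs)
        mu, se = float(beta[0]), float(math.sqrt(C[0, 0]))

    z = mu / se if se > 0 else math.inf * np.sign(mu) if mu else 0.0
    p = 2 * stats.norm.sf(abs(z)) if math.isfinite(z) else 0.0
    return MetaEstimate(
        mu=mu, se=se, ci_low=mu - Z_95 * se, ci_high=mu + Z_95 * se,
        tau2_study=t2s, tau2_obs=t2o, k=k, n_studies=n_studies,
        z=float(z), p=float(p), q_total=_cochran_q(y, v) if k > 1 else 0.0,
    )


def is_significant(est: MetaEstimate) -> bool:
    """True when the 95% CI excludes zero."""
    return not (est.ci_low <= 0.0 <= est.ci_high)


def fit_subgroup(effects: Sequence[EffectSize], labels: Sequence[str],
                 moderator: str = "moderator",
                 declared_levels: Sequence[str] | None = None) -> SubgroupResult:
    """Moderator analysis: level-specific pooled effects and the Q_M test.

    The model replaces the intercept with one dummy per level, sharing the
    two variance components across levels; Q_M tests equality of all level
    means (Wald chi-square, df = levels - 1).  When ``declared_levels``
    is given, a declared level with no observations is an error.
    """
    if len(labels) != len(effects):
        raise ValueError("labels must align with effects")
    levels = sorted(set(labels))
    if declared_levels is not None:
        empty = sorted(set(declared_levels) - set(levels))
        if empty:
            raise ValueError(f"declared level(s) with no observations: {empty}")
    if len(levels) < 2:
        raise ValueError(f"need >= 2 moderator levels, got {levels}")

    y = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0 for pooling")
    studies = [e.study_id for e in effects]
    lab_arr = np.asarray(labels, dtype=object)
    X = np.column_stack([(lab_arr == lv).astype(float) for lv in levels])

    beta, C, t2s, t2o = _reml_fit(y, v, studies, X)

    # omnibus: all adjacent-difference contrasts simultaneously zero
    m = len(levels)
    L = np.zeros((m - 1, m))
    for i in range(m - 1):
        L[i, i], L[i, i + 1] = 1.0, -1.0
    diff = L @ beta
    qm = float(diff @ np.linalg.solve(L @ C @ L.T, diff))
    df = m - 1
    p_qm = float(stats.chi2.sf(qm, df))

    estimates: dict[str, MetaEstimate] = {}
    for i, lv in enumerate(levels):
        mu, se = float(beta[i]), float(math.sqrt(C[i, i]))
        idx = lab_arr == lv
        z = mu / se if se > 0 else 0.0
        estimates[lv] = MetaEstimate(
            mu=mu, se=se, ci_low=mu - Z_95 * se, ci_high=mu + Z_95 * se,
            tau2_study=t2s, tau2_obs=t2o,
            k=int(idx.sum()), n_studies=len({s for s, m_ in zip(studies, idx) if m_}),
            z=z, p=float(2 * stats.norm.sf(abs(z))),
            q_total=_cochran_q(y[idx], v[idx]) if idx.sum() > 1 else 0.0,
        )
    return SubgroupResult(moderator=moderator, levels=levels, estimates=estimates,
                          qm=qm, df=df, p_qm=p_qm, _coef=beta, _cov=C)


def posthoc_pairwise(sub: SubgroupResult, seed: int,
                     n_draws: int = 100_000) -> list[tuple[str, str, float, float]]:
    """Tukey-style all-pairs comparisons with single-step max-|z| adjustment.

    Adjusted p-values come from the joint normal distribution of the
    pairwise contrasts, approximated by seeded Monte-Carlo draws of the
    maximum absolute z statistic; with a single contrast the adjusted p
    equals the unadjusted two-sided p.  Falls back to Bonferroni when the
    contrast covariance is singular.
    """
    levels, beta, C = sub.levels, sub._coef, sub._cov
    if beta is None or C is None:
        raise ValueError("run fit_subgroup first")
    m = len(levels)
    pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    L = np.zeros((len(pairs), m))
    for r, (i, j) in enumerate(pairs):
        L[r, i], L[r, j] = 1.0, -1.0
    cov = L @ C @ L.T
    sd = np.sqrt(np.diag(cov))
    z_obs = (L @ beta) / sd
    p_unadj = 2 * stats.norm.sf(np.abs(z_obs))

    if len(pairs) == 1:
        p_adj = p_unadj.copy()
    else:
        corr = cov / np.outer(sd, sd)
        try:
            chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(pairs)))
            rng = np.random.default_rng(seed)
            draws = rng.standard_normal((n_draws, len(pairs))) @ chol.T
            max_abs = np.max(np.abs(draws), axis=1)
            p_adj = np.array([float(np.mean(max_abs >= abs(z))) for z in z_obs])
        except np.linalg.LinAlgError:
            logger.warning("posthoc_pairwise: singular contrast covariance; Bonferroni fallback")
            p_adj = np.minimum(p_unadj * len(pairs), 1.0)
    p_adj = np.maximum(p_adj, p_unadj)  # single-step adjustment never anti-conservative

    table = [(levels[i], levels[j], float((L @ beta)[r]), float(p_adj[r]))
             for r, (i, j) in enumerate(pairs)]
    sub.pairwise = table
    return table
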