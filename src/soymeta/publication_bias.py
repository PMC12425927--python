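"""Publication-bias diagnostics: Rosenthal fail-safe N and a Begg-type
Kendall rank-correlation test.

The fail-safe number is the count of hypothetical null (zero-effect)
studies that would have to exist unpublished before the Stouffer combined
one-tailed p of the pooled result rises above alpha:

    N_fs = floor( (sum z_i)^2 / z_alpha^2 - k ),  z_i = y_i / sqrt(v_i)

floored at zero.  The result is called robust when N_fs exceeds 5k + 10.

The Begg-type test rank-correlates variance-standardized deviates from
the fixed-effect pooled mean with the sampling variances; a significant
Kendall tau signals funnel asymmetry.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .effect_sizes import EffectSize


@dataclass(frozen=True)
class BiasReport:
    failsafe_n: int
    n_obs: int
    threshold: int          # 5 * n_obs + 10
    robust: bool
    kendall_tau: float
    p_kendall: float


def failsafe_rosenthal(effects: Sequence[EffectSize], alpha: float = 0.05) -> int:
    """Rosenthal fail-safe number at one-tailed alpha (default 0.05).

    Satisfies the defining property: with N_fs added null studies the
    Stouffer combined one-tailed p (in the direction of the pooled
    z-sum) stays <= alpha, while N_fs + 1 pushes it above.
    """
    k = len(effects)
    if k < 1:
        raise ValueError("need at least one effect size")
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    z = np.array([e.value for e in effects]) / np.sqrt(v)
    s = abs(float(np.sum(z)))  # one-tailed in the direction of the combined effect
    z_alpha = stats.norm.isf(alpha)
    if s / math.sqrt(k) < z_alpha:
        return 0  # not significant to begin with; nothing to overturn
    return max(int(math.floor(s ** 2 / z_alpha ** 2 - k)), 0)


def _kendall_s_and_tau(u: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Kendall S statistic and tie-corrected tau-b."""
    n = len(u)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign(u[j] - u[i]) * np.sign(w[j] - w[i])
    n0 = n * (n - 1) / 2

    def tie_term(x: np.ndarray) -> float:
        _, counts = np.unique(x, return_counts=True)
        return float(np.sum(counts * (counts - 1) / 2))

    denom = math.sqrt((n0 - tie_term(u)) * (n0 - tie_term(w)))
    tau = float(s) / denom if denom > 0 else math.nan
    return float(s), tau


def kendall_tau_test(effects: Sequence[EffectSize]) -> tuple[float, float]:
    """Begg-type rank-correlation test for funnel asymmetry.

    Correlates u_i = (y_i - mu_FE) / sqrt(v_i - 1/sum(1/v)) with v_i.
    Two-sided p: exhaustive permutation enumeration for k <= 8, normal
    approximation with continuity correction (tie-corrected variance)
    otherwise.
    """
    k = len(effects)
    if k < 3:
        raise ValueError("need at least 3 effect sizes")
    y = np.array([e.value for e in effects])
    v = np.array([e.variance for e in effects])
    if np.any(v <= 0):
        raise ValueError("all sampling variances must be > 0")
    w = 1.0 / v
    mu_fe = float(np.sum(w * y) / np.sum(w))
    v_star = v - 1.0 / float(np.sum(w))
    v_star = np.maximum(v_star, np.finfo(float).tiny)
    u = (y - mu_fe) / np.sqrt(v_star)

    s_obs, tau = _kendall_s_and_tau(u, v)
    if math.isnan(tau):
        # complete ties in a coordinate: no orderable pairs, no asymmetry signal
        return 0.0, 1.0

    if k <= 8:
        # exact two-sided p by enumerating all relabelings of one coordinate
        count = 0
        total = 0
        for perm in itertools.permutations(range(k)):
            s_perm, _ = _kendall_s_and_tau(u[list(perm)], v)
            if abs(s_perm) >= abs(s_obs) - 1e-12:
                count += 1
            total += 1
        p = count / total
    else:
        n0 = k * (k - 1) * (2 * k + 5)

        def tie_var(x: np.ndarray) -> float:
            _, counts = np.unique(x, return_counts=True)
            return float(np.sum(counts * (counts - 1) * (2 * counts + 5)))

        var_s = (n0 - tie_var(u) - tie_var(v)) / 18.0
        z = (abs(s_obs) - 1.0) / math.sqrt(var_s) if abs(s_obs) > 1 else 0.0
        p = float(2 * stats.norm.sf(z))
    return tau, min(p, 1.0)


def bias_report(effects: Sequence[EffectSize], alpha: float = 0.05) -> BiasReport:
    """Assemble fail-safe N, the 5k+10 robustness rule, and Kendall's test."""
    n_fs = failsafe_rosenthal(effects, alpha=alpha)
    n_obs = len(effects)
    threshold = 5 * n_obs + 10
    tau, p = kendall_tau_test(effects) if n_obs >= 3 else (math.nan, math.nan)
    return BiasReport(
        failsafe_n=n_fs, n_obs=n_obs, threshold=threshold,
        robust=n_fs > threshold, kendall_tau=tau, p_kendall=p,
    )
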