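"""Effect sizes: the log response ratio, its sampling variance, SD
imputation, and the planting-density standardization metrics.

The effect metric throughout is the natural-log response ratio

    lnRR = ln(x_t / x_c)

with x_t the intercropping (treatment) mean and x_c the monoculture
(control) mean, and sampling variance

    v = s_t^2 / (n_t x_t^2) + s_c^2 / (n_c x_c^2)

i.e. the sum of the squared coefficient of variation over n for each arm.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .study_database import StudyObservation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EffectSize:
    """One lnRR effect size with its sampling variance."""

    obs_id: str
    study_id: str
    trait: str
    value: float
    variance: float
    imputed_sd: bool = False


def log_response_ratio(x_t: float, x_c: float) -> float:
    """ln(x_t) - ln(x_c); both means must be strictly positive."""
    if not x_t > 0:
        raise ValueError(f"treatment mean must be > 0, got {x_t}")
    if not x_c > 0:
        raise ValueError(f"control mean must be > 0, got {x_c}")
    return math.log(x_t) - math.log(x_c)


def lnrr_variance(s_t: float, n_t: int, x_t: float,
                  s_c: float, n_c: int, x_c: float) -> float:
    """Sampling variance of lnRR from per-arm SDs, sample sizes and means."""
    if s_t < 0 or s_c < 0:
        raise ValueError("standard deviations must be non-negative")
    if n_t < 1 or n_c < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (x_t > 0 and x_c > 0):
        raise ValueError("means must be strictly positive")
    return s_t ** 2 / (n_t * x_t ** 2) + s_c ** 2 / (n_c * x_c ** 2)


def compute_rdt(d1_ic: float, d1_sc: float, d2_ic: float, d2_sc: float) -> float:
    """Relative density total of a two-species intercrop.

    RDT = d1_ic/d1_sc + d2_ic/d2_sc, densities in plants per unit land
    area of the whole intercrop.  RDT = 1 is a replacement design,
    RDT > 1 an additive design.
    """
    for name, d in (("d1_ic", d1_ic), ("d1_sc", d1_sc), ("d2_ic", d2_ic), ("d2_sc", d2_sc)):
        if not d > 0:
            raise ValueError(f"density {name} must be > 0, got {d}")
    return d1_ic / d1_sc + d2_ic / d2_sc


def compute_prdt(d_ic: float, d_sc: float) -> float:
    """Plant relative density total for soybean alone: d_ic / d_sc."""
    if not d_ic > 0:
        raise ValueError(f"density d_ic must be > 0, got {d_ic}")
    if not d_sc > 0:
        raise ValueError(f"density d_sc must be > 0, got {d_sc}")
    return d_ic / d_sc


def _stratum_key(obs: StudyObservation, arm: str, pool: str) -> tuple:
    if pool == "global":
        return (arm,)
    if pool == "trait_arm":
        return (obs.trait, arm)
    raise ValueError(f"unknown CV pooling stratum {pool!r}")


def impute_sd(db: Sequence[StudyObservation], *, pool: str = "trait_arm",
              on_empty_stratum: str = "error") -> list[StudyObservation]:
    """Fill unreported SDs with mean x average coefficient of variation.

    For each observation with a reported SD the per-arm CV (sd/mean) is
    computed; unreported SDs are set to the row's mean multiplied by the
    average CV of its pooling stratum, and flagged as imputed.  Reported
    SDs are never modified; the operation is idempotent.

    pool: "trait_arm" (default) averages CVs within trait x arm, keeping
    treatment and control pools separate and preventing cross-trait scale
    contamination; "global" pools per arm across all traits.

    on_empty_stratum: "error" raises when a row needs imputation but its
    stratum has no reported SD; "skip" leaves the SD missing (such rows
    are later dropped from variance-weighted fits, with a warning).
    """
    cv_sums: dict[tuple, list[float]] = {}
    for obs in db:
        for arm, sd, mean in (("treat", obs.sd_treat, obs.mean_treat),
                              ("ctrl", obs.sd_ctrl, obs.mean_ctrl)):
            if not math.isnan(sd):
                cv_sums.setdefault(_stratum_key(obs, arm, pool), []).append(sd / mean)
    cv_mean = {key: sum(vals) / len(vals) for key, vals in cv_sums.items()}

    out: list[StudyObservation] = []
    empty_strata: set[tuple] = set()
    for obs in db:
        updates: dict[str, object] = {}
        for arm, sd, mean in (("treat", obs.sd_treat, obs.mean_treat),
                              ("ctrl", obs.sd_ctrl, obs.mean_ctrl)):
            if math.isnan(sd):
                key = _stratum_key(obs, arm, pool)
                if key in cv_mean:
                    updates[f"sd_{arm}"] = mean * cv_mean[key]
                    updates[f"sd_{arm}_imputed"] = True
                else:
                    empty_strata.add(key)
        out.append(replace(obs, **updates) if updates else obs)
    if empty_strata:
        msg = "no reported SD in stratum(s): " + ", ".join(map(str, sorted(empty_strata)))
        if on_empty_stratum == "error":
            raise ValueError(msg)
        logger.warning("impute_sd: %s; affected SDs left missing", msg)
    return out


def compute_effect_sizes(db: Sequence[StudyObservation]) -> list[EffectSize]:
    """Turn observations into lnRR effect sizes with sampling variances.

    Rows still missing an SD (imputation skipped or impossible) are
    dropped with a warning — they cannot enter a variance-weighted fit.
    """
    effects: list[EffectSize] = []
    dropped = 0
    for obs in db:
        if math.isnan(obs.sd_treat) or math.isnan(obs.sd_ctrl):
            dropped += 1
            continue
        effects.append(EffectSize(
            obs_id=obs.obs_id,
            study_id=obs.study_id,
            trait=obs.trait,
            value=log_response_ratio(obs.mean_treat, obs.mean_ctrl),
            variance=lnrr_variance(obs.sd_treat, obs.n_treat, obs.mean_treat,
                                   obs.sd_ctrl, obs.n_ctrl, obs.mean_ctrl),
            imputed_sd=obs.sd_treat_imputed or obs.sd_ctrl_imputed,
        ))
    if dropped:
        logger.warning("compute_effect_sizes: dropped %d row(s) with missing SDs", dropped)
    return effects


def write_effect_sizes(effects: Sequence[EffectSize], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["obs_id", "study_id", "trait", "lnrr", "variance", "imputed_sd"])
        for es in effects:
            writer.writerow([es.obs_id, es.study_id, es.trait,
                             repr(es.value), repr(es.variance),
                             "true" if es.imputed_sd else "false"])
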