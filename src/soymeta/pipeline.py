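"""Pipeline orchestration: wires the stages into the full analysis flow
and emits the report tables.

Every stage is a pure function of (input files, config, seeds); rerunning
with identical inputs produces byte-identical outputs.  Each emitted CSV
starts with a comment line carrying the config hash and seed, and every
row carries a provenance column listing the contributing observation ids.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effect_sizes import EffectSize, compute_effect_sizes, impute_sd, write_effect_sizes
from .meta_model import fit_multilevel_re, fit_subgroup, is_significant, posthoc_pairwise
from .moderator_analysis import (meta_regression, moderator_importance,
                                 quadratic_summary, select_model)
from .ordination import (OrdinationSet, load_ordination_csv, lnrr_beta,
                         lnrr_structure, summarize_distances, write_ordination_csv)
from .publication_bias import bias_report
from .study_database import (StudyObservation, filter_rdt, load_observations,
                             select_final_year, write_observations,
                             write_validation_report)
from .synthetic_data import SyntheticSpec, generate_observations, generate_ordination

logger = logging.getLogger(__name__)

ALL_TRAITS = ["shannon", "chao1", "richness", "beta_diversity", "structure", "yield"]
DEFAULT_MODERATORS = ["taxon_group", "n_source", "n_timing", "companion_type",
                      "system", "condition", "compartment", "strip"]
DEFAULT_COVARIATES = ["nfr_kg_ha", "map_mm", "mat_c", "duration_yr", "rdt", "prdt",
                      "phi", "soci", "tni", "rows_soybean", "dist_soybean_m"]


def setup_logging(level: int = logging.INFO) -> None:
    """Route package logs to stderr (idempotent)."""
    root = logging.getLogger("soymeta")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
        root.addHandler(handler)
    root.setLevel(level)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input: str | None = None
    ordination: str | None = None
    traits: list[str] = field(default_factory=lambda: list(ALL_TRAITS))
    moderators: list[str] = field(default_factory=lambda: list(DEFAULT_MODERATORS))
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    lnrrs_convention: str = "between_within"
    cv_pool: str = "trait_arm"
    alpha: float = 0.05
    n_perm: int = 9999
    posthoc_draws: int = 100_000
    seed: int = 0
    out_dir: str = "soymeta_out"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.lnrrs_convention not in {"as_printed", "between_within"}:
            raise ValueError(f"unknown lnRRs convention {self.lnrrs_convention!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        for key in raw:
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**raw)

    def hash(self) -> str:
        """Digest of the analysis configuration (output location excluded)."""
        fields = dataclasses.asdict(self)
        fields.pop("out_dir")
        payload = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path: str | Path, config: RunConfig) -> None:
    """CSV with a provenance comment line (config hash + seed)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as handle:
        handle.write(f"# soymeta config={config.hash()} seed={config.seed}\n")
        frame.to_csv(handle, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_manifest(config: RunConfig, counts: dict[str, int]) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "soymeta_version": __version__,
        "counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def prepare_database(config: RunConfig,
                     db: list[StudyObservation] | None = None) -> list[StudyObservation]:
    """Load + screen: density filter, final-year selection, SD imputation."""
    t0 = time.perf_counter()
    if db is None:
        if config.input is None:
            raise ValueError("config.input is not set and no database was supplied")
        db, issues = load_observations(config.input)
        if issues:
            report_path = Path(config.out_dir) / "validation_report.csv"
            report_path.parent.mkdir(parents=True, exist_ok=True)
            write_validation_report(issues, report_path)
    db = filter_rdt(db)
    db = select_final_year(db)
    db = impute_sd(db, pool=config.cv_pool, on_empty_stratum="skip")
    logger.info("prepare_database: %d observation(s) ready in %.2fs",
                len(db), time.perf_counter() - t0)
    return db


def _effects_by_trait(db: list[StudyObservation], traits: list[str]) -> dict[str, list[EffectSize]]:
    effects = compute_effect_sizes(db)
    return {trait: [e for e in effects if e.trait == trait] for trait in traits}


def run_overall(config: RunConfig, db: list[StudyObservation] | None = None) -> pd.DataFrame:
    """Pooled effect per trait: the overall forest table."""
    db = prepare_database(config, db)
    rows = []
    for trait, effects in _effects_by_trait(db, config.traits).items():
        if not effects:
            logger.warning("run_overall: no observations for trait %r", trait)
            rows.append({"trait": trait, "k": 0})
            continue
        est = fit_multilevel_re(effects)
        rows.append({
            "trait": trait, "k": est.k, "n_studies": est.n_studies,
            "mu": est.mu, "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
            "tau2_study": est.tau2_study, "tau2_obs": est.tau2_obs,
            "z": est.z, "p": est.p, "significant": is_significant(est),
            "obs_ids": ";".join(e.obs_id for e in effects),
        })
    return pd.DataFrame(rows)


def run_subgroups(config: RunConfig, db: list[StudyObservation] | None = None) -> pd.DataFrame:
    """Per moderator x trait: level estimates, Q_M, and post hoc pairs."""
    db = prepare_database(config, db)
    by_trait = _effects_by_trait(db, config.traits)
    obs_by_id = {obs.obs_id: obs for obs in db}
    rows = []
    for moderator in config.moderators:
        for trait, effects in by_trait.items():
            if not effects:
                continue
            labels = [getattr(obs_by_id[e.obs_id], moderator) for e in effects]
            observed = sorted(set(labels))
            if len(observed) < 2:
                logger.warning("run_subgroups: %s/%s has a single observed level; skipped",
                               trait, moderator)
                continue
            sub = fit_subgroup(effects, labels, moderator=moderator)
            pairs = (posthoc_pairwise(sub, seed=config.seed, n_draws=config.posthoc_draws)
                     if sub.p_qm < config.alpha else [])
            pair_text = ";".join(f"{a}-{b}:{diff:+.4f}(p={p:.4f})" for a, b, diff, p in pairs)
            for level in sub.levels:
                est = sub.estimates[level]
                rows.append({
                    "moderator": moderator, "trait": trait, "level": level,
                    "k": est.k, "n_studies": est.n_studies, "mu": est.mu, "se": est.se,
                    "ci_low": est.ci_low, "ci_high": est.ci_high,
                    "tau2_study": est.tau2_study, "tau2_obs": est.tau2_obs,
                    "qm": sub.qm, "df": sub.df, "p_qm": sub.p_qm,
                    "posthoc": pair_text,
                    "obs_ids": ";".join(e.obs_id for e, lab in zip(effects, labels)
                                        if lab == level),
                })
    return pd.DataFrame(rows)


def run_bias(config: RunConfig, db: list[StudyObservation] | None = None) -> pd.DataFrame:
    """Fail-safe N (5k+10 rule) and Kendall's test per trait."""
    db = prepare_database(config, db)
    rows = []
    for trait, effects in _effects_by_trait(db, config.traits).items():
        if len(effects) < 3:
            logger.warning("run_bias: <3 observations for trait %r; skipped", trait)
            continue
        rep = bias_report(effects, alpha=config.alpha)
        rows.append({
            "trait": trait, "k": rep.n_obs, "failsafe_n": rep.failsafe_n,
            "threshold_5n10": rep.threshold, "robust": rep.robust,
            "kendall_tau": rep.kendall_tau, "p_kendall": rep.p_kendall,
            "obs_ids": ";".join(e.obs_id for e in effects),
        })
    return pd.DataFrame(rows)


def run_modreg(config: RunConfig, db: list[StudyObservation] | None = None) -> pd.DataFrame:
    """Meta-regression of each trait's lnRR on each continuous covariate.

    Linear and quadratic forms are fitted with shared weights; the
    AIC-selected model is reported, with turning point and positive
    interval when the winner is quadratic.
    """
    db = prepare_database(config, db)
    obs_by_id = {obs.obs_id: obs for obs in db}
    rows = []
    for trait, effects in _effects_by_trait(db, config.traits).items():
        if len(effects) < 5:
            continue
        overall = fit_multilevel_re(effects)
        tau2 = overall.tau2_study + overall.tau2_obs
        for covariate in config.covariates:
            x = [getattr(obs_by_id[e.obs_id], covariate) for e in effects]
            n_obs = sum(1 for xi in x if not math.isnan(xi))
            if n_obs < 5 or len({xi for xi in x if not math.isnan(xi)}) < 3:
                continue
            try:
                fits = [meta_regression(effects, x, form, tau2=tau2)
                        for form in ("linear", "quadratic")]
            except ValueError as exc:
                logger.warning("run_modreg: %s ~ %s failed: %s", trait, covariate, exc)
                continue
            best = select_model(fits)
            row = {
                "trait": trait, "covariate": covariate, "form": best.form, "k": best.k,
                "intercept": best.coef[0], "b1": best.coef[1],
                "b2": best.coef[2] if best.form == "quadratic" else math.nan,
                "r2": best.r2, "p_model": best.p_model,
                "aic_linear": fits[0].aic, "aic_quadratic": fits[1].aic,
                "bic_linear": fits[0].bic, "bic_quadratic": fits[1].bic,
                "vertex_x": math.nan, "vertex_y": math.nan,
                "positive_low": math.nan, "positive_high": math.nan,
                "obs_ids": ";".join(e.obs_id for e, xi in zip(effects, x)
                                    if not math.isnan(xi)),
            }
            if best.form == "quadratic":
                summary = quadratic_summary(best)
                row["vertex_x"], row["vertex_y"] = summary.vertex_x, summary.vertex_y
                if summary.positive_interval is not None:
                    row["positive_low"], row["positive_high"] = summary.positive_interval
            rows.append(row)
    return pd.DataFrame(rows)


def run_importance(config: RunConfig, db: list[StudyObservation] | None = None,
                   trait: str = "shannon") -> pd.DataFrame:
    """Tree-ensemble permutation importance of the continuous covariates."""
    db = prepare_database(config, db)
    effects = {e.obs_id: e for e in compute_effect_sizes(db)}
    records = []
    for obs in db:
        if obs.trait == trait and obs.obs_id in effects:
            rec = {"lnrr": effects[obs.obs_id].value}
            for cov in config.covariates:
                rec[cov] = getattr(obs, cov)
            records.append(rec)
    frame = pd.DataFrame(records)
    ranked = moderator_importance(frame, "lnrr", config.covariates, seed=config.seed)
    return pd.DataFrame([{"trait": trait, "predictor": name, "importance": imp,
                          "rank": rank + 1}
                         for rank, (name, imp) in enumerate(ranked)])


def run_ordination(config: RunConfig,
                   osets: list[OrdinationSet] | None = None) -> pd.DataFrame:
    """Distance summaries and structure/β response ratios per ordination set."""
    if osets is None:
        if config.ordination is None:
            raise ValueError("config.ordination is not set and no coordinate sets supplied")
        osets = load_ordination_csv(config.ordination)
    rows = []
    for oset in osets:
        d = summarize_distances(oset)
        row = {
            "obs_id": oset.obs_id, "method": oset.method,
            "d_within_ctrl": d.d_within_ctrl, "d_within_treat": d.d_within_treat,
            "d_between": d.d_between, "degenerate": d.degenerate,
            "lnrr_beta": math.nan,
            "lnrr_structure": math.nan, "lnrr_structure_as_printed": math.nan,
        }
        if not d.degenerate:
            row["lnrr_beta"] = lnrr_beta(d)
            # audit mode: always emit both conventions
            row["lnrr_structure"] = lnrr_structure(d, config.lnrrs_convention)
            row["lnrr_structure_as_printed"] = lnrr_structure(d, "as_printed")
        rows.append(row)
    return pd.DataFrame(rows)


def run_simulate(config: RunConfig, spec: SyntheticSpec | None = None) -> dict[str, Path]:
    """Generate a synthetic database + ordination sets and write them out."""
    if spec is None:
        spec = SyntheticSpec(seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = generate_observations(spec)
    osets = [generate_ordination(spec, obs_id=f"ord{i:03d}", stream=i) for i in range(10)]
    db_path = out / "synthetic_observations.csv"
    ord_path = out / "synthetic_ordination.csv"
    write_observations(db, db_path)
    write_ordination_csv(osets, ord_path)
    logger.info("run_simulate: wrote %d observations and %d ordination sets", len(db), len(osets))
    return {"observations": db_path, "ordination": ord_path}


def run_report(config: RunConfig) -> dict[str, Path]:
    """Full analysis flow; writes every report table plus the run manifest."""
    setup_logging()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = prepare_database(config)
    stages = {
        "overall": run_overall(config, db),
        "subgroups": run_subgroups(config, db),
        "bias": run_bias(config, db),
        "modreg": run_modreg(config, db),
    }
    if config.ordination is not None:
        stages["ordination"] = run_ordination(config)
    effects = compute_effect_sizes(db)
    paths: dict[str, Path] = {}
    for name, frame in stages.items():
        t0 = time.perf_counter()
        paths[name] = out / f"{name}.csv"
        write_table(frame, paths[name], config)
        logger.info("stage %s: %d row(s) in %.2fs", name, len(frame), time.perf_counter() - t0)
    effects_path = out / "effect_sizes.csv"
    write_effect_sizes(effects, effects_path)
    paths["effects"] = effects_path
    write_manifest(config, {name: len(frame) for name, frame in stages.items()})
    return paths
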