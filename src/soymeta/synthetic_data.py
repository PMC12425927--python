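"""Seeded synthetic study databases with known truth.

The generator emulates the structure of a paired intercropping-vs-
monoculture meta-analytic database: observations nested in articles with
between-study heterogeneity, lognormal control means with treatment means
tied to a target lnRR, per-arm SDs built from a target coefficient of
variation (a fraction masked missing to exercise imputation), categorical
moderators with known level shifts, continuous covariates over realistic
agronomic ranges, 2-group 2D ordination clouds with controllable centroid
separation and dispersion, and a quadratic link from the Shannon response
to the yield response.

Default true effects mirror the magnitudes typical of soil-microbial
intercropping syntheses: small positive alpha-diversity responses, a
near-zero yield response, a weakly negative beta-diversity response, and
a large positive structure contrast.

Random streams are split hierarchically by (study, observation) index via
``numpy.random.SeedSequence``, so enlarging the database never reshuffles
earlier studies; a fixed seed yields byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ordination import OrdinationSet
from .study_database import StudyObservation

# sub-stream tags so the study, ordination and yield-link streams never collide
_STUDY_STREAM = 0
_ORDINATION_STREAM = 1
_YIELD_STREAM = 2

DEFAULT_MU_TRUE = {
    "shannon": 0.036,
    "chao1": 0.034,
    "richness": 0.102,
    "beta_diversity": -0.098,
    "structure": 0.741,
    "yield": -0.020,
}

# quadratic yield-vs-Shannon-response link: concave, turning point 0.212,
# positive yield response roughly over (0.016, 0.408)
DEFAULT_QUAD_LINK = (-1.0, 0.424, -0.00633)


@dataclass
class SyntheticSpec:
    """Full parameterization of a simulated study database."""

    seed: int = 0
    n_studies: int = 30
    obs_per_study: int = 3
    mu_true: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MU_TRUE))
    tau_study: float = 0.05          # SD of the article-level random effect
    sigma_obs: float = 0.03          # SD of the residual observation-level effect
    cv_arm: float = 0.2              # target within-arm coefficient of variation
    n_per_arm: int = 4               # replicates per arm
    moderator_levels: dict[str, list[tuple[str, float]]] = field(
        default_factory=lambda: {
            "n_source": [("mineral", 0.0), ("organic", 0.02), ("mixed", 0.06)],
        })
    quad_link: tuple[float, float, float] = DEFAULT_QUAD_LINK
    quad_noise_sd: float = 0.01
    nfr_range: tuple[float, float] = (0.0, 300.0)   # kg N / ha
    sd_missing_rate: float = 0.2
    ordination_n_per_group: int = 5
    ordination_separation: float = 3.4
    ordination_dispersion_ctrl: float = 1.0
    ordination_dispersion_treat: float = 1.0

    def validate(self) -> None:
        if self.n_studies < 1 or self.obs_per_study < 1:
            raise ValueError("n_studies and obs_per_study must be >= 1")
        if self.tau_study < 0 or self.sigma_obs < 0 or self.cv_arm < 0:
            raise ValueError("variance parameters must be non-negative")
        if not 0.0 <= self.sd_missing_rate <= 1.0:
            raise ValueError("sd_missing_rate must lie in [0, 1]")
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if not self.mu_true:
            raise ValueError("mu_true must name at least one trait")


def _rng(spec_seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec_seed, *path)))


def generate_observations(spec: SyntheticSpec) -> list[StudyObservation]:
    """Draw a seeded study database with known true effects.

    Per study i: b_i ~ N(0, tau_study^2).  Per observation j the latent
    effect is theta = mu_true[trait] + moderator shifts + b_i +
    N(0, sigma_obs^2); the true control mean is LogNormal(meanlog 1,
    sdlog 0.3) and the true treatment mean x_c * exp(theta).  Observed
    arm means then carry multiplicative sampling error of magnitude
    cv_arm/sqrt(n_per_arm), so the observed lnRR scatters around theta
    with variance close to its nominal sampling variance v — the
    condition under which variance-weighted pooling is calibrated.  With
    cv_arm = 0 the observed lnRR equals theta exactly.  Arm SDs are
    cv_arm times the observed mean, perturbed +/-10%, and masked missing
    at sd_missing_rate.  Traits cycle deterministically through mu_true
    for balance.
    """
    spec.validate()
    traits = list(spec.mu_true)
    observations: list[StudyObservation] = []
    for i in range(spec.n_studies):
        study_rng = _rng(spec.seed, _STUDY_STREAM, i)
        b_i = study_rng.normal(0.0, spec.tau_study)
        for j in range(spec.obs_per_study):
            rng = _rng(spec.seed, _STUDY_STREAM, i, j + 1)
            trait = traits[(i * spec.obs_per_study + j) % len(traits)]

            shifts = 0.0
            moderators = {"n_source": "none", "n_timing": "none"}
            for name, levels in spec.moderator_levels.items():
                idx = rng.integers(len(levels))
                level, shift = levels[idx]
                moderators[name] = level
                shifts += shift
            theta = spec.mu_true[trait] + shifts + b_i + rng.normal(0.0, spec.sigma_obs)

            x_c = float(rng.lognormal(mean=1.0, sigma=0.3))
            x_t = x_c * float(np.exp(theta))
            # observed arm means carry the sampling error implied by the arm
            # CV and replicate count (multiplicative, mean-preserving); the
            # log-scale bias is identical in both arms and cancels in lnRR
            if spec.cv_arm > 0:
                s_arm = math.sqrt(math.log1p(spec.cv_arm ** 2 / spec.n_per_arm))
                x_t *= math.exp(rng.normal(0.0, s_arm) - s_arm ** 2 / 2)
                x_c *= math.exp(rng.normal(0.0, s_arm) - s_arm ** 2 / 2)
            sd_t = spec.cv_arm * x_t * (1.0 + rng.uniform(-0.1, 0.1))
            sd_c = spec.cv_arm * x_c * (1.0 + rng.uniform(-0.1, 0.1))
            if rng.random() < spec.sd_missing_rate:
                sd_t = np.nan
            if rng.random() < spec.sd_missing_rate:
                sd_c = np.nan

            observations.append(StudyObservation(
                study_id=f"study{i:03d}",
                obs_id=f"s{i:03d}o{j:02d}",
                trait=trait,
                taxon_group=["bacteria", "fungi", "special_fungi"][int(rng.integers(3))],
                mean_treat=x_t,
                mean_ctrl=x_c,
                sd_treat=float(sd_t),
                sd_ctrl=float(sd_c),
                n_treat=spec.n_per_arm,
                n_ctrl=spec.n_per_arm,
                n_source=moderators["n_source"],
                n_timing=["basal", "topdressing", "none"][int(rng.integers(3))],
                companion_type=["legume", "non_legume"][int(rng.integers(2))],
                system=["soy_maize", "non_soy_maize"][int(rng.integers(2))],
                condition=["pot", "field"][int(rng.integers(2))],
                compartment=["rhizosphere", "bulk"][int(rng.integers(2))],
                strip=["soybean", "non_soybean"][int(rng.integers(2))],
                map_mm=float(rng.uniform(400, 1800)),
                mat_c=float(rng.uniform(5, 25)),
                duration_yr=float(rng.integers(1, 11)),
                nfr_kg_ha=float(rng.uniform(*spec.nfr_range)),
                rdt=float(rng.uniform(1.0, 2.0)),
                prdt=float(rng.uniform(0.3, 1.0)),
                phi=float(rng.uniform(5.0, 8.0)),
                soci=float(rng.uniform(5.0, 30.0)),
                tni=float(rng.uniform(0.5, 3.0)),
                rows_soybean=float(rng.integers(2, 7)),
                dist_soybean_m=float(rng.uniform(0.2, 0.6)),
                is_final_year=True,
            ))
    return observations


def generate_ordination(spec: SyntheticSpec, obs_id: str = "ord000",
                        method: str = "PCoA", stream: int = 0) -> OrdinationSet:
    """Two isotropic Gaussian clouds in 2D with known separation/dispersion.

    Control points are N((0,0), dispersion_ctrl^2 I); treatment points
    N((separation, 0), dispersion_treat^2 I).  ``stream`` selects an
    independent sub-stream for replicate draws.
    """
    spec.validate()
    n = spec.ordination_n_per_group
    if n < 2:
        raise ValueError("need >= 2 samples per group")
    rng = _rng(spec.seed, _ORDINATION_STREAM, stream)
    ctrl = rng.normal(0.0, spec.ordination_dispersion_ctrl, size=(n, 2))
    treat = rng.normal(0.0, spec.ordination_dispersion_treat, size=(n, 2))
    treat[:, 0] += spec.ordination_separation
    return OrdinationSet(
        obs_id=obs_id,
        method=method,
        sample_ids=[f"{obs_id}_c{i}" for i in range(n)] + [f"{obs_id}_t{i}" for i in range(n)],
        groups=np.array(["control"] * n + ["treatment"] * n, dtype=object),
        coords=np.vstack([ctrl, treat]),
    )


def generate_yield_pairs(spec: SyntheticSpec, shannon_lnrr: list[float]) -> list[float]:
    """Yield responses quadratically linked to Shannon responses.

    y = a s^2 + b s + c + N(0, quad_noise_sd^2) with (a, b, c) from
    ``spec.quad_link``; seeded, one draw per input value.
    """
    spec.validate()
    a, b, c = spec.quad_link
    rng = _rng(spec.seed, _YIELD_STREAM)
    s = np.asarray(shannon_lnrr, dtype=float)
    noise = rng.normal(0.0, spec.quad_noise_sd, size=s.shape) if spec.quad_noise_sd > 0 else 0.0
    return list((a * s ** 2 + b * s + c + noise).astype(float))
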