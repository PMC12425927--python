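import math

import pytest

from soymeta.study_database import StudyObservation

_DEFAULTS = dict(
    study_id="studyA",
    obs_id="obs1",
    trait="shannon",
    taxon_group="bacteria",
    mean_treat=2.0,
    mean_ctrl=1.0,
    sd_treat=0.4,
    sd_ctrl=0.2,
    n_treat=4,
    n_ctrl=4,
    n_source="mineral",
    n_timing="basal",
    companion_type="non_legume",
    system="soy_maize",
    condition="field",
    compartment="rhizosphere",
    strip="soybean",
)


@pytest.fixture
def make_obs():
    """Factory for valid StudyObservation rows with field overrides."""

    counter = {"n": 0}

    def factory(**overrides) -> StudyObservation:
        counter["n"] += 1
        kwargs = dict(_DEFAULTS)
        kwargs["obs_id"] = f"obs{counter['n']}"
        kwargs.update(overrides)
        return StudyObservation(**kwargs)

    return factory


@pytest.fixture
def nan():
    return math.nan
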