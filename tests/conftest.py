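import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from spafnirs import (
    CohortConfig,
    PreprocessCfg,
    SessionRecording,
    default_protocol,
    generate_cohort,
)
from spafnirs.synth import SubgroupModel


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_flat_session(
    subject_id="flat",
    sto2=70.0,
    spo2=97.0,
    pr=150.0,
    duration_s=3300,
    accel_value=0.0,
):
    """Artifact- and noise-free recording at the study's native rates."""
    n1 = duration_s
    nv = duration_s // 4
    return SessionRecording(
        subject_id=subject_id,
        sto2_ac=np.full(n1, sto2),
        sto2_pfc=np.full(n1, sto2),
        spo2=np.full(nv, spo2),
        pr=np.full(nv, pr),
        accel=np.full((3, n1), accel_value),
    )


@pytest.fixture()
def flat_session():
    return make_flat_session()


@pytest.fixture(scope="session")
def clean_cfg():
    """Cohort config with exact planted amplitudes and no artifacts."""
    cfg = CohortConfig(seed=11)
    cfg.subgroup_model = SubgroupModel(amplitude_sd=0.0, hct_coefficient=0.0)
    cfg.artifact.rate_per_hour = 0.0
    return cfg


@pytest.fixture(scope="session")
def small_cohort(clean_cfg):
    return generate_cohort(clean_cfg)


@pytest.fixture()
def pre_cfg():
    return PreprocessCfg()
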