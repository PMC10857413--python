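import numpy as np
import pytest

from cuffcomfort import (SimConfig, StimulusSchedule, SubjectProfile,
                         build_schedule)


def quiet_profile(**overrides) -> SubjectProfile:
    """A subject with no SCRs, no drift, no dip: constant-tonic EDA."""
    base = dict(
        subject_id="S01",
        scl_baseline_uS=5.0,
        scr_rate_base_per_min=0.0,
        scr_rate_gain_per_kPa=0.0,
        scr_amp_median_uS=0.3,
        scr_amp_gain_per_kPa=0.0,
        tonic_gain_uS_per_kPa=0.0,
        sto2_baseline_pct=70.0,
        sto2_drop_max_pct=60.0,
        sto2_tau_s=30.0,
        vas_sensitivity=1.0,
        sto2_recovery_tau_s=25.0,
    )
    base.update(overrides)
    return SubjectProfile(**base).validate()


@pytest.fixture
def profile() -> SubjectProfile:
    return quiet_profile()


@pytest.fixture
def schedule() -> StimulusSchedule:
    # one 5-min epoch at 10 kPa, compact session
    return build_schedule([10.0], 300.0, rest_s=60.0, pre_s=30.0)


@pytest.fixture
def noise_free() -> SimConfig:
    return SimConfig(fs_eda_hz=50.0, eda_noise_sd_uS=0.0, nirs_noise_sd_au=0.0)


def pressure_epoch(sched: StimulusSchedule):
    return next(e for e in sched.epochs if e.label == "pressure")
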