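import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vrtask.protocol import ReferencePoint, default_protocol
from vrtask.simulate import (
    ParticipantProfile,
    PhenotypeParams,
    SensorNoise,
    simulate_trial_response,
)
from vrtask.preprocess import CleanStream

settings.register_profile(
    "fast",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fast")


NOISELESS = SensorNoise(accel_noise_sd=0.0, heading_noise_sd=0.0)


def make_profile(
    heading_error_sd_deg=0.0,
    heading_bias_deg=0.0,
    hesitation_rate_per_trial=0.0,
    jerk_scale=1.0,
    tilt_wobble_sd=0.0,
    movement_duration_s=2.0,
    group="e33",
) -> ParticipantProfile:
    return ParticipantProfile(
        participant_id="test",
        group=group,
        age=63.0,
        sex="female",
        occupation=0,
        phenotype=PhenotypeParams(
            heading_error_sd_deg=heading_error_sd_deg,
            heading_bias_deg=heading_bias_deg,
            hesitation_rate_per_trial=hesitation_rate_per_trial,
            jerk_scale=jerk_scale,
            tilt_wobble_sd=tilt_wobble_sd,
            movement_duration_s=movement_duration_s,
        ),
    )


def clean_from(heading_unwrapped=None, accel=None, gyro=None, dt=0.003) -> CleanStream:
    """Build a CleanStream directly from arrays for feature unit tests."""
    if heading_unwrapped is None:
        heading_unwrapped = np.zeros(700)
    heading_unwrapped = np.asarray(heading_unwrapped, dtype=float)
    n = heading_unwrapped.size
    if accel is None:
        accel = np.zeros((n, 3))
    if gyro is None:
        gyro = np.zeros((n, 3))
    return CleanStream(
        t=np.arange(n) * dt,
        accel=np.asarray(accel, dtype=float),
        gyro=np.asarray(gyro, dtype=float),
        heading=heading_unwrapped % 360.0,
        heading_unwrapped=heading_unwrapped,
        sample_period_s=dt,
    )


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless_stream(protocol, rng):
    """A perfectly clean single-movement response to trial 1."""
    return simulate_trial_response(
        make_profile(),
        protocol[0],
        ReferencePoint(heading_deg=90.0),
        rng,
        noise=NOISELESS,
    )
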