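import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import fallradar as fr

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def radar_config() -> fr.RadarConfig:
    """Full-size default radar (5 s window, 12800 chirps)."""
    return fr.RadarConfig()


@pytest.fixture(scope="session")
def small_radar() -> fr.RadarConfig:
    """Short 1.2 s window for cheap unit tests."""
    return fr.RadarConfig(n_frames=24)


@pytest.fixture(scope="session")
def quiet() -> fr.NoiseSpec:
    """No impairments at all."""
    return fr.NoiseSpec(snr_db=300.0, clutter_amplitude=0.0, outlier_rate=0.0)


def static_trajectory(distance: float, duration: float = 6.0,
                      label: str = "nonmotion_fall") -> fr.Trajectory:
    """A target frozen at a fixed range (fall pushed past the window)."""
    return fr.trajectory_template(
        label, "static", walk_speed=0.0, seed=0, duration=duration,
        fall_onset=duration + 1.0, fall_duration=1.0,
        start_distance=distance)


def constant_rate_trajectory(d0: float, rate: float,
                             duration: float = 6.0) -> fr.Trajectory:
    """Linear range ramp d(t) = d0 + rate * t (no fall inside window)."""
    traj = static_trajectory(d0, duration)
    return fr.Trajectory(
        label=traj.label, approach=traj.approach,
        d_of_t=lambda t: d0 + rate * np.asarray(t, float),
        subject_height=traj.subject_height, walk_speed=abs(rate),
        fall_onset=traj.fall_onset, fall_duration=traj.fall_duration,
        duration=duration, start_distance=d0, fall_excursion=0.0)
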