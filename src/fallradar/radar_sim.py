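"""Synthetic FMCW echoes of walking-then-falling subjects.

The generator produces class-labeled radial trajectories and the complex
baseband data cubes a single-TX/single-RX FMCW radar would record for
them.  A person is modeled as one torso-dominant point scatterer whose
radial distance d(t) follows one of five templates:

* ``forward_fall`` / ``left_fall``: the walk-phase range trend simply
  steepens during the fall (monotone range, Doppler keeps its sign and
  grows); the forward excursion is larger than the left one.
* ``backward_fall`` / ``right_fall``: the range trend reverses at fall
  onset (Doppler changes sign); backward excursion exceeds right.
* ``nonmotion_fall``: stationary until onset, then a monotone excursion
  (zero Doppler before the fall).

Fall excursions scale linearly with subject height (taller subjects move
further while falling).  Each chirp ``m`` of the cube carries a complex
exponential at the beat frequency of d(t_m) whose slow-time phase
advances as 4*pi*fc*d(t_m)/c, which is what encodes Doppler: the
instantaneous slow-time frequency is (2*fc/c)*dd/dt, negative while
approaching the radar.  Complex white Gaussian noise and a static
zero-Doppler clutter reflector are added on top; sparse speckle
outliers for the PFE stage to remove are injected later, into the
feature maps (`inject_outliers`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np
import pandas as pd

from .config import (APPROACHES, C_LIGHT, FALL_LABELS, DatasetConfig,
                     NoiseSpec, RadarConfig)

# Fall-phase radial excursion (m) for a 1.75 m subject.
FALL_EXCURSION_M = {
    "forward_fall": 0.9,
    "backward_fall": 0.7,
    "left_fall": 0.3,
    "right_fall": 0.25,
    "nonmotion_fall": 0.5,
}
REFERENCE_HEIGHT_M = 1.75
MIN_RANGE_M = 0.2  # keep the target strictly in front of the radar


class TrajectoryError(ValueError):
    pass


@dataclass
class Trajectory:
    """A radial distance-vs-time function with its class label."""

    label: str
    approach: str
    d_of_t: Callable[[np.ndarray], np.ndarray]
    subject_height: float
    walk_speed: float
    fall_onset: float
    fall_duration: float
    duration: float
    start_distance: float
    fall_excursion: float

    def sample(self, t: np.ndarray) -> np.ndarray:
        d = np.asarray(self.d_of_t(np.asarray(t, dtype=np.float64)))
        if not np.all(np.isfinite(d)) or np.any(d <= 0):
            raise TrajectoryError("trajectory leaves the positive range axis")
        return d


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def trajectory_template(
    label: str,
    approach: str,
    subject_height: float = 1.75,
    walk_speed: float = 1.0,
    seed: int = 0,
    *,
    duration: float = 5.0,
    fall_onset: float | None = None,
    fall_duration: float | None = None,
    start_distance: float | None = None,
    max_range: float = 7.0,
) -> Trajectory:
    """Build a seeded class-template trajectory.

    Walk speed, fall onset/duration and excursion receive small seeded
    jitter.  The start distance is drawn (or clamped) so that the range
    stays inside (MIN_RANGE_M, max_range) for the whole window.
    """
    if label not in FALL_LABELS:
        raise TrajectoryError(
            f"unknown label {label!r}; expected one of {FALL_LABELS}")
    if approach not in APPROACHES:
        raise TrajectoryError(
            f"unknown approach {approach!r}; expected one of {APPROACHES}")
    if label == "nonmotion_fall":
        if approach != "static":
            raise TrajectoryError("nonmotion_fall requires approach='static'")
    elif approach == "static":
        raise TrajectoryError(f"{label} requires a moving approach")
    if not 1.4 <= subject_height <= 2.1:
        raise TrajectoryError("subject_height must be in [1.4, 2.1] m")

    rng = np.random.default_rng(seed)
    v = float(walk_speed) * rng.uniform(0.9, 1.1)
    onset = (float(fall_onset) if fall_onset is not None
             else rng.uniform(1.8, 3.0))
    fdur = (float(fall_duration) if fall_duration is not None
            else rng.uniform(0.6, 1.2))
    if onset <= 0 or fdur <= 0:
        raise TrajectoryError("fall onset/duration must be positive")
    exc = (FALL_EXCURSION_M[label] * (subject_height / REFERENCE_HEIGHT_M)
           * rng.uniform(0.9, 1.1))

    if label == "nonmotion_fall":
        v_signed = 0.0
        exc_signed = exc * (1.0 if rng.random() < 0.5 else -1.0)
        d0 = (float(start_distance) if start_distance is not None
              else rng.uniform(2.5, 5.5))
    else:
        toward = approach == "toward_radar"
        v_signed = -v if toward else v
        if label in ("forward_fall", "left_fall"):
            # fall continues the walk trend
            exc_signed = -exc if toward else exc
        else:
            # backward/right: trend reverses at onset
            exc_signed = exc if toward else -exc
        if start_distance is not None:
            d0 = float(start_distance)
        elif toward:
            d0 = rng.uniform(4.6, 6.0)
        else:
            d0 = rng.uniform(1.2, 2.2)

    # worst-case range over the window, clamp d0 to keep it in bounds
    drift = v_signed * onset
    lo = d0 + min(0.0, drift) + min(0.0, exc_signed)
    hi = d0 + max(0.0, drift) + max(0.0, exc_signed)
    if lo < MIN_RANGE_M:
        d0 += MIN_RANGE_M - lo
    elif hi > max_range:
        d0 -= hi - max_range
        if d0 + min(0.0, drift) + min(0.0, exc_signed) < MIN_RANGE_M:
            raise TrajectoryError("trajectory cannot fit inside radar range")

    def d_of_t(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        walk = d0 + v_signed * np.minimum(t, onset)
        fall = exc_signed * _smoothstep((t - onset) / fdur)
        return walk + fall

    return Trajectory(
        label=label, approach=approach, d_of_t=d_of_t,
        subject_height=float(subject_height), walk_speed=v,
        fall_onset=onset, fall_duration=fdur, duration=float(duration),
        start_distance=d0, fall_excursion=abs(exc_signed),
    )


def beat_frequency(distance_m, config: RadarConfig):
    """Beat frequency fb = beta * 2d/c of a target at ``distance_m``."""
    d = np.asarray(distance_m, dtype=np.float64)
    if np.any(d <= 0):
        raise ValueError("distance must be > 0")
    fb = config.chirp_slope * 2.0 * d / C_LIGHT
    return float(fb) if np.isscalar(distance_m) else fb


@dataclass
class DataCube:
    """Complex baseband matrix, fast time x slow time."""

    samples: np.ndarray          # (samples_per_chirp, n_chirps) complex64
    config: RadarConfig
    trajectory_id: str | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = (self.config.samples_per_chirp, self.config.n_chirps)
        if self.samples.shape != expect:
            raise ValueError(
                f"cube shape {self.samples.shape} != config {expect}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("cube contains non-finite samples")


def chirp_times(config: RadarConfig) -> np.ndarray:
    """Start time of every chirp, frame gaps included (s)."""
    frame_starts = np.arange(config.n_frames) * config.frame_period
    within = np.arange(config.chirps_per_frame) * config.chirp_interval
    return (frame_starts[:, None] + within[None, :]).ravel()


def _unit_phasor_powers(step_phase: np.ndarray, n: int) -> np.ndarray:
    """exp(1j * outer(arange(n), step_phase)) as complex64, shape (n, M).

    Built by repeated doubling (n-1 complex multiplies per column instead
    of n transcendental calls), accurate to ~1e-5 for n <= 512.
    """
    m = step_phase.shape[0]
    out = np.empty((n, m), dtype=np.complex64)
    out[0] = 1.0
    phase = step_phase.astype(np.float64)
    half = 1
    while half < n:
        # exp of the doubled phase is recomputed exactly, so rounding does
        # not compound across doubling steps
        c = np.exp(1j * (phase * half)).astype(np.complex64)
        k = min(half, n - half)
        np.multiply(out[:k], c, out=out[half:half + k])
        half *= 2
    return out


def synthesize_cube(
    trajectory: Trajectory,
    config: RadarConfig,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    trajectory_id: str | None = None,
) -> DataCube:
    """Render the baseband data cube of one trajectory.

    Chirp m at slow time t_m holds ``a(d) * exp(1j*(2*pi*fb(d)*t_fast +
    4*pi*fc*d/c))`` with a(d) = amplitude/d^2, plus (optionally) complex
    AWGN at ``noise.snr_db`` relative to the mean echo sample power and
    a static clutter exponential.  Bit-reproducible from ``seed``.
    """
    if trajectory.duration < config.duration - 1e-9:
        raise ValueError(
            f"trajectory ({trajectory.duration:.3g} s) shorter than the "
            f"observation window ({config.duration:.3g} s)")
    n = config.samples_per_chirp
    t_m = chirp_times(config)
    d = trajectory.sample(t_m)
    # continuity guard: per-chirp range step bounded by 10x the walk bound
    step_bound = 10.0 * max(trajectory.walk_speed, 2.0) * config.frame_period
    if np.abs(np.diff(d)).max() > step_bound:
        raise TrajectoryError("trajectory is discontinuous at chirp scale")

    fb = config.chirp_slope * 2.0 * d / C_LIGHT
    step_phase = (2.0 * np.pi * fb / config.sample_rate).astype(np.float64)
    cube = _unit_phasor_powers(step_phase, n)          # (n, M)
    amp = amplitude / d ** 2
    slow = amp * np.exp(1j * (4.0 * np.pi * config.start_frequency / C_LIGHT)
                        * d)
    cube *= slow.astype(np.complex64)[None, :]

    rng = np.random.Generator(np.random.PCG64DXSM(seed))
    if noise is not None:
        if noise.clutter_amplitude > 0:
            fb_c = config.chirp_slope * 2.0 * noise.clutter_range_m / C_LIGHT
            prof = (noise.clutter_amplitude
                    * np.exp(1j * (2.0 * np.pi * fb_c / config.sample_rate
                                   * np.arange(n)
                                   + rng.uniform(0, 2 * np.pi))))
            cube += prof.astype(np.complex64)[:, None]
        p_sig = float(np.mean(amp ** 2)) if amplitude != 0 else 1.0
        sigma = np.sqrt(p_sig / 10.0 ** (noise.snr_db / 10.0) / 2.0)
        wn = rng.standard_normal((2, n, cube.shape[1]), dtype=np.float32)
        cube += (sigma * wn[0]).astype(np.float32) \
            + 1j * (sigma * wn[1]).astype(np.float32)

    return DataCube(samples=cube, config=config, seed=seed,
                    trajectory_id=trajectory_id,
                    extras={"label": trajectory.label,
                            "approach": trajectory.approach})


def inject_outliers(
    values: np.ndarray, rate: float, gain_db: float, seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Sprinkle speckle outliers over a dB feature map.

    Each cell independently becomes an outlier with probability ``rate``;
    outliers are set to ``mean(values) + gain_db``.  Returns the
    corrupted copy and the boolean injection mask.
    """
    if not 0.0 <= rate <= 0.05:
        raise ValueError("rate must be in [0, 0.05]")
    rng = np.random.Generator(np.random.PCG64DXSM(seed))
    mask = rng.random(values.shape) < rate
    out = values.copy()
    out[mask] = values.mean() + gain_db
    return out, mask


# ---------------------------------------------------------------------------
# dataset generation

def build_manifest(
    n_per_class: int,
    seed: int,
    dataset: DatasetConfig | None = None,
) -> pd.DataFrame:
    """Balanced, seeded dataset manifest.

    Motion classes alternate toward/away approaches; heights are drawn
    uniformly from ``dataset.height_range``.  Each row carries the seeds
    for its trajectory and its cube, derived from the master seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    ds = dataset or DatasetConfig()
    rows = []
    i = 0
    for label in FALL_LABELS:
        for j in range(n_per_class):
            ss = np.random.SeedSequence([int(seed), i])
            tseed, cseed, hseed = (int(s) % 2**31
                                   for s in ss.generate_state(3))
            h_rng = np.random.default_rng(hseed)
            height = float(h_rng.uniform(*ds.height_range))
            if label == "nonmotion_fall":
                approach = "static"
            else:
                approach = "toward_radar" if j % 2 == 0 else "away_from_radar"
            rows.append({
                "sample_id": f"s{i:05d}", "label": label,
                "approach": approach, "height_m": round(height, 4),
                "seed": tseed, "cube_seed": cseed,
            })
            i += 1
    return pd.DataFrame(rows)


def trajectory_from_row(row, dataset: DatasetConfig | None = None,
                        duration: float = 5.0) -> Trajectory:
    ds = dataset or DatasetConfig()
    walk = 0.0 if row["label"] == "nonmotion_fall" else ds.walk_speed
    return trajectory_template(
        row["label"], row["approach"], subject_height=row["height_m"],
        walk_speed=walk, seed=int(row["seed"]), duration=duration)


def iter_dataset(
    manifest: pd.DataFrame,
    config: RadarConfig,
    noise: NoiseSpec | None = None,
    dataset: DatasetConfig | None = None,
) -> Iterator[tuple[DataCube, str]]:
    """Stream (cube, label) pairs for a manifest, one cube in memory at
    a time."""
    for _, row in manifest.iterrows():
        traj = trajectory_from_row(row, dataset, duration=config.duration)
        cube = synthesize_cube(traj, config, noise, seed=int(row["cube_seed"]),
                               trajectory_id=row["sample_id"])
        yield cube, row["label"]


def generate_dataset(
    n_per_class: int,
    config: RadarConfig,
    noise: NoiseSpec | None = None,
    height_range: tuple[float, float] = (1.55, 1.90),
    seed: int = 0,
) -> tuple[list[tuple[DataCube, str]], pd.DataFrame]:
    """Materialize a balanced cube dataset plus its manifest.

    Convenience wrapper over `build_manifest` + `iter_dataset`; for large
    datasets prefer streaming with `iter_dataset` (cubes are big).
    """
    ds = DatasetConfig(n_per_class=n_per_class, height_range=height_range)
    manifest = build_manifest(n_per_class, seed, ds)
    pairs = list(iter_dataset(manifest, config, noise, ds))
    return pairs, manifest
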