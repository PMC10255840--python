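"""Configuration objects for the fall-direction-detection pipeline.

Every stage of the pipeline (echo simulation, map formation, PFE
denoising, CNN training) is driven by a small dataclass defined here.
`RunConfig` bundles them and round-trips through a YAML file so that a
whole experiment is reconstructible from ``(config, master_seed)``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

C_LIGHT = 299_792_458.0  # m/s

FALL_LABELS = (
    "forward_fall",
    "backward_fall",
    "left_fall",
    "right_fall",
    "nonmotion_fall",
)
APPROACHES = ("toward_radar", "away_from_radar", "static")


class ConfigError(ValueError):
    """Raised when a configuration block fails validation."""


@dataclass
class RadarConfig:
    """FMCW chirp/frame parameters.

    Defaults follow a 60 GHz radar sweeping 3.015 GHz at 50.259 MHz/us:
    256 samples per chirp at 5 MHz, 128 chirps per frame, 100 us idle
    between chirps, four RX / one TX antennas.  ``frame_period`` is the
    wall-clock spacing of frame starts; the 128-chirp burst occupies
    ``chirps_per_frame * chirp_interval`` of it and the radar idles for
    the remainder.
    """

    start_frequency: float = 60e9       # Hz
    bandwidth: float = 3.015e9          # Hz
    chirp_slope: float = 50.259e12      # Hz/s
    chirp_duration: float = 60e-6       # s (ramp end time)
    sample_rate: float = 5e6            # Hz
    samples_per_chirp: int = 256
    chirps_per_frame: int = 128
    n_frames: int = 100
    idle_time: float = 100e-6           # s, between chirps
    frame_period: float = 0.05          # s, frame start to frame start
    rx_channels: int = 4
    tx_channels: int = 1

    def __post_init__(self) -> None:
        for name in ("start_frequency", "bandwidth", "chirp_slope",
                     "chirp_duration", "sample_rate", "idle_time",
                     "frame_period"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"RadarConfig.{name} must be > 0")
        for name in ("samples_per_chirp", "chirps_per_frame", "n_frames",
                     "rx_channels", "tx_channels"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigError(f"RadarConfig.{name} must be an int >= 1")
        implied = self.bandwidth / self.chirp_duration
        if abs(self.chirp_slope - implied) > 0.01 * implied:
            warnings.warn(
                f"chirp_slope {self.chirp_slope:.4g} deviates >1% from "
                f"bandwidth/chirp_duration = {implied:.4g}", stacklevel=2)
        if self.samples_per_chirp / self.sample_rate > self.chirp_duration:
            raise ConfigError(
                "samples_per_chirp / sample_rate exceeds chirp_duration")
        burst = self.chirps_per_frame * self.chirp_interval
        if burst > self.frame_period:
            raise ConfigError(
                f"chirp burst ({burst:.4g} s) does not fit in frame_period "
                f"({self.frame_period:.4g} s)")

    @property
    def chirp_interval(self) -> float:
        """Chirp start-to-start spacing within a burst (s)."""
        return self.chirp_duration + self.idle_time

    @property
    def n_chirps(self) -> int:
        """Total chirps in the record."""
        return self.chirps_per_frame * self.n_frames

    @property
    def duration(self) -> float:
        """Wall-clock span of the record (s)."""
        return self.n_frames * self.frame_period

    @property
    def range_bin_m(self) -> float:
        """Range spacing of one fast-time DFT bin (m), from d = c*fb/(2*beta)
        with fb quantized to sample_rate / samples_per_chirp."""
        dfb = self.sample_rate / self.samples_per_chirp
        return C_LIGHT * dfb / (2.0 * self.chirp_slope)

    @property
    def max_range_m(self) -> float:
        """Unambiguous range at the fast-time Nyquist beat (m)."""
        return C_LIGHT * (self.sample_rate / 2.0) / (2.0 * self.chirp_slope)


@dataclass
class NoiseSpec:
    """Additive impairments of the synthesized echo.

    snr_db: ratio of mean point-echo sample power to complex-noise power.
    clutter_amplitude: amplitude of a static zero-Doppler reflector
        (same unit as the target's 1/d^2 amplitude, i.e. a unit target
        at 1 m); 0 disables it.
    outlier_rate / outlier_gain: Bernoulli rate per feature-map cell and
    dB offset above the map mean for speckle outliers injected into the
    rendered maps (post-map, pre-PFE).
    """

    snr_db: float = 15.0
    clutter_amplitude: float = 0.02
    clutter_range_m: float = 1.2
    outlier_rate: float = 0.005
    outlier_gain_db: float = 20.0

    def __post_init__(self) -> None:
        import math
        if not math.isfinite(self.snr_db):
            raise ConfigError("snr_db must be finite")
        if not 0.0 <= self.outlier_rate <= 0.05:
            raise ConfigError("outlier_rate must be in [0, 0.05]")
        if self.clutter_amplitude < 0 or self.clutter_range_m <= 0:
            raise ConfigError("clutter parameters must be non-negative")


@dataclass
class StftParams:
    """Slow-time STFT numerics for the Doppler-time map."""

    window_length: int = 32   # chirps
    hop: int = 32             # chirps
    window_shape: str = "hann"
    fft_length: int = 64      # bins

    def __post_init__(self) -> None:
        if not (0 < self.hop <= self.window_length):
            raise ConfigError("need 0 < hop <= window_length")
        if self.fft_length < self.window_length:
            raise ConfigError("fft_length must be >= window_length")


@dataclass
class PfeParams:
    """Pattern-feature-extraction parameters.

    a: adaptive threshold weight, Pth = (1-a)*mean + a*(max+min).
    hampel_half_window / hampel_nth: Hampel filter K and nth.
    floor_policy: value given to sub-threshold cells ("min" only).
    """

    a: float = 0.30
    hampel_half_window: int = 5
    hampel_nth: float = 3.0
    floor_policy: str = "min"

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ConfigError("a must be in [0, 1]")
        if self.hampel_half_window < 1:
            raise ConfigError("hampel_half_window must be >= 1")
        if self.hampel_nth <= 0:
            raise ConfigError("hampel_nth must be > 0")
        if self.floor_policy != "min":
            raise ConfigError("floor_policy: only 'min' is supported")


@dataclass
class TrainConfig:
    """Optimization protocol: Adam at lr 5e-4, 50 epochs, step-decay."""

    learning_rate: float = 5e-4
    epochs: int = 50
    lr_step_size: int = 10
    lr_gamma: float = 0.5
    batch_size: int = 32
    split_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ConfigError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if not 0.0 < self.split_fraction < 1.0:
            raise ConfigError("split_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")


@dataclass
class DatasetConfig:
    """Size/diversity of the synthetic dataset."""

    n_per_class: int = 20
    height_range: tuple[float, float] = (1.55, 1.90)
    walk_speed: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.height_range
        if not (1.4 <= lo <= hi <= 2.1):
            raise ConfigError("height_range must lie within [1.4, 2.1] m")
        if self.n_per_class < 1:
            raise ConfigError("n_per_class must be >= 1")


@dataclass
class RunConfig:
    """Top-level bundle, YAML round-trippable."""

    radar: RadarConfig = field(default_factory=RadarConfig)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    stft: StftParams = field(default_factory=StftParams)
    pfe: PfeParams = field(default_factory=PfeParams)
    train: TrainConfig = field(default_factory=TrainConfig)
    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    workdir: str = "runs/default"
    master_seed: int = 42

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dataset"]["height_range"] = list(d["dataset"]["height_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        blocks = {
            "radar": RadarConfig, "noise": NoiseSpec, "stft": StftParams,
            "pfe": PfeParams, "train": TrainConfig, "dataset": DatasetConfig,
        }
        for key, typ in blocks.items():
            if key in kw and isinstance(kw[key], dict):
                sub = dict(kw[key])
                if key == "dataset" and "height_range" in sub:
                    sub["height_range"] = tuple(sub["height_range"])
                kw[key] = typ(**sub)
        return cls(**kw)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
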