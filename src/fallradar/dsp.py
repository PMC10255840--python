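"""Range-time and Doppler-time maps from baseband data cubes.

The RT map is the per-chirp DFT along fast time (power in dB over range
bins x time); the DT map is a short-time Fourier transform along slow
time of the range-gated, coherently summed range profiles (magnitude in
dB over Doppler bins x time).  Range bins are calibrated through the
distance equation d = c*fb/(2*beta); Doppler is signed so that a target
approaching the radar (dd/dt < 0) shows negative frequencies.

Chirps of consecutive frames are concatenated on one slow-time axis and
the inter-frame idle is ignored for STFT bin spacing; with the default
window/hop of 32 chirps no window straddles a 128-chirp frame boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import scipy.fft
from scipy.signal import get_window

from .config import C_LIGHT, RadarConfig, StftParams
from .radar_sim import DataCube, chirp_times

DB_FLOOR = 60.0  # maps are floored at max - 60 dB


@dataclass
class FeatureMap:
    """A real power map (RT or DT) with calibrated axes."""

    values: np.ndarray       # (feature_bins, time_bins), dB
    kind: str                # "RT" | "DT"
    feature_axis: np.ndarray  # m (RT) or Hz (DT)
    time_axis: np.ndarray    # s
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("RT", "DT"):
            raise ValueError("kind must be 'RT' or 'DT'")
        if self.values.shape != (len(self.feature_axis), len(self.time_axis)):
            raise ValueError("axis lengths do not match map dimensions")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("map contains non-finite values")
        for ax in (self.feature_axis, self.time_axis):
            if len(ax) > 1 and not np.all(np.diff(ax) > 0):
                raise ValueError("axes must be strictly increasing")

    def ridge(self) -> np.ndarray:
        """Per-time-bin argmax on the feature axis (m or Hz)."""
        return self.feature_axis[np.argmax(self.values, axis=0)]


def _to_db(power: np.ndarray, floor_db: float | None = DB_FLOOR) -> np.ndarray:
    db = 10.0 * np.log10(np.maximum(power, np.finfo(np.float64).tiny))
    if floor_db is not None:
        db = np.maximum(db, db.max() - floor_db)
    return db.astype(np.float32)


def range_axis(config: RadarConfig, n_bins: int) -> np.ndarray:
    """Distance of fast-time DFT bins 0..n_bins-1 via d = c*fb/(2*beta)."""
    dfb = config.sample_rate / config.samples_per_chirp
    return np.arange(n_bins) * C_LIGHT * dfb / (2.0 * config.chirp_slope)


def range_profiles(cube: DataCube, *, clutter_suppress: bool = False,
                   onesided: bool = True) -> np.ndarray:
    """Complex fast-time DFT of every chirp, shape (bins, n_chirps)."""
    x = scipy.fft.fft(np.ascontiguousarray(cube.samples.T), axis=1).T
    if clutter_suppress:
        x = x - x.mean(axis=1, keepdims=True)
    if onesided:
        x = x[: cube.config.samples_per_chirp // 2]
    return x


def range_time_map(
    cube: DataCube,
    *,
    clutter_suppress: bool = False,
    decimate: str | None = "frame",
    db: bool = True,
    onesided: bool = True,
) -> FeatureMap:
    """Range-time power map of a cube.

    ``decimate="frame"`` averages power over each frame's chirp burst so
    the time axis has one bin per frame; ``None`` keeps per-chirp
    columns.  ``db=False`` returns linear power with no floor (useful
    for energy bookkeeping).
    """
    cfg = cube.config
    if cube.samples.size == 0:
        raise ValueError("empty cube")
    prof = range_profiles(cube, clutter_suppress=clutter_suppress,
                          onesided=onesided)
    power = (prof.real.astype(np.float64) ** 2
             + prof.imag.astype(np.float64) ** 2)
    if decimate == "frame":
        power = power.reshape(power.shape[0], cfg.n_frames,
                              cfg.chirps_per_frame).mean(axis=2)
        t = (np.arange(cfg.n_frames) + 0.5) * cfg.frame_period
    elif decimate is None:
        t = chirp_times(cfg)
    else:
        raise ValueError("decimate must be 'frame' or None")
    values = _to_db(power) if db else power.astype(np.float32)
    return FeatureMap(
        values=values, kind="RT",
        feature_axis=range_axis(cfg, power.shape[0]), time_axis=t,
        provenance={"cube": cube.trajectory_id, "seed": cube.seed,
                    "clutter_suppress": clutter_suppress,
                    "decimate": decimate, "db": db})


def active_range_gate(prof: np.ndarray) -> np.ndarray:
    """Boolean gate of range bins whose slow-time power variance exceeds
    the median across bins (static clutter and empty bins drop out)."""
    var = np.var(np.abs(prof), axis=1)
    gate = var > np.median(var)
    if not gate.any():
        gate[:] = True
    return gate


def doppler_time_map(cube: DataCube, stft: StftParams | None = None,
                     *, gate: np.ndarray | None = None) -> FeatureMap:
    """Doppler-time magnitude map of a cube.

    The complex range profiles inside the active range gate are summed
    per chirp into one slow-time signal, windowed, and Fourier
    transformed; the zero-Doppler bin sits at the center of the axis,
    which spans +-1/(2 * chirp interval).
    """
    cfg = cube.config
    stft = stft or StftParams()
    m = cfg.n_chirps
    if stft.window_length > m:
        raise ValueError("STFT window longer than the chirp record")
    prof = range_profiles(cube)
    sel = gate if gate is not None else active_range_gate(prof)
    z = prof[sel].sum(axis=0)

    win = get_window(stft.window_shape, stft.window_length,
                     fftbins=True).astype(np.float64)
    starts = np.arange(0, m - stft.window_length + 1, stft.hop)
    frames = np.lib.stride_tricks.sliding_window_view(
        z, stft.window_length)[starts] * win
    spec = scipy.fft.fftshift(
        scipy.fft.fft(frames, n=stft.fft_length, axis=1), axes=1).T
    freq = scipy.fft.fftshift(
        scipy.fft.fftfreq(stft.fft_length, d=cfg.chirp_interval))
    # Doppler bin spacing uses the within-burst chirp interval; column
    # timestamps are wall-clock chirp times so RT and DT maps share one
    # physical time axis even when frames are duty-cycled.
    t = chirp_times(cfg)[np.minimum(starts + stft.window_length // 2,
                                    m - 1)]
    values = _to_db(np.abs(spec))  # magnitude, not power, for DT
    return FeatureMap(
        values=values, kind="DT", feature_axis=freq, time_axis=t,
        provenance={"cube": cube.trajectory_id, "seed": cube.seed,
                    "stft": {"window_length": stft.window_length,
                             "hop": stft.hop, "window_shape":
                             stft.window_shape,
                             "fft_length": stft.fft_length},
                    "n_gated_bins": int(sel.sum())})


def range_from_beat(fb_hz, config: RadarConfig):
    """Distance d = c*fb/(2*beta) of a beat frequency."""
    fb = np.asarray(fb_hz, dtype=np.float64)
    if np.any(fb < 0):
        raise ValueError("beat frequency must be >= 0")
    d = C_LIGHT * fb / (2.0 * config.chirp_slope)
    return float(d) if np.isscalar(fb_hz) else d


def render(fmap: FeatureMap, path: str | Path) -> None:
    """Write the map as an 8-bit grayscale PNG (linear min-max scaling,
    feature axis upward)."""
    from PIL import Image

    v = fmap.values
    span = v.max() - v.min()
    scaled = (v - v.min()) / span if span > 0 else np.full_like(v, 0.5)
    img = (255.0 * scaled[::-1]).astype(np.uint8)
    Image.fromarray(img, mode="L").save(str(path))


# ---------------------------------------------------------------------------
# HDF5 persistence

def save_cubes(path: str | Path, cubes: list[DataCube]) -> None:
    with h5py.File(path, "w") as f:
        for i, cube in enumerate(cubes):
            g = f.create_group(cube.trajectory_id or f"s{i:05d}")
            g.create_dataset("samples", data=cube.samples)
            g.attrs["seed"] = cube.seed
            for k, v in vars(cube.config).items():
                g.attrs[k] = v
            for k, v in cube.extras.items():
                g.attrs[f"extra_{k}"] = v


def load_cubes(path: str | Path) -> list[DataCube]:
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            cfg_fields = {k: (int(v) if isinstance(v, np.integer) else
                              float(v))
                          for k, v in g.attrs.items()
                          if not k.startswith("extra_") and k != "seed"}
            cfg = RadarConfig(**cfg_fields)
            extras = {k[6:]: (v if not isinstance(v, bytes) else v.decode())
                      for k, v in g.attrs.items() if k.startswith("extra_")}
            out.append(DataCube(samples=g["samples"][()], config=cfg,
                                trajectory_id=name,
                                seed=int(g.attrs["seed"]), extras=extras))
    return out


def save_maps(path: str | Path, maps: dict[str, dict[str, FeatureMap]]) -> None:
    """Persist {sample_id: {"rt": FeatureMap, "dt": FeatureMap}}."""
    with h5py.File(path, "w") as f:
        for sid, pair in maps.items():
            g = f.create_group(sid)
            for key, fmap in pair.items():
                sub = g.create_group(key)
                sub.create_dataset("values", data=fmap.values)
                sub.create_dataset("feature_axis", data=fmap.feature_axis)
                sub.create_dataset("time_axis", data=fmap.time_axis)
                sub.attrs["kind"] = fmap.kind
                sub.attrs["provenance"] = json.dumps(fmap.provenance)


def load_maps(path: str | Path) -> dict[str, dict[str, FeatureMap]]:
    out: dict[str, dict[str, FeatureMap]] = {}
    with h5py.File(path, "r") as f:
        for sid in sorted(f):
            out[sid] = {}
            for key in f[sid]:
                sub = f[sid][key]
                out[sid][key] = FeatureMap(
                    values=sub["values"][()], kind=str(sub.attrs["kind"]),
                    feature_axis=sub["feature_axis"][()],
                    time_axis=sub["time_axis"][()],
                    provenance=json.loads(sub.attrs["provenance"]))
    return out
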