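"""Pattern feature extraction: adaptive power threshold + Hampel filter.

Feature maps carry ambient noise and isolated speckle outliers that
confuse a downstream image classifier.  PFE cleans a map in two passes:

1. An adaptive power threshold ``Pth = (1-a)*mean(P) + a*(max(P)+min(P))``
   floors every cell below Pth to the map minimum, keeping only the
   high-power feature region.  ``a`` trades off how aggressive the cut
   is; at a=0 the threshold is the map mean, at a=1 it is max+min.
2. A Hampel filter slides a window of half-width K along each row's time
   series, estimates the local scale as 1.4826x the median absolute
   deviation, and replaces any sample deviating from the window median
   by more than ``nth`` of that scale with the median itself.  Isolated
   speckles that survived the threshold are pulled back to the local
   level; smooth ridges pass through untouched.
"""

from __future__ import annotations

import numpy as np

from .config import PfeParams
from .dsp import FeatureMap

MAD_SCALE = 1.4826  # Gaussian-consistency factor for the MAD


def adaptive_threshold(values: np.ndarray, a: float,
                       ) -> tuple[float, np.ndarray]:
    """Apply the adaptive power threshold to a map.

    Returns ``(Pth, masked)`` where cells below Pth are set to the map
    minimum and cells at or above it are untouched.
    """
    if not 0.0 <= a <= 1.0:
        raise ValueError("a must be in [0, 1]")
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0 or not np.all(np.isfinite(v)):
        raise ValueError("map must be non-empty and finite")
    pth = (1.0 - a) * v.mean() + a * (v.max() + v.min())
    masked = np.where(v < pth, v.min(), v).astype(values.dtype)
    return float(pth), masked


def _hampel_stats(window: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median and MAD scale along the last axis."""
    med = np.median(window, axis=-1)
    mad = np.median(np.abs(window - med[..., None]), axis=-1)
    return med, MAD_SCALE * mad


def hampel_filter_rows(values: np.ndarray, k: int, nth: float,
                       ) -> tuple[np.ndarray, int]:
    """Hampel-filter every row of a 2D array along its columns.

    Windows are truncated at the boundaries.  Replacement uses a strict
    inequality, so when the local MAD is zero any sample exactly at the
    median survives while true spikes are replaced.  Returns the
    filtered array and the number of replaced cells.
    """
    v = np.asarray(values)
    if v.ndim != 2:
        raise ValueError("expected a 2D array")
    n = v.shape[1]
    if k < 1:
        raise ValueError("k must be >= 1")
    med = np.empty_like(v, dtype=np.float64)
    scale = np.empty_like(v, dtype=np.float64)
    if n >= 2 * k + 1:
        win = np.lib.stride_tricks.sliding_window_view(v, 2 * k + 1, axis=1)
        med[:, k:n - k], scale[:, k:n - k] = _hampel_stats(win)
        edges = list(range(k)) + list(range(n - k, n))
    else:
        edges = range(n)
    for j in edges:
        lo, hi = max(0, j - k), min(n, j + k + 1)
        med[:, j], scale[:, j] = _hampel_stats(v[:, lo:hi])
    out = v.copy()
    replace = np.abs(v - med) > nth * scale
    out[replace] = med[replace].astype(v.dtype, copy=False)
    return out, int(replace.sum())


def hampel_filter(series: np.ndarray, k: int = 5, nth: float = 3.0,
                  ) -> np.ndarray:
    """Hampel-filter a 1D series (see `hampel_filter_rows`)."""
    s = np.asarray(series)
    if s.ndim != 1 or s.size < 1:
        raise ValueError("expected a non-empty 1D series")
    out, _ = hampel_filter_rows(s[None, :], k, nth)
    return out[0]


def pfe_clean(fmap: FeatureMap, params: PfeParams | None = None,
              ) -> FeatureMap:
    """Run the full PFE chain on a feature map.

    Thresholds first, then Hampel-filters each feature bin's time series.
    The returned map records ``a``, ``K``, ``nth``, the realized ``Pth``
    and the replacement count in its provenance.
    """
    p = params or PfeParams()
    pth, masked = adaptive_threshold(fmap.values, p.a)
    cleaned, n_replaced = hampel_filter_rows(
        masked, p.hampel_half_window, p.hampel_nth)
    prov = dict(fmap.provenance)
    prov["pfe"] = {
        "a": p.a, "K": p.hampel_half_window, "nth": p.hampel_nth,
        "Pth": pth, "n_replaced": n_replaced,
    }
    return FeatureMap(values=cleaned, kind=fmap.kind,
                      feature_axis=fmap.feature_axis,
                      time_axis=fmap.time_axis, provenance=prov)
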