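"""End-to-end orchestration: cubes -> maps -> PFE -> CNN tensors.

`build_feature_dataset` streams the simulator so that only one data cube
is resident at a time; the persisted artifacts of the CLI pipeline reuse
the same functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (FALL_LABELS, DatasetConfig, NoiseSpec, PfeParams,
                     RadarConfig, StftParams)
from .dsp import FeatureMap, doppler_time_map, range_time_map
from .model import LabeledDataset, preprocess
from .pfe import pfe_clean
from .radar_sim import DataCube, inject_outliers, iter_dataset

LABEL_INDEX = {name: i for i, name in enumerate(FALL_LABELS)}


def featurize_cube(
    cube: DataCube,
    stft: StftParams | None = None,
    pfe: PfeParams | None = None,
    noise: NoiseSpec | None = None,
) -> dict[str, FeatureMap]:
    """RT + DT maps of one cube, with speckle injection and PFE.

    ``noise`` controls post-map outlier injection (seeded from the cube
    seed so the corruption is reproducible); ``pfe=None`` skips the
    cleaning stage, which is the ablation baseline.
    """
    rt = range_time_map(cube)
    dt = doppler_time_map(cube, stft)
    out = {}
    for key, fmap in (("rt", rt), ("dt", dt)):
        if noise is not None and noise.outlier_rate > 0:
            corrupted, mask = inject_outliers(
                fmap.values, noise.outlier_rate, noise.outlier_gain_db,
                seed=(cube.seed + (1 if key == "rt" else 2)) % 2**31)
            fmap = FeatureMap(values=corrupted, kind=fmap.kind,
                              feature_axis=fmap.feature_axis,
                              time_axis=fmap.time_axis,
                              provenance={**fmap.provenance,
                                          "n_outliers": int(mask.sum())})
        if pfe is not None:
            fmap = pfe_clean(fmap, pfe)
        out[key] = fmap
    return out


def build_feature_dataset(
    manifest: pd.DataFrame,
    radar: RadarConfig | None = None,
    noise: NoiseSpec | None = None,
    stft: StftParams | None = None,
    pfe: PfeParams | None = None,
    dataset: DatasetConfig | None = None,
) -> LabeledDataset:
    """Simulate every manifest row and return preprocessed CNN inputs."""
    radar = radar or RadarConfig()
    n = len(manifest)
    x_rt = np.empty((n, 3, 54, 54), dtype=np.float32)
    x_dt = np.empty((n, 3, 54, 54), dtype=np.float32)
    y = np.empty(n, dtype=np.int64)
    for i, (cube, label) in enumerate(
            iter_dataset(manifest, radar, noise, dataset)):
        maps = featurize_cube(cube, stft, pfe, noise)
        x_rt[i] = preprocess(maps["rt"])
        x_dt[i] = preprocess(maps["dt"])
        y[i] = LABEL_INDEX[label]
    return LabeledDataset(x_rt=x_rt, x_dt=x_dt, y=y)


def build_feature_dataset_pair(
    manifest: pd.DataFrame,
    radar: RadarConfig | None = None,
    noise: NoiseSpec | None = None,
    stft: StftParams | None = None,
    pfe: PfeParams | None = None,
    dataset: DatasetConfig | None = None,
) -> tuple[LabeledDataset, LabeledDataset]:
    """PFE-cleaned and raw feature datasets from one simulation pass.

    Both variants see the identical cubes and injected outliers, so the
    comparison isolates the effect of the cleaning stage.
    """
    radar = radar or RadarConfig()
    pfe = pfe or PfeParams()
    n = len(manifest)
    shape = (n, 3, 54, 54)
    clean = LabeledDataset(np.empty(shape, np.float32),
                           np.empty(shape, np.float32),
                           np.empty(n, np.int64))
    raw = LabeledDataset(np.empty(shape, np.float32),
                         np.empty(shape, np.float32),
                         np.empty(n, np.int64))
    for i, (cube, label) in enumerate(
            iter_dataset(manifest, radar, noise, dataset)):
        raw_maps = featurize_cube(cube, stft, None, noise)
        for key, store in (("rt", raw.x_rt), ("dt", raw.x_dt)):
            store[i] = preprocess(raw_maps[key])
        for key, store in (("rt", clean.x_rt), ("dt", clean.x_dt)):
            store[i] = preprocess(pfe_clean(raw_maps[key], pfe))
        clean.y[i] = raw.y[i] = LABEL_INDEX[label]
    return clean, raw
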