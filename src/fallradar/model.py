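"""Dual-branch CNN for fall-direction classification.

Two parallel convolutional branches — one fed the RT map, one the DT map
— each stack Conv(16)-Pool-Conv(32)-Pool-Conv(64)-Pool-Conv(128) with
valid 3x3 kernels and 2x2 pools, so a 54x54x3 input flattens to exactly
1x1152 per branch.  The two feature vectors are concatenated (1x2304)
and a fully connected softmax head scores the five fall classes
(forward/backward/left/right during motion, toward/away merged, plus
fall from a stationary posture).

Training follows a fixed protocol: Adam at learning rate 5e-4, 50
epochs, step-decay schedule (x0.5 every 10 epochs), batch size 32,
stratified 80/20 split, cross-entropy loss.  Everything is seeded and
reproducible run-to-run on one machine.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split

from . import nn
from .config import FALL_LABELS, TrainConfig
from .dsp import FeatureMap


@dataclass
class NetworkSpec:
    """Architecture constants of the dual-branch CNN."""

    input_size: int = 54
    input_channels: int = 3
    conv_channels: tuple[int, ...] = (16, 32, 64, 128)
    kernel: int = 3
    n_classes: int = 5

    def branch_shapes(self) -> list[tuple[int, int]]:
        """(channels, spatial) after every conv stage; pooling follows
        every conv except the last."""
        s = self.input_size
        shapes = []
        for i, ch in enumerate(self.conv_channels):
            s = s - (self.kernel - 1)
            if s < 1:
                raise ValueError(
                    f"conv stage {i + 1}: spatial size collapsed to {s}")
            if i < len(self.conv_channels) - 1:
                if s % 2:
                    raise ValueError(
                        f"pool after conv stage {i + 1}: odd size {s}")
                s //= 2
            shapes.append((ch, s))
        return shapes

    @property
    def flatten_width(self) -> int:
        ch, s = self.branch_shapes()[-1]
        return ch * s * s

    @property
    def merged_width(self) -> int:
        return 2 * self.flatten_width


class DualBranchCNN:
    """Two convolutional branches plus a shared softmax head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0,
                 dtype=np.float32) -> None:
        spec.branch_shapes()  # raises on an inconsistent spec
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self.branch_rt = self._make_branch(rng)
        self.branch_dt = self._make_branch(rng)
        self.head = nn.Linear(spec.merged_width, spec.n_classes, rng,
                              dtype=dtype)

    def _make_branch(self, rng: np.random.Generator) -> nn.Sequential:
        spec = self.spec
        layers: list[nn.Layer] = []
        c_in = spec.input_channels
        for i, c_out in enumerate(spec.conv_channels):
            layers += [nn.Conv2d(c_in, c_out, spec.kernel, rng,
                                 dtype=self.dtype), nn.ReLU()]
            if i < len(spec.conv_channels) - 1:
                layers.append(nn.MaxPool2d())
            c_in = c_out
        layers.append(nn.Flatten())
        return nn.Sequential(layers)

    # -- forward / backward -------------------------------------------------
    def _to_nhwc(self, x: np.ndarray) -> np.ndarray:
        # public tensors are (n, channels, 54, 54); layers run NHWC
        return np.ascontiguousarray(
            np.asarray(x, dtype=self.dtype).transpose(0, 2, 3, 1))

    def forward(self, x_rt: np.ndarray, x_dt: np.ndarray) -> np.ndarray:
        f_rt = self.branch_rt.forward(self._to_nhwc(x_rt))
        f_dt = self.branch_dt.forward(self._to_nhwc(x_dt))
        self._split = f_rt.shape[1]
        return self.head.forward(
            np.concatenate([f_rt, f_dt], axis=1))

    def backward(self, dlogits: np.ndarray) -> None:
        dmerged = self.head.backward(dlogits)
        self.branch_rt.backward(dmerged[:, :self._split])
        self.branch_dt.backward(dmerged[:, self._split:])

    def predict_proba(self, x_rt: np.ndarray, x_dt: np.ndarray,
                      batch_size: int = 128) -> np.ndarray:
        out = []
        for i in range(0, len(x_rt), batch_size):
            out.append(nn.softmax(
                self.forward(x_rt[i:i + batch_size],
                             x_dt[i:i + batch_size]).astype(np.float64)))
        return np.concatenate(out)

    def predict(self, x_rt, x_dt, batch_size: int = 128) -> np.ndarray:
        return self.predict_proba(x_rt, x_dt, batch_size).argmax(axis=1)

    def param_slots(self) -> list[tuple[str, nn.Layer]]:
        slots = list(self.branch_rt.named_params("rt."))
        slots += list(self.branch_dt.named_params("dt."))
        slots += [(f"head.{k}", self.head) for k in self.head.params]
        return slots

    # -- persistence --------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: lyr.params[name.split(".")[-1]]
                for name, lyr in self.param_slots()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, lyr in self.param_slots():
            lyr.params[name.split(".")[-1]] = np.asarray(
                state[name], dtype=np.float32)

    def save(self, path: str | Path,
             train_config: TrainConfig | None = None) -> None:
        path = Path(path)
        np.savez(path, **self.state_dict())
        sidecar = {"network_spec": vars(self.spec) |
                   {"conv_channels": list(self.spec.conv_channels)}}
        if train_config is not None:
            sidecar["train_config"] = vars(train_config)
        path.with_suffix(".json").write_text(
            json.dumps(sidecar, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "DualBranchCNN":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        sd = dict(sidecar["network_spec"])
        sd["conv_channels"] = tuple(sd["conv_channels"])
        net = cls(NetworkSpec(**sd))
        with np.load(path if path.suffix else path.with_suffix(".npz")) as f:
            net.load_state_dict(dict(f))
        return net


def build_network(spec: NetworkSpec | None = None,
                  seed: int = 0) -> DualBranchCNN:
    """Seeded construction of the dual-branch CNN."""
    return DualBranchCNN(spec or NetworkSpec(), seed=seed)


# ---------------------------------------------------------------------------
# preprocessing

def preprocess(fmap: FeatureMap | np.ndarray, size: int = 54,
               channels: int = 3) -> np.ndarray:
    """FeatureMap -> CNN input tensor (channels, size, size) in [0, 1].

    Min-max normalizes (so a constant dB offset cancels), resamples with
    bilinear interpolation, and replicates the grayscale image across
    channels.  A degenerate constant map becomes all 0.5.
    """
    v = np.asarray(fmap.values if isinstance(fmap, FeatureMap) else fmap,
                   dtype=np.float64)
    span = v.max() - v.min()
    if span <= 0:
        warnings.warn("constant feature map; emitting a flat 0.5 image",
                      stacklevel=2)
        img = np.full((size, size), 0.5)
    else:
        v = (v - v.min()) / span
        rows = np.linspace(0, v.shape[0] - 1, size)
        cols = np.linspace(0, v.shape[1] - 1, size)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        img = map_coordinates(v, [rr, cc], order=1, mode="nearest")
    return np.broadcast_to(
        img.astype(np.float32), (channels, size, size)).copy()


@dataclass
class LabeledDataset:
    """Preprocessed image pairs with integer labels."""

    x_rt: np.ndarray   # (n, 3, 54, 54) float32
    x_dt: np.ndarray
    y: np.ndarray      # (n,) int labels into class_names
    class_names: tuple[str, ...] = FALL_LABELS

    def __post_init__(self) -> None:
        n = len(self.y)
        if not (len(self.x_rt) == len(self.x_dt) == n):
            raise ValueError("inputs and labels disagree in length")

    def __len__(self) -> int:
        return len(self.y)


# ---------------------------------------------------------------------------
# training / evaluation

@dataclass
class TrainResult:
    history: pd.DataFrame
    train_idx: np.ndarray
    val_idx: np.ndarray


def stratified_split(y: np.ndarray, split_fraction: float, seed: int,
                     ) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(len(y))
    train_idx, val_idx = train_test_split(
        idx, train_size=split_fraction, stratify=y,
        random_state=int(seed) % 2**31)
    return np.sort(train_idx), np.sort(val_idx)


def train(net: DualBranchCNN, data: LabeledDataset,
          cfg: TrainConfig | None = None) -> TrainResult:
    """Fit the network; returns per-epoch history and the split used.

    The validation split (1 - split_fraction of the data, stratified) is
    never used for updates — it is the held-out set that `evaluate`
    should be pointed at.
    """
    cfg = cfg or TrainConfig()
    if len(np.unique(data.y)) < 2:
        raise ValueError("training needs at least two classes present")
    train_idx, val_idx = stratified_split(
        data.y, cfg.split_fraction, cfg.seed)
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty train or validation split")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.Adam(net.param_slots(), lr=cfg.learning_rate)
    rows = []
    for epoch in range(cfg.epochs):
        opt.lr = nn.step_lr(cfg.learning_rate, epoch,
                            cfg.lr_step_size, cfg.lr_gamma)
        order = rng.permutation(train_idx)
        losses, hits, seen = [], 0, 0
        for i in range(0, len(order), cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            logits = net.forward(data.x_rt[b], data.x_dt[b])
            loss, dlogits = nn.cross_entropy(logits, data.y[b])
            if cfg.learning_rate > 0:
                net.backward(dlogits)
                opt.step()
            losses.append(loss * len(b))
            hits += int((logits.argmax(axis=1) == data.y[b]).sum())
            seen += len(b)
        val_logits = _forward_batched(net, data, val_idx)
        val_loss, _ = nn.cross_entropy(val_logits, data.y[val_idx])
        rows.append({
            "epoch": epoch + 1,
            "lr": opt.lr,
            "train_loss": float(np.sum(losses) / seen),
            "train_acc": hits / seen,
            "val_loss": val_loss,
            "val_acc": float((val_logits.argmax(axis=1)
                              == data.y[val_idx]).mean()),
        })
    return TrainResult(history=pd.DataFrame(rows),
                       train_idx=train_idx, val_idx=val_idx)


def _forward_batched(net: DualBranchCNN, data: LabeledDataset,
                     idx: np.ndarray, batch: int = 128) -> np.ndarray:
    out = [net.forward(data.x_rt[idx[i:i + batch]],
                       data.x_dt[idx[i:i + batch]])
           for i in range(0, len(idx), batch)]
    return np.concatenate(out)


@dataclass
class ClassificationReport:
    """Confusion matrix (rows = truth) and derived per-class metrics."""

    confusion: np.ndarray
    accuracy: float
    tpr: np.ndarray        # per-class recall; NaN if class absent
    precision: np.ndarray  # NaN if class never predicted
    n_samples: int
    class_names: tuple[str, ...] = FALL_LABELS

    def to_json(self) -> str:
        def clean(arr):
            return [None if not np.isfinite(v) else float(v) for v in arr]
        return json.dumps({
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "tpr": clean(self.tpr),
            "precision": clean(self.precision),
            "n_samples": self.n_samples,
            "class_names": list(self.class_names),
        }, indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.class_names,
            "tpr": self.tpr,
            "precision": self.precision,
            "support": self.confusion.sum(axis=1),
        })


def report_from_confusion(cm: np.ndarray,
                          class_names=FALL_LABELS) -> ClassificationReport:
    cm = np.asarray(cm)
    total = cm.sum()
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpr = np.where(row > 0, np.diag(cm) / row, np.nan)
        precision = np.where(col > 0, np.diag(cm) / col, np.nan)
    return ClassificationReport(
        confusion=cm, accuracy=float(np.trace(cm) / total) if total else
        float("nan"), tpr=tpr, precision=precision,
        n_samples=int(total), class_names=class_names)


def evaluate(net: DualBranchCNN, data: LabeledDataset,
             idx: np.ndarray | None = None) -> ClassificationReport:
    """Score the network on (a subset of) a dataset."""
    idx = np.arange(len(data)) if idx is None else np.asarray(idx)
    pred = _forward_batched(net, data, idx).argmax(axis=1)
    cm = confusion_matrix(data.y[idx], pred,
                          labels=np.arange(len(data.class_names)))
    return report_from_confusion(cm, data.class_names)
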