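"""Training and evaluation loop for the segmentation network.

Per-pixel softmax cross-entropy, Adam, deterministic train/validation split
by seed.  Evaluation micro-averages: pixel confusion counts are pooled over
the whole dataset first and the scores computed once, matching the
count-based definitions in :mod:`gbseg.metrics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from gbseg import metrics as M
from gbseg import nn, phantom
from gbseg.network import NetworkConfig, SegNet

HISTORY_COLUMNS = ["epoch", "train_loss", "val_loss", "train_acc", "val_acc"]
DEFAULT_TARGET_CLASS = phantom.CLASS_LESION


class DataError(ValueError):
    pass


class TrainingError(RuntimeError):
    """Raised when the loss diverges; message names the epoch."""


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0
    val_fraction: float = 0.2
    loss_name: str = "cross_entropy"

    def validate(self) -> None:
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning_rate must be positive and batch_size >= 1")
        if self.loss_name != "cross_entropy":
            raise ValueError(f"unknown loss {self.loss_name!r}")


@dataclass
class TrainHistory:
    """Per-epoch train/validation loss and pixel accuracy."""

    records: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.records.append({k: record[k] for k in HISTORY_COLUMNS})

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records, columns=HISTORY_COLUMNS)

    def save_csv(self, path: Path) -> None:
        self.to_frame().to_csv(path, index=False)


def split_indices(n: int, val_fraction: float, seed: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic disjoint train/validation index split."""
    perm = np.random.default_rng(seed).permutation(n)
    n_val = min(n - 1, max(1, round(val_fraction * n))) if n > 1 else 0
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _batch_eval(model: SegNet, images: np.ndarray, masks: np.ndarray,
                batch_size: int) -> tuple[float, float, M.ConfusionCounts]:
    """(mean loss, pixel accuracy, pooled lesion confusion) in eval mode."""
    model.eval()
    losses, correct, counts = [], 0, M.ConfusionCounts(0, 0, 0, 0)
    for start in range(0, len(images), batch_size):
        xb = images[start:start + batch_size]
        yb = masks[start:start + batch_size]
        logits = model.forward(xb)
        loss, _ = nn.softmax_cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        pred = logits.argmax(axis=1)
        correct += int((pred == yb).sum())
        counts = counts + M.confusion(pred, yb, DEFAULT_TARGET_CLASS)
    acc = correct / masks.size
    return float(np.sum(losses) / len(images)), acc, counts


def fit(images: np.ndarray, masks: np.ndarray, net_config: NetworkConfig,
        train_config: TrainConfig,
        on_epoch_end: Callable[[int, SegNet, TrainHistory], bool] | None = None
        ) -> tuple[SegNet, TrainHistory]:
    """Train on in-memory arrays; returns (model, history).

    ``on_epoch_end(epoch, model, history)`` may return True to stop early.
    The whole pipeline is a pure function of the two configs' seeds.
    """
    train_config.validate()
    if len(images) == 0:
        raise DataError("empty dataset")
    masks = masks.astype(np.int64)
    tr, va = split_indices(len(images), train_config.val_fraction, train_config.seed)
    model = SegNet(net_config, seed=train_config.seed)
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    rng = np.random.default_rng(phantom.derive_seed(train_config.seed, 0xBA7C4))
    history = TrainHistory()
    bs = train_config.batch_size

    for epoch in range(train_config.epochs):
        model.train()
        order = rng.permutation(tr)
        epoch_loss, correct = 0.0, 0
        for start in range(0, len(order), bs):
            idx = order[start:start + bs]
            xb, yb = images[idx], masks[idx]
            logits = model.forward(xb)
            loss, grad = nn.softmax_cross_entropy(logits, yb)
            if not np.isfinite(loss):
                raise TrainingError(f"loss diverged (non-finite) at epoch {epoch}")
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        if not all(np.isfinite(p.data).all() for p in model.parameters()):
            raise TrainingError(f"weights diverged (non-finite) at epoch {epoch}")
        train_loss = epoch_loss / len(order)
        train_acc = correct / (len(order) * masks[0].size)
        if len(va):
            val_loss, val_acc, _ = _batch_eval(model, images[va], masks[va], bs)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        history.append(epoch=epoch, train_loss=train_loss, val_loss=val_loss,
                       train_acc=train_acc, val_acc=val_acc)
        if on_epoch_end is not None and on_epoch_end(epoch, model, history):
            break
    model.eval()
    return model, history


def train_model(manifest: Path | pd.DataFrame, net_config: NetworkConfig,
                train_config: TrainConfig, **kwargs) -> tuple[SegNet, TrainHistory]:
    """Train from a dataset manifest (CSV path or DataFrame with a root attr)."""
    try:
        images, masks = phantom.load_dataset(manifest)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    return fit(images, masks, net_config, train_config, **kwargs)


def evaluate(model: SegNet, images: np.ndarray, masks: np.ndarray,
             target_class: int = DEFAULT_TARGET_CLASS, batch_size: int = 8) -> dict:
    """Micro-averaged IoU/precision/recall/pixel accuracy over a dataset."""
    model.eval()
    counts = M.ConfusionCounts(0, 0, 0, 0)
    correct = 0
    for start in range(0, len(images), batch_size):
        pred = model.predict(images[start:start + batch_size])
        yb = masks[start:start + batch_size]
        counts = counts + M.confusion(pred, yb, target_class)
        correct += int((pred == yb).sum())
    out = M.summarize(counts)
    out["pixel_accuracy"] = correct / masks.size
    return out


def evaluate_model(model: SegNet | Path, net_config: NetworkConfig | None,
                   manifest: Path | pd.DataFrame,
                   target_class: int = DEFAULT_TARGET_CLASS) -> dict:
    """Evaluate a model (or checkpoint path) against a dataset manifest."""
    if not isinstance(model, SegNet):
        model = SegNet.load(model)
    images, masks = phantom.load_dataset(manifest)
    return evaluate(model, images, masks, target_class)


def threshold_baseline(images: np.ndarray, masks: np.ndarray,
                       lo: float, hi: float = 1.0,
                       target_class: int = DEFAULT_TARGET_CLASS) -> dict:
    """Intensity-band baseline: predict target where lo <= intensity <= hi.

    Serves as the learnability yardstick: a phantom task on which even this
    baseline scores well must be separable by any trained network.
    """
    pred = np.where((images >= lo) & (images <= hi), target_class, 0)
    counts = M.ConfusionCounts(0, 0, 0, 0)
    for p, t in zip(pred, masks):
        counts = counts + M.confusion(p, t, target_class)
    return M.summarize(counts)


def plot_history(history: TrainHistory, path: Path) -> None:
    """Loss and pixel-accuracy curves for train and validation sets."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = history.to_frame()
    fig, (ax_loss, ax_acc) = plt.subplots(1, 2, figsize=(9, 3.5))
    for split in ("train", "val"):
        ax_loss.plot(frame["epoch"], frame[f"{split}_loss"], label=split)
        ax_acc.plot(frame["epoch"], frame[f"{split}_acc"], label=split)
    ax_loss.set_xlabel("epoch"); ax_loss.set_ylabel("cross-entropy loss")
    ax_acc.set_xlabel("epoch"); ax_acc.set_ylabel("pixel accuracy")
    ax_loss.legend(); ax_acc.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


METRIC_KEYS = ("iou", "precision", "recall", "pixel_accuracy")


def compare_variants(manifest: Path | pd.DataFrame, net_config: NetworkConfig,
                     train_config: TrainConfig, n_seeds: int = 1) -> pd.DataFrame:
    """Train plain and pyramid variants over shared seeds; tabulate deltas.

    Rows: plain, pyramid (mean and sd of validation metrics over seeds) and
    delta = pyramid − plain, computed per seed then averaged.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    images, masks = phantom.load_dataset(manifest)
    plain_cfg = NetworkConfig(**{**net_config.to_dict(), "pyramid_bins": ()})
    pyr_bins = net_config.pyramid_bins or (1, 2, 3, 6)
    pyramid_cfg = NetworkConfig(**{**net_config.to_dict(), "pyramid_bins": pyr_bins})

    results = {"plain": [], "pyramid": []}
    for s in range(n_seeds):
        tc = TrainConfig(**{**train_config.__dict__, "seed": train_config.seed + s})
        _, va = split_indices(len(images), tc.val_fraction, tc.seed)
        for arm, cfg in (("plain", plain_cfg), ("pyramid", pyramid_cfg)):
            model, _ = fit(images, masks, cfg, tc)
            scores = evaluate(model, images[va], masks[va])
            results[arm].append([scores[k] if scores[k] is not None else np.nan
                                 for k in METRIC_KEYS])

    plain = np.asarray(results["plain"], dtype=float)
    pyramid = np.asarray(results["pyramid"], dtype=float)
    delta = pyramid - plain
    rows = []
    for name, arr in (("plain", plain), ("pyramid", pyramid), ("delta", delta)):
        row = {"variant": name, "n_seeds": n_seeds}
        for j, key in enumerate(METRIC_KEYS):
            row[f"{key}_mean"] = float(np.mean(arr[:, j]))
            row[f"{key}_sd"] = float(np.std(arr[:, j], ddof=1)) if n_seeds > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
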