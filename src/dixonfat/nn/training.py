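"""Training and inference for the two segmentation U-Nets.

The training recipe follows the standard single-slice setup: inputs
min-max normalized to [0, 1] and zero-padded to the network input size,
Adam optimization (initial learning rate 1e-4), batch size 8, 100 epochs,
and a reduce-on-plateau learning-rate scheduler with a patience of 10
epochs monitoring validation loss (factor 0.1). The weights of the best
validation epoch are retained. One master seed fans out deterministically
to weight initialization, the train/validation split, and batch shuffling.

``task`` selects the target encoding built from a phantom ground truth:

* ``"region"`` — 0 background, 1 abdominal-wall ring (outer minus inner),
  2 inner region;
* ``"fat"``    — 0 background, 1 SAT, 2 VAT.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ..core import DixonSlice
from .. import image_io
from ..phantom import GroundTruth
from .loss import WassersteinLossConfig, gwd_loss_and_grad
from .unet import UNet, UNetConfig, build_unet, softmax

__all__ = [
    "TrainConfig",
    "Adam",
    "encode_targets",
    "load_training_set",
    "train_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

TASKS = ("region", "fat")


@dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the standard recipe)."""

    learning_rate: float = 1e-4
    batch_size: int = 8
    epochs: int = 100
    scheduler_patience: int = 10
    scheduler_factor: float = 0.1
    val_fraction: float = 0.1
    seed: int = 0
    loss: Optional[WassersteinLossConfig] = None

    def validate(self) -> None:
        if min(self.learning_rate, self.batch_size, self.epochs) <= 0:
            raise ValueError("learning_rate, batch_size, epochs must be positive")
        if self.scheduler_patience <= 0 or not (0 < self.scheduler_factor < 1):
            raise ValueError("scheduler_patience > 0 and 0 < factor < 1 required")
        if not (0.0 <= self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in [0, 1)")


class Adam:
    """Adam optimizer over a list of autodiff parameter leaves."""

    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def encode_targets(truth: GroundTruth, task: str) -> np.ndarray:
    """Integer per-pixel target labels for one task (see module docstring)."""
    if task == "region":
        lab = np.zeros(truth.outer_mask.shape, dtype=np.int64)
        lab[truth.outer_mask & ~truth.inner_mask] = 1
        lab[truth.inner_mask] = 2
        return lab
    if task == "fat":
        lab = np.zeros(truth.sat_mask.shape, dtype=np.int64)
        lab[truth.sat_mask] = 1
        lab[truth.vat_mask] = 2
        return lab
    raise ValueError(f"task must be one of {TASKS}, got {task!r}")


def _prepare_input(slc: DixonSlice, input_size: int) -> np.ndarray:
    norm = image_io.normalize_intensity(slc)
    return image_io.pad_to(norm.intensities, input_size).astype(np.float32)


def load_training_set(
    manifest: pd.DataFrame,
    task: str,
    input_size: int,
    data: Optional[dict] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (X, Y, subject_ids) from a cohort manifest.

    ``data`` may hold in-memory ``(DixonSlice, GroundTruth)`` pairs keyed by
    ``(subject_id, visit, level)``; rows missing from it are read from the
    manifest's file paths.
    """
    if len(manifest) == 0:
        raise ValueError("manifest is empty")
    from ..phantom import labelmap_to_truth

    xs, ys, subjects = [], [], []
    for row in manifest.itertuples(index=False):
        key = (row.subject_id, row.visit, row.level)
        if data is not None and key in data:
            slc, truth = data[key]
        else:
            slc = image_io.read_image(row.image_path)
            truth = labelmap_to_truth(image_io.read_labelmap(row.truth_path))
        xs.append(_prepare_input(slc, input_size))
        ys.append(image_io.pad_to(encode_targets(truth, task), input_size))
        subjects.append(row.subject_id)
    x = np.stack(xs)[:, None]  # (N, 1, S, S)
    y = np.stack(ys).astype(np.int64)
    return x, y, np.asarray(subjects)


def _split_by_subject(subjects: np.ndarray, val_fraction: float,
                      rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    uniq = np.array(sorted(set(subjects.tolist())))
    if val_fraction == 0.0 or len(uniq) < 2:
        idx = np.arange(len(subjects))
        return idx, idx  # validate on the training images themselves
    n_val = max(1, int(round(val_fraction * len(uniq))))
    val_subjects = set(rng.permutation(uniq)[:n_val].tolist())
    mask = np.array([s in val_subjects for s in subjects])
    return np.flatnonzero(~mask), np.flatnonzero(mask)


def train_model(
    manifest: pd.DataFrame,
    task: str,
    ucfg: Optional[UNetConfig] = None,
    tcfg: Optional[TrainConfig] = None,
    data: Optional[dict] = None,
) -> tuple[UNet, list[dict]]:
    """Train one U-Net for ``task`` on a cohort manifest.

    Returns the model (restored to its best-validation-epoch weights) and
    the per-epoch history (train loss, validation loss, learning rate).
    Classes absent from every target raise a warning, not an error.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    ucfg = ucfg or UNetConfig()
    tcfg = tcfg or TrainConfig(loss=WassersteinLossConfig.for_task(task))
    ucfg.validate()
    tcfg.validate()
    loss_cfg = tcfg.loss or WassersteinLossConfig.for_task(task)

    x, y, subjects = load_training_set(manifest, task, ucfg.input_size, data=data)
    present = set(np.unique(y).tolist())
    missing = set(range(ucfg.out_classes)) - present
    if missing:
        import warnings

        warnings.warn(f"classes {sorted(missing)} absent from all targets", stacklevel=2)

    rng = np.random.default_rng(tcfg.seed)
    model = build_unet(ucfg, seed=int(rng.integers(0, 2**31 - 1)))
    train_idx, val_idx = _split_by_subject(subjects, tcfg.val_fraction, rng)
    opt = Adam(model.parameters(), lr=tcfg.learning_rate)

    history: list[dict] = []
    best_val = np.inf
    best_state = model.state_dict()
    epochs_since_improve = 0
    for epoch in range(tcfg.epochs):
        order = rng.permutation(train_idx)
        train_losses = []
        for start in range(0, len(order), tcfg.batch_size):
            batch = order[start:start + tcfg.batch_size]
            logits = model.forward(x[batch])  # NHWC
            probs = softmax(logits.data, axis=-1)
            loss, dprob = gwd_loss_and_grad(
                probs.transpose(0, 3, 1, 2), y[batch], loss_cfg)
            dprob = dprob.transpose(0, 2, 3, 1)
            # chain rule through softmax: dL/dz = p * (g - sum_l g_l p_l)
            inner = np.sum(dprob * probs, axis=-1, keepdims=True)
            dlogits = (probs * (dprob - inner)).astype(np.float32)
            opt.zero_grad()
            logits.backward(dlogits)
            opt.step()
            train_losses.append(loss)
        val_losses = []
        for start in range(0, len(val_idx), tcfg.batch_size):
            batch = val_idx[start:start + tcfg.batch_size]
            probs = model.predict_proba(x[batch])
            val_loss, _ = gwd_loss_and_grad(probs, y[batch], loss_cfg, need_grad=False)
            val_losses.append(val_loss)
        train_loss = float(np.mean(train_losses))
        val_loss = float(np.mean(val_losses))
        history.append({"epoch": epoch, "train_loss": train_loss,
                        "val_loss": val_loss, "lr": opt.lr})
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state_dict()
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve >= tcfg.scheduler_patience:
                opt.lr *= tcfg.scheduler_factor
                epochs_since_improve = 0
    model.load_state(best_state)
    return model, history


def predict(model: UNet, slc: DixonSlice, mode: str = "pad") -> tuple[np.ndarray, np.ndarray]:
    """Run one slice through a model; results in the original image frame.

    The slice is normalized to [0, 1] and harmonized to the network input
    size; the class probability maps are mapped back to the input frame
    before the argmax. Ties break toward the lower class index, so a
    uniform probability field yields background.

    Returns ``(probabilities, labels)`` with shapes ``(C, H, W)`` and
    ``(H, W)``.
    """
    s = model.config.input_size
    x = _prepare_input(slc, s)[None, None]
    probs = model.predict_proba(x)[0]  # (C, S, S)
    out = np.stack([
        image_io.unharmonize_size(p, slc.shape, mode=mode) for p in probs
    ])
    labels = np.argmax(out, axis=0)  # first (lowest) index wins ties
    return out, labels


def save_checkpoint(path: str | Path, model: UNet, history: Optional[list] = None,
                    task: str = "") -> None:
    """Persist weights plus the embedded architecture config as one .npz."""
    meta = {"config": asdict(model.config), "task": task,
            "history": history or []}
    arrays = {f"param_{i:03d}": a for i, a in enumerate(model.state_dict())}
    np.savez_compressed(path, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        arrays = [z[k] for k in sorted(k for k in z.files if k.startswith("param_"))]
    model = UNet(UNetConfig(**meta["config"]))
    model.load_state(arrays)
    return model, meta
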