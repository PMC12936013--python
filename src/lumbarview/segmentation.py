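"""Stage-1 encoder-decoder semantic segmentation of lumbar bony landmarks.

The segmenter is a symmetric encoder-decoder with skip connections.
In the primary ``single`` mode the foramen and transverse-process classes
are merged into one foreground category (a target-vs-background problem,
which is easier to learn from small cohorts); the ``multi`` mode keeps
them separate (background / F / T) and serves as the in-study comparator.

Training uses Adam with a fixed learning rate and a combined
cross-entropy + soft-dice loss, selects the checkpoint with the lowest
validation loss, and touches only the train/val subsets of the shared
patient-level split.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn, dataset

__all__ = [
    "SegConfig",
    "SegPrediction",
    "build_segmenter",
    "train_segmenter",
    "predict_mask",
    "save_model",
    "load_model",
]


@dataclass
class SegConfig:
    """Segmenter architecture and training hyperparameters.

    ``base_channels=16`` is the desk-scale default (CPU-trainable);
    paper-scale capacity is reached by raising it (e.g. 64).
    ``n_classes=1`` is the merged single-category mode; 3 the multi-class
    variant. ``loss``: bce, dice or bce+dice (bce means cross-entropy in
    the multi-class variant).
    """

    input_size: tuple[int, int] = (224, 224)
    depth: int = 4
    base_channels: int = 16
    n_classes: int = 1
    loss: str = "bce+dice"
    epochs: int = 15
    batch_size: int = 4
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.n_classes not in (1, 3):
            raise ValueError("n_classes must be 1 (single) or 3 (multi)")
        if self.loss not in ("bce", "dice", "bce+dice"):
            raise ValueError("loss must be bce, dice or bce+dice")


@dataclass
class SegPrediction:
    prob: np.ndarray  # (H, W) or (n_classes, H, W), in [0, 1]
    mask: np.ndarray  # uint8; {0,1} single-class, {0,1,2} multi-class


def build_segmenter(config: SegConfig) -> _nn.UNet:
    """Instantiate the encoder-decoder for ``config`` (seeded init)."""
    model = _nn.UNet(
        depth=config.depth,
        base_channels=config.base_channels,
        n_classes=config.n_classes,
        seed=config.seed,
    )
    model.check_input(config.input_size)
    return model


def _load_subset(manifest, split, subset, config, mode):
    rows = manifest.rows_for(split, subset)
    if len(rows) == 0:
        raise ValueError(f"subset '{subset}' of the split contains no images")
    xs, ys = [], []
    for _, r in rows.iterrows():
        image, mask = dataset.load_pair(r["image"], r["mask"], config.input_size)
        xs.append(image[None])
        ys.append(dataset.merge_classes(mask) if mode == "single" else mask)
    return np.stack(xs).astype(np.float32), np.stack(ys)


def _batch_loss(model, x, y, config, mode):
    logits = model.forward(x)
    if mode == "single":
        return _nn.binary_seg_loss(logits, y[:, None], config.loss)
    return _nn.multiclass_seg_loss(logits, y.astype(np.intp), config.loss)


def train_segmenter(model, manifest, split, config: SegConfig, mode: str = "single"):
    """Train on the split's train subset; return (model, history frame).

    ``mode='single'`` merges the landmark classes in the targets;
    ``mode='multi'`` keeps the raw 3-class targets and requires
    ``config.n_classes == 3``. The weights restored at the end are those
    of the epoch with the lowest validation loss.
    """
    if mode not in ("single", "multi"):
        raise ValueError("mode must be 'single' or 'multi'")
    if mode == "single" and config.n_classes != 1:
        raise ValueError("single mode requires n_classes=1")
    if mode == "multi" and config.n_classes != 3:
        raise ValueError("multi mode requires n_classes=3")
    x_tr, y_tr = _load_subset(manifest, split, "train", config, mode)
    x_va, y_va = _load_subset(manifest, split, "val", config, mode)
    opt = _nn.Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best = (np.inf, model.get_weights())
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        tr_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            loss, dlogits = _batch_loss(model, x_tr[idx], y_tr[idx], config, mode)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            tr_losses.append(loss)
        val_loss = 0.0
        for start in range(0, len(x_va), config.batch_size):
            sl = slice(start, start + config.batch_size)
            l, _ = _batch_loss(model, x_va[sl], y_va[sl], config, mode)
            val_loss += l * (len(x_va[sl]) / len(x_va))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(tr_losses)), "val_loss": float(val_loss)}
        )
        if val_loss < best[0]:
            best = (val_loss, model.get_weights())
    model.set_weights(best[1])
    return model, pd.DataFrame(history)


def predict_mask(model, image: np.ndarray, threshold: float = 0.5) -> SegPrediction:
    """Per-pixel probabilities and the thresholded/argmax label mask.

    Single-class: ``mask = prob >= threshold`` (lowering the threshold can
    only grow the foreground). Multi-class: per-pixel argmax over the
    softmax probabilities.
    """
    x = np.asarray(image, dtype=np.float32)
    if x.shape != tuple(dataset.NETWORK_SIZE):
        raise ValueError(f"image must be {dataset.NETWORK_SIZE}, got {x.shape}")
    logits = model.forward(x[None, None])
    if model.n_classes == 1:
        prob = _nn._sigmoid(logits.astype(np.float64))[0, 0]
        mask = (prob >= threshold).astype(np.uint8)
    else:
        prob = _nn._softmax(logits.astype(np.float64))[0]
        mask = prob.argmax(axis=0).astype(np.uint8)
    return SegPrediction(prob=prob, mask=mask)


def save_model(model, config: SegConfig, path):
    """Weights to one .npz plus a JSON sidecar describing the architecture."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(path, *weights)
    path.with_suffix(".json").write_text(json.dumps(asdict(config), indent=1))


def load_model(path):
    path = Path(path)
    config = SegConfig(**{
        k: tuple(v) if k == "input_size" else v
        for k, v in json.loads(path.with_suffix(".json").read_text()).items()
    })
    model = build_segmenter(config)
    with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
        model.set_weights([data[f"arr_{i}"] for i in range(len(data.files))])
    return model, config
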