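"""Second-stage view classification.

The primary classifier is an SVM on grid-occupancy features of the
segmentation masks: the foramen (F) and transverse-process (T) landmarks
occupy characteristically different spatial patterns, so a margin
classifier on the 256-bit occupancy vectors separates the PTFV and PTV-TP
views. An end-to-end CNN trained directly on the images serves as the
comparison baseline.

Each image contains one dominant landmark, so classifying the image and
labelling its segmented region are the same decision; the label mapping
(F -> PTFV, T -> PTV_TP) lives in one shared constant.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import joblib
import numpy as np
from sklearn.svm import SVC

from . import _nn, dataset
from ._labels import VIEW_FOR_CLASS, CLASS_FOR_VIEW, VIEW_LABELS
from .features import FeatureMatrix, GridFeature

__all__ = [
    "ClassifierBundle",
    "CNNConfig",
    "train_svm",
    "predict_view",
    "train_cnn_baseline",
    "predict_view_image",
    "save_bundle",
    "load_bundle",
    "VIEW_FOR_CLASS",
    "CLASS_FOR_VIEW",
]

#: label emitted (with a warning) for an all-zero feature vector
NO_STRUCTURE_DEFAULT = VIEW_FOR_CLASS["T"]


@dataclass
class ClassifierBundle:
    """A fitted classifier plus its training metadata."""

    kind: str  # "svm" | "cnn"
    model: object
    meta: dict = field(default_factory=dict)


@dataclass
class CNNConfig:
    """Baseline CNN hyperparameters (small fixed convnet, not tuned)."""

    base_channels: int = 8
    epochs: int = 15
    batch_size: int = 8
    learning_rate: float = 1e-3
    seed: int = 0


def train_svm(
    features: FeatureMatrix,
    labels=None,
    kernel: str = "linear",
    C: float = 1.0,
    seed: int = 0,
) -> ClassifierBundle:
    """Fit the margin classifier on grid-occupancy features.

    ``labels`` defaults to the labels carried by the feature matrix. Both
    view classes must be present in the training rows.
    """
    if kernel not in ("linear", "rbf"):
        raise ValueError("kernel must be 'linear' or 'rbf'")
    y = [str(l) for l in (labels if labels is not None else features.labels)]
    if len(y) != features.n:
        raise ValueError("label count must match feature rows")
    present = set(y)
    missing = set(VIEW_LABELS) - present
    if missing:
        raise ValueError(
            f"training set contains no samples of class {sorted(missing)[0]}"
        )
    x = features.matrix.astype(np.float64)
    model = SVC(kernel=kernel, C=C, random_state=seed)
    model.fit(x, y)
    meta = {"kind": "svm", "kernel": kernel, "C": C, "seed": seed, "n_train": features.n}
    return ClassifierBundle(kind="svm", model=model, meta=meta)


def predict_view(bundle: ClassifierBundle, feature: GridFeature) -> str:
    """Deterministic view label for one grid feature.

    An all-zero feature means the segmenter found no structure; the bundle
    still returns a label but a ``no structure detected`` warning is
    raised so pipelines can surface the flag.
    """
    if bundle.kind != "svm":
        raise ValueError("predict_view expects a feature-based (svm) bundle")
    expected = bundle.model.n_features_in_
    if feature.bits.size != expected:
        raise ValueError(
            f"feature length {feature.bits.size} does not match the "
            f"classifier's training dimension {expected}"
        )
    if feature.is_empty:
        warnings.warn(
            "no structure detected: empty segmentation mask, label is a default guess",
            stacklevel=2,
        )
    return str(bundle.model.predict(feature.bits.reshape(1, -1).astype(np.float64))[0])


# --------------------------------------------------------------------------
# CNN baseline


def _load_images(manifest, split, subset):
    rows = manifest.rows_for(split, subset)
    if len(rows) == 0:
        raise ValueError(f"subset '{subset}' of the split contains no images")
    xs, ys = [], []
    for _, r in rows.iterrows():
        image, _ = dataset.load_pair(r["image"], r["mask"])
        xs.append(image[None])  # channel axis
        ys.append(VIEW_LABELS.index(r["view_label"]))
    return np.stack(xs).astype(np.float32), np.asarray(ys)


def train_cnn_baseline(manifest, split, config: CNNConfig | None = None) -> ClassifierBundle:
    """Train the end-to-end image classifier on the train subset, selecting
    the epoch with the best validation loss."""
    config = config or CNNConfig()
    x_tr, y_tr = _load_images(manifest, split, "train")
    x_va, y_va = _load_images(manifest, split, "val")
    net = _nn.SmallConvNet(
        n_classes=len(VIEW_LABELS), base_channels=config.base_channels, seed=config.seed
    )
    opt = _nn.Adam(net.params(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    best = (np.inf, net.get_weights())
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(x_tr))
        tr_losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(x_tr[idx])
            loss, dlogits = _nn.softmax_ce_loss(logits, y_tr[idx])
            opt.zero_grad()
            net.backward(dlogits)
            opt.step()
            tr_losses.append(loss)
        val_loss = 0.0
        for start in range(0, len(x_va), config.batch_size):
            sl = slice(start, start + config.batch_size)
            logits = net.forward(x_va[sl])
            l, _ = _nn.softmax_ce_loss(logits, y_va[sl])
            val_loss += l * (logits.shape[0] / len(x_va))
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(tr_losses)), "val_loss": float(val_loss)}
        )
        if val_loss < best[0]:
            best = (val_loss, net.get_weights())
    net.set_weights(best[1])
    meta = {
        "kind": "cnn",
        **asdict(config),
        "history": history,
        "classes": list(VIEW_LABELS),
    }
    return ClassifierBundle(kind="cnn", model=net, meta=meta)


def predict_view_image(bundle: ClassifierBundle, image: np.ndarray) -> str:
    """View label for one 224x224 grayscale image using the CNN baseline."""
    if bundle.kind != "cnn":
        raise ValueError("predict_view_image expects a cnn bundle")
    x = np.asarray(image, dtype=np.float32)
    if x.shape != dataset.NETWORK_SIZE:
        raise ValueError(f"image must be {dataset.NETWORK_SIZE}, got {x.shape}")
    logits = bundle.model.forward(x[None, None])
    return VIEW_LABELS[int(logits.argmax(axis=1)[0])]


# --------------------------------------------------------------------------
# persistence


def save_bundle(bundle: ClassifierBundle, path):
    """Serialize a bundle to one file plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if bundle.kind == "cnn":
        payload = {"kind": "cnn", "weights": bundle.model.get_weights(), "meta": bundle.meta}
    else:
        payload = {"kind": bundle.kind, "model": bundle.model, "meta": bundle.meta}
    joblib.dump(payload, path)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"kind": bundle.kind, **{k: v for k, v in bundle.meta.items() if k != "history"}},
                   indent=1, sort_keys=True, default=str)
    )


def load_bundle(path) -> ClassifierBundle:
    payload = joblib.load(path)
    if payload["kind"] == "cnn":
        cfg = payload["meta"]
        net = _nn.SmallConvNet(
            n_classes=len(cfg.get("classes", VIEW_LABELS)),
            base_channels=cfg["base_channels"],
            seed=cfg["seed"],
        )
        net.set_weights(payload["weights"])
        return ClassifierBundle(kind="cnn", model=net, meta=payload["meta"])
    return ClassifierBundle(kind=payload["kind"], model=payload["model"], meta=payload["meta"])
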