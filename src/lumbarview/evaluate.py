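"""Evaluation metrics and the four-way model comparison harness.

Segmentation is scored by intersection-over-union (IoU = |pred AND truth| /
|pred OR truth|), reported both as the mean of per-image IoUs (headline)
and as the pixel-pooled ratio over the whole test set; classification by
accuracy (correct / total). ``run_comparison`` trains and evaluates the
four configurations on identical patient-level splits per seed:

* ``sseg_svm`` — single-class segmenter + grid-feature SVM (the two-stage method)
* ``sseg``     — single-class segmenter alone, classified by a mask-only
                 contour heuristic (a documented reconstruction)
* ``mcseg``    — multi-class segmenter (background/F/T)
* ``cnn``      — end-to-end image CNN baseline (no segmentation IoU)
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify, dataset, features, segmentation
from ._labels import VIEW_FOR_CLASS, VIEW_LABELS

__all__ = [
    "EvalReport",
    "iou",
    "accuracy",
    "confusion_counts",
    "run_comparison",
    "reports_to_frame",
    "write_markdown_table",
]

MODEL_TAGS = ("sseg_svm", "sseg", "mcseg", "cnn")


@dataclass
class EvalReport:
    model_tag: str
    seed: int
    per_image_iou: list = field(default_factory=list)
    mean_iou: float = float("nan")
    pooled_iou: float = float("nan")
    accuracy: float = float("nan")
    confusion: np.ndarray | None = None  # rows = truth, cols = predicted
    n_test: int = 0


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Convention for degenerate cases: both masks empty -> 1.0 (perfect
    agreement on absence); one empty -> 0.0.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for name, m in (("pred", pred), ("truth", truth)):
        if not set(np.unique(m).tolist()) <= {0, 1}:
            raise ValueError(f"{name} mask must be binary")
    p = pred > 0
    t = truth > 0
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)


def accuracy(predictions, truths) -> float:
    """Proportion of correctly classified samples."""
    predictions = list(predictions)
    truths = list(truths)
    if len(predictions) != len(truths):
        raise ValueError("prediction and truth lists must have equal length")
    if not predictions:
        raise ValueError("accuracy of an empty prediction list is undefined")
    return float(np.mean([p == t for p, t in zip(predictions, truths)]))


def confusion_counts(predictions, truths) -> np.ndarray:
    """2x2 counts, rows ordered by true label, columns by predicted label,
    both in ``VIEW_LABELS`` order."""
    mat = np.zeros((len(VIEW_LABELS), len(VIEW_LABELS)), dtype=int)
    for p, t in zip(predictions, truths):
        mat[VIEW_LABELS.index(t), VIEW_LABELS.index(p)] += 1
    return mat


def _foreground_iou_multi(pred: np.ndarray, truth: np.ndarray) -> float:
    """Mean of the per-class IoUs over the two landmark classes, background
    excluded; classes absent from both masks are skipped."""
    vals = []
    for c in (1, 2):
        p = pred == c
        t = truth == c
        union = np.logical_or(p, t).sum()
        if union == 0:
            continue
        vals.append(np.logical_and(p, t).sum() / union)
    return float(np.mean(vals)) if vals else 1.0


def _heuristic_view_from_mask(mask: np.ndarray) -> str:
    """Mask-only view heuristic used by the segmenter-alone row: the
    foramen ridge is wider than tall, the transverse process taller than
    wide, so the bounding-box aspect ratio (width/height, threshold 1)
    decides. Empty masks default to PTV_TP."""
    if not mask.any():
        return classify.NO_STRUCTURE_DEFAULT
    fg = mask > 0
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    aspect = (cols[-1] - cols[0] + 1) / (rows[-1] - rows[0] + 1)
    cls = "F" if aspect > 1.0 else "T"
    return VIEW_FOR_CLASS[cls]


def _majority_view_from_multimask(mask: np.ndarray) -> str:
    counts = {c: int((mask == v).sum()) for c, v in (("F", 1), ("T", 2))}
    if counts["F"] == counts["T"] == 0:
        return classify.NO_STRUCTURE_DEFAULT
    cls = "F" if counts["F"] > counts["T"] else "T"
    return VIEW_FOR_CLASS[cls]


def _predict_subset(model, manifest, split, subset, merged_truth=True):
    """Predicted masks + merged ground truth + view labels for a subset."""
    rows = manifest.rows_for(split, subset)
    preds, truths, labels = [], [], []
    for _, r in rows.iterrows():
        image, mask = dataset.load_pair(r["image"], r["mask"])
        pred = segmentation.predict_mask(model, image)
        preds.append(pred.mask)
        truths.append(dataset.merge_classes(mask) if merged_truth else mask)
        labels.append(r["view_label"])
    return preds, truths, labels


def _pooled_iou(preds, truths) -> float:
    inter = sum(int(np.logical_and(p > 0, t > 0).sum()) for p, t in zip(preds, truths))
    union = sum(int(np.logical_or(p > 0, t > 0).sum()) for p, t in zip(preds, truths))
    return float(inter / union) if union else 1.0


def run_comparison(
    manifest,
    split,
    seg_config: segmentation.SegConfig | None = None,
    seeds=(0,),
    cnn_config: classify.CNNConfig | None = None,
    svm_kernel: str = "linear",
    svm_c: float = 1.0,
) -> list[EvalReport]:
    """Train and evaluate all four model rows for every seed.

    All rows of one seed share the same patient-level split; ``sseg_svm``
    and ``sseg`` share the same trained segmenter (hence identical IoU).
    The SVM is trained on features of the *predicted* train-subset masks,
    mirroring the deployment condition.
    """
    if not len(list(seeds)):
        raise ValueError("need at least one seed")
    base = seg_config or segmentation.SegConfig()
    reports = []
    for seed in seeds:
        cfg1 = dataclasses.replace(base, n_classes=1, seed=seed)
        seg1 = segmentation.build_segmenter(cfg1)
        seg1, _ = segmentation.train_segmenter(seg1, manifest, split, cfg1, mode="single")

        te_preds, te_truths, te_labels = _predict_subset(seg1, manifest, split, "test")
        per_image = [iou(p, t) for p, t in zip(te_preds, te_truths)]
        mean_iou = float(np.mean(per_image))
        pooled = _pooled_iou(te_preds, te_truths)

        # two-stage: SVM on predicted-mask grid features
        tr_preds, _, tr_labels = _predict_subset(seg1, manifest, split, "train")
        fm = features.build_feature_matrix(tr_preds, tr_labels)
        bundle = classify.train_svm(fm, kernel=svm_kernel, C=svm_c, seed=seed)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # empty-mask flags are counted, not fatal
            svm_pred = [
                classify.predict_view(bundle, features.vectorize_mask(p)) for p in te_preds
            ]
        reports.append(
            EvalReport(
                model_tag="sseg_svm",
                seed=seed,
                per_image_iou=per_image,
                mean_iou=mean_iou,
                pooled_iou=pooled,
                accuracy=accuracy(svm_pred, te_labels),
                confusion=confusion_counts(svm_pred, te_labels),
                n_test=len(te_labels),
            )
        )

        # segmenter alone with the mask-only heuristic
        heur_pred = [_heuristic_view_from_mask(p) for p in te_preds]
        reports.append(
            EvalReport(
                model_tag="sseg",
                seed=seed,
                per_image_iou=per_image,
                mean_iou=mean_iou,
                pooled_iou=pooled,
                accuracy=accuracy(heur_pred, te_labels),
                confusion=confusion_counts(heur_pred, te_labels),
                n_test=len(te_labels),
            )
        )

        # multi-class comparator
        cfg3 = dataclasses.replace(base, n_classes=3, seed=seed)
        seg3 = segmentation.build_segmenter(cfg3)
        seg3, _ = segmentation.train_segmenter(seg3, manifest, split, cfg3, mode="multi")
        m_preds, m_truths, m_labels = _predict_subset(
            seg3, manifest, split, "test", merged_truth=False
        )
        m_per_image = [_foreground_iou_multi(p, t) for p, t in zip(m_preds, m_truths)]
        m_pred_views = [_majority_view_from_multimask(p) for p in m_preds]
        reports.append(
            EvalReport(
                model_tag="mcseg",
                seed=seed,
                per_image_iou=m_per_image,
                mean_iou=float(np.mean(m_per_image)),
                pooled_iou=_pooled_iou(
                    [p > 0 for p in m_preds], [t > 0 for t in m_truths]
                ),
                accuracy=accuracy(m_pred_views, m_labels),
                confusion=confusion_counts(m_pred_views, m_labels),
                n_test=len(m_labels),
            )
        )

        # end-to-end CNN baseline
        ccfg = dataclasses.replace(cnn_config or classify.CNNConfig(), seed=seed)
        cnn = classify.train_cnn_baseline(manifest, split, ccfg)
        rows = manifest.rows_for(split, "test")
        cnn_pred, cnn_truth = [], []
        for _, r in rows.iterrows():
            image, _ = dataset.load_pair(r["image"], r["mask"])
            cnn_pred.append(classify.predict_view_image(cnn, image))
            cnn_truth.append(r["view_label"])
        reports.append(
            EvalReport(
                model_tag="cnn",
                seed=seed,
                accuracy=accuracy(cnn_pred, cnn_truth),
                confusion=confusion_counts(cnn_pred, cnn_truth),
                n_test=len(cnn_truth),
            )
        )
    return reports


def reports_to_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_tag": r.model_tag,
                "seed": r.seed,
                "mean_iou": r.mean_iou,
                "pooled_iou": r.pooled_iou,
                "accuracy": r.accuracy,
                "n_test": r.n_test,
            }
            for r in reports
        ]
    )


def write_markdown_table(reports, path):
    """Human-readable comparison table (means over seeds per model row)."""
    df = reports_to_frame(reports)
    agg = df.groupby("model_tag", sort=False).agg(
        mean_iou=("mean_iou", "mean"), accuracy=("accuracy", "mean")
    )
    lines = [
        "| Model | Segmentation IoU (%) | Classification accuracy (%) |",
        "|---|---|---|",
    ]
    names = {
        "sseg_svm": "Single-class segmenter + SVM",
        "sseg": "Single-class segmenter (contour heuristic)",
        "mcseg": "Multi-class segmenter",
        "cnn": "CNN baseline",
    }
    for tag in MODEL_TAGS:
        if tag not in agg.index:
            continue
        miou = agg.loc[tag, "mean_iou"]
        acc = agg.loc[tag, "accuracy"]
        iou_s = "/" if np.isnan(miou) else f"{100 * miou:.2f}"
        lines.append(f"| {names[tag]} | {iou_s} | {100 * acc:.2f} |")
    from pathlib import Path

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(lines) + "\n")
    return "\n".join(lines)
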