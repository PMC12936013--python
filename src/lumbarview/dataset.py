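"""Cohort manifest I/O, image/mask loading at network resolution, and
leak-free patient-level splitting.

Correlated images from one subject must never straddle the train/val/test
boundary, so the unit of splitting is the patient identifier, with subset
sizes fixed at 70/10/20 percent by largest-remainder rounding. The same
split object is reused verbatim by the segmentation stage and the
classifier stage.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._labels import VIEW_LABELS

__all__ = [
    "CohortManifest",
    "PatientSplit",
    "split_by_patient",
    "load_pair",
    "merge_classes",
    "DEFAULT_FRACTIONS",
    "NETWORK_SIZE",
]

DEFAULT_FRACTIONS = (0.70, 0.10, 0.20)
SUBSETS = ("train", "val", "test")
NETWORK_SIZE = (224, 224)

_COLUMNS = ["patient_id", "image", "mask", "view_label"]


@dataclass
class CohortManifest:
    """Table of (patient_id, image path, mask path, view label) rows."""

    table: pd.DataFrame

    @classmethod
    def from_rows(cls, rows) -> "CohortManifest":
        df = pd.DataFrame(rows, columns=_COLUMNS)
        m = cls(table=df)
        m._validate_structure()
        return m

    def _validate_structure(self):
        if list(self.table.columns) != _COLUMNS:
            raise ValueError(f"manifest columns must be {_COLUMNS}")
        dup = self.table.duplicated(subset=["patient_id", "image"])
        if dup.any():
            raise ValueError(
                f"duplicate (patient_id, image) rows: {self.table[dup]['image'].tolist()}"
            )
        bad = ~self.table["view_label"].isin(VIEW_LABELS)
        if bad.any():
            raise ValueError(
                f"unknown view labels: {sorted(self.table[bad]['view_label'].unique())}"
            )

    def __len__(self):
        return len(self.table)

    @property
    def patients(self) -> list[str]:
        return sorted(self.table["patient_id"].unique())

    def rows_for(self, split: "PatientSplit", subset: str) -> pd.DataFrame:
        pids = split.patients(subset)
        return self.table[self.table["patient_id"].isin(pids)].reset_index(drop=True)

    def save(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(path, index=False)

    @classmethod
    def load(cls, path, check_files: bool = True) -> "CohortManifest":
        df = pd.read_csv(path, dtype=str)
        m = cls(table=df)
        m._validate_structure()
        if check_files:
            for col in ("image", "mask"):
                for p in df[col]:
                    if not Path(p).exists():
                        raise FileNotFoundError(f"manifest references missing file {p}")
        return m


@dataclass
class PatientSplit:
    """Assignment of every patient to exactly one of train/val/test."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS
    seed: int = 0

    def patients(self, subset: str) -> list[str]:
        if subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}")
        return sorted(p for p, s in self.assignment.items() if s == subset)

    def counts(self) -> dict[str, int]:
        return {s: len(self.patients(s)) for s in SUBSETS}

    def save(self, path):
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        payload = {
            "assignment": self.assignment,
            "fractions": list(self.fractions),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "PatientSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            assignment=payload["assignment"],
            fractions=tuple(payload["fractions"]),
            seed=payload["seed"],
        )


def _largest_remainder_counts(n: int, fractions) -> list[int]:
    raw = [f * n for f in fractions]
    base = [math.floor(r) for r in raw]
    leftover = n - sum(base)
    # distribute by remainder, ties broken by subset order (train, val, test)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_by_patient(
    manifest: CohortManifest | list[str],
    fractions=DEFAULT_FRACTIONS,
    seed: int = 0,
) -> PatientSplit:
    """Shuffle patients by ``seed`` and allocate them to train/val/test by
    largest-remainder rounding of ``fraction * n_patients``."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    patients = manifest.patients if isinstance(manifest, CohortManifest) else sorted(set(manifest))
    n = len(patients)
    n_nonzero = sum(1 for f in fractions if f > 0)
    if n < max(3, n_nonzero):
        raise ValueError(f"need at least {max(3, n_nonzero)} patients, got {n}")
    rng = np.random.default_rng(seed)
    shuffled = [patients[i] for i in rng.permutation(n)]
    counts = _largest_remainder_counts(n, fractions)
    assignment = {}
    start = 0
    for subset, k in zip(SUBSETS, counts):
        for pid in shuffled[start : start + k]:
            assignment[pid] = subset
        start += k
    return PatientSplit(assignment=assignment, fractions=tuple(fractions), seed=seed)


def merge_classes(mask: np.ndarray) -> np.ndarray:
    """Merge the two landmark classes into a single foreground category:
    output is 1 where input is 1 or 2, else 0."""
    mask = np.asarray(mask)
    _validate_mask_values(mask)
    return (mask > 0).astype(np.uint8)


def _validate_mask_values(mask: np.ndarray):
    values = np.unique(mask)
    bad = set(values.tolist()) - {0, 1, 2}
    if bad:
        raise ValueError(f"mask contains unexpected value {sorted(bad)[0]}")


def load_pair(image_path, mask_path, target_size=NETWORK_SIZE):
    """Load an image/mask pair and resize to network resolution.

    The image is resized with bilinear interpolation and scaled to float32
    in [0, 1]; the mask with nearest-neighbour interpolation, which cannot
    invent label values. Mask values are validated against {0, 1, 2}.
    """
    img = Image.open(image_path).convert("L")
    msk = Image.open(mask_path).convert("L")
    _validate_mask_values(np.asarray(msk))
    th, tw = target_size
    img = img.resize((tw, th), Image.BILINEAR)
    msk = msk.resize((tw, th), Image.NEAREST)
    image = np.asarray(img, dtype=np.float32) / 255.0
    mask = np.asarray(msk, dtype=np.uint8)
    _validate_mask_values(mask)
    return image, mask
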