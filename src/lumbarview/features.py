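"""Grid-occupancy vectorization of binary segmentation masks.

Each 224x224 mask is divided into a 16-by-16 grid of non-overlapping
subregions (14x14 px each), giving 256 subregions per image. Bit ``c_j`` of
the feature vector is 1 iff subregion ``j`` contains at least one
foreground pixel, with row-major indexing (``j = 16 * row + col``;
``c_0`` is top-left). Stacking N masks yields the N x 256 feature matrix
that the second-stage SVM consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GridFeature", "FeatureMatrix", "vectorize_mask", "build_feature_matrix"]

MASK_SIZE = (224, 224)
DEFAULT_GRID_SIDE = 16


@dataclass
class GridFeature:
    bits: np.ndarray  # uint8, length grid_side**2, values {0, 1}
    grid_side: int = DEFAULT_GRID_SIDE
    mask_size: tuple[int, int] = MASK_SIZE

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8).ravel()
        if self.bits.size != self.grid_side ** 2:
            raise ValueError(
                f"feature length {self.bits.size} != grid_side**2 = {self.grid_side ** 2}"
            )
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("feature bits must be binary")

    @property
    def is_empty(self) -> bool:
        """True when no subregion is occupied — no structure detected."""
        return not self.bits.any()


def _validate_binary_mask(mask: np.ndarray, grid_side: int) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.shape != MASK_SIZE:
        raise ValueError(f"mask must be {MASK_SIZE}, got {mask.shape}")
    values = np.unique(mask)
    if not set(values.tolist()) <= {0, 1}:
        raise ValueError(
            f"mask must be binary; found value {sorted(set(values.tolist()) - {0, 1})[0]}"
        )
    if MASK_SIZE[0] % grid_side or MASK_SIZE[1] % grid_side:
        raise ValueError(
            f"grid_side={grid_side} does not divide mask size {MASK_SIZE} evenly"
        )
    return mask


def vectorize_mask(mask: np.ndarray, grid_side: int = DEFAULT_GRID_SIDE) -> GridFeature:
    """Occupancy bits of a binary 224x224 mask over a grid_side^2 grid.

    With the default 16-by-16 grid each cell spans 14x14 px and the output
    has length 256. No padding is ever applied: a geometry that does not
    divide evenly is an error.
    """
    mask = _validate_binary_mask(mask, grid_side)
    cell_h = MASK_SIZE[0] // grid_side
    cell_w = MASK_SIZE[1] // grid_side
    occ = (
        mask.reshape(grid_side, cell_h, grid_side, cell_w)
        .any(axis=(1, 3))
        .astype(np.uint8)
    )
    return GridFeature(bits=occ.ravel(), grid_side=grid_side)


@dataclass
class FeatureMatrix:
    matrix: np.ndarray  # (N, L) uint8
    labels: list[str] = field(default_factory=list)
    grid_side: int = DEFAULT_GRID_SIDE

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("label count must match row count")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path):
        cols = [f"c{j}" for j in range(self.matrix.shape[1])]
        df = pd.DataFrame(self.matrix, columns=cols)
        df["label"] = self.labels
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").astype(str).tolist()
        matrix = df.to_numpy(dtype=np.uint8)
        side = int(round(np.sqrt(matrix.shape[1])))
        return cls(matrix=matrix, labels=labels, grid_side=side)


def build_feature_matrix(masks, labels, grid_side: int = DEFAULT_GRID_SIDE) -> FeatureMatrix:
    """Row i is ``vectorize_mask(masks[i])``; shape (N, grid_side**2)."""
    masks = list(masks)
    labels = list(labels)
    if not masks:
        raise ValueError("cannot build a feature matrix from zero masks")
    if len(labels) != len(masks):
        raise ValueError(
            f"got {len(masks)} masks but {len(labels)} labels"
        )
    rows = [vectorize_mask(m, grid_side).bits for m in masks]
    return FeatureMatrix(matrix=np.stack(rows), labels=[str(l) for l in labels], grid_side=grid_side)
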