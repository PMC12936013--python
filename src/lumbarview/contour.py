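"""Upper-contour shape oracle for bony-landmark masks.

The two landmark classes differ in the geometry of the bone surface seen by
the probe: the intervertebral foramen (F) presents a smooth "goat peak"
profile — two peaks, one trough, few inflection points — while the
transverse process (T) presents an irregular profile with many inflection
points. These functions measure that contrast directly on a binary mask:
extract the top-of-foreground height profile, smooth it, and count extrema
and curvature sign changes. They are deliberately simple and independent of
any learned model, so they double as a ground-truth check on the synthetic
generator and as the mask-only heuristic classifier.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "upper_contour",
    "count_profile_extrema",
    "count_curvature_sign_changes",
    "INFLECTION_THRESHOLD",
]

#: Decision threshold on the curvature sign-change count: F-shapes are
#: constructed to score <= 4 and T-shapes >= 5, so 4.5 separates them.
INFLECTION_THRESHOLD = 4.5

#: Profile smoothing (px) and minimum slope / curvature magnitudes treated
#: as nonzero. Chosen for native-resolution masks (structures a few hundred
#: px across); they only discard pixel-quantization jitter, not real bumps.
_SMOOTH_SIGMA = 6.0
_SLOPE_TOL = 0.08
_CURV_TOL = 0.004


def upper_contour(mask: np.ndarray) -> np.ndarray:
    """Height profile of the top of the foreground, one value per column.

    Height is measured upward (``n_rows - first_foreground_row``) over the
    contiguous span of columns that contain any foreground, so a taller
    bone surface gives a larger value. Raises on an empty mask.
    """
    fg = np.asarray(mask) > 0
    cols = np.flatnonzero(fg.any(axis=0))
    if cols.size == 0:
        raise ValueError("mask has no foreground; no contour to extract")
    span = np.arange(cols[0], cols[-1] + 1)
    top = np.full(span.size, fg.shape[0], dtype=float)
    sub = fg[:, span]
    has = sub.any(axis=0)
    top[has] = sub[:, has].argmax(axis=0)
    # columns inside the span with no foreground (possible for very concave
    # shapes) are bridged by interpolation to keep the profile continuous
    if not has.all():
        top = np.interp(span, span[has], top[has])
    return fg.shape[0] - top


def _nonzero_sign_runs(values: np.ndarray, tol: float) -> np.ndarray:
    """Signs of ``values`` with |v| <= tol zeroed, consecutive repeats and
    zeros collapsed — the sequence of distinct slope/curvature signs."""
    s = np.sign(np.where(np.abs(values) > tol, values, 0.0))
    s = s[s != 0]
    if s.size == 0:
        return s
    return s[np.r_[True, s[1:] != s[:-1]]]


def count_profile_extrema(profile: np.ndarray, smooth_sigma: float = _SMOOTH_SIGMA):
    """(n_maxima, n_interior_minima) of the smoothed height profile.

    Counted as sign transitions of the first difference: ``+ -> -`` is a
    local maximum, ``- -> +`` an interior local minimum (a trough between
    peaks; the profile ends do not count).
    """
    smooth = gaussian_filter1d(np.asarray(profile, dtype=float), smooth_sigma, mode="nearest")
    runs = _nonzero_sign_runs(np.diff(smooth), _SLOPE_TOL)
    n_max = int(np.sum((runs[:-1] > 0) & (runs[1:] < 0)))
    n_min = int(np.sum((runs[:-1] < 0) & (runs[1:] > 0)))
    return n_max, n_min


def count_curvature_sign_changes(
    profile: np.ndarray, smooth_sigma: float = _SMOOTH_SIGMA
) -> int:
    """Number of curvature (second-difference) sign changes along the
    smoothed height profile — the inflection-point count."""
    smooth = gaussian_filter1d(np.asarray(profile, dtype=float), smooth_sigma, mode="nearest")
    curv = np.diff(smooth, 2)
    runs = _nonzero_sign_runs(curv, _CURV_TOL)
    return max(0, runs.size - 1)
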