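"""Synthetic B-mode lumbar phantom: bony-landmark masks and ultrasound-like
renders.

The generator emulates the two lumbar transverse views at the level of the
bone surface the probe actually sees:

* **F** (intervertebral foramen, PTFV view): a smooth "goat peak" surface —
  two peaks and one trough with few inflection points — built as two
  Gaussian bumps on a baseline and filled downward.
* **T** (transverse process, PTV-TP view): an irregular, distorted surface
  with many inflection points, built as a star-convex polygon with random
  radial offsets at ``n_control_points`` control points.

Renders add the dominant B-mode degradations: a hyperechoic rim along the
bone surface, acoustic shadowing beneath it, multiplicative speckle and
Gaussian blur. Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.measure import label as cc_label

from ._labels import CLASS_VALUE, VIEW_FOR_CLASS
from . import contour

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "PhantomSizingError",
    "PhantomDegenerateError",
    "generate_foramen_shape",
    "generate_transverse_process_shape",
    "render_bmode",
    "generate_cohort",
]

_MAX_ATTEMPTS = 50


class PhantomSizingError(ValueError):
    """The requested structure cannot fit inside the canvas."""


class PhantomDegenerateError(RuntimeError):
    """Shape sampling failed to meet its contour contract within the retry
    limit."""


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the synthetic image/mask generator.

    ``canvas_size`` defaults to the native acquisition raster (720 rows by
    960 columns); images are rendered at this size and resized to the
    network resolution downstream. ``structure_scale`` is the structure
    footprint as a fraction of canvas width. ``speckle_sigma`` scales
    multiplicative noise ``1 + sigma * z``; ``shadow_attenuation``
    multiplies everything below the bone surface (1 = no shadow);
    ``blur_sigma`` is the point-spread blur in px.
    """

    shape_class: str = "F"
    canvas_size: tuple[int, int] = (720, 960)
    structure_scale: float = 0.40
    center_jitter: tuple[float, float] = (30.0, 40.0)  # (row, col) px
    rotation_range: float = 8.0  # degrees, symmetric
    speckle_sigma: float = 0.15
    shadow_attenuation: float = 0.45
    blur_sigma: float = 1.5
    n_control_points: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.shape_class not in ("F", "T"):
            raise ValueError(f"shape_class must be 'F' or 'T', got {self.shape_class!r}")
        h, w = self.canvas_size
        if h <= 0 or w <= 0:
            raise ValueError("canvas_size components must be positive")
        if not 0.0 < self.structure_scale < 1.0:
            raise ValueError("structure_scale must be in (0, 1)")
        if not 0.0 <= self.shadow_attenuation <= 1.0:
            raise ValueError("shadow_attenuation must be in [0, 1]")
        if self.speckle_sigma < 0 or self.blur_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if self.n_control_points < 4:
            raise ValueError("n_control_points must be >= 4")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class PhantomSample:
    image: np.ndarray  # float32 in [0, 1]
    mask: np.ndarray  # uint8, values {0, class value}
    view_label: str
    patient_id: str


# --------------------------------------------------------------------------
# geometry helpers


def _draw_center(spec: PhantomSpec, rng, anchor=None):
    h, w = spec.canvas_size
    jr, jc = spec.center_jitter
    if anchor is None:
        anchor = (0.45 * h, 0.5 * w)
    cy = anchor[0] + rng.uniform(-jr, jr)
    cx = anchor[1] + rng.uniform(-jc, jc)
    return cy, cx


def _rotate_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    if abs(angle_deg) < 1e-9:
        return mask
    return ndimage.rotate(mask, angle_deg, reshape=False, order=0, prefilter=False)


def _fits_canvas(mask: np.ndarray) -> bool:
    return (
        not mask[0, :].any()
        and not mask[-1, :].any()
        and not mask[:, 0].any()
        and not mask[:, -1].any()
    )


def _single_component(mask: np.ndarray) -> bool:
    return cc_label(mask > 0, connectivity=2).max() == 1


def _check_sizing(spec: PhantomSpec):
    h, w = spec.canvas_size
    jr, jc = spec.center_jitter
    width = spec.structure_scale * w * 1.25  # envelope incl. per-patient scale spread
    # structure extends ~width/2 sideways, ~0.35*width up (both peaks) and
    # ~0.2*width down from a centre that wanders up to 3x the jitter range
    if (
        width / 2 + 3 * jc + 10 > w / 2
        or 0.35 * width + 3 * jr + 10 > 0.45 * h
        or 0.20 * width + 3 * jr + 10 > 0.55 * h
    ):
        raise PhantomSizingError(
            f"structure_scale={spec.structure_scale} with jitter {spec.center_jitter} "
            f"does not fit the {spec.canvas_size} canvas"
        )


def generate_foramen_shape(
    spec: PhantomSpec,
    rng: np.random.Generator,
    *,
    _anchor=None,
    _scale_mult: float = 1.0,
    _rotation: float | None = None,
) -> np.ndarray:
    """Binary mask of a goat-peak (foramen) bone surface.

    The upper contour is the sum of two Gaussian bumps over a baseline,
    filled downward; by construction it has exactly two local maxima
    separated by one trough and at most 4 curvature sign changes. The
    sampled mask is verified against the contour oracle and resampled on
    the rare discretization failure.
    """
    if spec.shape_class != "F":
        raise ValueError("spec.shape_class must be 'F'")
    _check_sizing(spec)
    h, w = spec.canvas_size
    for _ in range(_MAX_ATTEMPTS):
        cy, cx = _draw_center(spec, rng, _anchor)
        width = spec.structure_scale * w * _scale_mult * rng.uniform(0.92, 1.08)
        half = width / 2
        sep = rng.uniform(0.34, 0.46) * width
        sig = rng.uniform(0.085, 0.125) * width * np.ones(2)
        sig *= rng.uniform(0.85, 1.15, size=2)
        amp = rng.uniform(0.16, 0.26) * width * np.ones(2)
        amp *= rng.uniform(0.8, 1.2, size=2)
        if sep < 2.4 * sig.max():  # bumps would merge into one peak
            continue
        depth = rng.uniform(0.10, 0.16) * width
        x0 = int(round(cx - half))
        x1 = int(round(cx + half))
        xs = np.arange(x0, x1 + 1, dtype=float)
        u = xs - cx
        bumps = amp[0] * np.exp(-0.5 * ((u + sep / 2) / sig[0]) ** 2) + amp[1] * np.exp(
            -0.5 * ((u - sep / 2) / sig[1]) ** 2
        )
        taper = np.clip((half - np.abs(u)) / (0.18 * width), 0.0, 1.0)
        top = cy - bumps * taper
        bottom = cy + depth * np.sqrt(np.clip(1 - (u / half) ** 2, 0.0, None))
        mask = np.zeros((h, w), dtype=np.uint8)
        rows = np.arange(h, dtype=float)[:, None]
        cols_ok = (xs >= 0) & (xs < w)
        sub = (rows >= top[None, cols_ok]) & (rows <= bottom[None, cols_ok])
        mask[:, xs[cols_ok].astype(int)] = sub.astype(np.uint8)
        angle = _rotation if _rotation is not None else rng.uniform(
            -spec.rotation_range, spec.rotation_range
        )
        mask = _rotate_mask(mask, angle)
        if not (mask.any() and _fits_canvas(mask) and _single_component(mask)):
            continue
        prof = contour.upper_contour(mask)
        n_max, n_min = contour.count_profile_extrema(prof)
        if n_max == 2 and n_min == 1 and contour.count_curvature_sign_changes(prof) <= 4:
            return mask
    raise PhantomDegenerateError(
        "could not sample a goat-peak mask meeting the contour contract"
    )


def generate_transverse_process_shape(
    spec: PhantomSpec,
    rng: np.random.Generator,
    *,
    _anchor=None,
    _scale_mult: float = 1.0,
    _rotation: float | None = None,
) -> np.ndarray:
    """Binary mask of an irregular (transverse-process) bone structure.

    A star-convex polygon with random radial offsets at
    ``n_control_points`` control points, densified by periodic
    interpolation of the radius; resampled until the upper contour shows at
    least 5 curvature sign changes (strictly above the goat-peak bound).
    """
    if spec.shape_class != "T":
        raise ValueError("spec.shape_class must be 'T'")
    if spec.n_control_points < 6:
        raise ValueError("n_control_points must be >= 6 for the T shape")
    _check_sizing(spec)
    h, w = spec.canvas_size
    n = spec.n_control_points
    for _ in range(_MAX_ATTEMPTS):
        cy, cx = _draw_center(spec, rng, _anchor)
        width = spec.structure_scale * w * _scale_mult * rng.uniform(0.92, 1.08)
        r0 = width / 2 * 0.55
        base_angles = np.sort(
            (np.arange(n) + rng.uniform(-0.35, 0.35, n)) * (2 * np.pi / n)
        )
        radii = r0 * (1.0 + rng.uniform(-0.42, 0.42, n))
        radii = np.clip(radii, 0.3 * r0, 1.45 * r0)
        # periodic radius profile sampled densely -> smooth wavy outline
        dense = np.linspace(0, 2 * np.pi, 241)
        ang_ext = np.r_[base_angles - 2 * np.pi, base_angles, base_angles + 2 * np.pi]
        rad_ext = np.r_[radii, radii, radii]
        r_dense = np.interp(dense, ang_ext, rad_ext)
        # the process reads as the narrow "stem of the shamrock": taller
        # than wide, in contrast to the foramen's wide shallow ridge
        ys = cy + 1.15 * r_dense * np.sin(dense)
        xs = cx + 0.75 * r_dense * np.cos(dense)
        rr, cc = draw_polygon(ys, xs, shape=(h, w))
        mask = np.zeros((h, w), dtype=np.uint8)
        mask[rr, cc] = 1
        angle = _rotation if _rotation is not None else rng.uniform(
            -spec.rotation_range, spec.rotation_range
        )
        mask = _rotate_mask(mask, angle)
        if not (mask.any() and _fits_canvas(mask) and _single_component(mask)):
            continue
        prof = contour.upper_contour(mask)
        if contour.count_curvature_sign_changes(prof) >= 5:
            return mask
    raise PhantomDegenerateError(
        "could not sample an irregular transverse-process mask meeting the "
        "contour contract"
    )


def generate_shape(spec: PhantomSpec, rng: np.random.Generator, **kw) -> np.ndarray:
    if spec.shape_class == "F":
        return generate_foramen_shape(spec, rng, **kw)
    return generate_transverse_process_shape(spec, rng, **kw)


# --------------------------------------------------------------------------
# rendering


def _soft_tissue_texture(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Background echo field: baseline soft tissue plus a few undulating
    echogenic bands (fascial planes / muscle interfaces) whose depth,
    brightness and undulation vary image to image. The bands carry no
    information about the view class — they exist to give global texture
    the patient-to-patient variability real scans have."""
    img = np.full((h, w), 0.40, dtype=np.float64)
    xs = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)[:, None]
    for _ in range(int(rng.integers(2, 5))):
        depth0 = rng.uniform(0.05, 0.90) * h
        amp = rng.uniform(10.0, 40.0)
        period = rng.uniform(0.5, 2.0) * w
        phase = rng.uniform(0, 2 * np.pi)
        center = depth0 + amp * np.sin(2 * np.pi * xs / period + phase)
        thickness = rng.uniform(6.0, 18.0)
        brightness = rng.uniform(0.12, 0.30)
        img += brightness * np.exp(-0.5 * ((rows - center[None, :]) / thickness) ** 2)
    return img


def _add_distractor_reflectors(img: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One to three bright curved arcs with their own partial shadows —
    adjacent bony prominences and strong fascial reflectors that *look*
    bone-like in the raw image but are not the annotated landmark. They
    make end-to-end image classification genuinely hard (several candidate
    reflectors per scene) while leaving the landmark annotation clean."""
    h, w = img.shape
    rows = np.arange(h, dtype=float)[:, None]
    for _ in range(int(rng.integers(1, 4))):
        length = rng.uniform(0.12, 0.30) * w
        x0 = rng.uniform(0.05 * w, 0.95 * w - length)
        depth0 = rng.uniform(0.15, 0.75) * h
        bend = rng.uniform(-0.25, 0.25) * length
        xs = np.arange(int(x0), int(x0 + length))
        u = (xs - (x0 + length / 2)) / (length / 2)
        center = depth0 + bend * u ** 2
        brightness = rng.uniform(0.35, 0.55)
        sigma = rng.uniform(3.0, 6.0)
        att = rng.uniform(0.5, 0.8)
        col = img[:, xs]
        col += brightness * np.exp(-0.5 * ((rows - center[None, :]) / sigma) ** 2)
        col[rows > (center[None, :] + 2 * sigma)] *= att
        img[:, xs] = col
    return img


def render_bmode(mask: np.ndarray, spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Render a B-mode-like grayscale image from a binary bone mask.

    Composition order: base tissue texture (variable soft-tissue bands,
    with the bone interior at an elevated echo level), hyperechoic rim
    along the bone's upper surface, multiplicative acoustic shadow strictly
    below the surface, per-image gain, multiplicative speckle, Gaussian
    blur, clip to [0, 1].
    """
    mask = np.asarray(mask)
    if mask.shape != tuple(spec.canvas_size):
        raise ValueError(
            f"mask shape {mask.shape} does not match spec canvas {spec.canvas_size}"
        )
    h, w = mask.shape
    fg = mask > 0
    img = _soft_tissue_texture(h, w, rng)
    img[fg] = 0.85  # bone interior echoes brighter than soft tissue

    has = fg.any(axis=0)
    top = np.where(has, fg.argmax(axis=0), h).astype(float)  # h == "no surface"
    rows = np.arange(h, dtype=float)[:, None]
    # hyperechoic rim: bright band centred on the surface row
    rim = 0.55 * np.exp(-0.5 * ((rows - top[None, :]) / 5.0) ** 2)
    rim[:, ~has] = 0.0
    img += rim
    # acoustic shadow: everything strictly below the bone surface attenuated
    below = rows > top[None, :]
    img[below] *= spec.shadow_attenuation
    img *= rng.uniform(0.85, 1.15)  # overall gain varies scan to scan
    if spec.speckle_sigma > 0:
        img *= 1.0 + spec.speckle_sigma * rng.standard_normal((h, w))
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.blur_sigma)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_sample(spec: PhantomSpec, rng: np.random.Generator, patient_id: str = "P0000", **kw) -> PhantomSample:
    shape = generate_shape(spec, rng, **kw)
    image = render_bmode(shape, spec, rng)
    mask = (shape * CLASS_VALUE[spec.shape_class]).astype(np.uint8)
    return PhantomSample(
        image=image,
        mask=mask,
        view_label=VIEW_FOR_CLASS[spec.shape_class],
        patient_id=patient_id,
    )


# --------------------------------------------------------------------------
# cohort generation


def generate_cohort(
    n_patients: int,
    images_per_patient: int,
    class_balance: float,
    base_spec: PhantomSpec,
    seed: int,
    out_dir,
):
    """Write a synthetic cohort to ``out_dir`` and return its manifest.

    ``class_balance`` is the fraction of patients whose view class is F
    (PTFV). All images of one patient share one view class and a
    patient-level geometry anchor (centre, scale, rotation), with smaller
    per-image jitter on top — so patient-level splitting is meaningful.
    Images and masks are 8-bit grayscale PNG; mask pixels hold the literal
    class value (0 background, 1 F, 2 T).
    """
    from .dataset import CohortManifest  # local import: no module cycle at import time

    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if images_per_patient < 1:
        raise ValueError("images_per_patient must be >= 1")
    if not 0.0 <= class_balance <= 1.0:
        raise ValueError("class_balance must be in [0, 1]")

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    msk_dir = out_dir / "masks"
    img_dir.mkdir(parents=True, exist_ok=True)
    msk_dir.mkdir(parents=True, exist_ok=True)

    n_f = int(round(class_balance * n_patients))
    h, w = base_spec.canvas_size
    jr, jc = base_spec.center_jitter
    rows = []
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    for p in range(n_patients):
        rng = np.random.default_rng(streams[p])
        cls = "F" if p < n_f else "T"
        pid = f"P{p:04d}"
        spec = dataclasses.replace(base_spec, shape_class=cls, seed=seed)
        # patient-level anchor shared by all of this patient's images
        anchor = (
            0.45 * h + rng.uniform(-2.0, 2.0) * jr,
            0.5 * w + rng.uniform(-2.0, 2.0) * jc,
        )
        scale_mult = rng.uniform(0.85, 1.15)
        rot0 = rng.uniform(-spec.rotation_range, spec.rotation_range)
        for i in range(images_per_patient):
            rot = rot0 + rng.uniform(-2.0, 2.0)
            sample = generate_sample(
                spec,
                rng,
                patient_id=pid,
                _anchor=anchor,
                _scale_mult=scale_mult,
                _rotation=rot,
            )
            img_path = img_dir / f"{pid}_{i:02d}.png"
            msk_path = msk_dir / f"{pid}_{i:02d}.png"
            Image.fromarray(
                np.round(sample.image * 255).astype(np.uint8), mode="L"
            ).save(img_path)
            Image.fromarray(sample.mask, mode="L").save(msk_path)
            rows.append(
                {
                    "patient_id": pid,
                    "image": str(img_path),
                    "mask": str(msk_path),
                    "view_label": sample.view_label,
                }
            )
    manifest = CohortManifest.from_rows(rows)
    manifest.save(out_dir / "manifest.csv")
    return manifest
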