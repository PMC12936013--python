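"""Phantom generator: shape contracts, rendering physics, cohort plumbing."""

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pytest
from skimage.measure import label as cc_label

from lumbarview import contour, phantom
from lumbarview.phantom import PhantomSpec


def _noise_free(cls, seed):
    return PhantomSpec(shape_class=cls, speckle_sigma=0.0, blur_sigma=0.0, seed=seed)


class TestForamenShape:
    def test_goat_peak_profile_two_peaks_one_trough(self):
        spec = PhantomSpec(shape_class="F", seed=1)
        mask = phantom.generate_foramen_shape(spec, spec.rng())
        n_max, n_min = contour.count_profile_extrema(contour.upper_contour(mask))
        assert (n_max, n_min) == (2, 1)

    def test_smooth_contour_few_inflections(self):
        spec = PhantomSpec(shape_class="F", seed=1)
        mask = phantom.generate_foramen_shape(spec, spec.rng())
        assert contour.count_curvature_sign_changes(contour.upper_contour(mask)) <= 4

    def test_same_seed_identical_mask(self):
        spec = _noise_free("F", 4)
        m1 = phantom.generate_foramen_shape(spec, spec.rng())
        m2 = phantom.generate_foramen_shape(spec, spec.rng())
        assert np.array_equal(m1, m2)

    def test_different_seeds_differ(self):
        s1, s2 = PhantomSpec(shape_class="F", seed=1), PhantomSpec(shape_class="F", seed=2)
        m1 = phantom.generate_foramen_shape(s1, s1.rng())
        m2 = phantom.generate_foramen_shape(s2, s2.rng())
        assert (m1 != m2).sum() >= 1

    def test_oversized_structure_raises_sizing_error(self):
        spec = PhantomSpec(shape_class="F", structure_scale=0.95, seed=0)
        with pytest.raises(phantom.PhantomSizingError):
            phantom.generate_foramen_shape(spec, spec.rng())

    def test_wrong_class_rejected(self):
        spec = PhantomSpec(shape_class="T", seed=0)
        with pytest.raises(ValueError, match="'F'"):
            phantom.generate_foramen_shape(spec, spec.rng())


class TestTransverseProcessShape:
    def test_irregular_contour_many_inflections(self):
        spec = PhantomSpec(shape_class="T", seed=3)
        mask = phantom.generate_transverse_process_shape(spec, spec.rng())
        assert contour.count_curvature_sign_changes(contour.upper_contour(mask)) >= 5

    def test_too_few_control_points_rejected(self):
        spec = PhantomSpec(shape_class="T", n_control_points=4, seed=0)
        with pytest.raises(ValueError, match="control_points"):
            phantom.generate_transverse_process_shape(spec, spec.rng())

    @pytest.mark.parametrize("cls", ["F", "T"])
    def test_single_component_inside_canvas(self, cls):
        for seed in (0, 7, 13):
            spec = PhantomSpec(shape_class=cls, seed=seed)
            mask = phantom.generate_shape(spec, spec.rng())
            assert cc_label(mask > 0, connectivity=2).max() == 1
            assert not mask[0].any() and not mask[-1].any()
            assert not mask[:, 0].any() and not mask[:, -1].any()


class TestRender:
    def _mask_and_spec(self, **kw):
        spec = PhantomSpec(shape_class="F", seed=6, **kw)
        mask = phantom.generate_foramen_shape(spec, spec.rng())
        return mask, spec

    def test_output_clipped_to_unit_interval(self):
        mask, spec = self._mask_and_spec(speckle_sigma=0.6)
        img = phantom.render_bmode(mask, spec, spec.rng())
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_attenuation_acts_multiplicatively_below_surface(self):
        mask, _ = self._mask_and_spec()
        base = dict(shape_class="F", speckle_sigma=0.0, blur_sigma=0.0, seed=6)
        spec1 = PhantomSpec(shadow_attenuation=1.0, **base)
        img1 = phantom.render_bmode(mask, spec1, spec1.rng())
        spec0 = PhantomSpec(shadow_attenuation=0.6, **base)
        img0 = phantom.render_bmode(mask, spec0, spec0.rng())
        region = _subbone_region(mask) & (img1 < 0.99)  # exclude clipped pixels
        np.testing.assert_allclose(img0[region], 0.6 * img1[region], atol=1e-6)
        # and identity attenuation touches nothing: images agree above surface
        above = ~_subbone_region(mask)
        np.testing.assert_allclose(img0[above], img1[above], atol=1e-6)

    def test_shadow_darker_than_lateral_tissue(self):
        mask, spec = self._mask_and_spec(shadow_attenuation=0.3)
        img = phantom.render_bmode(mask, spec, spec.rng())
        sub = _subbone_region(mask)
        lateral = np.zeros_like(sub)
        rows = sub.any(axis=1)
        cols = sub.any(axis=0)
        lateral[np.ix_(rows, ~cols)] = True
        assert img[sub].mean() < img[lateral].mean()

    def test_lower_attenuation_never_brightens_shadow(self):
        mask, _ = self._mask_and_spec()
        means = []
        for att in (0.8, 0.5, 0.2):
            spec = PhantomSpec(shape_class="F", shadow_attenuation=att, seed=6)
            img = phantom.render_bmode(mask, spec, spec.rng())
            means.append(img[_subbone_region(mask)].mean())
        assert means[0] >= means[1] >= means[2]

    def test_canvas_mismatch_rejected(self):
        mask, spec = self._mask_and_spec()
        small = dataclasses.replace(spec, canvas_size=(224, 224))
        with pytest.raises(ValueError, match="canvas"):
            phantom.render_bmode(mask, small, small.rng())


def _subbone_region(mask):
    """Pixels strictly below the bone surface, within the mask's columns."""
    fg = mask > 0
    has = fg.any(axis=0)
    top = np.where(has, fg.argmax(axis=0), mask.shape[0])
    rows = np.arange(mask.shape[0])[:, None]
    return rows > top[None, :]


class TestSpecValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"structure_scale": 0.0},
            {"structure_scale": 1.0},
            {"shadow_attenuation": 1.5},
            {"speckle_sigma": -0.1},
            {"n_control_points": 3},
            {"canvas_size": (0, 960)},
            {"shape_class": "X"},
        ],
    )
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            PhantomSpec(**kw)


class TestCohort:
    def test_rows_and_balance(self, tiny_cohort):
        assert len(tiny_cohort) == 16
        per_view = tiny_cohort.table.groupby("view_label")["patient_id"].nunique()
        assert per_view["PTFV"] == 4 and per_view["PTV_TP"] == 4

    def test_patient_images_share_view(self, tiny_cohort):
        views = tiny_cohort.table.groupby("patient_id")["view_label"].nunique()
        assert (views == 1).all()

    def test_masks_use_literal_class_values(self, tiny_cohort):
        from PIL import Image

        for view, expected in (("PTFV", 1), ("PTV_TP", 2)):
            row = tiny_cohort.table[tiny_cohort.table["view_label"] == view].iloc[0]
            values = set(np.unique(np.asarray(Image.open(row["mask"]))).tolist())
            assert values == {0, expected}

    def test_regeneration_is_byte_identical(self, tmp_path):
        spec = PhantomSpec()
        paths = []
        for sub in ("a", "b"):
            phantom.generate_cohort(3, 1, 0.5, spec, seed=33, out_dir=tmp_path / sub)
            paths.append(tmp_path / sub)
        man_a = (paths[0] / "manifest.csv").read_text().replace(str(paths[0]), "")
        man_b = (paths[1] / "manifest.csv").read_text().replace(str(paths[1]), "")
        assert man_a == man_b
        for img in sorted((paths[0] / "images").iterdir()):
            other = paths[1] / "images" / img.name
            assert hashlib.sha256(img.read_bytes()).digest() == hashlib.sha256(
                other.read_bytes()
            ).digest()

    def test_invalid_args_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            phantom.generate_cohort(0, 1, 0.5, PhantomSpec(), 0, tmp_path)
        with pytest.raises(ValueError):
            phantom.generate_cohort(2, 1, 1.5, PhantomSpec(), 0, tmp_path)
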