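"""Manifest I/O, patient-level splitting, loading and class merging."""

import numpy as np
import pytest
from PIL import Image

from lumbarview import dataset
from lumbarview.dataset import CohortManifest, PatientSplit, merge_classes, split_by_patient


class TestSplit:
    def test_counts_at_100_patients(self):
        patients = [f"P{i:03d}" for i in range(100)]
        split = split_by_patient(patients, (0.7, 0.1, 0.2), seed=0)
        assert split.counts() == {"train": 70, "val": 10, "test": 20}

    def test_largest_remainder_at_425_patients(self):
        # raw allocations 297.5 / 42.5 / 85.0: one leftover seat goes to
        # train on the train>val>test tie-break
        patients = [f"P{i:04d}" for i in range(425)]
        split = split_by_patient(patients, (0.7, 0.1, 0.2), seed=0)
        assert split.counts() == {"train": 298, "val": 42, "test": 85}

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_partition_no_overlap_no_loss(self, seed):
        patients = [f"P{i:03d}" for i in range(37)]
        split = split_by_patient(patients, seed=seed)
        subsets = [set(split.patients(s)) for s in ("train", "val", "test")]
        assert set().union(*subsets) == set(patients)
        assert sum(len(s) for s in subsets) == len(patients)

    def test_deterministic_across_runs(self):
        patients = [f"P{i:03d}" for i in range(41)]
        a = split_by_patient(patients, seed=7).assignment
        b = split_by_patient(patients, seed=7).assignment
        assert a == b
        c = split_by_patient(patients, seed=8).assignment
        assert a != c

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_by_patient([f"P{i}" for i in range(10)], (0.5, 0.2, 0.2), seed=0)

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            split_by_patient(["P0", "P1"], seed=0)

    def test_round_trip_json(self, tmp_path):
        split = split_by_patient([f"P{i}" for i in range(10)], seed=4)
        split.save(tmp_path / "split.json")
        loaded = PatientSplit.load(tmp_path / "split.json")
        assert loaded.assignment == split.assignment
        assert loaded.fractions == split.fractions
        assert loaded.seed == split.seed

    def test_no_image_level_leakage(self, tiny_cohort, tiny_split):
        test_rows = tiny_cohort.rows_for(tiny_split, "test")
        train_rows = tiny_cohort.rows_for(tiny_split, "train")
        assert not set(test_rows["image"]) & set(train_rows["image"])
        assert not set(test_rows["patient_id"]) & set(train_rows["patient_id"])


class TestLoadPair:
    def test_resizes_to_network_resolution(self, tiny_cohort):
        row = tiny_cohort.table.iloc[0]
        image, mask = dataset.load_pair(row["image"], row["mask"])
        assert image.shape == (224, 224) and mask.shape == (224, 224)
        assert image.dtype == np.float32 and 0.0 <= image.min() <= image.max() <= 1.0

    def test_mask_values_preserved_under_resize(self, tiny_cohort):
        for _, row in tiny_cohort.table.iterrows():
            _, mask = dataset.load_pair(row["image"], row["mask"])
            assert set(np.unique(mask).tolist()) <= {0, 1, 2}

    def test_all_zero_mask_stays_zero(self, tmp_path):
        img_p, msk_p = tmp_path / "i.png", tmp_path / "m.png"
        Image.fromarray(np.zeros((720, 960), dtype=np.uint8)).save(img_p)
        Image.fromarray(np.zeros((720, 960), dtype=np.uint8)).save(msk_p)
        _, mask = dataset.load_pair(img_p, msk_p)
        assert not mask.any()

    def test_unexpected_mask_value_named_in_error(self, tmp_path):
        img_p, msk_p = tmp_path / "i.png", tmp_path / "m.png"
        Image.fromarray(np.zeros((64, 64), dtype=np.uint8)).save(img_p)
        bad = np.zeros((64, 64), dtype=np.uint8)
        bad[5, 5] = 7
        Image.fromarray(bad).save(msk_p)
        with pytest.raises(ValueError, match="7"):
            dataset.load_pair(img_p, msk_p)

    def test_mask_write_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 3, (224, 224)).astype(np.uint8)
        p = tmp_path / "m.png"
        Image.fromarray(mask, mode="L").save(p)
        loaded = np.asarray(Image.open(p))
        assert np.array_equal(loaded, mask)


class TestMergeClasses:
    def test_examples(self):
        assert (merge_classes(np.full((4, 4), 2, dtype=np.uint8)) == 1).all()
        m = np.zeros((10, 10), dtype=np.uint8)
        m.flat[:10] = 1
        m.flat[10:17] = 2
        assert merge_classes(m).sum() == 17

    def test_idempotent(self, rng):
        m = rng.integers(0, 3, (50, 50)).astype(np.uint8)
        once = merge_classes(m)
        assert np.array_equal(merge_classes(once), once)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError, match="3"):
            merge_classes(np.full((2, 2), 3, dtype=np.uint8))


class TestManifest:
    def test_duplicate_rows_rejected(self):
        rows = [
            {"patient_id": "P0", "image": "a.png", "mask": "b.png", "view_label": "PTFV"},
            {"patient_id": "P0", "image": "a.png", "mask": "b.png", "view_label": "PTFV"},
        ]
        with pytest.raises(ValueError, match="duplicate"):
            CohortManifest.from_rows(rows)

    def test_missing_file_detected_on_load(self, tiny_cohort, tmp_path):
        path = tmp_path / "manifest.csv"
        bad = tiny_cohort.table.copy()
        bad.loc[0, "image"] = str(tmp_path / "nope.png")
        bad.to_csv(path, index=False)
        with pytest.raises(FileNotFoundError):
            CohortManifest.load(path)

    def test_csv_round_trip(self, tiny_cohort, tmp_path):
        path = tmp_path / "manifest.csv"
        tiny_cohort.save(path)
        loaded = CohortManifest.load(path)
        assert loaded.table.equals(tiny_cohort.table)
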