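"""Synthetic cohort generator: planted signals, mask geometry, determinism."""

import numpy as np
import pytest
from scipy import ndimage, stats

from gliotask.phantom import (
    BACKGROUND, EDEMA, ENHANCING, MODALITIES, NECROTIC, PhantomSpec,
    PhantomSubject, extract_patch, generate_cohort, load_cohort,
    make_feature_table, save_cohort,
)


def interior_t2_flair_gap(subject: PhantomSubject) -> float:
    interior = (subject.roi_mask == NECROTIC) | (subject.roi_mask == ENHANCING)
    return float((subject.volumes["t2"][interior]
                  - subject.volumes["flair"][interior]).mean())


class TestGenerateCohort:
    def test_stratified_counts_exact(self):
        cohort = generate_cohort(PhantomSpec(
            n_subjects=20, grid_size=16, idh_mutant_fraction=0.2, seed=1))
        n_mut = sum(s.idh_label for s in cohort)
        assert n_mut == 4
        assert len(cohort) - n_mut == 16

    def test_null_mismatch_effect_gives_indistinguishable_classes(self):
        cohort = generate_cohort(PhantomSpec(
            n_subjects=100, grid_size=16, mismatch_effect=0.0, seed=2))
        gaps = np.array([interior_t2_flair_gap(s) for s in cohort])
        labels = np.array([s.idh_label for s in cohort])
        _, p = stats.ttest_ind(gaps[labels == 1], gaps[labels == 0])
        assert p > 0.01

    def test_necrosis_effect_inflates_high_grade_cores(self):
        cohort = generate_cohort(PhantomSpec(
            n_subjects=100, grid_size=16, necrosis_effect=2.0, seed=3))
        counts = {0: [], 1: []}
        for s in cohort:
            counts[s.grade_label].append(int((s.roi_mask == NECROTIC).sum()))
        assert np.mean(counts[1]) > np.mean(counts[0])

    def test_determinism(self):
        spec = PhantomSpec(n_subjects=4, grid_size=16, seed=7)
        a, b = generate_cohort(spec), generate_cohort(spec)
        for sa, sb in zip(a, b):
            assert sa.idh_label == sb.idh_label
            assert sa.grade_label == sb.grade_label
            np.testing.assert_array_equal(sa.roi_mask, sb.roi_mask)
            np.testing.assert_array_equal(sa.features, sb.features)
            for m in MODALITIES:
                np.testing.assert_array_equal(sa.volumes[m], sb.volumes[m])

    def test_mask_geometry(self):
        cohort = generate_cohort(PhantomSpec(
            n_subjects=6, grid_size=24, necrosis_effect=2.0, seed=4))
        for s in cohort:
            labels = set(np.unique(s.roi_mask))
            assert labels <= {BACKGROUND, NECROTIC, ENHANCING, EDEMA}
            assert {NECROTIC, ENHANCING, EDEMA} <= labels
            # tumor is one connected component
            _, n_comp = ndimage.label(s.roi_mask > 0)
            assert n_comp == 1
            # necrotic core strictly inside the enhancing rim: no necrotic
            # voxel touches edema or background
            core = s.roi_mask == NECROTIC
            dilated = ndimage.binary_dilation(core)
            touched = set(np.unique(s.roi_mask[dilated]))
            assert touched <= {NECROTIC, ENHANCING}

    def test_mismatch_signal_monotone_in_effect(self):
        diffs = []
        for effect in (0.0, 1.0, 2.0):
            cohort = generate_cohort(PhantomSpec(
                n_subjects=100, grid_size=16, mismatch_effect=effect, seed=9))
            gaps = np.array([interior_t2_flair_gap(s) for s in cohort])
            labels = np.array([s.idh_label for s in cohort])
            diffs.append(gaps[labels == 1].mean() - gaps[labels == 0].mean())
        assert diffs[0] <= diffs[1] <= diffs[2]

    def test_validation_errors(self):
        with pytest.raises(ValueError, match="n_subjects"):
            PhantomSpec(n_subjects=1)
        with pytest.raises(ValueError, match="too small"):
            PhantomSpec(grid_size=8)
        with pytest.raises(ValueError, match="fraction"):
            PhantomSpec(idh_mutant_fraction=1.5)


class TestExtractPatch:
    @staticmethod
    def make_subject(grid: int, center: tuple[int, int, int], radius: int = 3):
        mask = np.zeros((grid,) * 3, dtype=np.int16)
        sl = tuple(slice(c - radius, c + radius + 1) for c in center)
        mask[sl] = ENHANCING
        rng = np.random.default_rng(0)
        vols = {m: rng.standard_normal((grid,) * 3) for m in MODALITIES}
        return PhantomSubject("sub-test", vols, mask, 0, 0, np.zeros(101))

    def test_centered_crop_spans_expected_range(self):
        s = self.make_subject(64, (32, 32, 32))
        patch = extract_patch(s, 32)
        for m in MODALITIES:
            np.testing.assert_array_equal(
                patch.volumes[m], s.volumes[m][16:48, 16:48, 16:48])

    def test_near_corner_crop_zero_pads_and_preserves_center(self):
        s = self.make_subject(64, (5, 5, 5))
        patch = extract_patch(s, 32)
        # crop spans [-11, 21): 11 zero voxels on the low side of each axis
        assert np.all(patch.volumes["t1"][:11] == 0)
        np.testing.assert_array_equal(
            patch.volumes["t1"][11:, 11:, 11:], s.volumes["t1"][:21, :21, :21])
        # ROI midpoint lands at the patch center
        idx = np.argwhere(patch.roi_mask > 0)
        mid = (idx.min(axis=0) + idx.max(axis=0) + 1) // 2
        np.testing.assert_array_equal(mid, [16, 16, 16])

    def test_empty_roi_names_subject(self):
        s = self.make_subject(16, (8, 8, 8))
        s.roi_mask[:] = 0
        with pytest.raises(ValueError, match="sub-test"):
            extract_patch(s, 8)


def _label_only_subjects(n: int, seed: int, coupled: bool = True):
    """Subjects with labels but trivial volumes, for feature-table tests."""
    rng = np.random.default_rng(seed)
    subjects = []
    for i in range(n):
        idh = int(rng.random() < 0.5)
        grade = (1 - idh if rng.random() < 0.7 else idh) if coupled \
            else int(rng.random() < 0.5)
        subjects.append(PhantomSubject(
            f"s{i:03d}", {m: np.zeros((2, 2, 2)) for m in MODALITIES},
            np.ones((2, 2, 2), dtype=np.int16), idh, grade, np.zeros(101)))
    return subjects


class TestFeatureTable:
    def test_width_is_always_101(self):
        for n in (10, 57):
            res = make_feature_table(_label_only_subjects(n, 0), seed=1)
            assert res.table.shape == (n, 101)
            assert list(res.table.columns[-2:]) == ["age", "sex"]

    def test_null_effect_calibration(self):
        # effect 0: fraction of columns with |t| above the 0.999 normal
        # quantile should be at most ~1%
        subjects = _label_only_subjects(200, 3, coupled=False)
        res = make_feature_table(subjects, n_informative=10, effect=0.0, seed=4)
        X = res.table.to_numpy()[:, :99]
        y = res.idh_labels
        t = stats.ttest_ind(X[y == 1], X[y == 0], axis=0).statistic
        frac = float(np.mean(np.abs(t) > stats.norm.ppf(0.999)))
        assert frac <= 0.01 + 1e-9

    def test_planted_columns_have_largest_correlations(self):
        hits = []
        for seed in range(10):
            subjects = _label_only_subjects(400, 100 + seed)
            res = make_feature_table(subjects, n_informative=10, effect=2.0,
                                     seed=seed)
            X = res.table.to_numpy()[:, :99]
            planted_hits = 0
            for cols, labels in ((res.informative_idh, res.idh_labels),
                                 (res.informative_grade, res.grade_labels)):
                r = np.array([stats.pointbiserialr(labels, X[:, j])[0]
                              for j in range(99)])
                top = set(np.argsort(-np.abs(r))[:10])
                planted_hits += len(top & set(cols))
            hits.append(planted_hits >= 9)
        assert sum(hits) >= 9  # >= 9/10 seeds recover >= 9 of 10 planted

    def test_age_is_wildtype_shifted(self):
        subjects = _label_only_subjects(400, 5)
        res = make_feature_table(subjects, seed=6)
        age = res.table["age"].to_numpy()
        y = res.idh_labels
        assert age[y == 0].mean() > age[y == 1].mean()

    def test_rejects_too_many_informative(self):
        with pytest.raises(ValueError, match="n_informative"):
            make_feature_table(_label_only_subjects(10, 0), n_informative=100)


def test_cohort_io_roundtrip(tmp_path):
    cohort = generate_cohort(PhantomSpec(n_subjects=3, grid_size=16, seed=13))
    save_cohort(cohort, tmp_path / "cohort")
    loaded = load_cohort(tmp_path / "cohort")
    assert [s.subject_id for s in loaded] == [s.subject_id for s in cohort]
    for a, b in zip(cohort, loaded):
        assert (a.idh_label, a.grade_label) == (b.idh_label, b.grade_label)
        np.testing.assert_array_equal(a.roi_mask, b.roi_mask)
        np.testing.assert_allclose(a.features, b.features, rtol=1e-6)
        for m in MODALITIES:
            np.testing.assert_allclose(a.volumes[m], b.volumes[m], atol=1e-6)
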