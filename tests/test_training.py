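import dataclasses

import numpy as np
import pytest

from wmhseg import (
    BinaryMask,
    FeatureSpec,
    SubjectRecord,
    TrainingConfig,
    Volume,
    assemble_training_set,
    lesion_border,
    select_training_points,
    select_training_subjects,
)
from wmhseg.training import NONWMH, WMH


def _toy_subject(sid, n_wmh_vox, shape=(12, 12, 12), seed=0):
    """Small subject with a cuboid lesion of the requested size."""
    rng = np.random.default_rng(seed)
    flair = Volume(data=rng.normal(100, 5, shape), affine=np.eye(4))
    brain = BinaryMask(data=np.ones(shape, dtype=np.uint8), affine=np.eye(4))
    manual = np.zeros(shape, dtype=np.uint8)
    flat = np.unravel_index(np.arange(n_wmh_vox), shape)
    manual[flat] = 1
    return SubjectRecord(
        subject_id=sid, modalities={"flair": flair}, brain_mask=brain,
        manual_mask=BinaryMask(data=manual, affine=np.eye(4)),
        to_mni_affine=np.eye(4),
    )


class TestSubjectSelection:
    def _cohort(self, loads):
        out = []
        for i, load in enumerate(loads):
            s = _toy_subject(f"s{i:02d}", 10, seed=i)
            s.load_score = load
            out.append(s)
        return out

    def test_high_load_takes_largest(self):
        cohort = self._cohort(range(21))
        picked = select_training_subjects(cohort, "high_load", 11)
        assert sorted(s.load_score for s in picked) == list(range(10, 21))

    def test_low_load_takes_smallest(self):
        cohort = self._cohort(range(21))
        picked = select_training_subjects(cohort, "low_load", 10)
        assert sorted(s.load_score for s in picked) == list(range(10))

    def test_tie_break_lexicographic(self):
        cohort = self._cohort([5, 5, 5])
        picked = select_training_subjects(cohort, "high_load", 2)
        assert [s.subject_id for s in picked] == ["s00", "s01"]

    def test_clamped_with_warning(self):
        cohort = self._cohort([1, 2])
        with pytest.warns(UserWarning, match="clamp"):
            picked = select_training_subjects(cohort, "any_load", 5)
        assert len(picked) == 2

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError, match=">= 1"):
            select_training_subjects(self._cohort([1]), "any_load", 0)


class TestLesionBorder:
    def test_empty_mask_empty_border(self):
        m = BinaryMask(data=np.zeros((5, 5, 5), dtype=np.uint8), affine=np.eye(4))
        assert lesion_border(m).n_voxels == 0

    def test_single_voxel_26_shell(self):
        data = np.zeros((7, 7, 7), dtype=np.uint8)
        data[3, 3, 3] = 1
        border = lesion_border(BinaryMask(data=data, affine=np.eye(4)), 1)
        assert border.n_voxels == 26
        assert border.data[3, 3, 3] == 0

    def test_full_grid_has_no_border(self):
        m = BinaryMask(data=np.ones((4, 4, 4), dtype=np.uint8), affine=np.eye(4))
        assert lesion_border(m).n_voxels == 0

    def test_width_two_shell(self):
        data = np.zeros((9, 9, 9), dtype=np.uint8)
        data[4, 4, 4] = 1
        border = lesion_border(BinaryMask(data=data, affine=np.eye(4)), 2)
        assert border.n_voxels == 5**3 - 1


class TestPointSelection:
    def test_fe_caps_at_available_and_balances(self):
        s = _toy_subject("a", 500)
        wmh, non = select_training_points(
            s, TrainingConfig(mode="FE", n_wmh=2000), rng_seed=0
        )
        assert len(wmh) == 500 and len(non) == 500

    def test_fu_counts(self):
        s = _toy_subject("a", 5000, shape=(26, 26, 26))
        wmh, non = select_training_points(
            s, TrainingConfig(mode="FU", n_wmh=2000, n_nonwmh=10000), rng_seed=0
        )
        assert len(wmh) == 2000 and len(non) == 10000

    def test_ae_takes_all_wmh(self):
        s = _toy_subject("a", 321)
        wmh, non = select_training_points(s, TrainingConfig(mode="AE"), rng_seed=5)
        assert len(wmh) == 321 and len(non) == 321

    def test_no_border_avoids_shell(self):
        shape = (9, 9, 9)
        s = _toy_subject("a", 0, shape=shape)
        manual = np.zeros(shape, dtype=np.uint8)
        manual[4, 4, 4] = 1
        s = dataclasses.replace(s, manual_mask=BinaryMask(data=manual, affine=np.eye(4)))
        cfg = TrainingConfig(mode="FU", n_wmh=1, n_nonwmh=500, location="no_border")
        wmh, non = select_training_points(s, cfg, rng_seed=0)
        border = lesion_border(s.manual_mask, 1).data.astype(bool)
        assert not border[tuple(non.T)].any()

    def test_surround_prefers_shell(self):
        shape = (9, 9, 9)
        s = _toy_subject("a", 0, shape=shape)
        manual = np.zeros(shape, dtype=np.uint8)
        manual[4, 4, 4] = 1
        s = dataclasses.replace(s, manual_mask=BinaryMask(data=manual, affine=np.eye(4)))
        cfg = TrainingConfig(mode="FU", n_wmh=1, n_nonwmh=20, location="surround")
        wmh, non = select_training_points(s, cfg, rng_seed=0)
        border = lesion_border(s.manual_mask, 1).data.astype(bool)
        assert border[tuple(non.T)].all()

    def test_surround_falls_back_when_shell_too_small(self):
        shape = (9, 9, 9)
        s = _toy_subject("a", 0, shape=shape)
        manual = np.zeros(shape, dtype=np.uint8)
        manual[4, 4, 4] = 1
        s = dataclasses.replace(s, manual_mask=BinaryMask(data=manual, affine=np.eye(4)))
        cfg = TrainingConfig(mode="FU", n_wmh=1, n_nonwmh=100, location="surround")
        wmh, non = select_training_points(s, cfg, rng_seed=0)
        assert len(non) == 100  # 26 from the shell + 74 from the rest

    def test_empty_manual_mask_skipped_with_warning(self):
        s = _toy_subject("a", 0)
        with pytest.warns(UserWarning, match="empty manual mask"):
            assert select_training_points(s, TrainingConfig(), 0) is None

    def test_seed_determinism(self):
        s = _toy_subject("a", 200)
        cfg = TrainingConfig(mode="FE", n_wmh=50)
        a1 = select_training_points(s, cfg, rng_seed=7)
        a2 = select_training_points(s, cfg, rng_seed=7)
        b = select_training_points(s, cfg, rng_seed=8)
        assert np.array_equal(a1[0], a2[0]) and np.array_equal(a1[1], a2[1])
        assert not np.array_equal(a1[1], b[1])

    def test_ae_wmh_set_independent_of_seed(self):
        s = _toy_subject("a", 150)
        cfg = TrainingConfig(mode="AE")
        w1, _ = select_training_points(s, cfg, rng_seed=1)
        w2, _ = select_training_points(s, cfg, rng_seed=2)
        assert np.array_equal(w1, w2)


class TestAssembly:
    SPEC = FeatureSpec(modality_names=("flair",), spatial_weight=0)

    def test_leave_one_out_provenance(self):
        cohort = [_toy_subject(sid, 100, seed=i) for i, sid in enumerate("ABC")]
        ts = assemble_training_set(cohort, TrainingConfig(mode="FE", n_wmh=50),
                                   self.SPEC, exclude={"A"})
        assert ts.subject_ids == {"B", "C"}

    def test_row_count_arithmetic(self):
        cohort = [_toy_subject(sid, 3000, shape=(20, 20, 20), seed=i)
                  for i, sid in enumerate("AB")]
        cfg = TrainingConfig(mode="FU", n_wmh=2000, n_nonwmh=4000)
        ts = assemble_training_set(cohort, cfg, self.SPEC)
        assert len(ts) == 2 * (2000 + 4000)
        assert (ts.features.labels == WMH).sum() == 4000
        assert (ts.features.labels == NONWMH).sum() == 8000

    def test_empty_manual_subject_dropped(self):
        cohort = [_toy_subject("A", 100), _toy_subject("B", 0), _toy_subject("C", 80)]
        with pytest.warns(UserWarning, match="empty manual mask"):
            ts = assemble_training_set(cohort, TrainingConfig(mode="FE", n_wmh=50),
                                       self.SPEC)
        assert ts.subject_ids == {"A", "C"}

    def test_all_excluded_rejected(self):
        cohort = [_toy_subject("A", 100)]
        with pytest.raises(ValueError, match="excluded"):
            assemble_training_set(cohort, TrainingConfig(), self.SPEC, exclude={"A"})

    def test_subject_contribution_invariant_to_cohort(self):
        # a subject's sampled rows do not depend on who else is present
        a, b, c = (_toy_subject(sid, 120, seed=i) for i, sid in enumerate("ABC"))
        cfg = TrainingConfig(mode="FE", n_wmh=60, seed=3)
        two = assemble_training_set([a, b], cfg, self.SPEC)
        three = assemble_training_set([a, b, c], cfg, self.SPEC)
        rows_a_two = two.features.rows[two.provenance == "A"]
        rows_a_three = three.features.rows[three.provenance == "A"]
        assert np.array_equal(rows_a_two, rows_a_three)
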