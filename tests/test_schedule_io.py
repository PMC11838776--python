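"""Frame schedules, TAC/metadata/expression I/O and ROI extraction."""

import numpy as np
import pandas as pd
import pytest

from ptspo import (ExpressionMap, RegionalTAC, SubjectRecord, extract_roi_tacs,
                   read_expression_map, read_subject_table, read_tac_table,
                   write_expression_map, write_subject_table, write_tac_table)
from ptspo.errors import (CovariateError, DimensionError, FormatError,
                          ScheduleError)
from ptspo.io import read_schedule, write_schedule
from ptspo.schedule import PRESET_SCHEDULES, FrameSchedule


class TestFrameSchedule:
    def test_mid_times_and_counts(self):
        sched = PRESET_SCHEDULES["pbr28_90min"]
        assert sched.n_frames == 26
        assert sched.total_minutes == pytest.approx(90.0)
        np.testing.assert_allclose(sched.mid_times,
                                   sched.start_times + sched.durations / 2)
        assert np.all(np.diff(sched.start_times) > 0)

    @pytest.mark.parametrize("name, n, total", [
        ("pbr28_60min", 23, 60.0), ("pk11195_60min", 17, 60.0),
        ("dpa714_60min", 26, 61.0)])
    def test_presets(self, name, n, total):
        sched = PRESET_SCHEDULES[name]
        assert sched.n_frames == n
        assert sched.total_minutes == pytest.approx(total)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ScheduleError):
            FrameSchedule([0.0, 1.0], [1.0, -0.5])     # negative duration
        with pytest.raises(ScheduleError):
            FrameSchedule([0.0, 0.5], [1.0, 1.0])      # overlap
        with pytest.raises(ScheduleError):
            FrameSchedule([1.0, 0.5], [0.2, 0.2])      # non-increasing starts

    def test_frames_within_window(self):
        sched = PRESET_SCHEDULES["pbr28_90min"]
        sel = sched.frames_within(4.0)
        assert np.all(sched.mid_times[sel] <= 4.0)
        assert np.all(sched.mid_times[np.setdiff1d(np.arange(26), sel)] > 4.0)

    def test_schedule_file_roundtrip(self, tmp_path):
        sched = PRESET_SCHEDULES["pbr28_90min"]
        for name in ("s.csv", "s.yaml"):
            write_schedule(sched, tmp_path / name)
            back = read_schedule(tmp_path / name)
            np.testing.assert_allclose(back.start_times, sched.start_times)
            np.testing.assert_allclose(back.durations, sched.durations)


class TestTacTables:
    def _make_tacs(self, sched, n_sub=2, n_roi=3, seed=0):
        rng = np.random.default_rng(seed)
        return [RegionalTAC(f"roi{r}", f"sub{s}", sched,
                            rng.random(sched.n_frames) * 10)
                for s in range(n_sub) for r in range(n_roi)]

    def test_roundtrip_bit_exact(self, tmp_path, pbr28_schedule):
        tacs = self._make_tacs(pbr28_schedule)
        write_tac_table(tacs, tmp_path / "t.csv", tmp_path / "sched.csv")
        back = read_tac_table(tmp_path / "t.csv", tmp_path / "sched.csv")
        assert len(back) == 6
        orig = {(t.subject_id, t.roi_id): t.activity for t in tacs}
        for t in back:
            np.testing.assert_array_equal(t.activity, orig[(t.subject_id, t.roi_id)])

    def test_missing_frame_is_format_error(self, tmp_path, pbr28_schedule):
        tacs = self._make_tacs(pbr28_schedule, n_sub=1, n_roi=1)
        write_tac_table(tacs, tmp_path / "t.csv")
        df = pd.read_csv(tmp_path / "t.csv").iloc[:-1]  # drop the last frame row
        df.to_csv(tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError):
            read_tac_table(tmp_path / "bad.csv", pbr28_schedule)

    def test_missing_column_is_format_error(self, tmp_path, pbr28_schedule):
        pd.DataFrame({"subject_id": ["a"], "roi_id": ["r"]}).to_csv(
            tmp_path / "bad.csv", index=False)
        with pytest.raises(FormatError):
            read_tac_table(tmp_path / "bad.csv", pbr28_schedule)

    def test_activity_length_must_match_schedule(self, pbr28_schedule):
        with pytest.raises(FormatError):
            RegionalTAC("r", "s", pbr28_schedule, np.ones(5))


class TestSubjectAndExpressionIO:
    def test_subject_roundtrip_and_validation(self, tmp_path):
        subs = [SubjectRecord("s1", 40.0, "male", "HAB", 330.0, 75.0,
                              "d1", "HC"),
                SubjectRecord("s2", 25.0, "female", "MAB", 350.0, 60.0,
                              "d2", "case")]
        write_subject_table(subs, tmp_path / "subs.csv")
        back = read_subject_table(tmp_path / "subs.csv")
        assert [s.subject_id for s in back] == ["s1", "s2"]
        assert back[1].dose_over_weight == pytest.approx(350.0 / 60.0)
        with pytest.raises(CovariateError):
            SubjectRecord("bad", -1.0, "male", "HAB", 330.0, 75.0)
        with pytest.raises(CovariateError):
            SubjectRecord("bad", 40.0, "male", "LAB", 330.0, 75.0)

    def test_expression_roundtrip(self, tmp_path):
        emap = ExpressionMap({"thal": 2.0, "occ": 0.1, "ctx": 0.7},
                             {"thal": "high", "occ": "low", "ctx": "unlabelled"})
        write_expression_map(emap, tmp_path / "e.csv")
        back = read_expression_map(tmp_path / "e.csv")
        assert back.scores == emap.scores
        assert back.low_rois == ["occ"] and back.high_rois == ["thal"]


class TestRoiExtraction:
    def _schedule(self, n=4):
        return FrameSchedule.from_durations([1.0] * n)

    def test_constant_phantom(self):
        sched = self._schedule()
        img = np.zeros((4, 4, 2, 4))
        atlas = np.zeros((4, 4, 2), dtype=int)
        atlas[:2, :2, 0] = 1
        img[atlas == 1] = 5.0
        tacs, excluded = extract_roi_tacs(img, atlas, np.ones_like(atlas), sched)
        assert excluded == []
        np.testing.assert_allclose(tacs[0].activity, 5.0)

    def test_mask_restricts_voxels(self):
        sched = self._schedule()
        img = np.zeros((4, 1, 1, 4))
        atlas = np.ones((4, 1, 1), dtype=int)
        img[:2] = 2.0
        img[2:] = 4.0
        mask = np.zeros_like(atlas)
        mask[2:] = 1  # only value-4 voxels survive
        tacs, _ = extract_roi_tacs(img, atlas, mask, sched)
        np.testing.assert_allclose(tacs[0].activity, 4.0)

    def test_mean_matches_bruteforce_voxel_loop(self):
        rng = np.random.default_rng(3)
        sched = self._schedule(6)
        img = rng.random((5, 4, 3, 6))
        atlas = rng.integers(0, 3, size=(5, 4, 3))
        mask = rng.random((5, 4, 3)) > 0.3
        tacs, _ = extract_roi_tacs(img, atlas, mask, sched)
        for tac in tacs:
            label = int(tac.roi_id)
            acc = np.zeros(6)
            n = 0
            for i in range(5):
                for j in range(4):
                    for k in range(3):
                        if atlas[i, j, k] == label and mask[i, j, k]:
                            acc += img[i, j, k]
                            n += 1
            np.testing.assert_allclose(tac.activity, acc / n, rtol=1e-12)

    def test_empty_roi_reported_not_dropped(self):
        sched = self._schedule()
        img = np.ones((2, 2, 1, 4))
        atlas = np.ones((2, 2, 1), dtype=int)
        atlas[0, 0, 0] = 2
        mask = np.ones_like(atlas)
        mask[0, 0, 0] = 0  # label 2 fully masked out
        with pytest.warns(UserWarning, match="label 2"):
            tacs, excluded = extract_roi_tacs(img, atlas, mask, sched)
        assert excluded == [2]
        assert [t.roi_id for t in tacs] == ["1"]

    def test_nifti_volumes_supported(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        sched = self._schedule()
        rng = np.random.default_rng(9)
        img = rng.random((3, 3, 2, 4))
        atlas = rng.integers(0, 2, (3, 3, 2))
        affine = np.eye(4)
        for name, arr in (("img.nii", img), ("atlas.nii", atlas.astype(np.int16)),
                          ("mask.nii", np.ones((3, 3, 2), np.uint8))):
            nib.save(nib.Nifti1Image(arr, affine), tmp_path / name)
        from ptspo.io import load_volume
        tacs, _ = extract_roi_tacs(load_volume(tmp_path / "img.nii"),
                                   load_volume(tmp_path / "atlas.nii"),
                                   load_volume(tmp_path / "mask.nii"), sched)
        ref, _ = extract_roi_tacs(img, atlas, np.ones((3, 3, 2)), sched)
        for a, b in zip(tacs, ref):
            np.testing.assert_allclose(a.activity, b.activity, rtol=1e-6)

    def test_grid_mismatch_errors(self):
        sched = self._schedule()
        img = np.ones((2, 2, 2, 4))
        with pytest.raises(DimensionError):
            extract_roi_tacs(img, np.ones((3, 2, 2), int), np.ones((2, 2, 2)), sched)
        with pytest.raises(ScheduleError):
            extract_roi_tacs(np.ones((2, 2, 2, 3)), np.ones((2, 2, 2), int),
                             np.ones((2, 2, 2)), sched)
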