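import numpy as np
import pandas as pd
import pytest

import cbctqa as q
from cbctqa.exceptions import AlignmentError, DetectionError, MatchingError

from conftest import match_to_truth


def make_record(run_id, direction, angles, values):
    return q.CalibrationRecord(
        run_id=run_id, direction=direction, angles=np.asarray(angles, float),
        corrections=pd.DataFrame(values, columns=list(q.CORRECTIONS)))


class TestSchedule:
    @pytest.mark.parametrize("start,rng,step,n", [
        (0, 520, 10, 53),   # the device's calibration orbit
        (0, 0, 10, 1),
        (0, 360, 90, 5),
    ])
    def test_view_counts(self, start, rng, step, n):
        angles = q.calibration_schedule(start, rng, step)
        assert len(angles) == n
        assert angles[0] == start

    def test_non_dividing_step_warns(self):
        with pytest.warns(UserWarning, match="does not divide"):
            angles = q.calibration_schedule(0, 100, 30)
        assert angles[-1] == 90


class TestCalibrationStats:
    def test_identical_runs_all_zero(self):
        vals = np.arange(9, dtype=float)[None, :].repeat(3, axis=0)
        recs = [make_record(f"r{i}", d, [0, 10, 20], vals)
                for i in range(2) for d in ("cw", "ccw")]
        stats = q.calibration_stats(recs)
        assert np.all(stats.overall_sd.to_numpy() == 0)
        assert np.all(stats.per_angle_sd.to_numpy() == 0)
        assert np.all(stats.hysteresis_abs.to_numpy() == 0)

    def test_two_runs_sample_sd(self):
        recs = [make_record("a", "cw", [0.0], np.full((1, 9), 1.0)),
                make_record("b", "cw", [0.0], np.full((1, 9), 3.0))]
        stats = q.calibration_stats(recs)
        assert np.allclose(stats.per_angle_sd.to_numpy(), np.sqrt(2.0))
        assert np.allclose(stats.overall_mean.to_numpy(), 2.0)

    def test_matches_naive_two_loop_oracle(self):
        rng = np.random.default_rng(17)
        angles = [0.0, 10.0, 20.0, 30.0]
        data = {}  # (run, dir) -> (angles, 9) array
        recs = []
        for run in "abc":
            for d in ("cw", "ccw"):
                v = rng.normal(size=(4, 9))
                data[(run, d)] = v
                recs.append(make_record(run, d, angles, v))
        stats = q.calibration_stats(recs)
        # naive: explicit loops over corrections / angles / runs
        for ci, c in enumerate(q.CORRECTIONS):
            pool = [data[k][ai, ci] for k in data for ai in range(4)]
            assert stats.overall_mean[c] == pytest.approx(np.mean(pool), rel=1e-12)
            assert stats.overall_sd[c] == pytest.approx(np.std(pool, ddof=1), rel=1e-12)
            for ai in range(4):
                per_dir = []
                for d in ("cw", "ccw"):
                    vals = [data[(run, d)][ai, ci] for run in "abc"]
                    per_dir.append(np.std(vals, ddof=1))
                assert stats.per_angle_sd[c].iloc[ai] == pytest.approx(
                    np.mean(per_dir), rel=1e-12)
                diffs = [data[(run, "cw")][ai, ci] - data[(run, "ccw")][ai, ci]
                         for run in "abc"]
                assert stats.hysteresis_abs[c].iloc[ai] == pytest.approx(
                    abs(np.mean(diffs)), rel=1e-12)

    def test_offset_recovery_from_simulation(self):
        spec = q.CalibrationSimSpec(
            n_runs=8, offsets=(0, 0, 0, 0, 0, 11.5, 0, 0, 0),
            modulation_amp=(0,) * 9,
            fluctuation_sd=(0, 0, 0, 0, 0, 0.4, 0, 0, 0),
            hysteresis=(0,) * 9, seed=4)
        records, _ = q.simulate_calibration_runs(spec)
        stats = q.calibration_stats(records)
        assert stats.overall_mean["tCz"] == pytest.approx(11.5, abs=0.4)

    def test_hysteresis_symmetric_under_label_swap(self):
        rng = np.random.default_rng(23)
        angles = [0.0, 10.0]
        recs, swapped = [], []
        for run in "ab":
            vcw, vccw = rng.normal(size=(2, 2, 9))
            recs += [make_record(run, "cw", angles, vcw),
                     make_record(run, "ccw", angles, vccw)]
            swapped += [make_record(run, "ccw", angles, vcw),
                        make_record(run, "cw", angles, vccw)]
        a = q.calibration_stats(recs).hysteresis_abs
        b = q.calibration_stats(swapped).hysteresis_abs
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_angle_grids_rejected(self):
        recs = [make_record("a", "cw", [0, 10], np.zeros((2, 9))),
                make_record("b", "cw", [0, 20], np.zeros((2, 9)))]
        with pytest.raises(AlignmentError):
            q.calibration_stats(recs)


class TestDetectRods:
    def test_noiseless_centroids(self, rod_render):
        vol, truth = rod_render
        centers = q.detect_rods(vol, 0, "bright", 4)
        errs = match_to_truth(centers, np.asarray(truth["rod_centers_mm"]))
        assert errs.max() < 0.05

    def test_noisy_centroids_few_seeds(self):
        spec = q.catphan_rod_module()
        grid = q.GridSpec(shape=(400, 400), spacing=(0.4, 0.4, 1.0))
        for seed in range(5):
            vol, truth = q.render_phantom(spec, q.DegradationSpec(noise_sigma=20.0,
                                                                  seed=seed), grid)
            centers = q.detect_rods(vol, 0, "bright", 4)
            errs = match_to_truth(centers, np.asarray(truth["rod_centers_mm"]))
            assert errs.max() < 0.2

    def test_dark_polarity(self):
        spec = q.PhantomSpec("insert_module", diameter=150.0, background_hu=100.0,
                             rods=tuple(((r, c), 3.0, -800.0)
                                        for r in (-25, 25) for c in (-25, 25)))
        vol, truth = q.render_phantom(spec, q.DegradationSpec(seed=0),
                                      q.GridSpec(shape=(400, 400),
                                                 spacing=(0.4, 0.4, 1.0)))
        # inverted air outside the disk is the brightest structure; the
        # search radius keeps the detection inside the phantom
        centers = q.detect_rods(vol, 0, "dark", 4, search_radius_mm=45.0)
        errs = match_to_truth(centers, np.asarray(truth["rod_centers_mm"]))
        assert errs.max() < 0.05

    def test_too_few_components_raises(self):
        spec = q.PhantomSpec("insert_module", diameter=150.0, background_hu=100.0,
                             rods=(((0.0, -25.0), 3.0, 950.0),
                                   ((0.0, 25.0), 3.0, 950.0),
                                   ((25.0, 0.0), 3.0, 950.0)))
        vol, _ = q.render_phantom(spec, q.DegradationSpec(seed=0),
                                  q.GridSpec(shape=(400, 400), spacing=(0.4, 0.4, 1.0)))
        with pytest.raises(DetectionError, match="3"):
            q.detect_rods(vol, 0, "bright", 4)


class TestImagingFidelity:
    SQUARE = np.array([[0.0, 0.0], [0.0, 50.0], [50.0, 0.0], [50.0, 50.0]])

    def test_exact_square_zero_error(self):
        res = q.imaging_fidelity(self.SQUARE, 50.0)
        assert res.mean_abs_error == 0.0
        assert res.mean_side_length == 50.0

    def test_rigid_shift_invariance(self):
        res = q.imaging_fidelity(self.SQUARE + np.array([0.1, 0.1]), 50.0)
        assert res.mean_abs_error == pytest.approx(0.0, abs=1e-12)

    def test_rotation_invariance(self):
        th = np.deg2rad(37.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        res = q.imaging_fidelity(self.SQUARE @ rot.T, 50.0)
        assert res.mean_abs_error == pytest.approx(0.0, abs=1e-9)

    def test_displaced_corner_matches_brute_force(self):
        centers = self.SQUARE.copy()
        shift = 0.5 / np.sqrt(2.0)
        centers[3] += shift  # outward along the diagonal
        res = q.imaging_fidelity(centers, 50.0)
        # independent hand computation of the six distances
        dists = sorted(float(np.hypot(*(centers[i] - centers[j])))
                       for i in range(4) for j in range(i + 1, 4))
        nominal = sorted([50.0] * 4 + [50.0 * np.sqrt(2.0)] * 2)
        expected = np.abs(np.array(dists) - np.array(nominal))
        assert res.mean_abs_error == pytest.approx(expected.mean(), rel=1e-12)
        assert res.sd_abs_error == pytest.approx(expected.std(ddof=1), rel=1e-12)

    def test_degenerate_layout_rejected(self):
        with pytest.raises(MatchingError):
            q.imaging_fidelity(self.SQUARE, [50.0] * 6)

    def test_wrong_center_count_rejected(self):
        with pytest.raises(MatchingError):
            q.imaging_fidelity(self.SQUARE[:3], 50.0)


class TestRecordCSV:
    def test_roundtrip(self, tmp_path):
        spec = q.CalibrationSimSpec(n_runs=2, seed=0)
        records, _ = q.simulate_calibration_runs(spec)
        path = q.records_to_csv(records, tmp_path / "runs.csv")
        back = q.records_from_csv(path)
        assert len(back) == len(records)
        orig = {(r.run_id, r.direction): r for r in records}
        for rec in back:
            ref = orig[(rec.run_id, rec.direction)]
            np.testing.assert_allclose(rec.corrections.to_numpy(),
                                       ref.corrections.to_numpy(), rtol=1e-12)
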