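import numpy as np
import pytest
from hypothesis import given, strategies as st

import cbctqa as q
from cbctqa.exceptions import DegenerateFitError, ProfileError, UndefinedCNRError

GRID = q.GridSpec(shape=(340, 340), spacing=(0.4, 0.4, 1.0))
UNIFORM = q.catphan_uniform_module(background_hu=20.0, diameter=120.0)


def cupping_volume(amplitude, seed=0, offset_hu=0.0):
    spec = q.PhantomSpec("uniform_module", diameter=120.0,
                         background_hu=20.0 + offset_hu)
    return q.render_phantom(spec, q.DegradationSpec(cupping_amplitude=amplitude,
                                                    seed=seed), GRID)


class TestLinearity:
    def _vol(self, values):
        vox = np.full((1, 40, 40), 0.0)
        vol = q.ImageVolume(vox, spacing=(1, 1, 1))
        rois = []
        for i, v in enumerate(values):
            r, c = 8 + 8 * (i // 4), 8 + 8 * (i % 4)
            vol.voxels[0, r - 2:r + 3, c - 2:c + 3] = v
            rois.append(q.CircularROI(0, (float(r), float(c)), 2.2))
        return vol, rois

    def test_identity_line(self):
        values = [-1000.0, -100.0, 0.0, 120.0, 340.0, 990.0]
        vol, rois = self._vol(values)
        res = q.ct_number_linearity(vol, list(zip(rois, values)))
        assert res.slope == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_point_line(self):
        vol, rois = self._vol([0.0, 100.0])
        res = q.ct_number_linearity(vol, list(zip(rois, [0.0, 200.0])))
        assert res.slope == pytest.approx(0.5, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identical_nominals_rejected(self):
        vol, rois = self._vol([0.0, 100.0])
        with pytest.raises(DegenerateFitError):
            q.ct_number_linearity(vol, [(rois[0], 5.0), (rois[1], 5.0)])

    def test_synthetic_inserts_with_noise(self):
        vol, truth = q.render_phantom(
            q.catphan_insert_module(), q.DegradationSpec(noise_sigma=10.0, seed=3),
            q.GridSpec(shape=(540, 540), spacing=(0.4, 0.4, 1.0)))
        entries = [(name, q.CircularROI(0, truth["insert_centers_mm"][name], 3.6), hu)
                   for name, hu in truth["insert_hu"].items()]
        res = q.ct_number_linearity(vol, entries)
        assert res.r_squared > 0.999
        assert res.slope == pytest.approx(1.0, abs=0.01)

    def test_slope_recovery_over_seeds(self):
        # render once, re-noise the insert means cheaply via fresh seeds
        slopes = []
        for seed in range(10):
            vol, truth = q.render_phantom(
                q.catphan_insert_module(),
                q.DegradationSpec(noise_sigma=10.0, seed=seed),
                q.GridSpec(shape=(540, 540), spacing=(0.4, 0.4, 1.0)))
            entries = [(q.CircularROI(0, truth["insert_centers_mm"][n], 3.6), hu)
                       for n, hu in truth["insert_hu"].items()]
            slopes.append(q.ct_number_linearity(vol, entries).slope)
        assert 0.995 <= np.mean(slopes) <= 1.005


class TestUniformity:
    def test_constant_phantom_zero(self):
        vol, _ = q.render_phantom(UNIFORM, q.DegradationSpec(seed=0), GRID)
        for direction in ("lateral", "ap"):
            res = q.uniformity_profile(vol, 0, direction)
            assert res.nonuniformity == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("amplitude", [50.0, -50.0])
    def test_parabolic_cupping_closed_form(self, amplitude):
        # edge sample at 5% of the masked extent sits at r = 0.9 R, where the
        # parabola reads amplitude * 0.81 relative to the center
        vol, _ = cupping_volume(amplitude)
        res = q.uniformity_profile(vol, 0, "lateral")
        assert res.nonuniformity == pytest.approx(0.81 * amplitude, abs=1.0)

    def test_global_offset_invariance_exact(self):
        vol, _ = cupping_volume(40.0)
        mask = q.phantom_mask(vol, 0)
        shifted = q.ImageVolume(vol.voxels + 100.0, spacing=vol.spacing)
        a = q.uniformity_profile(vol, 0, "lateral", mask=mask)
        b = q.uniformity_profile(shifted, 0, "lateral", mask=mask)
        assert b.nonuniformity == pytest.approx(a.nonuniformity, abs=1e-12)

    def test_rim_smear_negative_nonuniformity(self):
        vol, _ = q.render_phantom(
            q.PhantomSpec("uniform_module", diameter=120.0, background_hu=20.0),
            q.DegradationSpec(edge_smear=(8.0, -40.0), seed=0), GRID)
        res = q.uniformity_profile(vol, 0, "ap")
        # deficit of the rendered rim field at the 5% position (r = 0.9 R)
        expected = -40.0 * np.exp(-0.5 * (0.1 * 60.0 / 8.0) ** 2)
        assert res.nonuniformity < 0
        assert res.nonuniformity == pytest.approx(expected, abs=3.0)

    def test_short_mask_rejected(self):
        vol = q.ImageVolume(np.full((1, 30, 30), -1000.0), spacing=(1, 1, 1))
        vol.voxels[0, 14:16, 14:16] = 100.0
        with pytest.raises(ProfileError):
            q.uniformity_profile(vol, 0, "lateral")

    def test_longitudinal_spread(self):
        amplitudes = [0.0, 49.4, 92.6]  # -> nonuniformities ~ (0, 40, 75)
        vols = [(cupping_volume(a)[0], 20.0 * i) for i, a in enumerate(amplitudes)]
        table = q.uniformity_vs_longitudinal(vols)
        assert len(table) == 3
        assert table.attrs["max_spread"] == pytest.approx(0.81 * 92.6, abs=2.0)

    def test_identical_offsets_zero_spread(self):
        vol, _ = cupping_volume(30.0)
        table = q.uniformity_vs_longitudinal([(vol, 0.0), (vol, 20.0)])
        assert table.attrs["max_spread"] == 0.0


class TestCNR:
    def test_equal_means_zero(self):
        a = q.ROIStats(100.0, 5.0, 50)
        assert q.cnr(a, q.ROIStats(100.0, 7.0, 50)).cnr == 0.0

    def test_hand_values(self):
        res = q.cnr(q.ROIStats(0.0, 10.0, 10), q.ROIStats(100.0, 10.0, 10))
        assert res.cnr == pytest.approx(10.0, rel=1e-12)
        res = q.cnr(q.ROIStats(0.0, 0.0, 10), q.ROIStats(10.0, 10.0, 10))
        assert res.cnr == pytest.approx(10.0 / np.sqrt(50.0), rel=1e-12)

    def test_both_sds_zero_undefined(self):
        with pytest.raises(UndefinedCNRError):
            q.cnr(q.ROIStats(0.0, 0.0, 10), q.ROIStats(1.0, 0.0, 10))

    @given(mi=st.floats(-500, 500), mb=st.floats(-500, 500),
           si=st.floats(0.1, 50), sb=st.floats(0.1, 50))
    def test_antisymmetry_and_sd_scaling(self, mi, mb, si, sb):
        fwd = q.cnr(q.ROIStats(mi, si, 5), q.ROIStats(mb, sb, 5)).cnr
        rev = q.cnr(q.ROIStats(mb, si, 5), q.ROIStats(mi, sb, 5)).cnr
        assert fwd == pytest.approx(-rev, rel=1e-9, abs=1e-12)
        doubled = q.cnr(q.ROIStats(mi, 2 * si, 5), q.ROIStats(mb, 2 * sb, 5)).cnr
        assert doubled == pytest.approx(fwd / 2.0, rel=1e-9, abs=1e-12)

    def test_background_roi_placement_avoids_inserts(self):
        centers = [(60.0 * np.sin(np.deg2rad(a)), 60.0 * np.cos(np.deg2rad(a)))
                   for a in range(0, 315, 45)]  # free azimuth at 315 deg
        target = q.CircularROI(0, centers[-1], 4.0)  # insert at 270 deg
        roi = q.background_roi_for_insert(target, centers, (0.0, 0.0))
        az = np.rad2deg(np.arctan2(roi.center[0], roi.center[1])) % 360
        assert az == pytest.approx(315.0, abs=1.0)
        assert np.hypot(*roi.center) == pytest.approx(60.0, abs=1e-9)
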