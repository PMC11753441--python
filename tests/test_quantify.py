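"""VOI statistics, percent deviations, %ID/cc and profile tools."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ovopet.petsim import decay_factor
from ovopet.phantoms import AcquisitionMeta, EggGeometry, default_organs, make_inovo_phantom
from ovopet.quantify import (
    VOI,
    average_replicates,
    line_profile,
    percent_deviation,
    percent_difference_image,
    pid_cc,
    total_activity_image,
    voi_mean,
)
from ovopet.volume import make_grid


class TestVoiMean:
    def test_uniform_volume(self):
        vol = make_grid((20, 20, 20), 1.0)
        vol.values[:] = 7.5
        voi = VOI("s", center_mm=(0, 0, 0), radius_mm=4.0)
        assert voi_mean(vol, voi) == 7.5

    def test_sphere_inside_hot_region(self):
        vol = make_grid((30, 30, 30), 1.0)
        x, y, z = vol.meshgrid()
        vol.values[x**2 + y**2 + z**2 <= 100.0] = 3.0
        assert voi_mean(vol, VOI("s", center_mm=(0, 0, 0), radius_mm=5.0)) == 3.0

    def test_linear_gradient_mean_is_center_value(self):
        # odd symmetry of the gradient about the sphere centre
        vol = make_grid((41, 41, 41), 1.0)
        x, _, _ = vol.meshgrid()
        vol.values[:] = 100.0 + 2.0 * x
        m = voi_mean(vol, VOI("s", center_mm=(3.0, 0, 0), radius_mm=5.0))
        assert m == pytest.approx(106.0, rel=0.005)

    def test_label_mask_voi(self):
        vol = make_grid((10, 10, 10), 1.0)
        labels = make_grid((10, 10, 10), 1.0, unit="label")
        labels.values[2:5] = 4
        vol.values[2:5] = 9.0
        assert voi_mean(vol, VOI("liver", kind="label_mask", label_id=4), labels=labels) == 9.0

    def test_empty_voi_error(self):
        vol = make_grid((10, 10, 10), 1.0)
        with pytest.raises(ValueError, match="no voxels"):
            voi_mean(vol, VOI("far", center_mm=(100.0, 0, 0), radius_mm=1.0))


class TestPercentDeviation:
    @pytest.mark.parametrize(
        "measured, actual, expected",
        [(30.1, 61.4, -51.0), (49.0, 61.4, -20.2), (61.4, 61.4, 0.0), (59.8, 117.0, -48.9)],
    )
    def test_tabulated_values(self, measured, actual, expected):
        assert percent_deviation(measured, actual) == expected

    def test_invalid_actual(self):
        with pytest.raises(ValueError):
            percent_deviation(1.0, 0.0)


class TestTotalActivity:
    def test_arithmetic(self):
        vol = make_grid((20, 20, 20), 1.0)
        vol.values[:10, :10, :10] = 1.0  # 1000 voxels of 1 mm^3 at 1 kBq/cc
        res = total_activity_image(vol, VOI("whole", center_mm=(0, 0, 0), radius_mm=30.0))
        assert res.total_kBq == pytest.approx(1.0)

    def test_linearity(self):
        vol = make_grid((20, 20, 20), 1.0)
        vol.values[:] = 2.0
        voi = VOI("whole", center_mm=(0, 0, 0), radius_mm=8.0)
        t1 = total_activity_image(vol, voi).total_kBq
        vol2 = vol.like(2.0 * vol.values)
        assert total_activity_image(vol2, voi).total_kBq == pytest.approx(2.0 * t1)

    def test_truncation_warning_recorded(self):
        vol = make_grid((30, 30, 30), 1.0)
        vol.values[:] = 1.0
        support = np.ones(vol.shape, dtype=bool)
        with pytest.warns(UserWarning, match="beyond the whole-egg sphere"):
            res = total_activity_image(
                vol, VOI("whole", center_mm=(0, 0, 0), radius_mm=5.0), support=support
            )
        assert res.truncated


class TestPidCc:
    def test_arithmetic(self):
        assert pid_cc(10.0, 1000.0, "image") == pytest.approx(1.0)

    @given(bias=st.floats(min_value=0.05, max_value=20.0))
    @settings(max_examples=30, deadline=None)
    def test_image_mode_invariant_under_global_bias(self, bias):
        # the formal core of the image-normalisation recommendation: any
        # global multiplicative reconstruction bias cancels exactly
        conc, total = 12.5, 3210.0
        assert pid_cc(bias * conc, bias * total, "image") == pytest.approx(
            pid_cc(conc, total, "image"), rel=1e-12
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pid_cc(1.0, 0.0)
        with pytest.raises(ValueError):
            pid_cc(1.0, 1.0, mode="banana")


class TestLostFractionRecovery:
    def test_estimator_recovers_simulated_loss(self):
        # f_hat = 1 - imageTotal/calibratorInjected on the noiseless phantom
        f = 0.17
        meta = AcquisitionMeta(
            dispensed_activity_kBq=5000.0,
            residual_activity_kBq=200.0,
            lost_activity_kBq=f * 4800.0,
        )
        grid = make_grid((64, 64, 64), 1.5)
        activity, _, _, _ = make_inovo_phantom(EggGeometry(), default_organs(), meta, grid)
        dc = decay_factor(meta.nuclide, meta.frame_start_min)
        total = activity.values.sum() * activity.voxel_volume_cc / dc
        f_hat = 1.0 - total / meta.calibrator_injected_kBq
        assert f_hat == pytest.approx(f, abs=1e-6)


class TestAverageReplicates:
    def test_filter_preserves_uniform_mean(self):
        vol = make_grid((20, 20, 20), 1.0)
        vol.values[:] = 5.0
        out = average_replicates([vol], fwhm_mm=2.0)
        assert out.values[10, 10, 10] == pytest.approx(5.0, rel=1e-6)

    def test_three_identical_equal_one(self):
        vol = make_grid((16, 16, 16), 1.0)
        vol.values[:] = np.random.default_rng(0).random(vol.shape)
        one = average_replicates([vol], fwhm_mm=2.0)
        three = average_replicates([vol, vol, vol], fwhm_mm=2.0)
        np.testing.assert_allclose(three.values, one.values)

    def test_delta_peak_matches_analytic_kernel(self):
        vol = make_grid((21, 21, 21), 1.0)
        vol.values[10, 10, 10] = 1.0
        out = average_replicates([vol], fwhm_mm=2.0)
        sigma = 2.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        expected_peak = (2.0 * np.pi * sigma**2) ** -1.5  # 3-D Gaussian at the origin
        assert out.values[10, 10, 10] == pytest.approx(expected_peak, rel=0.01)

    def test_decay_scaling(self):
        vol = make_grid((8, 8, 8), 1.0)
        vol.values[:] = 1.0
        out = average_replicates([vol, vol], fwhm_mm=0.0, scale_factors=[1.0, 3.0])
        assert out.values[4, 4, 4] == pytest.approx(2.0)

    def test_grid_mismatch_error(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            average_replicates([make_grid((8, 8, 8), 1.0), make_grid((9, 9, 9), 1.0)])


class TestLineProfile:
    def test_uniform_truth_flat_100(self):
        vol = make_grid((16, 16, 16), 1.0)
        vol.values[:] = 42.0
        _, prof = line_profile(vol, axis=0, actual_concentration=42.0)
        np.testing.assert_allclose(prof, 100.0)

    def test_outside_grid_error(self):
        vol = make_grid((16, 16, 16), 1.0)
        with pytest.raises(ValueError, match="outside the grid"):
            line_profile(vol, axis=0, actual_concentration=1.0, through_mm=(0.0, 99.0, 0.0))


class TestPercentDifference:
    def _pair(self):
        truth = make_grid((12, 12, 12), 1.0)
        x, y, z = truth.meshgrid()
        truth.values[x**2 + y**2 + z**2 <= 16.0] = 10.0
        return truth

    def test_identical_gives_zero(self):
        truth = self._pair()
        out = percent_difference_image(truth, truth)
        mask = truth.values > 0
        np.testing.assert_allclose(out.values[mask], 0.0)
        assert np.isnan(out.values[~mask]).all()

    def test_half_gives_minus_fifty(self):
        truth = self._pair()
        recon = truth.like(0.5 * truth.values)
        out = percent_difference_image(recon, truth)
        np.testing.assert_allclose(out.values[truth.values > 0], -50.0)

    def test_masked_mean_consistent_with_voi_deviation(self, rng):
        # for uniform truth the masked mean of the difference image must
        # equal the VOI-mean deviation
        truth = self._pair()
        mask = truth.values > 0
        recon = truth.like(truth.values * rng.uniform(0.5, 0.9, truth.shape))
        out = percent_difference_image(recon, truth)
        voi_dev = 100.0 * (recon.values[mask].mean() - 10.0) / 10.0
        assert np.nanmean(out.values) == pytest.approx(voi_dev, abs=0.1)

    def test_empty_mask_error(self):
        vol = make_grid((4, 4, 4), 1.0)
        with pytest.raises(ValueError, match="empty"):
            percent_difference_image(vol, vol)
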