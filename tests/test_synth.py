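"""Virtual-microscope and virtual-tissue tests: protocols, noise, round trips."""

import numpy as np
import pandas as pd
import pytest

from pshgcal.calfit import fit_calibration, predict_intensity
from pshgcal.polmodel import SystemParameters, WaveplateSetting
from pshgcal.pshgfit import MASK_SATURATED, fit_image
from pshgcal.solve import apply_power_calibration, power_factors, settings_for_linear_angle
from pshgcal.synth import (
    VirtualMicroscope,
    VirtualTissue,
    acquire_calibration,
    acquire_stack,
    calibration_schedule,
)


class TestCalibrationSchedule:
    def test_default_protocol_row_count(self):
        sched = calibration_schedule()
        assert len(sched) == 19 * 10 * 7 == 1330
        assert sched["qwp_deg"].nunique() == 19
        assert sched["hwp_deg"].nunique() == 10
        assert sched["analyzer_deg"].nunique() == 7

    def test_single_setting_sweep(self):
        sched = calibration_schedule(qwp=[80.0], hwp=[13.0])
        assert len(sched) == 7

    def test_fine_window_counts(self):
        """A 2-degree verification window around a circular candidate."""
        sched = calibration_schedule(
            qwp=np.arange(119.0, 131.0 + 1e-9, 2.0),
            hwp=np.arange(26.0, 40.0 + 1e-9, 2.0),
        )
        assert len(sched) == 7 * 8 * 7

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            calibration_schedule(qwp=[])


class TestAcquireCalibration:
    def test_noiseless_equals_model_prediction(self, bench_params):
        vm = VirtualMicroscope(true_params=bench_params)
        data = acquire_calibration(vm)
        clean = predict_intensity(bench_params, data.angles)
        assert np.allclose(data.intensity, clean, atol=1e-15)

    def test_seed_reproducibility(self, bench_params):
        vm = VirtualMicroscope(true_params=bench_params, noise_sigma=0.02, seed=7)
        a = acquire_calibration(vm)
        b = acquire_calibration(VirtualMicroscope(
            true_params=bench_params, noise_sigma=0.02, seed=7))
        assert np.array_equal(a.intensity, b.intensity)
        c = acquire_calibration(VirtualMicroscope(
            true_params=bench_params, noise_sigma=0.02, seed=8))
        assert not np.array_equal(a.intensity, c.intensity)

    def test_sample_averaging_clt(self):
        """Averaging 10 raw readings shrinks the per-row std to sigma/sqrt(10)."""
        params = SystemParameters(delta=10.0, gamma=0.95)
        sched = pd.concat([calibration_schedule(qwp=[30.0], hwp=[20.0])] * 150,
                          ignore_index=True)
        vm = VirtualMicroscope(true_params=params, noise_sigma=0.01, n_samples=10, seed=2)
        data = acquire_calibration(vm, sched)
        clean = predict_intensity(params, data.angles)
        resid = data.intensity - clean
        assert np.std(resid) == pytest.approx(0.01 / np.sqrt(10), rel=0.15)


class TestAcquireStack:
    def _linear_settings(self, params):
        settings = []
        for t in np.arange(0.0, 181.0, 10.0) % 180.0:
            a, _ = settings_for_linear_angle(params, float(t))
            settings.append(a)
        return settings

    def test_round_trip_ideal_microscope(self):
        vm = VirtualMicroscope()
        tissue = VirtualTissue.uniform((10, 10), ratio33=1.5, ratio15=1.0,
                                       fiber_angle_deg=30.0)
        stack = acquire_stack(vm, tissue, self._linear_settings(vm.true_params))
        result = fit_image(stack, low_thresh=0.5)
        assert result.valid.all()
        assert np.allclose(result.ratio33, 1.5, atol=1e-7)
        assert np.allclose(result.ratio15, 1.0, atol=1e-7)
        assert np.allclose(result.fiber_angle, 30.0, atol=1e-6)

    def test_quantized_bright_pixels_masked_saturated(self):
        vm = VirtualMicroscope()
        tissue = VirtualTissue.uniform((8, 8), brightness=50.0)
        bright = np.asarray(tissue.brightness) * np.ones((8, 8))
        bright[2:4, 2:4] = 500.0  # clips at 255 after quantization
        tissue.brightness = bright
        stack = acquire_stack(vm, tissue, self._linear_settings(vm.true_params),
                              quantize_8bit=True)
        result = fit_image(stack, low_thresh=0.5)
        assert np.all(result.mask[2:4, 2:4] == MASK_SATURATED)

    def test_attenuation_bias_removed_by_squared_compensation(self):
        """gamma != 1 modulates excitation power across polarizations and biases
        the ratio maps; dividing each frame by r^2 (SHG is quadratic in the
        excitation intensity) restores the unbiased fit."""
        params = SystemParameters(delta=0.0, gamma=0.8)
        vm = VirtualMicroscope(true_params=params)
        tissue = VirtualTissue.uniform((6, 6), ratio33=1.5, ratio15=1.0,
                                       fiber_angle_deg=30.0)
        settings = self._linear_settings(params)
        stack = acquire_stack(vm, tissue, settings)
        with pytest.warns(UserWarning):
            biased = fit_image(stack, low_thresh=0.5)
        # the uncompensated profile is either inconsistent with the tensor
        # model (pixels masked fit_failed) or systematically off
        assert (not biased.valid.any()) or abs(np.nanmedian(biased.ratio33) - 1.5) > 0.05

        cal = power_factors(params, settings, settings[0])
        frames = np.stack([
            apply_power_calibration(stack.frames[k], float(cal.r[k]),
                                    mode="inverse-squared")
            for k in range(len(settings))
        ])
        from pshgcal.pshgfit import PSHGStack

        fixed = fit_image(PSHGStack(frames=frames, angles_deg=stack.angles_deg),
                          low_thresh=0.1)
        assert np.allclose(fixed.ratio33[fixed.valid], 1.5, atol=1e-6)
        assert np.allclose(fixed.ratio15[fixed.valid], 1.0, atol=1e-6)

    def test_elliptical_settings_warn(self):
        vm = VirtualMicroscope()
        tissue = VirtualTissue.uniform((6, 6))
        # QWP parked 12 deg off the linear condition: noticeably elliptical
        # output whose orientation still sweeps with the HWP
        settings = [WaveplateSetting(12.0, h) for h in np.arange(0.0, 90.0, 10.0)]
        with pytest.warns(UserWarning, match="elliptical"):
            acquire_stack(vm, tissue, settings, warn_elliptical=True)

    def test_empty_settings_rejected(self):
        with pytest.raises(ValueError):
            acquire_stack(VirtualMicroscope(), VirtualTissue.uniform((4, 4)), [])


class TestEndToEnd:
    def test_simulate_calibrate_solve_image_analyze(self):
        """Headline integration: a skewed virtual instrument is calibrated from
        its own simulated measurements, the solved settings drive imaging of a
        virtual tissue, and both the instrument parameters and the tissue
        ground truth are recovered."""
        true = SystemParameters(delta=-35.0, gamma=1.1, phi0=23.0, theta0=61.0,
                                alpha0=140.0, I0=1.4)
        vm = VirtualMicroscope(true_params=true, noise_sigma=0.005, seed=13)
        res = fit_calibration(acquire_calibration(vm))
        from pshgcal.calfit import canonical_difference

        err = canonical_difference(res.params, true)
        assert np.all(err <= np.maximum(5.0 * res.std, 1e-2))

        tissue = VirtualTissue.blocks(shape=(24, 24), seed=5, n_blocks=2,
                                      brightness=120.0)
        settings = []
        for t in np.arange(0.0, 181.0, 10.0) % 180.0:
            a, _ = settings_for_linear_angle(res.params, float(t))
            settings.append(a)
        stack = acquire_stack(vm, tissue, settings)
        # the fitted gamma != 1 modulates excitation power across the
        # settings; SHG is quadratic in it, so compensate each frame by r^2
        cal = power_factors(res.params, settings, settings[0])
        frames = np.stack([
            apply_power_calibration(stack.frames[k], float(cal.r[k]),
                                    mode="inverse-squared")
            for k in range(len(settings))
        ])
        from pshgcal.pshgfit import PSHGStack

        result = fit_image(PSHGStack(frames=frames, angles_deg=stack.angles_deg),
                           low_thresh=0.1)
        sel = result.valid.copy()
        for edge in (11, 12):  # block seams mixed by the 3x3 filter
            sel[edge - 1:edge + 2, :] = False
            sel[:, edge - 1:edge + 2] = False
        err33 = np.abs(result.ratio33 - tissue.ratio33)[sel]
        dphi = np.abs((result.fiber_angle - tissue.fiber_angle_deg + 90) % 180 - 90)[sel]
        assert np.median(err33) < 0.05
        assert np.median(dphi) < 1.0
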