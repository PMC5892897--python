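"""Forward-model tests: field coefficients, analyzer projection, ellipse summary."""

import math

import numpy as np
import pytest

from pshgcal.polmodel import (
    FieldState,
    InsufficientDataError,
    InvalidParameterError,
    SystemParameters,
    WaveplateSetting,
    ZeroFieldError,
    analyzer_intensity,
    field_components,
    fit_malus,
    polarization_state_analytic,
)

SQ2 = math.sqrt(2.0) / 2.0


def jones_oracle(params: SystemParameters, setting: WaveplateSetting):
    """Independent 2x2 complex Jones composition: i * M . H(theta) . Q(phi) . x-hat.

    Q is a quarter-wave retarder (fast axis x: diag(1, -i)), H a half-wave
    retarder (diag(1, -1)), M = diag(gamma e^{i delta}, 1) the microscope;
    the global phase i matches the coefficient convention of the closed form.
    """
    phi = np.deg2rad(setting.phi_prime - params.phi0)
    th = np.deg2rad(setting.theta_prime - params.theta0)

    def rot(a):
        return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])

    Q = rot(phi) @ np.diag([1.0, -1.0j]) @ rot(-phi)
    H = rot(th) @ np.diag([1.0, -1.0]) @ rot(-th)
    M = np.diag([params.gamma * np.exp(1j * np.deg2rad(params.delta)), 1.0])
    return 1j * (M @ H @ Q @ np.array([1.0, 0.0]))


class TestFieldComponents:
    @pytest.mark.parametrize(
        "params, setting, expected",
        [
            (SystemParameters(), WaveplateSetting(0, 0), (0, 1, 0, 0)),
            (SystemParameters(), WaveplateSetting(45, 22.5), (0, SQ2, SQ2, 0)),
        ],
        ids=["aligned-plates-pass-linear-x", "qwp-at-45-gives-circular"],
    )
    def test_textbook_settings(self, params, setting, expected):
        f = field_components(params, setting)
        assert np.allclose((f.d1, f.d2, f.d3, f.d4), expected, atol=1e-12)

    def test_matches_jones_oracle_for_skewed_system(self):
        params = SystemParameters(delta=30, gamma=0.8, phi0=10, theta0=5)
        setting = WaveplateSetting(20, 45)
        f = field_components(params, setting)
        E = jones_oracle(params, setting)
        assert abs(f.Ex - E[0]) < 1e-12
        assert abs(f.Ey - E[1]) < 1e-12

    def test_matches_jones_oracle_over_random_draws(self, rng):
        for _ in range(1000):
            params = SystemParameters(
                delta=rng.uniform(-180, 180),
                gamma=rng.uniform(0.3, 2.0),
                phi0=rng.uniform(0, 180),
                theta0=rng.uniform(0, 90),
            )
            setting = WaveplateSetting(rng.uniform(-360, 360), rng.uniform(-360, 360))
            f = field_components(params, setting)
            E = jones_oracle(params, setting)
            assert abs(f.Ex - E[0]) + abs(f.Ey - E[1]) < 1e-12

    def test_lossless_energy_conservation(self, rng):
        params = SystemParameters(delta=rng.uniform(-90, 90), gamma=1.0,
                                  phi0=3.0, theta0=7.0)
        for _ in range(50):
            f = field_components(
                params, WaveplateSetting(rng.uniform(0, 180), rng.uniform(0, 90))
            )
            assert f.d1**2 + f.d2**2 + f.d3**2 + f.d4**2 == pytest.approx(1.0, abs=1e-12)

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidParameterError):
            SystemParameters(gamma=-0.5)
        with pytest.raises(InvalidParameterError):
            SystemParameters(delta=float("nan"))
        with pytest.raises(InvalidParameterError):
            field_components(SystemParameters(), WaveplateSetting(float("inf"), 0))


class TestAnalyzerIntensity:
    def test_crossed_analyzer_extinguishes_linear_light(self):
        assert analyzer_intensity(FieldState(0, 1, 0, 0), 90.0) == pytest.approx(0, abs=1e-15)

    def test_circular_light_transmits_half_at_every_angle(self):
        f = FieldState(0, SQ2, SQ2, 0)
        for a in np.arange(0, 180, 7.5):
            assert analyzer_intensity(f, a) == pytest.approx(0.5, abs=1e-12)

    def test_matches_complex_projection_oracle(self):
        params = SystemParameters(delta=30, gamma=0.8, phi0=10, theta0=5)
        f = field_components(params, WaveplateSetting(20, 45))
        for a in np.arange(0.0, 181.0, 30.0):
            proj = abs(f.Ex * math.cos(math.radians(a)) + f.Ey * math.sin(math.radians(a))) ** 2
            assert analyzer_intensity(f, a) == pytest.approx(proj, abs=1e-13)

    def test_stokes_identity(self, rng):
        """I(alpha) equals I0 (S0 + S1 cos 2a + S2 sin 2a) / 2 for any field."""
        for _ in range(30):
            f = FieldState(*rng.normal(size=4))
            s0, s1, s2, _ = f.stokes()
            a = rng.uniform(0, 360)
            expect = (s0 + s1 * math.cos(2 * math.radians(a))
                      + s2 * math.sin(2 * math.radians(a))) / 2.0
            assert analyzer_intensity(f, a) == pytest.approx(expect, abs=1e-12)


class TestPolarizationStateAnalytic:
    def test_linear_x(self):
        st = polarization_state_analytic(FieldState(1, 0, 0, 0))
        assert st.rho == 0.0
        assert st.alpha_max == 0.0
        assert st.Imax == pytest.approx(1.0)

    def test_elliptic_example_against_dense_sweep(self):
        # Ex = 0.8, Ey = 0.6i
        f = FieldState(0.8, 0, 0, 0.6)
        st = polarization_state_analytic(f)
        assert st.Imax == pytest.approx(0.64, abs=1e-12)
        assert st.Imin == pytest.approx(0.36, abs=1e-12)
        assert st.rho == pytest.approx(0.75, abs=1e-12)
        assert st.alpha_max == pytest.approx(0.0, abs=1e-9)
        # brute-force sweep of the analyzer at 0.01-degree resolution
        sweep = analyzer_intensity(f, np.arange(0.0, 180.0, 0.01))
        assert st.Imax == pytest.approx(sweep.max(), abs=1e-8)
        assert st.Imin == pytest.approx(sweep.min(), abs=1e-8)

    def test_circular_orientation_degenerates_to_zero(self):
        st = polarization_state_analytic(FieldState(SQ2, 0, 0, SQ2))
        assert st.rho == pytest.approx(1.0, abs=1e-12)
        assert st.degenerate_orientation
        assert st.alpha_max == 0.0

    def test_energy_conservation_over_settings_grid(self):
        """Lossless optics split I0 exactly into Imax + Imin at every setting."""
        params = SystemParameters(delta=37.0, gamma=1.0, phi0=11.0, theta0=4.0, I0=2.5)
        for q in np.arange(0.0, 181.0, 10.0):
            for h in np.arange(0.0, 91.0, 10.0):
                st = polarization_state_analytic(
                    field_components(params, WaveplateSetting(q, h)), I0=params.I0
                )
                assert st.Imax + st.Imin == pytest.approx(params.I0, abs=1e-10)

    def test_zero_field_raises(self):
        with pytest.raises(ZeroFieldError):
            polarization_state_analytic(FieldState(0, 0, 0, 0))

    def test_handedness_sign_convention(self):
        # Ey = i Ex: S3 > 0 -> "right"
        assert polarization_state_analytic(FieldState(1, 0, 0, 1)).handedness == "right"
        assert polarization_state_analytic(FieldState(1, 0, 0, -1)).handedness == "left"


class TestFitMalus:
    angles7 = np.arange(0.0, 181.0, 30.0)

    def test_constant_intensity_is_circular(self):
        st = fit_malus(self.angles7, np.full(7, 0.5))
        assert st.Imax == pytest.approx(0.5, abs=1e-12)
        assert st.Imin == pytest.approx(0.5, abs=1e-12)
        assert st.rho == pytest.approx(1.0, abs=1e-9)

    def test_pure_malus_law(self):
        st = fit_malus(self.angles7, np.cos(np.deg2rad(self.angles7)) ** 2)
        assert st.Imax == pytest.approx(1.0, abs=1e-12)
        assert st.Imin == pytest.approx(0.0, abs=1e-12)
        assert st.rho == pytest.approx(0.0, abs=1e-9)
        assert st.alpha_max == pytest.approx(0.0, abs=1e-9)

    def test_elliptic_profile_matches_analytic_state(self):
        a = np.deg2rad(self.angles7)
        I = 0.64 * np.cos(a) ** 2 + 0.36 * np.sin(a) ** 2
        st = fit_malus(self.angles7, I)
        assert st.Imax == pytest.approx(0.64, abs=1e-12)
        assert st.Imin == pytest.approx(0.36, abs=1e-12)
        assert st.rho == pytest.approx(0.75, abs=1e-12)

    def test_recovers_noiseless_samples_exactly(self, rng):
        """Any noiseless two-level cos^2/sin^2 profile is recovered to 1e-9."""
        for _ in range(25):
            imax, frac = rng.uniform(0.5, 3.0), rng.uniform(0, 1)
            imin = frac * imax
            amax = rng.uniform(0, 180)
            a = np.deg2rad(self.angles7 - amax)
            I = imax * np.cos(a) ** 2 + imin * np.sin(a) ** 2
            st = fit_malus(self.angles7, I)
            assert st.Imax == pytest.approx(imax, abs=1e-9)
            assert st.Imin == pytest.approx(imin, abs=1e-9)
            if not st.degenerate_orientation:
                diff = abs((st.alpha_max - amax + 90.0) % 180.0 - 90.0)
                assert diff < 1e-9 or imax == pytest.approx(imin, abs=1e-9)

    def test_insufficient_data_errors(self):
        with pytest.raises(InsufficientDataError):
            fit_malus([0, 30, 60], [1, 1, 1])
        with pytest.raises(InsufficientDataError):
            fit_malus([0, 10, 20, 30], [1, 1, 1, 1])  # span < 90 deg
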