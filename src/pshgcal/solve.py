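"""Waveplate settings realizing linear and circular polarization.

Given calibrated system parameters, this module inverts the forward model:

* **Linear output.**  The field at the image plane is linear exactly when
  ``tan(2 phi) = -tan(delta) sin(2 x)`` with ``x = 2 theta - phi`` the
  retarder combination angle (physical angles).  For each ``x`` there are
  two QWP solutions, ``phi`` in (-45, 45] and ``phi + 90``, which produce
  linear light of generally different orientation — hence two distinct
  motor settings per requested polarization angle.
* **Circular output.**  Requiring ``Ey = +/- i Ex`` gives two coupled
  tangent conditions whose simultaneous solution reduces to the closed
  form ``sin(2 phi) = -2 s gamma cos(delta) / (1 + gamma^2)`` per sign
  pairing ``s``; ``x`` then follows from
  ``tan(x) = -gamma sin(delta) cos(phi) / (gamma cos(delta) sin(phi) +
  s cos(phi))``.  Each candidate is polished against the forward model and
  validated to machine-level circularity.  The two sign pairings give the
  two handednesses.
* **Power calibration.**  The polarization-dependent attenuation modulates
  the peak power across linear settings; ``r = Imax(setting) /
  Imax(reference)`` normalizes images acquired at different settings to a
  common reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .polmodel import (
    SystemParameters,
    WaveplateSetting,
    field_components,
    polarization_state_analytic,
)

__all__ = [
    "LinearSolutionCurve",
    "CircularSolution",
    "PowerCalibration",
    "linear_condition_phi",
    "linear_curve",
    "circular_settings",
    "settings_for_linear_angle",
    "power_factors",
    "apply_power_calibration",
    "SolverError",
]


class SolverError(RuntimeError):
    """Raised when a settings inversion fails; may carry a diagnostic curve."""

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def linear_condition_phi(params: SystemParameters, x) -> float | np.ndarray:
    """QWP physical angle ``phi`` (degrees) giving linear output at combination angle ``x``.

    ``x = 2 theta - phi`` in physical (offset-corrected) degrees.  The
    principal branch ``phi in (-45, 45]`` is returned; ``phi + 90`` is the
    second solution.  Closed form, no iteration.
    """
    xr = np.deg2rad(np.asarray(x, dtype=float))
    tan2phi = -math.tan(math.radians(params.delta)) * np.sin(2.0 * xr)
    phi = np.rad2deg(np.arctan(tan2phi) / 2.0)
    # arctan lands in (-45, 45); map -45 exactly to +45 if it ever occurs
    phi = np.where(phi <= -45.0, phi + 90.0, phi)
    if np.ndim(x) == 0:
        return float(phi)
    return phi


def _motor_setting(params: SystemParameters, phi: float, x: float) -> WaveplateSetting:
    """Motor angles from physical QWP angle and combination angle ``x = 2 theta - phi``."""
    phi_prime = phi + params.phi0
    theta_prime = (x + phi) / 2.0 + params.theta0
    return WaveplateSetting(phi_prime, theta_prime).canonical()


@dataclass
class LinearSolutionCurve:
    """The one-parameter family of linear-polarization settings.

    Parameterized by ``x = 2 theta' - phi'`` (motor angles, degrees, in
    [0, 180)); ``branch`` 0 is the principal QWP branch, 1 the branch
    shifted by 90 degrees.  ``alpha_max`` is the output polarization angle
    and ``rho`` the (near-zero) predicted ellipticity at each point.
    """

    x: np.ndarray
    phi_prime: np.ndarray
    theta_prime: np.ndarray
    alpha_max: np.ndarray
    rho: np.ndarray
    branch: int


def linear_curve(
    params: SystemParameters, x_grid=None, branch: int = 0
) -> LinearSolutionCurve:
    """Evaluate the linear-polarization solution curve on an ``x`` grid.

    ``x`` here is the motor-angle combination ``2 theta' - phi'``; it maps
    to the physical combination angle via ``x_phys = x - 2 theta0 + phi0``.
    """
    if x_grid is None:
        x_grid = np.arange(0.0, 180.0, 1.0)
    x = np.asarray(x_grid, dtype=float)
    x_phys = x - 2.0 * params.theta0 + params.phi0
    phi = linear_condition_phi(params, x_phys) + 90.0 * branch
    phi_prime = np.asarray(phi) + params.phi0
    theta_prime = (x + phi_prime) / 2.0
    amax = np.empty_like(x)
    rho = np.empty_like(x)
    for k in range(x.size):
        st = polarization_state_analytic(
            field_components(params, WaveplateSetting(phi_prime[k], theta_prime[k])),
            I0=params.I0,
        )
        amax[k] = st.alpha_max
        rho[k] = st.rho
    return LinearSolutionCurve(
        x=x,
        phi_prime=phi_prime % 180.0,
        theta_prime=theta_prime % 90.0,
        alpha_max=amax,
        rho=rho,
        branch=branch,
    )


@dataclass(frozen=True)
class CircularSolution:
    """One waveplate setting producing circular light, with handedness."""

    setting: WaveplateSetting
    handedness: str
    rho: float


def circular_settings(
    params: SystemParameters, *, tol: float = 1e-9
) -> list[CircularSolution]:
    """All waveplate settings (canonical cell) giving circular polarization.

    Solves the paired tangent conditions in closed form per sign pairing,
    refines each candidate by maximizing forward-model ellipticity, and
    keeps solutions with ``rho > 1 - tol``.  Solutions come in
    opposite-handed pairs; for an ideal instrument (``delta = 0``,
    ``gamma = 1``) the conditions are degenerate — any HWP angle works —
    and the representative with ``x_phys = 0`` is returned.
    """
    g = params.gamma
    cd = math.cos(math.radians(params.delta))
    sd = math.sin(math.radians(params.delta))
    out: list[CircularSolution] = []
    seen: list[tuple[float, float]] = []
    for s in (+1.0, -1.0):
        rhs = -2.0 * s * g * cd / (1.0 + g * g)
        rhs = min(1.0, max(-1.0, rhs))
        base = math.degrees(math.asin(rhs))
        for two_phi in (base, 180.0 - base, base + 360.0, 540.0 - base):
            phi = two_phi / 2.0
            sp, cp = math.sin(math.radians(phi)), math.cos(math.radians(phi))
            num = -g * sd * cp
            den = g * cd * sp + s * cp
            x = 0.0 if (abs(num) < 1e-14 and abs(den) < 1e-14) else math.degrees(
                math.atan2(num, den)
            )
            cand = _motor_setting(params, phi, x)
            st = polarization_state_analytic(
                field_components(params, cand), I0=params.I0
            )
            if st.rho <= 1.0 - 1e-12:  # closed form off target: polish numerically
                cand = _polish_circular(params, cand)
                st = polarization_state_analytic(
                    field_components(params, cand), I0=params.I0
                )
            if st.rho <= 1.0 - tol:
                continue
            key = (round(cand.phi_prime, 6) % 180.0, round(cand.theta_prime, 6) % 90.0)
            if any(
                _ang_close(key[0], k0, 180.0, 1e-4) and _ang_close(key[1], k1, 90.0, 1e-4)
                for k0, k1 in seen
            ):
                continue
            seen.append(key)
            out.append(
                CircularSolution(setting=cand, handedness=st.handedness or "right",
                                 rho=st.rho)
            )
    if not out:
        raise SolverError("no circular solution found for these parameters")
    return sorted(out, key=lambda c: (c.setting.phi_prime, c.setting.theta_prime))


def _ang_close(a: float, b: float, period: float, tol: float) -> bool:
    d = (a - b) % period
    return min(d, period - d) < tol


def _polish_circular(
    params: SystemParameters, setting: WaveplateSetting
) -> WaveplateSetting:
    """Local refinement of a circular candidate by maximizing rho on the forward model."""

    def neg_rho(v):
        st = polarization_state_analytic(
            field_components(params, WaveplateSetting(v[0], v[1])), I0=params.I0
        )
        return -st.rho

    from scipy.optimize import minimize

    res = minimize(
        neg_rho,
        np.array([setting.phi_prime, setting.theta_prime]),
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 600},
    )
    if res.fun <= neg_rho([setting.phi_prime, setting.theta_prime]):
        return WaveplateSetting(float(res.x[0]), float(res.x[1])).canonical()
    return setting


def settings_for_linear_angle(
    params: SystemParameters, target_angle: float, *, tol_deg: float = 0.01
) -> tuple[WaveplateSetting, WaveplateSetting]:
    """The two motor settings producing linear light at ``target_angle`` degrees.

    Inverts the output-orientation map ``alpha_max(x)`` along each QWP
    branch of the linear solution curve by bracketed root finding on the
    wrapped angular difference.  Returns (set A, set B) ordered by
    ascending ``theta'``; both satisfy ``|alpha_max - target| < tol_deg``.
    """
    if not 0.0 <= target_angle < 180.0 + 1e-9:
        raise ValueError("target angle must be in [0, 180)")
    solutions: list[WaveplateSetting] = []
    diag = []
    for branch in (0, 1):
        grid = np.arange(0.0, 180.0 + 0.25, 0.25)
        curve = linear_curve(params, grid, branch=branch)
        diff = (curve.alpha_max - target_angle + 90.0) % 180.0 - 90.0
        diag.append(curve)

        def f(xv: float) -> float:
            c = linear_curve(params, np.array([xv]), branch=branch)
            return float((c.alpha_max[0] - target_angle + 90.0) % 180.0 - 90.0)

        roots: list[float] = []
        for i in range(diff.size - 1):
            a, b = diff[i], diff[i + 1]
            if a == 0.0:
                roots.append(grid[i])
            elif a * b < 0 and abs(a - b) < 90.0:  # genuine crossing, not a wrap
                roots.append(brentq(f, grid[i], grid[i + 1], xtol=1e-10))
        if diff[-1] == 0.0:
            roots.append(grid[-1])
        for r in roots:
            c = linear_curve(params, np.array([r]), branch=branch)
            s = WaveplateSetting(float(c.phi_prime[0]), float(c.theta_prime[0])).canonical()
            if abs(float((c.alpha_max[0] - target_angle + 90.0) % 180.0 - 90.0)) < tol_deg:
                if not any(
                    _ang_close(s.phi_prime, t.phi_prime, 180.0, 1e-6)
                    and _ang_close(s.theta_prime, t.theta_prime, 90.0, 1e-6)
                    for t in solutions
                ):
                    solutions.append(s)
    if len(solutions) != 2:
        raise SolverError(
            f"expected 2 linear settings for target {target_angle} deg, "
            f"found {len(solutions)}",
            diagnostics=diag,
        )
    solutions.sort(key=lambda s: (s.theta_prime, s.phi_prime))
    return solutions[0], solutions[1]


@dataclass
class PowerCalibration:
    """Per-setting power factors ``r = Imax(setting) / Imax(reference)``."""

    reference: WaveplateSetting
    settings: list[WaveplateSetting]
    r: np.ndarray

    def factor(self, setting: WaveplateSetting) -> float:
        for s, rv in zip(self.settings, self.r):
            if (
                _ang_close(s.phi_prime, setting.phi_prime, 180.0, 1e-6)
                and _ang_close(s.theta_prime, setting.theta_prime, 90.0, 1e-6)
            ):
                return float(rv)
        raise KeyError(f"setting {setting} not in power calibration")


def power_factors(
    params: SystemParameters,
    settings: list[WaveplateSetting],
    reference: WaveplateSetting,
) -> PowerCalibration:
    """Power-calibration factors for a list of settings against a reference.

    ``Imax`` is the peak of the model-predicted analyzer sweep at each
    setting (the analytic maximum of the Malus fit).
    """

    def imax(s: WaveplateSetting) -> float:
        return polarization_state_analytic(
            field_components(params, s), I0=params.I0
        ).Imax

    ref = imax(reference)
    if ref <= 0:
        raise SolverError("reference setting has zero peak power")
    r = np.array([imax(s) / ref for s in settings])
    return PowerCalibration(reference=reference, settings=list(settings), r=r)


def apply_power_calibration(
    image: np.ndarray, r: float, *, mode: str = "direct"
) -> np.ndarray:
    """Scale an SHG image by its power factor.

    ``mode='direct'`` multiplies by ``r`` (the printed convention);
    ``'inverse'`` divides by ``r``; ``'inverse-squared'`` divides by
    ``r**2``, which undoes the quadratic dependence of SHG on excitation
    power when ``r`` is a ratio of excitation intensities.  Output is
    float64 regardless of input dtype.
    """
    if r <= 0:
        raise ValueError("power factor must be > 0")
    img = np.asarray(image, dtype=np.float64)
    if mode == "direct":
        return img * r
    if mode == "inverse":
        return img / r
    if mode == "inverse-squared":
        return img / (r * r)
    raise ValueError(f"unknown compensation mode: {mode!r}")
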