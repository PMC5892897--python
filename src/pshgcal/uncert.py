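"""Delta-method propagation of calibration covariance onto solved settings.

The calibration fit returns a 6x6 covariance over ``(delta, gamma, phi0,
theta0, alpha0, I0)``.  The solved waveplate settings are smooth functions
of those parameters, so first-order (delta-method) propagation gives their
standard deviations: ``var(f) = g^T C g`` with ``g`` the gradient of the
setting with respect to the parameters, evaluated by central finite
differences (relative step 1e-6, absolute floor 1e-8 degrees).

Two propagation paths mirror how the solutions are constructed:

* **Circular**: the QWP motor angle is a function ``phi'(phi0, delta,
  gamma)``; the HWP angle is then propagated as ``theta'(theta0, phi0,
  delta, gamma)`` holding ``phi'`` fixed at its nominal value (the QWP is
  parked before the HWP is solved, so its realized angle carries no
  uncertainty into the HWP equation).
* **Linear**: along the solution curve parameterized by ``x = 2 theta' -
  phi'`` (assumed exact), the band is the pointwise std of ``phi'(x)``;
  its image in the (phi', theta') plane follows from ``theta' = (x +
  phi')/2``, i.e. half the phi' std at fixed x.

Reported intervals default to +/- 3 std.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .calfit import CalibrationResult
from .polmodel import SystemParameters
from .solve import CircularSolution, circular_settings, linear_condition_phi

__all__ = [
    "SolutionUncertainty",
    "propagate_circular",
    "propagate_linear",
]


@dataclass
class SolutionUncertainty:
    """Propagated standard deviations for solved waveplate settings.

    For circular solutions ``std_phi_prime``/``std_theta_prime`` are per
    solution; for the linear curve they are per grid point of ``x``.
    ``multiplier`` is the reporting factor for interval display (+/- k std).
    """

    kind: str  # "circular" | "linear"
    std_phi_prime: np.ndarray
    std_theta_prime: np.ndarray
    multiplier: float = 3.0
    solutions: list[CircularSolution] | None = None
    x: np.ndarray | None = None
    phi_prime: np.ndarray | None = None
    theta_prime: np.ndarray | None = None

    @property
    def interval_phi_prime(self) -> np.ndarray:
        """Half-width of the reported phi' interval (multiplier * std)."""
        return self.multiplier * self.std_phi_prime

    @property
    def interval_theta_prime(self) -> np.ndarray:
        return self.multiplier * self.std_theta_prime


def _fd_gradient(func, v0: np.ndarray) -> np.ndarray:
    """Central-difference gradient of a scalar function of the parameter vector."""
    g = np.zeros_like(v0)
    for k in range(v0.size):
        step = max(1e-6 * abs(v0[k]), 1e-8)
        vp, vm = v0.copy(), v0.copy()
        vp[k] += step
        vm[k] -= step
        g[k] = (func(vp) - func(vm)) / (2.0 * step)
    return g


def _check_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (6, 6):
        raise ValueError("covariance must be 6x6")
    if np.linalg.matrix_rank(cov) < 6:
        warnings.warn(
            "singular covariance matrix; propagated stds may understate "
            "the true uncertainty",
            stacklevel=3,
        )
    return cov


def _circular_phi_branch(sol: CircularSolution, params: SystemParameters):
    """Identify (sign pairing, asin branch) reproducing this solution's phi'."""
    g, d = params.gamma, math.radians(params.delta)
    phi_nom = sol.setting.phi_prime - params.phi0
    for s in (+1.0, -1.0):
        rhs = max(-1.0, min(1.0, -2.0 * s * g * math.cos(d) / (1.0 + g * g)))
        base = math.degrees(math.asin(rhs))
        for two_phi in (base, 180.0 - base, base + 360.0, 540.0 - base):
            if abs((two_phi / 2.0 - phi_nom + 90.0) % 180.0 - 90.0) < 1e-6:
                return s, two_phi - base  # offset from the principal asin value
    raise ValueError("could not match circular solution to an analytic branch")


def _wrap_near(value: float, reference: float, period: float) -> float:
    """Shift ``value`` by multiples of ``period`` to land nearest ``reference``."""
    return value + period * round((reference - value) / period)


def propagate_circular(
    result: CalibrationResult, *, multiplier: float = 3.0
) -> SolutionUncertainty:
    """Std of the circular-polarization QWP and HWP motor angles.

    One (std_phi', std_theta') pair per circular solution of the fitted
    parameters, in the order returned by ``circular_settings``.
    """
    cov = _check_cov(result.covariance)
    params = result.params
    sols = circular_settings(params)
    v0 = params.as_array()
    std_p, std_t = [], []
    for sol in sols:
        s, branch_off = _circular_phi_branch(sol, params)
        phi_nom = sol.setting.phi_prime

        def phi_prime_of(v, s=s, branch_off=branch_off, phi_nom=phi_nom):
            d, g, p0 = math.radians(v[0]), v[1], v[2]
            rhs = max(-1.0, min(1.0, -2.0 * s * g * math.cos(d) / (1.0 + g * g)))
            two_phi = math.degrees(math.asin(rhs)) + branch_off
            return _wrap_near(two_phi / 2.0 + p0, phi_nom, 180.0)

        theta_nom = sol.setting.theta_prime

        def theta_prime_of(v, s=s, phi_nom=phi_nom, theta_nom=theta_nom):
            # phi' held fixed at its nominal value (no uncertainty)
            d, g, p0, t0 = math.radians(v[0]), v[1], v[2], v[3]
            phi = math.radians(phi_nom - p0)
            num = -g * math.sin(d) * math.cos(phi)
            den = g * math.cos(d) * math.sin(phi) + s * math.cos(phi)
            x = 0.0 if (abs(num) < 1e-14 and abs(den) < 1e-14) else math.degrees(
                math.atan2(num, den)
            )
            theta = (x + math.degrees(phi)) / 2.0 + t0
            return _wrap_near(theta, theta_nom, 90.0)

        gp = _fd_gradient(phi_prime_of, v0)
        gt = _fd_gradient(theta_prime_of, v0)
        std_p.append(math.sqrt(max(gp @ cov @ gp, 0.0)))
        std_t.append(math.sqrt(max(gt @ cov @ gt, 0.0)))
    return SolutionUncertainty(
        kind="circular",
        std_phi_prime=np.array(std_p),
        std_theta_prime=np.array(std_t),
        multiplier=multiplier,
        solutions=sols,
    )


def propagate_linear(
    result: CalibrationResult,
    x_grid=None,
    *,
    branch: int = 0,
    multiplier: float = 3.0,
) -> SolutionUncertainty:
    """Std band around the linear-solution curve ``phi'(x)``.

    ``x = 2 theta' - phi'`` (motor angles) is treated as exact; the band in
    the (phi', theta') plane follows through ``theta' = (x + phi') / 2``.
    """
    if x_grid is None:
        x_grid = np.arange(0.0, 180.0, 1.0)
    x = np.asarray(x_grid, dtype=float)
    if np.any((x < 0.0) | (x >= 180.0 + 1e-9)):
        raise ValueError("x must lie in [0, 180)")
    cov = _check_cov(result.covariance)
    params = result.params
    v0 = params.as_array()
    std_p = np.empty_like(x)
    phi_nom = np.empty_like(x)
    for k, xk in enumerate(x):

        def phi_prime_of(v, xk=xk):
            p = SystemParameters.from_array(v)
            x_phys = xk - 2.0 * p.theta0 + p.phi0
            return linear_condition_phi(p, x_phys) + 90.0 * branch + p.phi0

        phi_nom[k] = phi_prime_of(v0)
        g = _fd_gradient(phi_prime_of, v0)
        std_p[k] = math.sqrt(max(g @ cov @ g, 0.0))
    return SolutionUncertainty(
        kind="linear",
        std_phi_prime=std_p,
        std_theta_prime=std_p / 2.0,
        multiplier=multiplier,
        x=x,
        phi_prime=phi_nom % 180.0,
        theta_prime=((x + phi_nom) / 2.0) % 90.0,
    )
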