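"""Forward polarization model of the excitation path.

The excitation beam is linearly polarized along ``x``, passes a rotatable
quarter-wave plate (QWP, fast axis at ``phi`` to ``x``) and half-wave plate
(HWP, fast axis at ``theta``), and then traverses the microscope optics —
chiefly the dichroic mirror — which impose a relative phase shift ``delta``
and amplitude attenuation ``gamma`` on the ``x`` component of the field
relative to ``y``.  The waveplate motors are not referenced to the ``x``
axis, so physical angles are obtained from motor angles via fixed offsets:
``phi = phi' - phi0``, ``theta = theta' - theta0``, and likewise
``alpha = alpha' - alpha0`` for the analyzer used during calibration.

All public interfaces take and return angles in degrees; trigonometry is
done in radians internally.  The field at the image plane is written as
``E = E0 * [(d1 + i d2) x + (d3 + i d4) y]`` with real coefficients
``d1..d4`` in units of the input amplitude ``E0``; for a lossless system
(``gamma = 1``) they satisfy ``d1^2 + d2^2 + d3^2 + d4^2 = 1``.

Convention notes
----------------
* ``gamma`` and ``delta`` act on the **x** component of the field
  (``Ex -> gamma * exp(i delta) * Ex``); the model is explicit about this
  because only the relative change between the components is observable.
* Handedness: the Stokes parameter ``S3 = -2 Im(Ex conj(Ey))`` is positive
  for light labelled "right".  The sign is an arbitrary but fixed
  convention.
* For near-circular light (``rho > 0.999``) the ellipse orientation is
  meaningless; ``alpha_max`` is reported as 0 with a
  ``degenerate_orientation`` flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SystemParameters",
    "WaveplateSetting",
    "FieldState",
    "PolarizationState",
    "IDEAL_PARAMS",
    "field_components",
    "analyzer_intensity",
    "polarization_state_analytic",
    "fit_malus",
]

#: ellipticity above which the ellipse orientation is considered undefined
DEGENERATE_RHO = 0.999


class InvalidParameterError(ValueError):
    """Raised for non-finite angles or non-positive gamma / I0."""


class InsufficientDataError(ValueError):
    """Raised when a fit has too few or too degenerate observations."""


class ZeroFieldError(ValueError):
    """Raised when a polarization state is requested for a null field."""


@dataclass(frozen=True)
class SystemParameters:
    """The six unknowns of the polarization calibration.

    Parameters
    ----------
    delta : float
        Relative phase shift between x and y field components, degrees.
    gamma : float
        Relative amplitude attenuation of the x component (dimensionless,
        > 0; 1 means lossless).
    phi0, theta0, alpha0 : float
        QWP / HWP fast-axis and analyzer transmission-axis offsets at
        motor zero, degrees.
    I0 : float
        Intensity scale ``E0**2`` in arbitrary power units (> 0).
    """

    delta: float = 0.0
    gamma: float = 1.0
    phi0: float = 0.0
    theta0: float = 0.0
    alpha0: float = 0.0
    I0: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.delta, self.gamma, self.phi0, self.theta0, self.alpha0, self.I0)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidParameterError(f"non-finite system parameter in {vals}")
        if self.gamma <= 0:
            raise InvalidParameterError(f"gamma must be > 0, got {self.gamma}")
        if self.I0 <= 0:
            raise InvalidParameterError(f"I0 must be > 0, got {self.I0}")

    def as_array(self) -> np.ndarray:
        """Parameter vector in the fixed order (delta, gamma, phi0, theta0, alpha0, I0)."""
        return np.array(
            [self.delta, self.gamma, self.phi0, self.theta0, self.alpha0, self.I0]
        )

    @classmethod
    def from_array(cls, v) -> "SystemParameters":
        d, g, p0, t0, a0, i0 = (float(x) for x in v)
        return cls(delta=d, gamma=g, phi0=p0, theta0=t0, alpha0=a0, I0=i0)


#: an ideal instrument: no phase shift, no attenuation, calibrated motors
IDEAL_PARAMS = SystemParameters()


@dataclass(frozen=True)
class WaveplateSetting:
    """Motor angles (degrees) of the QWP and HWP rotation stages."""

    phi_prime: float
    theta_prime: float

    def canonical(self) -> "WaveplateSetting":
        """Fold into the fundamental domain phi' in [0, 180), theta' in [0, 90).

        A QWP is physically periodic in 180 deg and an HWP in 90 deg
        (its Jones matrix changes only by a global sign).
        """
        return WaveplateSetting(self.phi_prime % 180.0, self.theta_prime % 90.0)


@dataclass(frozen=True)
class FieldState:
    """Real coefficients of the complex field at the imaging plane.

    ``Ex = d1 + i d2``, ``Ey = d3 + i d4`` in units of ``E0``.
    """

    d1: float
    d2: float
    d3: float
    d4: float

    @property
    def Ex(self) -> complex:
        return complex(self.d1, self.d2)

    @property
    def Ey(self) -> complex:
        return complex(self.d3, self.d4)

    def stokes(self) -> tuple[float, float, float, float]:
        """Stokes parameters (S0, S1, S2, S3) in units of ``E0**2``."""
        ex, ey = self.Ex, self.Ey
        s0 = abs(ex) ** 2 + abs(ey) ** 2
        s1 = abs(ex) ** 2 - abs(ey) ** 2
        cross = ex * ey.conjugate()
        return s0, s1, 2.0 * cross.real, -2.0 * cross.imag


@dataclass(frozen=True)
class PolarizationState:
    """Summary of a polarization ellipse from intensity measurements.

    ``Imax``/``Imin`` are the transmitted powers at the best/worst analyzer
    angle, ``alpha_max`` (degrees, in [0, 180)) the analyzer angle of
    maximum transmission, and ``rho = Emin/Emax = sqrt(Imin/Imax)`` the
    ellipticity (0 linear, 1 circular).
    """

    Imax: float
    Imin: float
    alpha_max: float
    rho: float
    degenerate_orientation: bool = False
    handedness: str | None = field(default=None, compare=False)


def _field_components_arrays(params: SystemParameters, phi_prime, theta_prime):
    """Vectorized d1..d4 for arrays of motor angles (degrees)."""
    phi = np.deg2rad(np.asarray(phi_prime, dtype=float) - params.phi0)
    theta = np.deg2rad(np.asarray(theta_prime, dtype=float) - params.theta0)
    x = 2.0 * theta - phi  # retarder combination angle, radians
    cd, sd = math.cos(math.radians(params.delta)), math.sin(math.radians(params.delta))
    g = params.gamma
    sp, cp = np.sin(phi), np.cos(phi)
    sx, cx = np.sin(x), np.cos(x)
    d1 = -g * (cd * sp * sx + sd * cp * cx)
    d2 = -g * (sd * sp * sx - cd * cp * cx)
    d3 = sp * cx
    d4 = cp * sx
    return d1, d2, d3, d4


def field_components(params: SystemParameters, setting: WaveplateSetting) -> FieldState:
    """Field at the imaging plane for one waveplate setting.

    Evaluates the closed-form coefficients of the QWP -> HWP -> microscope
    cascade acting on x-polarized input.
    """
    if not (math.isfinite(setting.phi_prime) and math.isfinite(setting.theta_prime)):
        raise InvalidParameterError("non-finite motor angle")
    d1, d2, d3, d4 = _field_components_arrays(
        params, setting.phi_prime, setting.theta_prime
    )
    return FieldState(float(d1), float(d2), float(d3), float(d4))


def analyzer_intensity(
    field: FieldState, alpha_prime, alpha0: float = 0.0, I0: float = 1.0
):
    """Power behind a linear analyzer at motor angle ``alpha_prime`` (degrees).

    Malus-law projection of the complex field:
    ``I = I0 * [|Ex|^2 cos^2(a) + |Ey|^2 sin^2(a) + 2 Re(Ex Ey*) sin(a) cos(a)]``
    with ``a = alpha' - alpha0``.  Accepts a scalar or array of angles.
    """
    a = np.deg2rad(np.asarray(alpha_prime, dtype=float) - alpha0)
    ex, ey = field.Ex, field.Ey
    ca, sa = np.cos(a), np.sin(a)
    out = I0 * (
        abs(ex) ** 2 * ca**2
        + abs(ey) ** 2 * sa**2
        + 2.0 * (ex * ey.conjugate()).real * sa * ca
    )
    # clamp tiny negative round-off at extinction
    out = np.where((out < 0) & (out > -1e-12 * I0), 0.0, out)
    if np.ndim(alpha_prime) == 0:
        return float(out)
    return out


def polarization_state_analytic(field: FieldState, I0: float = 1.0) -> PolarizationState:
    """Closed-form ellipse summary from the Stokes parameters.

    Equivalent to maximizing the analyzer transmission over all angles:
    ``Imax/Imin = I0 (S0 +/- sqrt(S1^2 + S2^2)) / 2`` and
    ``alpha_max = atan2(S2, S1) / 2``.
    """
    s0, s1, s2, s3 = field.stokes()
    if s0 <= 0.0:
        raise ZeroFieldError("zero field has no polarization state")
    amp = math.hypot(s1, s2)
    imax = I0 * (s0 + amp) / 2.0
    # a pure state satisfies S0^2 = S1^2 + S2^2 + S3^2 exactly, so
    # S0 - amp = S3^2 / (S0 + amp): immune to cancellation near linearity
    imin = I0 * s3 * s3 / (2.0 * (s0 + amp))
    rho = min(abs(s3) / (s0 + amp), 1.0)
    degenerate = rho > DEGENERATE_RHO
    alpha_max = 0.0 if degenerate else math.degrees(math.atan2(s2, s1) / 2.0) % 180.0
    handedness = "right" if s3 > 0 else ("left" if s3 < 0 else None)
    return PolarizationState(
        Imax=imax,
        Imin=imin,
        alpha_max=alpha_max,
        rho=rho,
        degenerate_orientation=degenerate,
        handedness=handedness,
    )


def fit_malus(analyzer_angles, intensities) -> PolarizationState:
    """Recover the polarization ellipse from analyzer-sweep intensities.

    Fits ``I(a) = Imax cos^2(amax - a) + Imin sin^2(amax - a)`` by its exact
    Fourier form ``I(a) = c0 + c1 cos(2a) + s1 sin(2a)`` (an ordinary linear
    least-squares problem), then reads off ``Imax = c0 + sqrt(c1^2 + s1^2)``,
    ``Imin = c0 - sqrt(c1^2 + s1^2)`` and ``amax = atan2(s1, c1)/2``.  No
    initialization or iteration is needed.
    """
    ang = np.asarray(analyzer_angles, dtype=float)
    inten = np.asarray(intensities, dtype=float)
    if ang.shape != inten.shape or ang.ndim != 1:
        raise InsufficientDataError("angles and intensities must be equal-length 1-D")
    distinct = np.unique(np.round(ang % 180.0, 9))
    if distinct.size < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct analyzer angles, got {distinct.size}"
        )
    if distinct.max() - distinct.min() < 90.0 - 1e-9:
        raise InsufficientDataError("analyzer angles must span at least 90 degrees")
    a2 = np.deg2rad(2.0 * ang)
    design = np.column_stack([np.ones_like(a2), np.cos(a2), np.sin(a2)])
    coef, _, rank, _ = np.linalg.lstsq(design, inten, rcond=None)
    if rank < 3:
        raise InsufficientDataError("degenerate analyzer design (rank-deficient)")
    c0, c1, s1 = coef
    amp = math.hypot(c1, s1)
    imax = c0 + amp
    imin = max(c0 - amp, 0.0)
    if imax <= 0:
        raise ZeroFieldError("fitted intensity is not positive")
    rho = min(math.sqrt(imin / imax), 1.0)
    degenerate = rho > DEGENERATE_RHO
    alpha_max = 0.0 if degenerate else math.degrees(math.atan2(s1, c1) / 2.0) % 180.0
    return PolarizationState(
        Imax=float(imax),
        Imin=float(imin),
        alpha_max=float(alpha_max),
        rho=float(rho),
        degenerate_orientation=degenerate,
    )
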