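"""Six-parameter calibration fit of analyzer-sweep measurements.

The calibration protocol steps the QWP and HWP motors over a factorial grid
and, at each setting, records the power behind a rotating analyzer.  Every
row ``(phi', theta', alpha', I)`` is a sample of the forward model, and a
nonlinear least-squares fit over all rows estimates the six system
parameters ``(delta, gamma, phi0, theta0, alpha0, I0)`` jointly.

Identifiability
---------------
The intensity model is invariant under a discrete group of parameter
transformations, so the optimum is never unique.  Besides the obvious
periodicities (``phi0`` mod 180, ``theta0`` mod 90, ``alpha0`` mod 180,
from the waveplate/analyzer symmetries) the group has two nontrivial
generators, enumerated empirically on the simulator:

* ``(delta, phi0) -> (-delta, phi0 + 90)``
* the x/y relabelling ``(gamma, I0, phi0, theta0, alpha0) ->
  (1/gamma, gamma**2 I0, phi0 + 90, theta0 + 45, alpha0 + 90)``

Every fit is therefore mapped into the canonical cell
``delta in (-90, 90], gamma > 0, phi0 in [0, 180), theta0 in [0, 90),
alpha0 in [0, 180)`` by picking, over the four-element orbit, the
representative with lexicographically smallest ``(gamma, phi0, delta,
theta0, alpha0)``.  For instruments sitting exactly on a group boundary
(``gamma = 1``) the choice between equivalent representations can switch
under noise; all representatives predict identical intensities.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .polmodel import (
    InsufficientDataError,
    PolarizationState,
    SystemParameters,
    _field_components_arrays,
    fit_malus,
    polarization_state_analytic,
    FieldState,
)

__all__ = [
    "CalibrationDataset",
    "CalibrationResult",
    "EllipticityMap",
    "fit_calibration",
    "predict_intensity",
    "ellipticity_map",
    "canonicalize_parameters",
    "FitFailureError",
]

CSV_COLUMNS = ["qwp_deg", "hwp_deg", "analyzer_deg", "intensity"]


class FitFailureError(RuntimeError):
    """Raised when no restart converges; carries the best candidate found."""

    def __init__(self, message: str, best: "CalibrationResult | None" = None):
        super().__init__(message)
        self.best = best


class IdentifiabilityWarning(UserWarning):
    """Emitted when the Jacobian at the optimum is rank-deficient."""


@dataclass
class CalibrationDataset:
    """Measurement table of (QWP, HWP, analyzer) motor angles and intensity.

    Thin wrapper over a DataFrame with columns
    ``qwp_deg, hwp_deg, analyzer_deg, intensity``.
    """

    table: pd.DataFrame
    metadata: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in CSV_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"calibration table missing column(s): {missing}")
        t = self.table
        if len(t) == 0:
            raise InsufficientDataError("empty calibration dataset")
        if not np.all(np.isfinite(t[CSV_COLUMNS].to_numpy())):
            raise ValueError("non-finite values in calibration table")
        if (t["intensity"] < 0).any():
            raise ValueError("negative intensities in calibration table")

    def validate_design(self) -> None:
        """Check the grid is rich enough for the six-parameter fit.

        Six unknowns require variation in all three motor angles: at least
        six distinct (QWP, HWP) settings and four analyzer angles.
        """
        t = self.table
        n_settings = len(t[["qwp_deg", "hwp_deg"]].drop_duplicates())
        n_alpha = t["analyzer_deg"].round(9).nunique()
        if n_settings < 6 or n_alpha < 4:
            raise InsufficientDataError(
                f"need >= 6 waveplate settings and >= 4 analyzer angles, "
                f"got {n_settings} and {n_alpha}"
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def angles(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        t = self.table
        return (
            t["qwp_deg"].to_numpy(float),
            t["hwp_deg"].to_numpy(float),
            t["analyzer_deg"].to_numpy(float),
        )

    @property
    def intensity(self) -> np.ndarray:
        return self.table["intensity"].to_numpy(float)

    @classmethod
    def from_csv(cls, path) -> "CalibrationDataset":
        df = pd.read_csv(path)
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(
                f"calibration CSV {path} is missing column(s): {missing}; "
                f"expected header {','.join(CSV_COLUMNS)}"
            )
        return cls(df[CSV_COLUMNS].copy())

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, columns=CSV_COLUMNS)


@dataclass
class CalibrationResult:
    """Fitted system parameters with covariance and fit diagnostics.

    ``covariance`` is the 6x6 matrix over ``(delta, gamma, phi0, theta0,
    alpha0, I0)`` estimated as ``sigma^2 (J^T J)^-1`` with
    ``sigma^2 = RSS / (n - 6)``.
    """

    params: SystemParameters
    covariance: np.ndarray
    rms: float
    n_obs: int
    dof: int
    converged: bool
    n_iterations: int

    @property
    def std(self) -> np.ndarray:
        """Per-parameter standard deviations (sqrt of the covariance diagonal)."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))

    def to_json(self, path=None) -> str:
        p = self.params
        obj = {
            "params": {
                "delta_deg": p.delta,
                "gamma": p.gamma,
                "phi0_deg": p.phi0,
                "theta0_deg": p.theta0,
                "alpha0_deg": p.alpha0,
                "I0": p.I0,
            },
            "covariance": np.asarray(self.covariance).ravel().tolist(),
            "rms": self.rms,
            "n_obs": self.n_obs,
            "dof": self.dof,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
        }
        text = json.dumps(obj, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationResult":
        if isinstance(source, (str, Path)) and "\n" not in str(source):
            text = Path(source).read_text()
        else:
            text = str(source)
        obj = json.loads(text)
        p = obj["params"]
        params = SystemParameters(
            delta=p["delta_deg"],
            gamma=p["gamma"],
            phi0=p["phi0_deg"],
            theta0=p["theta0_deg"],
            alpha0=p["alpha0_deg"],
            I0=p["I0"],
        )
        cov = np.asarray(obj["covariance"], dtype=float).reshape(6, 6)
        return cls(
            params=params,
            covariance=cov,
            rms=obj["rms"],
            n_obs=obj["n_obs"],
            dof=obj.get("dof", obj["n_obs"] - 6),
            converged=obj.get("converged", True),
            n_iterations=obj.get("n_iterations", 0),
        )


def predict_intensity(params: SystemParameters, rows) -> np.ndarray:
    """Model intensity for rows of motor angles ``(phi', theta', alpha')``.

    ``rows`` may be an (n, 3) array-like or a tuple of three 1-D arrays.
    """
    if isinstance(rows, tuple):
        qwp, hwp, ana = (np.asarray(r, dtype=float) for r in rows)
    else:
        arr = np.asarray(rows, dtype=float).reshape(-1, 3)
        qwp, hwp, ana = arr[:, 0], arr[:, 1], arr[:, 2]
    d1, d2, d3, d4 = _field_components_arrays(params, qwp, hwp)
    a = np.deg2rad(ana - params.alpha0)
    ex2 = d1 * d1 + d2 * d2
    ey2 = d3 * d3 + d4 * d4
    cross = 2.0 * (d1 * d3 + d2 * d4)  # 2 Re(Ex Ey*)
    ca, sa = np.cos(a), np.sin(a)
    return params.I0 * (ex2 * ca * ca + ey2 * sa * sa + cross * sa * ca)


# --- canonicalization --------------------------------------------------------


def _orbit(params: SystemParameters) -> list[SystemParameters]:
    """The four orbit representatives of ``params`` under the invariance group."""
    d, g, p0, t0, a0, i0 = params.as_array()
    raw = [
        (d, g, p0, t0, a0, i0),
        (-d, g, p0 + 90.0, t0, a0, i0),  # delta sign flip
        (d, 1.0 / g, p0 + 90.0, t0 + 45.0, a0 + 90.0, g * g * i0),  # x/y swap
        (-d, 1.0 / g, p0 + 180.0, t0 + 45.0, a0 + 90.0, g * g * i0),
    ]
    out = []
    for dd, gg, pp, tt, aa, ii in raw:
        dd = (dd + 180.0) % 360.0 - 180.0  # (-180, 180]
        if dd == -180.0:
            dd = 180.0
        out.append(
            SystemParameters(
                delta=dd,
                gamma=gg,
                phi0=pp % 180.0,
                theta0=tt % 90.0,
                alpha0=aa % 180.0,
                I0=ii,
            )
        )
    return out


def canonicalize_parameters(params: SystemParameters) -> SystemParameters:
    """Map parameters into the canonical identifiability cell.

    Chooses, among the four physically equivalent representations, the one
    with lexicographically smallest ``(gamma, phi0, delta, theta0, alpha0)``
    restricted to ``delta in (-90, 90]`` where possible.
    """
    members = _orbit(params)
    in_cell = [m for m in members if -90.0 < m.delta <= 90.0]
    pool = in_cell if in_cell else members
    return min(pool, key=lambda m: (m.gamma, m.phi0, m.delta, m.theta0, m.alpha0))


_ANGLE_PERIODS = (360.0, None, 180.0, 90.0, 180.0, None)  # per parameter slot


def canonical_difference(a: SystemParameters, b: SystemParameters) -> np.ndarray:
    """Componentwise difference between two parameter sets modulo the
    invariance group (angles wrapped to their periods).

    Useful for comparing repeated calibrations of the same instrument:
    two fits that landed in different orbit representations still compare
    as equal.
    """
    va = canonicalize_parameters(a).as_array()
    vb = canonicalize_parameters(b).as_array()
    out = np.abs(va - vb)
    for k, period in enumerate(_ANGLE_PERIODS):
        if period is not None:
            d = out[k] % period
            out[k] = min(d, period - d)
    return out


# --- fitting -----------------------------------------------------------------

# coarse multi-start lattice over the angle offsets; gamma = 1, I0 = max(I)
_LAT_DELTA = (-67.5, -22.5, 22.5, 67.5)
_LAT_PHI0 = tuple(np.arange(0.0, 180.0, 22.5))
_LAT_THETA0 = (0.0, 22.5, 45.0, 67.5)
_LAT_ALPHA0 = tuple(np.arange(0.0, 180.0, 30.0))


def _start_candidates(data: CalibrationDataset) -> np.ndarray:
    i0 = float(np.max(data.intensity))
    grid = np.array(
        [
            (d, 1.0, p, t, a, i0)
            for d in _LAT_DELTA
            for p in _LAT_PHI0
            for t in _LAT_THETA0
            for a in _LAT_ALPHA0
        ]
    )
    return grid


def fit_calibration(
    data: CalibrationDataset,
    init: SystemParameters | None = None,
    *,
    n_starts: int = 10,
) -> CalibrationResult:
    """Estimate the six system parameters from a calibration grid.

    Without ``init`` the fit is multi-started: the residual cost is
    pre-screened on a coarse lattice of angle offsets (the model is
    multimodal in them) and Levenberg-Marquardt style trust-region
    refinement is run from the ``n_starts`` best lattice points; the lowest
    final cost wins.  The winning optimum is canonicalized and the
    covariance evaluated at the canonical point.
    """
    data.validate_design()
    qwp, hwp, ana = data.angles
    y = data.intensity
    n = len(y)
    rows = (qwp, hwp, ana)

    def residuals(v: np.ndarray) -> np.ndarray:
        p = SystemParameters(
            delta=v[0], gamma=abs(v[1]) + 1e-12, phi0=v[2], theta0=v[3],
            alpha0=v[4], I0=abs(v[5]) + 1e-300,
        )
        return predict_intensity(p, rows) - y

    if init is not None:
        starts = [init.as_array()]
    else:
        cand = _start_candidates(data)
        costs = np.array([float(residuals(v) @ residuals(v)) for v in cand])
        order = np.argsort(costs)[: max(n_starts, 1)]
        starts = [cand[i] for i in order]

    best = None
    total_nfev = 0
    for v0 in starts:
        try:
            res = least_squares(residuals, v0, method="trf", ftol=1e-10,
                                xtol=1e-12, gtol=1e-12, max_nfev=2000)
        except Exception:  # pragma: no cover - defensive
            continue
        total_nfev += res.nfev
        if best is None or res.cost < best.cost:
            best = res
        if best.cost < 1e-18 * max(1.0, float(y @ y)):
            break  # numerically exact fit; later starts cannot improve

    if best is None or not np.all(np.isfinite(best.x)):
        raise FitFailureError("calibration fit failed from every start", None)

    fitted = SystemParameters(
        delta=best.x[0], gamma=abs(best.x[1]), phi0=best.x[2],
        theta0=best.x[3], alpha0=best.x[4], I0=abs(best.x[5]),
    )
    params = canonicalize_parameters(fitted)

    # covariance at the canonical optimum (same cost; FD Jacobian of the model)
    rss = 2.0 * best.cost
    dof = max(n - 6, 1)
    sigma2 = rss / dof
    J = _model_jacobian(params, rows)
    JTJ = J.T @ J
    rank = np.linalg.matrix_rank(JTJ)
    if rank < 6:
        warnings.warn(
            "rank-deficient Jacobian at the optimum; parameters are not "
            "locally identifiable from this design",
            IdentifiabilityWarning,
            stacklevel=2,
        )
        cov = sigma2 * np.linalg.pinv(JTJ)
    else:
        cov = sigma2 * np.linalg.inv(JTJ)
    cov = (cov + cov.T) / 2.0

    result = CalibrationResult(
        params=params,
        covariance=cov,
        rms=float(np.sqrt(rss / n)),
        n_obs=n,
        dof=dof,
        converged=bool(best.success),
        n_iterations=int(total_nfev),
    )
    if not best.success:
        raise FitFailureError(
            f"calibration fit did not converge (status {best.status})", result
        )
    return result


def _model_jacobian(params: SystemParameters, rows) -> np.ndarray:
    """Central finite-difference Jacobian of the intensity model, n x 6."""
    v0 = params.as_array()
    steps = np.maximum(1e-6 * np.abs(v0), 1e-8)
    cols = []
    for k in range(6):
        vp, vm = v0.copy(), v0.copy()
        vp[k] += steps[k]
        vm[k] -= steps[k]
        ip = predict_intensity(SystemParameters.from_array(vp), rows)
        im = predict_intensity(SystemParameters.from_array(vm), rows)
        cols.append((ip - im) / (2.0 * steps[k]))
    return np.column_stack(cols)


# --- ellipticity maps --------------------------------------------------------


@dataclass
class EllipticityMap:
    """Polarization-ellipse summary on a (QWP, HWP) grid.

    2-D arrays are indexed ``[i_qwp, i_hwp]``.
    """

    qwp_deg: np.ndarray
    hwp_deg: np.ndarray
    rho: np.ndarray
    alpha_max: np.ndarray
    Imax: np.ndarray
    Imin: np.ndarray

    def state(self, i: int, j: int) -> PolarizationState:
        return PolarizationState(
            Imax=float(self.Imax[i, j]),
            Imin=float(self.Imin[i, j]),
            alpha_max=float(self.alpha_max[i, j]),
            rho=float(self.rho[i, j]),
        )


def ellipticity_map(
    source: SystemParameters | CalibrationDataset,
    qwp_grid=None,
    hwp_grid=None,
) -> EllipticityMap:
    """Map of ellipticity (and ellipse summary) over waveplate settings.

    With ``SystemParameters`` the map is model-predicted on the supplied
    grids (coarse 10-degree overview maps and fine 2-degree windows are
    both just grid choices).  With a ``CalibrationDataset`` each measured
    (QWP, HWP) cell is summarized by a Malus fit of its analyzer sweep and
    the grids are taken from the data.
    """
    if isinstance(source, SystemParameters):
        if qwp_grid is None or hwp_grid is None:
            raise ValueError("model-predicted map needs explicit qwp/hwp grids")
        qwp = np.asarray(qwp_grid, dtype=float)
        hwp = np.asarray(hwp_grid, dtype=float)
        if qwp.size == 0 or hwp.size == 0:
            raise ValueError("empty grid")
        QQ, TT = np.meshgrid(qwp, hwp, indexing="ij")
        d1, d2, d3, d4 = _field_components_arrays(source, QQ.ravel(), TT.ravel())
        shape = QQ.shape
        rho = np.empty(shape)
        amax = np.empty(shape)
        imax = np.empty(shape)
        imin = np.empty(shape)
        flat = [a.ravel() for a in (rho, amax, imax, imin)]
        for k in range(QQ.size):
            st = polarization_state_analytic(
                FieldState(d1[k], d2[k], d3[k], d4[k]), I0=source.I0
            )
            flat[0][k] = st.rho
            flat[1][k] = st.alpha_max
            flat[2][k] = st.Imax
            flat[3][k] = st.Imin
        return EllipticityMap(qwp, hwp, rho, amax, imax, imin)

    data = source
    t = data.table
    qwp = np.sort(t["qwp_deg"].unique())
    hwp = np.sort(t["hwp_deg"].unique())
    if qwp_grid is not None:
        qwp = np.asarray(qwp_grid, dtype=float)
    if hwp_grid is not None:
        hwp = np.asarray(hwp_grid, dtype=float)
    if qwp.size == 0 or hwp.size == 0:
        raise ValueError("empty grid")
    shape = (qwp.size, hwp.size)
    rho = np.full(shape, np.nan)
    amax = np.full(shape, np.nan)
    imax = np.full(shape, np.nan)
    imin = np.full(shape, np.nan)
    grouped = t.groupby(["qwp_deg", "hwp_deg"])
    for (q, h), cell in grouped:
        i = np.flatnonzero(np.isclose(qwp, q))
        j = np.flatnonzero(np.isclose(hwp, h))
        if i.size == 0 or j.size == 0:
            continue
        st = fit_malus(cell["analyzer_deg"].to_numpy(), cell["intensity"].to_numpy())
        rho[i[0], j[0]] = st.rho
        amax[i[0], j[0]] = st.alpha_max
        imax[i[0], j[0]] = st.Imax
        imin[i[0], j[0]] = st.Imin
    return EllipticityMap(qwp, hwp, rho, amax, imax, imin)
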