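"""Virtual microscope and virtual tissue with known ground truth.

Every analysis module in this package can be exercised without hardware:
the :class:`VirtualMicroscope` evaluates the same forward model the
calibration fit assumes — a system with true ``(delta, gamma, phi0,
theta0, alpha0, I0)`` — and adds measurement noise in the way the real
acquisition does (each tabulated intensity is the mean of ``n_samples``
noisy power-meter readings).  The :class:`VirtualTissue` holds per-pixel
ground-truth maps of the C6v tensor ratios and fiber angle, from which
polarization-resolved image stacks are rendered.

Rendered pixel intensities scale with the *square* of the excitation peak
intensity (SHG is a two-photon process), so a polarization-dependent
attenuation ``gamma != 1`` in the virtual microscope produces exactly the
power bias that the power-calibration factors are meant to remove.

All generators are deterministic under their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .calfit import CalibrationDataset, predict_intensity
from .polmodel import (
    SystemParameters,
    WaveplateSetting,
    field_components,
    polarization_state_analytic,
)
from .pshgfit import PSHGStack

__all__ = [
    "VirtualMicroscope",
    "VirtualTissue",
    "calibration_schedule",
    "acquire_calibration",
    "acquire_stack",
    "DEFAULT_QWP_GRID",
    "DEFAULT_HWP_GRID",
    "DEFAULT_ANALYZER_GRID",
]

# the coarse factorial calibration protocol: QWP 0-180 and HWP 0-90 in
# 10-degree increments, analyzer 0-180 in 30-degree increments (inclusive)
DEFAULT_QWP_GRID = np.arange(0.0, 180.0 + 1e-9, 10.0)  # 19 angles
DEFAULT_HWP_GRID = np.arange(0.0, 90.0 + 1e-9, 10.0)  # 10 angles
DEFAULT_ANALYZER_GRID = np.arange(0.0, 180.0 + 1e-9, 30.0)  # 7 angles


@dataclass
class VirtualMicroscope:
    """Simulated instrument with known true parameters and noise model.

    ``noise_sigma`` is the std of additive Gaussian noise on each raw
    power reading, as a fraction of ``I0``; ``jitter`` an optional
    multiplicative per-reading std; ``n_samples`` raw readings are
    averaged per tabulated measurement.
    """

    true_params: SystemParameters = dc_field(default_factory=SystemParameters)
    noise_sigma: float = 0.0
    jitter: float = 0.0
    n_samples: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0 or self.jitter < 0:
            raise ValueError("noise levels must be >= 0")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def calibration_schedule(
    qwp=None, hwp=None, analyzer=None
) -> pd.DataFrame:
    """Full factorial measurement schedule as a DataFrame of motor angles.

    Defaults reproduce the coarse protocol (19 x 10 x 7 = 1330 rows); pass
    explicit grids for fine windows (e.g. 2-degree steps around a
    candidate setting).
    """
    qwp = DEFAULT_QWP_GRID if qwp is None else np.asarray(qwp, dtype=float)
    hwp = DEFAULT_HWP_GRID if hwp is None else np.asarray(hwp, dtype=float)
    analyzer = (
        DEFAULT_ANALYZER_GRID if analyzer is None else np.asarray(analyzer, dtype=float)
    )
    if qwp.size == 0 or hwp.size == 0 or analyzer.size == 0:
        raise ValueError("empty angle range in calibration schedule")
    Q, H, A = np.meshgrid(qwp, hwp, analyzer, indexing="ij")
    return pd.DataFrame(
        {
            "qwp_deg": Q.ravel(),
            "hwp_deg": H.ravel(),
            "analyzer_deg": A.ravel(),
        }
    )


def acquire_calibration(
    vm: VirtualMicroscope, schedule: pd.DataFrame | None = None
) -> CalibrationDataset:
    """Simulate the calibration measurement loop over a schedule.

    Each row's intensity is the mean of ``vm.n_samples`` noisy draws of
    the model intensity at the true parameters.
    """
    if schedule is None:
        schedule = calibration_schedule()
    rows = (
        schedule["qwp_deg"].to_numpy(float),
        schedule["hwp_deg"].to_numpy(float),
        schedule["analyzer_deg"].to_numpy(float),
    )
    clean = predict_intensity(vm.true_params, rows)
    n = clean.size
    if vm.noise_sigma == 0.0 and vm.jitter == 0.0:
        measured = clean
    else:
        rng = vm.rng()
        draws = np.tile(clean[:, None], (1, vm.n_samples))
        if vm.jitter > 0:
            draws = draws * (1.0 + vm.jitter * rng.standard_normal(draws.shape))
        if vm.noise_sigma > 0:
            draws = draws + vm.noise_sigma * vm.true_params.I0 * rng.standard_normal(
                draws.shape
            )
        measured = draws.mean(axis=1)
    table = schedule.copy()
    table["intensity"] = np.clip(measured, 0.0, None)
    return CalibrationDataset(table, metadata={"seed": vm.seed, "n_samples": vm.n_samples})


@dataclass
class VirtualTissue:
    """Ground-truth maps of a cylindrically symmetric SHG source.

    ``ratio33`` and ``ratio15`` are chi33/chi31 and chi15/chi31 (> 0),
    ``fiber_angle_deg`` in [0, 180); ``brightness`` scales the rendered
    signal per pixel and ``background`` adds a constant offset.
    """

    ratio33: np.ndarray
    ratio15: np.ndarray
    fiber_angle_deg: np.ndarray
    brightness: np.ndarray | float = 100.0
    background: float = 0.0

    def __post_init__(self) -> None:
        self.ratio33 = np.asarray(self.ratio33, dtype=float)
        self.ratio15 = np.asarray(self.ratio15, dtype=float)
        self.fiber_angle_deg = np.asarray(self.fiber_angle_deg, dtype=float)
        if not (self.ratio33.shape == self.ratio15.shape == self.fiber_angle_deg.shape):
            raise ValueError("ground-truth maps must share one shape")
        if np.any(self.ratio33 <= 0) or np.any(self.ratio15 < 0):
            raise ValueError("tensor ratios must be positive")
        if np.any((self.fiber_angle_deg < 0) | (self.fiber_angle_deg >= 180)):
            raise ValueError("fiber angles must lie in [0, 180)")

    @classmethod
    def uniform(
        cls,
        shape: tuple[int, int],
        ratio33: float = 1.5,
        ratio15: float = 1.0,
        fiber_angle_deg: float = 30.0,
        brightness: float = 100.0,
        background: float = 0.0,
    ) -> "VirtualTissue":
        H, W = shape
        return cls(
            ratio33=np.full((H, W), ratio33),
            ratio15=np.full((H, W), ratio15),
            fiber_angle_deg=np.full((H, W), fiber_angle_deg),
            brightness=brightness,
            background=background,
        )

    @classmethod
    def blocks(
        cls,
        shape: tuple[int, int] = (64, 64),
        seed: int = 0,
        n_blocks: int = 4,
        brightness: float = 100.0,
        background: float = 0.0,
    ) -> "VirtualTissue":
        """Piecewise-constant random tissue: a grid of homogeneous patches."""
        rng = np.random.default_rng(seed)
        H, W = shape
        r33 = np.empty((H, W))
        r15 = np.empty((H, W))
        phi = np.empty((H, W))
        ys = np.array_split(np.arange(H), n_blocks)
        xs = np.array_split(np.arange(W), n_blocks)
        for yb in ys:
            for xb in xs:
                r33[np.ix_(yb, xb)] = rng.uniform(1.2, 2.2)
                r15[np.ix_(yb, xb)] = rng.uniform(0.5, 1.5)
                phi[np.ix_(yb, xb)] = rng.uniform(0.0, 180.0)
        return cls(r33, r15, phi, brightness=brightness, background=background)

    def response(self, alpha_deg: float) -> np.ndarray:
        """Normalized C6v polarization response at excitation angle ``alpha`` (degrees)."""
        ap = np.deg2rad(alpha_deg - self.fiber_angle_deg)
        sin2, cos2 = np.sin(ap) ** 2, np.cos(ap) ** 2
        return (sin2 + self.ratio33 * cos2) ** 2 + (
            self.ratio15 * np.sin(2.0 * ap)
        ) ** 2


def acquire_stack(
    vm: VirtualMicroscope,
    tissue: VirtualTissue,
    settings: list[WaveplateSetting],
    *,
    noise: str = "none",
    quantize_8bit: bool = False,
    set_label: str | np.ndarray | None = None,
    warn_elliptical: bool = True,
) -> PSHGStack:
    """Render a P-SHG image stack for a list of waveplate settings.

    Per frame the forward model gives the image-plane polarization; the
    pixel signal is ``brightness * (Imax / I0)^2 * response(alpha_max) +
    background`` plus optional noise (``'gaussian'`` uses
    ``vm.noise_sigma`` as a fraction of the local signal; ``'poisson'``
    draws counts at the signal mean).  ``quantize_8bit`` clips and rounds
    to uint8, creating genuinely saturated pixels.
    """
    if len(settings) == 0:
        raise ValueError("no waveplate settings supplied")
    import warnings

    rng = vm.rng()
    angles = np.empty(len(settings))
    frames = np.empty((len(settings),) + tissue.ratio33.shape, dtype=np.float64)
    for k, s in enumerate(settings):
        st = polarization_state_analytic(
            field_components(vm.true_params, s), I0=vm.true_params.I0
        )
        if warn_elliptical and st.rho >= 0.05:
            warnings.warn(
                f"setting {s} yields elliptical excitation (rho={st.rho:.3f}); "
                "the C6v linear-excitation model will be biased",
                stacklevel=2,
            )
        angles[k] = st.alpha_max
        rel_power = st.Imax / vm.true_params.I0
        signal = (
            np.asarray(tissue.brightness) * rel_power**2 * tissue.response(st.alpha_max)
            + tissue.background
        )
        if noise == "gaussian" and vm.noise_sigma > 0:
            signal = signal + vm.noise_sigma * signal * rng.standard_normal(signal.shape)
        elif noise == "poisson":
            signal = rng.poisson(np.clip(signal, 0.0, None)).astype(np.float64)
        elif noise not in ("none", "gaussian"):
            raise ValueError(f"unknown noise model: {noise!r}")
        frames[k] = signal
    if quantize_8bit:
        frames = np.clip(np.round(frames), 0, 255).astype(np.uint8)
    labels = None
    if set_label is not None:
        labels = (
            np.full(len(settings), set_label)
            if isinstance(set_label, str)
            else np.asarray(set_label)
        )
    return PSHGStack(
        frames=frames,
        angles_deg=angles,
        settings=list(settings),
        set_label=labels,
    )
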