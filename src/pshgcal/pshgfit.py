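"""Pixel-wise susceptibility-tensor-ratio analysis of P-SHG image series.

For collagen (and other C6v / cylindrically symmetric SHG sources) the SHG
intensity as a function of the excitation polarization angle ``alpha`` is

``I(alpha) ∝ (chi31 sin^2 a' + chi33 cos^2 a')^2 + (chi15 sin 2a')^2``

with ``a' = alpha - phi`` and ``phi`` the in-plane fiber angle.  This is a
five-term trigonometric polynomial ``a0 + a2 cos 2a + b2 sin 2a + a4 cos
4a + b4 sin 4a``, so each pixel is fitted by *linear* least squares on
that basis and the tensor ratios recovered from the harmonic amplitudes:
with ``c = (chi33 + chi31)/2``, ``d = (chi33 - chi31)/2``, ``e = chi15``
(all times the sqrt of an overall brightness factor),

* ``a0 = c^2 + d^2/2 + e^2/2``
* amplitude of the 2nd harmonic ``= 2 c d`` (phase ``2 phi``)
* amplitude of the 4th harmonic ``= d^2/2 - e^2/2`` (phase ``4 phi``)

Inverting these is a quadratic whose two roots are ``c^2`` and ``d^2``;
the assignment ``c >= d`` is the branch with ``chi33/chi31 >= 1`` (the
collagen case).  The intensity model cannot distinguish ``(R33, R15,
phi)`` from ``(1/R33, R15/R33, phi + 90)``, so the fit resolves the 90-
degree fiber-angle ambiguity by that convention; only ``chi15^2`` enters
the model, so the reported ``chi15/chi31`` is an absolute value.

Preprocessing follows the standard P-SHG recipe: a 3x3 averaging filter
per frame (reflect padding), exclusion of pixels saturated in any raw
frame, and exclusion of pixels whose across-frame mean smoothed intensity
falls below a gray-value threshold (default 10).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .polmodel import WaveplateSetting

__all__ = [
    "PSHGStack",
    "TensorRatioMap",
    "MASK_OK",
    "MASK_SATURATED",
    "MASK_LOW_INTENSITY",
    "MASK_FIT_FAILED",
    "preprocess",
    "fit_pixel",
    "fit_image",
    "difference_map",
]

MASK_OK = 0
MASK_SATURATED = 1
MASK_LOW_INTENSITY = 2
MASK_FIT_FAILED = 3

#: harmonic amplitude below this fraction of a0 counts as absent
_HARMONIC_FLOOR = 1e-9


@dataclass
class PSHGStack:
    """Polarization-resolved SHG image series.

    ``frames`` is (F, H, W); ``angles_deg`` gives the linear excitation
    polarization angle of each frame; ``settings`` the originating
    waveplate setting (optional, informational); ``set_label`` tags which
    of the two equivalent waveplate-solution sets produced each frame.
    """

    frames: np.ndarray
    angles_deg: np.ndarray
    settings: list[WaveplateSetting] | None = None
    set_label: np.ndarray | None = None
    pixel_size_um: float | None = None
    saturation_value: float | None = None  # dtype max if None and integer dtype

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be (F, H, W)")
        if self.frames.shape[0] != self.angles_deg.size:
            raise ValueError(
                f"{self.frames.shape[0]} frames but {self.angles_deg.size} angles"
            )
        if self.frames.shape[0] < 5:
            raise ValueError("need >= 5 frames (5 fitted coefficients)")
        span = self.angles_deg.max() - self.angles_deg.min()
        if span < 180.0 - 1e-9 and (self.angles_deg.size < 9 or span < 160.0):
            raise ValueError("polarization angles must span (close to) 180 degrees")

    @property
    def effective_saturation(self) -> float | None:
        if self.saturation_value is not None:
            return self.saturation_value
        if np.issubdtype(self.frames.dtype, np.integer):
            return float(np.iinfo(self.frames.dtype).max)
        return None

    def subset(self, indices) -> "PSHGStack":
        idx = np.asarray(indices)
        return PSHGStack(
            frames=self.frames[idx],
            angles_deg=self.angles_deg[idx],
            settings=[self.settings[i] for i in idx] if self.settings else None,
            set_label=self.set_label[idx] if self.set_label is not None else None,
            pixel_size_um=self.pixel_size_um,
            saturation_value=self.saturation_value,
        )


@dataclass
class TensorRatioMap:
    """Per-pixel tensor ratios, fiber angle and exclusion mask.

    ``mask`` uses reason codes 0 ok / 1 saturated / 2 low intensity /
    3 fit failed; masked pixels hold NaN in the value maps.
    """

    ratio33: np.ndarray
    ratio15: np.ndarray
    fiber_angle: np.ndarray
    mask: np.ndarray
    residual: np.ndarray | None = None

    @property
    def valid(self) -> np.ndarray:
        return self.mask == MASK_OK


def preprocess(
    stack: PSHGStack,
    low_thresh: float = 10.0,
    saturation_value: float | None = None,
) -> tuple[PSHGStack, np.ndarray]:
    """Smooth frames and build the exclusion mask.

    Applies a 3x3 mean filter per frame (reflect padding).  A pixel is
    masked ``saturated`` if any *raw* frame reaches the saturation value
    (dtype max for integer stacks unless overridden) and ``low_intensity``
    if the across-frame mean of the smoothed stack is below ``low_thresh``.
    Saturation takes precedence in the reason code.
    """
    frames = stack.frames
    if frames.shape[1] < 3 or frames.shape[2] < 3:
        raise ValueError("frames must be at least 3x3 for the averaging filter")
    sat = saturation_value
    if sat is None:
        sat = stack.effective_saturation
    smoothed = np.empty(frames.shape, dtype=np.float64)
    for k in range(frames.shape[0]):
        smoothed[k] = uniform_filter(
            frames[k].astype(np.float64), size=3, mode="reflect"
        )
    mask = np.zeros(frames.shape[1:], dtype=np.uint8)
    mean_img = smoothed.mean(axis=0)
    mask[mean_img < low_thresh] = MASK_LOW_INTENSITY
    if sat is not None:
        mask[(frames >= sat).any(axis=0)] = MASK_SATURATED
    out = PSHGStack(
        frames=smoothed,
        angles_deg=stack.angles_deg,
        settings=stack.settings,
        set_label=stack.set_label,
        pixel_size_um=stack.pixel_size_um,
        saturation_value=stack.saturation_value,
    )
    return out, mask


def _harmonic_design(angles_deg: np.ndarray) -> np.ndarray:
    a = np.deg2rad(angles_deg)
    return np.column_stack(
        [np.ones_like(a), np.cos(2 * a), np.sin(2 * a), np.cos(4 * a), np.sin(4 * a)]
    )


def _invert_harmonics(a0: float, s2: float, s4: float):
    """Recover (ratio33, ratio15) from rotated harmonic amplitudes.

    ``s2 >= 0`` is the signed 2nd-harmonic amplitude along the fitted fiber
    phase, ``s4`` the signed 4th-harmonic amplitude.  Returns None when the
    amplitudes are inconsistent with the intensity model (negative
    discriminant or negative squared coefficients).
    """
    # roots of v^2 - (a0 + s4) v + s2^2/4 = 0 are {c^2, d^2} (times brightness)
    b = a0 + s4
    disc = b * b - s2 * s2
    if disc < -1e-12 * max(a0 * a0, 1.0):
        return None
    disc = max(disc, 0.0)
    root = math.sqrt(disc)
    v_small = (b - root) / 2.0  # d^2
    v_large = (b + root) / 2.0  # c^2
    w = v_small - 2.0 * s4  # e^2
    if v_large <= 0 or v_small < -1e-12 or w < -1e-9 * max(a0, 1.0):
        return None
    c = math.sqrt(v_large)
    d = math.sqrt(max(v_small, 0.0))
    e = math.sqrt(max(w, 0.0))
    chi31 = c - d
    if chi31 <= 0:
        return None
    return (c + d) / chi31, e / chi31


def fit_pixel(intensities, angles_deg):
    """Tensor ratios and fiber angle from one pixel's polarization response.

    Returns ``(ratio33, ratio15, fiber_angle_deg, residual_rms)`` or raises
    ``ValueError`` for degenerate (isotropic / model-inconsistent) input.
    """
    y = np.asarray(intensities, dtype=float)
    ang = np.asarray(angles_deg, dtype=float)
    if y.size != ang.size or y.size < 5:
        raise ValueError("need >= 5 matched intensities and angles")
    X = _harmonic_design(ang)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 5:
        raise ValueError("angle design is rank-deficient for a 5-term harmonic fit")
    res = float(np.sqrt(np.mean((X @ coef - y) ** 2)))
    out = _ratios_from_coefficients(coef)
    if out is None:
        raise ValueError("harmonic amplitudes inconsistent with the tensor model")
    r33, r15, phi = out
    return r33, r15, phi, res


def _ratios_from_coefficients(coef):
    a0, a2, b2, a4, b4 = (float(v) for v in coef)
    amp2 = math.hypot(a2, b2)
    amp4 = math.hypot(a4, b4)
    if a0 <= 0 or max(amp2, amp4) <= _HARMONIC_FLOOR * max(a0, 1e-300):
        return None  # isotropic: no orientation information
    if amp2 > _HARMONIC_FLOOR * a0:
        phi = math.degrees(math.atan2(b2, a2) / 2.0) % 180.0
    else:
        # chi33 ~ chi31: orientation only defined modulo 90 from the 4th harmonic
        phi = math.degrees(math.atan2(b4, a4) / 4.0) % 180.0
    c4 = math.cos(math.radians(4.0 * phi))
    s4v = math.sin(math.radians(4.0 * phi))
    s2 = amp2
    s4 = a4 * c4 + b4 * s4v
    ratios = _invert_harmonics(a0, s2, s4)
    if ratios is None:
        return None
    return ratios[0], ratios[1], phi


def fit_image(
    stack: PSHGStack,
    mask: np.ndarray | None = None,
    low_thresh: float = 10.0,
    *,
    preprocessed: bool = False,
) -> TensorRatioMap:
    """Pixel-wise tensor-ratio fit over a (preprocessed) stack.

    If ``preprocessed`` is False the stack is smoothed and masked first.
    The per-pixel linear solves are batched with a single pseudoinverse
    (the design depends only on the shared angle list), so a 512x512 stack
    fits in well under a minute.
    """
    if not preprocessed:
        stack, mask = preprocess(stack, low_thresh=low_thresh)
    if mask is None:
        mask = np.zeros(stack.frames.shape[1:], dtype=np.uint8)
    mask = mask.astype(np.uint8).copy()
    F, H, W = stack.frames.shape
    X = _harmonic_design(stack.angles_deg)
    pinv = np.linalg.pinv(X)
    flat = stack.frames.reshape(F, -1).astype(np.float64)
    coefs = pinv @ flat  # (5, H*W)
    resid = np.sqrt(np.mean((X @ coefs - flat) ** 2, axis=0)).reshape(H, W)

    ratio33 = np.full((H, W), np.nan)
    ratio15 = np.full((H, W), np.nan)
    fiber = np.full((H, W), np.nan)
    todo = np.flatnonzero(mask.ravel() == MASK_OK)
    r33f, r15f, phif = ratio33.ravel(), ratio15.ravel(), fiber.ravel()
    maskf = mask.ravel()
    for idx in todo:
        out = _ratios_from_coefficients(coefs[:, idx])
        if out is None:
            maskf[idx] = MASK_FIT_FAILED
            continue
        r33f[idx], r15f[idx], phif[idx] = out
    mask = maskf.reshape(H, W)
    if not np.any(mask == MASK_OK):
        import warnings

        warnings.warn("all pixels masked; tensor-ratio map is empty", stacklevel=2)
    bad = mask != MASK_OK
    resid[bad] = np.nan
    return TensorRatioMap(
        ratio33=ratio33, ratio15=ratio15, fiber_angle=fiber, mask=mask, residual=resid
    )


def difference_map(a: TensorRatioMap, b: TensorRatioMap) -> TensorRatioMap:
    """Elementwise ``a - b`` on jointly unmasked pixels.

    Fiber-angle differences are wrapped to (-90, 90] (orientations are
    defined modulo 180).  The output mask is 0 where both inputs are valid
    and the maximum of the two reason codes elsewhere.
    """
    if a.ratio33.shape != b.ratio33.shape:
        raise ValueError("difference_map requires equal-shaped maps")
    joint = a.valid & b.valid
    mask = np.where(joint, MASK_OK, np.maximum(a.mask, b.mask)).astype(np.uint8)
    d33 = np.where(joint, a.ratio33 - b.ratio33, np.nan)
    d15 = np.where(joint, a.ratio15 - b.ratio15, np.nan)
    dphi = a.fiber_angle - b.fiber_angle
    dphi = -((-dphi + 90.0) % 180.0 - 90.0)  # wrap to (-90, 90]
    dphi = np.where(joint, dphi, np.nan)
    return TensorRatioMap(ratio33=d33, ratio15=d15, fiber_angle=dphi, mask=mask)
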