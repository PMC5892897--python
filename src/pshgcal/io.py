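"""File formats: calibration CSV, result JSON, TIFF stacks with sidecar tables.

On-disk conventions
-------------------
* Calibration measurements: CSV with header
  ``qwp_deg,hwp_deg,analyzer_deg,intensity`` (UTF-8, '.' decimal).
* Calibration result: JSON with the six parameters, the row-major 6x6
  covariance, RMS residual and observation count.
* P-SHG series: multi-frame grayscale TIFF plus a sidecar CSV
  ``frame,angle_deg,qwp_deg,hwp_deg,set_label`` with one row per frame.
* Result maps: 32-bit float single-channel TIFFs (ratio33, ratio15,
  fiber_angle) and an 8-bit mask TIFF with reason codes 0/1/2/3.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .polmodel import WaveplateSetting
from .pshgfit import PSHGStack, TensorRatioMap

__all__ = [
    "read_stack",
    "write_stack",
    "write_maps",
    "read_maps",
    "SIDECAR_COLUMNS",
]

SIDECAR_COLUMNS = ["frame", "angle_deg", "qwp_deg", "hwp_deg", "set_label"]


def write_stack(stack: PSHGStack, tiff_path, sidecar_path=None) -> None:
    """Write a P-SHG stack as a multi-frame TIFF with a sidecar angle table."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".csv")
    tifffile.imwrite(tiff_path, np.asarray(stack.frames))
    n = stack.frames.shape[0]
    settings = stack.settings or [WaveplateSetting(np.nan, np.nan)] * n
    labels = stack.set_label if stack.set_label is not None else [""] * n
    pd.DataFrame(
        {
            "frame": np.arange(n),
            "angle_deg": stack.angles_deg,
            "qwp_deg": [s.phi_prime for s in settings],
            "hwp_deg": [s.theta_prime for s in settings],
            "set_label": list(labels),
        }
    ).to_csv(sidecar_path, index=False)


def read_stack(tiff_path, sidecar_path=None) -> PSHGStack:
    """Read a multi-frame TIFF and its sidecar CSV into a :class:`PSHGStack`."""
    tiff_path = Path(tiff_path)
    if sidecar_path is None:
        sidecar_path = tiff_path.with_suffix(".csv")
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = pd.read_csv(sidecar_path)
    missing = [c for c in ("frame", "angle_deg") if c not in sidecar.columns]
    if missing:
        raise ValueError(f"sidecar {sidecar_path} missing column(s): {missing}")
    if len(sidecar) != frames.shape[0]:
        raise ValueError(
            f"sidecar has {len(sidecar)} rows but TIFF has {frames.shape[0]} frames"
        )
    sidecar = sidecar.sort_values("frame")
    settings = None
    if "qwp_deg" in sidecar.columns and "hwp_deg" in sidecar.columns:
        settings = [
            WaveplateSetting(float(q), float(h))
            for q, h in zip(sidecar["qwp_deg"], sidecar["hwp_deg"])
        ]
    labels = None
    if "set_label" in sidecar.columns and sidecar["set_label"].notna().any():
        labels = sidecar["set_label"].astype(str).to_numpy()
    return PSHGStack(
        frames=frames,
        angles_deg=sidecar["angle_deg"].to_numpy(float),
        settings=settings,
        set_label=labels,
    )


def write_maps(result: TensorRatioMap, out_dir, prefix: str = "") -> dict[str, Path]:
    """Write tensor-ratio maps as float32 TIFFs and the mask as uint8 TIFF."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in (
        ("ratio33", result.ratio33),
        ("ratio15", result.ratio15),
        ("fiber_angle", result.fiber_angle),
    ):
        p = out / f"{prefix}{name}.tiff"
        tifffile.imwrite(p, np.asarray(arr, dtype=np.float32))
        paths[name] = p
    p = out / f"{prefix}mask.tiff"
    tifffile.imwrite(p, np.asarray(result.mask, dtype=np.uint8))
    paths["mask"] = p
    return paths


def read_maps(out_dir, prefix: str = "") -> TensorRatioMap:
    out = Path(out_dir)
    return TensorRatioMap(
        ratio33=tifffile.imread(out / f"{prefix}ratio33.tiff"),
        ratio15=tifffile.imread(out / f"{prefix}ratio15.tiff"),
        fiber_angle=tifffile.imread(out / f"{prefix}fiber_angle.tiff"),
        mask=tifffile.imread(out / f"{prefix}mask.tiff"),
    )
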