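"""Pseudocolor rendering of ratio images.

The ratio is mapped to hue within a calibration range pinned by the maximal
redox excursions achievable in vivo (fully reduced anchor R_min, fully
oxidised anchor R_max): blue (240°) at R ≤ R_min through to red (0°) at
R ≥ R_max, saturation 1.  The HSV Value channel carries the overall
intensity (800 nm + 900 nm), normalised by percentile clipping, so dim
voxels stay dark whatever their ratio.  Invalid-ratio voxels render gray
(saturation 0) at their intensity.  Pure visualisation: nothing here feeds
back into quantitative outputs.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .config import CalibrationRange
from .ratiometry import RatioImage


def render_pseudocolor(
    ratio: RatioImage,
    intensity: np.ndarray,
    calib: Optional[CalibrationRange] = None,
    intensity_percentile: float = 99.5,
) -> np.ndarray:
    """Render an 8-bit RGB pseudocolor image (shape = input shape + (3,)).

    ``intensity`` is typically the summed-channel image; it is normalised to
    [0, 1] by clipping at its ``intensity_percentile``-th percentile.
    """
    calib = calib or ratio.calibration
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != ratio.values.shape:
        raise ValueError(
            f"intensity shape {intensity.shape} != ratio shape {ratio.values.shape}"
        )
    ceiling = np.percentile(intensity, intensity_percentile)
    if ceiling <= 0:
        ceiling = max(float(intensity.max()), 1.0)
    value = np.clip(intensity / ceiling, 0.0, 1.0)

    t = (np.nan_to_num(ratio.values, nan=calib.r_min) - calib.r_min) / (
        calib.r_max - calib.r_min
    )
    t = np.clip(t, 0.0, 1.0)
    hue = (240.0 / 360.0) * (1.0 - t)  # 240° blue (reduced) → 0° red (oxidised)
    sat = np.where(ratio.valid, 1.0, 0.0)  # invalid voxels: gray at their Value

    hsv = np.stack([hue, sat, value], axis=-1)
    rgb = hsv_to_rgb(hsv)
    return np.round(rgb * 255.0).astype(np.uint8)


def render_slice(
    ratio: RatioImage,
    intensity: np.ndarray,
    z: int,
    calib: Optional[CalibrationRange] = None,
    intensity_percentile: float = 99.5,
) -> np.ndarray:
    """Figure-style 2-D panel from a single z-slice (the default display mode)."""
    sliced = RatioImage(
        values=ratio.values[z], valid=ratio.valid[z], calibration=ratio.calibration
    )
    return render_pseudocolor(sliced, intensity[z], calib, intensity_percentile)


def render_projection(
    ratio: RatioImage,
    intensity: np.ndarray,
    calib: Optional[CalibrationRange] = None,
    intensity_percentile: float = 99.5,
) -> np.ndarray:
    """Maximum-intensity projection panel: ratio taken from the brightest
    valid voxel along z at each (y, x)."""
    masked = np.where(ratio.valid, intensity, -np.inf)
    zbest = masked.argmax(axis=0)
    iy, ix = np.indices(zbest.shape)
    proj_vals = ratio.values[zbest, iy, ix]
    proj_valid = ratio.valid[zbest, iy, ix]
    proj_int = intensity.max(axis=0)
    sliced = RatioImage(values=proj_vals, valid=proj_valid, calibration=ratio.calibration)
    return render_pseudocolor(sliced, proj_int, calib, intensity_percentile)
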