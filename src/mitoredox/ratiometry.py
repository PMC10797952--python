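"""Ratio 800/900 quantification: per-object sum ratios, per-pixel ratio
images, per-stack summaries, paired ΔR/R0 analysis and ratio histograms.

The per-object estimator is the *sum ratio*: Σ(ch800 − bg800)⁺ / Σ(ch900 −
bg900)⁺ over the segmented footprint, with per-voxel clipping at zero
before summation.  Summing before dividing pools photons, so the estimator
is far less noisy than averaging per-pixel ratios, and it is exactly
scale-invariant (multiplying both channels by any c > 0 changes nothing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import CalibrationRange
from .stacks import TwoChannelStack

#: paired-response rule: a z-stack "responds" when ΔR/R0 is at least this (%)
RESPONDER_THRESHOLD_PCT = 25.0


@dataclass
class RatioImage:
    """Per-voxel Ratio 800/900 with a validity mask.

    Voxels whose background-corrected 900-nm signal falls below the
    intensity floor are invalid (ratio undefined there).
    """

    values: np.ndarray
    valid: np.ndarray
    calibration: CalibrationRange = field(default_factory=CalibrationRange)

    def __post_init__(self) -> None:
        if self.values.shape != self.valid.shape:
            raise ValueError("ratio and validity shapes differ")

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid]


@dataclass
class StackSummary:
    """Per-stack aggregate of valid objects (unweighted by object size)."""

    stack_id: str
    mean_ratio: Optional[float]
    n_objects: int
    compartment_means: dict[str, float] = field(default_factory=dict)
    compartment_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class PairedMeasurement:
    """Basal vs post-treatment per-stack ratios and their relative change.

    delta_pct = 100 × (R_after − R_basal) / R_basal; the responder flag is
    inclusive at +25%.
    """

    stack_id: str
    r_basal: float
    r_after: float
    delta_pct: float = field(init=False)
    responder: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.r_basal <= 0:
            raise ValueError("R_basal must be positive")
        self.delta_pct = 100.0 * (self.r_after - self.r_basal) / self.r_basal
        self.responder = self.delta_pct >= RESPONDER_THRESHOLD_PCT


@dataclass
class HistogramResult:
    """Normalized ratio frequency distribution.

    ``frequencies`` cover the given bins; values falling outside the edges
    are reported in the open-ended ``under``/``over`` fractions.  All
    fractions sum to 1.
    """

    bin_edges: np.ndarray
    frequencies: np.ndarray
    under: float
    over: float
    n: int


def object_ratio(
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray],
    stack: TwoChannelStack,
    background,
) -> tuple[float, float, float]:
    """Sum-ratio over a footprint: returns (ratio, sum800, sum900).

    ``background`` is a :class:`~mitoredox.segmentation.Background`.  Ratio is
    NaN when the corrected 900-nm sum is nonpositive (caller should exclude
    and log such objects rather than crash).
    """
    zz, yy, xx = voxels
    if len(zz) == 0:
        raise ValueError("footprint is empty")
    c800 = stack.ch800[zz, yy, xx].astype(float) - background.bg800[zz]
    c900 = stack.ch900[zz, yy, xx].astype(float) - background.bg900[zz]
    s800 = float(np.clip(c800, 0, None).sum())
    s900 = float(np.clip(c900, 0, None).sum())
    ratio = s800 / s900 if s900 > 0 else math.nan
    return ratio, s800, s900


def ratio_image(
    stack: TwoChannelStack,
    background,
    intensity_floor: Optional[float] = None,
    calibration: CalibrationRange = CalibrationRange(),
) -> RatioImage:
    """Per-voxel division of background-corrected channels.

    Voxels with corrected 900-nm signal below ``intensity_floor`` are
    invalid.  The default floor is twice the background shot-noise SD
    (√bg900 per slice), so near-background voxels never produce ratios.
    """
    b800 = background.bg800[:, None, None]
    b900 = background.bg900[:, None, None]
    c800 = stack.ch800.astype(float) - b800
    c900 = stack.ch900.astype(float) - b900
    if intensity_floor is None:
        floor = 2.0 * np.sqrt(np.maximum(background.bg900, 0.0))[:, None, None]
    else:
        if intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        floor = np.full((stack.shape[0], 1, 1), float(intensity_floor))
    valid = c900 >= np.maximum(floor, np.finfo(float).tiny)
    values = np.full(stack.shape, math.nan)
    np.divide(np.clip(c800, 0, None), c900, out=values, where=valid)
    valid = valid & np.isfinite(values) & (values > 0)
    values[~valid] = math.nan
    return RatioImage(values=values, valid=valid, calibration=calibration)


def stack_summary(objects: Sequence, stack_id: str = "") -> StackSummary:
    """Unweighted mean ratio over valid objects, plus per-compartment means."""
    valid = [o for o in objects if getattr(o, "valid", True) and np.isfinite(o.ratio)]
    if not valid:
        return StackSummary(stack_id=stack_id, mean_ratio=None, n_objects=0)
    ratios = np.array([o.ratio for o in valid])
    comp_means: dict[str, float] = {}
    comp_counts: dict[str, int] = {}
    for comp in ("soma", "neurite"):
        sel = [o.ratio for o in valid if o.compartment == comp]
        if sel:
            comp_means[comp] = float(np.mean(sel))
            comp_counts[comp] = len(sel)
    return StackSummary(
        stack_id=stack_id,
        mean_ratio=float(ratios.mean()),
        n_objects=len(valid),
        compartment_means=comp_means,
        compartment_counts=comp_counts,
    )


def delta_r(before: StackSummary, after: StackSummary) -> PairedMeasurement:
    """ΔR/R0 between two summaries of the same field of view."""
    if before.n_objects == 0 or after.n_objects == 0:
        raise ValueError("both summaries must contain valid objects")
    if before.stack_id != after.stack_id:
        raise ValueError(
            f"paired summaries from different stacks: "
            f"{before.stack_id!r} vs {after.stack_id!r}"
        )
    return PairedMeasurement(
        stack_id=before.stack_id,
        r_basal=before.mean_ratio,
        r_after=after.mean_ratio,
    )


def ratio_histogram(ratios, bin_edges) -> HistogramResult:
    """Frequency distribution of ratios over given bin edges (sums to 1)."""
    ratios = np.asarray(ratios, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if ratios.size == 0:
        raise ValueError("need at least one ratio value")
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    counts, _ = np.histogram(ratios, bins=edges)
    under = int((ratios < edges[0]).sum())
    over = int((ratios > edges[-1]).sum())
    n = ratios.size
    return HistogramResult(
        bin_edges=edges,
        frequencies=counts / n,
        under=under / n,
        over=over / n,
        n=n,
    )


def objects_to_table(
    objects: Sequence,
    metadata: Optional[dict] = None,
    distances: Optional[dict[int, Optional[float]]] = None,
) -> pd.DataFrame:
    """Build MeasurementTable rows (one per valid object) from MitoObjects."""
    metadata = metadata or {}
    rows = []
    for o in objects:
        if not (getattr(o, "valid", True) and np.isfinite(o.ratio)):
            continue
        rows.append(
            {
                "subject_id": metadata.get("subject_id", ""),
                "stack_id": metadata.get("stack_id", ""),
                "object_id": o.object_id,
                "compartment": o.compartment,
                "ratio": o.ratio,
                "sum800": o.sum800,
                "sum900": o.sum900,
                "volume_voxels": o.volume_voxels,
                "centroid_z_um": o.centroid_um[0],
                "centroid_y_um": o.centroid_um[1],
                "centroid_x_um": o.centroid_um[2],
                "distance_um": distances.get(o.object_id) if distances else np.nan,
                "condition": metadata.get("condition", ""),
                "timepoint": metadata.get("timepoint", ""),
            }
        )
    from .io import TABLE_COLUMNS

    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
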