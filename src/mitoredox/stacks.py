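"""In-memory containers for voxel data.

Axis order is (C, Z, Y, X) for multi-channel data and (Z, Y, X) for single
volumes, everywhere in the package.  Indices are 0-based; the physical
position of voxel (k, i, j) is (k, i, j) × spacing (voxel centres), in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

CHANNEL_NAMES = ("ch800", "ch900")


@dataclass
class TwoChannelStack:
    """A two-excitation-channel voxel volume with physical spacing metadata.

    ``ch800`` and ``ch900`` hold nonnegative photon counts of shape
    (n_slices, px, px); ``ch_plaque`` is an optional plaque-label channel.
    ``spacing`` is (z_step_um, pitch_um, pitch_um).
    """

    ch800: np.ndarray
    ch900: np.ndarray
    spacing: tuple[float, float, float]
    ch_plaque: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch800 = np.asarray(self.ch800)
        self.ch900 = np.asarray(self.ch900)
        if self.ch800.shape != self.ch900.shape:
            raise ValueError(
                f"channel shapes differ: {self.ch800.shape} vs {self.ch900.shape}"
            )
        if self.ch800.ndim != 3:
            raise ValueError("channels must be 3-D (Z, Y, X)")
        if self.ch_plaque is not None:
            self.ch_plaque = np.asarray(self.ch_plaque)
            if self.ch_plaque.shape != self.ch800.shape:
                raise ValueError("plaque channel shape differs from data channels")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values (z, y, x) in µm")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ch800.shape

    @property
    def n_channels(self) -> int:
        return 2 if self.ch_plaque is None else 3

    def channels(self) -> np.ndarray:
        """Stack all channels into a (C, Z, Y, X) array."""
        chans = [self.ch800, self.ch900]
        if self.ch_plaque is not None:
            chans.append(self.ch_plaque)
        return np.stack(chans, axis=0)


@dataclass
class LabelImage:
    """Integer label volume: 0 = background, k ≥ 1 = object k (contiguous labels)."""

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def n_objects(self) -> int:
        return int(self.labels.max(initial=0))


def relabel_contiguous(labels: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Relabel an arbitrary nonnegative label volume to {0..K}.

    Returns the relabelled volume and the old→new mapping (background excluded).
    Order of new labels follows sorted old labels.
    """
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    mapping = {int(old): new for new, old in enumerate(present, start=1)}
    if not mapping:
        return labels.astype(np.int32, copy=True), {}
    lut = np.zeros(int(present.max()) + 1, dtype=np.int32)
    for old, new in mapping.items():
        lut[old] = new
    return lut[labels], mapping
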