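"""Reading and writing stacks, masks, measurement tables and configs.

Stacks are multi-page TIFF in (C, Z, Y, X) order with a JSON metadata block
(``pixel_size_um``, ``z_step_um``, ``channel_names``) in the ImageDescription
tag.  Tables are CSV with a fixed, documented column order; configs are YAML.
All round trips are lossless: voxel data bit-exactly, metadata to float
precision.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import (
    ConfigError,
    GeneratorConfig,
    SegmentationParams,
    dict_to_generator_config,
    dict_to_segmentation_params,
    generator_config_to_dict,
)
from .stacks import CHANNEL_NAMES, LabelImage, TwoChannelStack, relabel_contiguous

logger = logging.getLogger("mitoredox")

DEFAULT_PIXEL_SIZE_UM = 127.0 / 512.0  # default acquisition: 127 µm over 512 px
DEFAULT_Z_STEP_UM = 2.0

#: fixed MeasurementTable column order
TABLE_COLUMNS = [
    "subject_id",
    "stack_id",
    "object_id",
    "compartment",
    "ratio",
    "sum800",
    "sum900",
    "volume_voxels",
    "centroid_z_um",
    "centroid_y_um",
    "centroid_x_um",
    "distance_um",
    "condition",
    "timepoint",
]


class StackIOError(IOError):
    """Raised for unreadable or structurally invalid image files."""


# ------------------------------------------------------------------- stacks


def write_stack(stack: TwoChannelStack, path: Union[str, Path]) -> None:
    """Write a stack as multi-page TIFF, axis order (C, Z, Y, X)."""
    data = stack.channels()
    meta = {
        "shape_czyx": list(data.shape),
        "pixel_size_um": stack.spacing[1],
        "z_step_um": stack.spacing[0],
        "channel_names": list(CHANNEL_NAMES) + (
            ["ch_plaque"] if stack.ch_plaque is not None else []
        ),
        "metadata": {k: v for k, v in stack.metadata.items() if _jsonable(v)},
    }
    tifffile.imwrite(
        str(path),
        data,
        photometric="minisblack",
        description=json.dumps(meta),
        metadata=None,
    )


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def _read_tiff_with_description(path: Union[str, Path]) -> tuple[np.ndarray, dict]:
    path = Path(path)
    if not path.exists():
        raise StackIOError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(str(path)) as tf:
            data = tf.asarray()
            desc = tf.pages[0].description
    except (tifffile.TiffFileError, ValueError) as exc:
        raise StackIOError(f"corrupt or unreadable TIFF: {path}: {exc}") from exc
    meta: dict = {}
    if desc:
        try:
            parsed = json.loads(desc)
            if isinstance(parsed, dict):
                meta = parsed
        except json.JSONDecodeError:
            pass
    return data, meta


def read_stack(path: Union[str, Path]) -> TwoChannelStack:
    """Read a two- or three-channel stack; missing metadata falls back to the
    default acquisition geometry (127/512 µm pitch, 2 µm z-step) with a warning.
    """
    data, meta = _read_tiff_with_description(path)
    if "shape_czyx" in meta:  # pages back into (C, Z, Y, X)
        data = data.reshape(meta["shape_czyx"])
    if data.ndim == 3:  # single-channel file: not a valid two-channel stack
        raise StackIOError(
            f"{path}: expected >= 2 channels in (C, Z, Y, X) order, "
            f"got a 3-D volume (1 channel)"
        )
    if data.ndim != 4 or data.shape[0] < 2:
        raise StackIOError(
            f"{path}: expected >= 2 channels in (C, Z, Y, X) order, got shape {data.shape}"
        )
    if "pixel_size_um" in meta and "z_step_um" in meta:
        pitch = float(meta["pixel_size_um"])
        z_step = float(meta["z_step_um"])
    else:
        pitch, z_step = DEFAULT_PIXEL_SIZE_UM, DEFAULT_Z_STEP_UM
        warnings.warn(
            f"{path}: missing voxel-size metadata; assuming defaults "
            f"pixel_size_um={pitch:.4f}, z_step_um={z_step}",
            stacklevel=2,
        )
        logger.warning("%s: missing voxel-size metadata, defaults applied", path)
    ch_plaque = data[2] if data.shape[0] >= 3 else None
    return TwoChannelStack(
        ch800=data[0],
        ch900=data[1],
        ch_plaque=ch_plaque,
        spacing=(z_step, pitch, pitch),
        metadata=dict(meta.get("metadata", {})),
    )


# -------------------------------------------------------------------- masks


def write_mask(mask: LabelImage, path: Union[str, Path]) -> None:
    meta = {"pixel_size_um": mask.spacing[1], "z_step_um": mask.spacing[0]}
    tifffile.imwrite(
        str(path),
        mask.labels.astype(np.int32),
        photometric="minisblack",
        description=json.dumps(meta),
        metadata=None,
    )


def read_mask(path: Union[str, Path]) -> LabelImage:
    """Read a label image; non-contiguous labels are relabelled to {0..K} and
    the mapping is logged."""
    data, meta = _read_tiff_with_description(path)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise StackIOError(f"{path}: expected a 2-D or 3-D label image, got {data.shape}")
    if data.min() < 0:
        raise StackIOError(f"{path}: negative labels are not allowed")
    relabelled, mapping = relabel_contiguous(data)
    if any(old != new for old, new in mapping.items()):
        logger.info("%s: relabelled to contiguous ids: %s", path, mapping)
    pitch = float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM))
    z_step = float(meta.get("z_step_um", DEFAULT_Z_STEP_UM))
    return LabelImage(labels=relabelled, spacing=(z_step, pitch, pitch))


# ------------------------------------------------------------------- tables


def write_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a MeasurementTable as CSV with the fixed column order."""
    out = table.copy()
    for col in TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    extra = [c for c in out.columns if c not in TABLE_COLUMNS]
    out[TABLE_COLUMNS + extra].to_csv(path, index=False)


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise StackIOError(f"{path}: missing measurement-table columns: {missing}")
    return df


# ------------------------------------------------------------------- config


def save_config(config: Union[GeneratorConfig, SegmentationParams, dict],
                path: Union[str, Path]) -> None:
    if isinstance(config, GeneratorConfig):
        payload = {"generator": generator_config_to_dict(config)}
    elif isinstance(config, SegmentationParams):
        from dataclasses import asdict

        payload = {"segmentation": asdict(config)}
    else:
        payload = dict(config)
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_config(path: Union[str, Path]):
    """Load a YAML config.  A top-level ``generator`` block yields a
    GeneratorConfig, ``segmentation`` a SegmentationParams; unknown keys are
    rejected with a :class:`~mitoredox.config.ConfigError`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known_blocks = {"generator", "segmentation"}
    unknown = set(raw) - known_blocks
    if unknown:
        raise ConfigError(f"{path}: unknown config blocks: {sorted(unknown)}")
    out = {}
    if "generator" in raw:
        out["generator"] = dict_to_generator_config(raw["generator"] or {})
    if "segmentation" in raw:
        out["segmentation"] = dict_to_segmentation_params(raw["segmentation"] or {})
    if len(out) == 1:
        return next(iter(out.values()))
    return out
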