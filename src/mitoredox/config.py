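"""Parameter containers for the simulator, the segmentation stage and full runs.

All physical quantities are micrometres (µm); photon parameters are expected
counts per voxel.  Every container validates itself on construction and can be
round-tripped through YAML (:func:`mitoredox.io.load_config`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Optional, Sequence


class ConfigError(ValueError):
    """Raised when a configuration value or key is invalid."""


@dataclass(frozen=True)
class GradientModel:
    """Plaque-proximity redox model: R(d) = r_far + (r_near - r_far)·exp(-d/lambda_um).

    ``r_near`` is the true ratio at the plaque edge (d = 0), ``r_far`` the
    asymptotic ratio far from any plaque, ``lambda_um`` the decay length.
    """

    r_near: float = 1.6
    r_far: float = 1.0
    lambda_um: float = 20.0

    def __post_init__(self) -> None:
        if self.r_near <= 0 or self.r_far <= 0:
            raise ConfigError("gradient ratios must be positive")
        if self.lambda_um <= 0:
            raise ConfigError("gradient lambda_um must be positive")

    def ratio_at(self, distance_um):
        import numpy as np

        d = np.asarray(distance_um, dtype=float)
        return self.r_far + (self.r_near - self.r_far) * np.exp(-d / self.lambda_um)


@dataclass(frozen=True)
class Plaque:
    """A spherical amyloid-beta deposit: centre in µm (z, y, x) and radius in µm."""

    center_um: tuple[float, float, float]
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ConfigError("plaque radius_um must be positive")
        if len(self.center_um) != 3:
            raise ConfigError("plaque center_um must be (z, y, x)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Forward-model parameters for synthetic two-channel z-stacks.

    Defaults emulate the in vivo acquisition geometry: a 127 µm × 127 µm field
    sampled at 512 × 512 pixels (pitch ≈ 0.248 µm), 2 µm z-steps, with bright
    punctate/tubular mitochondria on a dim background and Poisson photon noise.
    """

    fov_um: float = 127.0
    px: int = 512
    n_slices: int = 20
    z_step_um: float = 2.0
    photon_budget: float = 400.0
    background: tuple[float, float] = (20.0, 20.0)  # (ch800, ch900)
    psf_sigma_um: float = 0.3  # lateral Gaussian blur; 0 disables
    n_neurite_objects: int = 70
    n_soma_objects: int = 30
    ratio_mean: float = 1.06
    ratio_sd: float = 0.15
    gradient: Optional[GradientModel] = None
    plaques: tuple[Plaque, ...] = ()
    seed: int = 0
    poisson_noise: bool = True
    # scene geometry (µm); chosen to emulate ~1 µm mitochondria and ~10 µm somas
    neurite_length_um: tuple[float, float] = (1.0, 4.0)
    neurite_width_um: float = 0.75
    soma_radius_um: float = 5.0
    soma_mito_radius_um: float = 0.55
    mito_per_soma: int = 10
    min_separation_um: float = 2.5
    plaque_peak: float = 300.0
    plaque_background: float = 5.0

    def __post_init__(self) -> None:
        if self.fov_um <= 0 or self.px <= 0 or self.n_slices <= 0:
            raise ConfigError("fov_um, px and n_slices must be positive")
        if self.z_step_um <= 0:
            raise ConfigError("z_step_um must be positive")
        if self.photon_budget < 0:
            raise ConfigError("photon_budget must be nonnegative")
        if len(self.background) != 2 or any(b < 0 for b in self.background):
            raise ConfigError("background must be two nonnegative values (ch800, ch900)")
        if self.psf_sigma_um < 0:
            raise ConfigError("psf_sigma_um must be nonnegative")
        if self.n_neurite_objects < 0 or self.n_soma_objects < 0:
            raise ConfigError("object counts must be nonnegative")
        if self.ratio_mean <= 0:
            raise ConfigError("ratio_mean must be positive")
        if self.ratio_sd < 0:
            raise ConfigError("ratio_sd must be nonnegative")
        if self.plaque_peak < 0 or self.plaque_background < 0:
            raise ConfigError("plaque photon parameters must be nonnegative")
        lo, hi = self.neurite_length_um
        if not (0 < lo <= hi):
            raise ConfigError("neurite_length_um must be an increasing positive range")
        # normalise container types so configs hash/compare predictably
        object.__setattr__(self, "background", tuple(float(b) for b in self.background))
        object.__setattr__(self, "plaques", tuple(self.plaques))

    @property
    def pitch_um(self) -> float:
        """Lateral pixel size: field edge length / pixels per edge."""
        return self.fov_um / self.px

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing (z, y, x) in µm."""
        return (self.z_step_um, self.pitch_um, self.pitch_um)

    def replace(self, **kwargs) -> "GeneratorConfig":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class SegmentationParams:
    """Adaptive-threshold segmentation parameters.

    ``window_um`` is the local-mean neighbourhood width; ``offset`` is the
    threshold offset in units of the background-noise standard deviation.
    Size limits are in pixels (per connected unit); at the default 0.248 µm
    pitch, 8 px ≈ 0.49 µm² and 1500 px ≈ 92 µm².
    """

    window_um: float = 4.0
    offset: float = 2.0
    connectivity: str = "2d8"  # or "3d26"
    min_area_px: int = 8
    max_area_px: int = 1500
    soma_area_um2: float = 50.0

    def __post_init__(self) -> None:
        if not (0 < self.min_area_px < self.max_area_px):
            raise ConfigError("need 0 < min_area_px < max_area_px")
        if self.connectivity not in ("2d8", "3d26"):
            raise ConfigError("connectivity must be '2d8' or '3d26'")
        if self.window_um <= 0:
            raise ConfigError("window_um must be positive")

    def validate_for_pitch(self, pitch_um: float) -> None:
        if self.window_um <= 2 * pitch_um:
            raise ConfigError(
                f"window_um={self.window_um} must exceed twice the pixel pitch "
                f"({pitch_um:.4f} µm)"
            )

    def replace(self, **kwargs) -> "SegmentationParams":
        from dataclasses import replace

        return replace(self, **kwargs)


@dataclass(frozen=True)
class CalibrationRange:
    """Pseudocolor calibration anchors.

    The colour range is pinned to the maximal redox excursions achievable
    in vivo with the reductant DTT and the oxidant DTDP; the defaults
    [1.0, 1.6] bracket the printed basal (1.06) and oxidised (1.55) means.
    """

    r_min: float = 1.0
    r_max: float = 1.6

    def __post_init__(self) -> None:
        if not (0 < self.r_min < self.r_max):
            raise ConfigError("need 0 < r_min < r_max")


def _known_fields(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def dict_to_generator_config(d: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a plain dict, rejecting unknown keys."""
    d = dict(d)
    unknown = set(d) - _known_fields(GeneratorConfig)
    if unknown:
        raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
    if "gradient" in d and d["gradient"] is not None and not isinstance(d["gradient"], GradientModel):
        g = dict(d["gradient"])
        bad = set(g) - _known_fields(GradientModel)
        if bad:
            raise ConfigError(f"unknown gradient keys: {sorted(bad)}")
        d["gradient"] = GradientModel(**g)
    if "plaques" in d and d["plaques"]:
        plaques = []
        for p in d["plaques"]:
            if isinstance(p, Plaque):
                plaques.append(p)
            else:
                p = dict(p)
                bad = set(p) - _known_fields(Plaque)
                if bad:
                    raise ConfigError(f"unknown plaque keys: {sorted(bad)}")
                plaques.append(Plaque(tuple(p["center_um"]), p["radius_um"]))
        d["plaques"] = tuple(plaques)
    if "background" in d:
        d["background"] = tuple(d["background"])
    if "neurite_length_um" in d:
        d["neurite_length_um"] = tuple(d["neurite_length_um"])
    return GeneratorConfig(**d)


def dict_to_segmentation_params(d: dict) -> SegmentationParams:
    d = dict(d)
    unknown = set(d) - _known_fields(SegmentationParams)
    if unknown:
        raise ConfigError(f"unknown segmentation config keys: {sorted(unknown)}")
    return SegmentationParams(**d)


def generator_config_to_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["background"] = list(cfg.background)
    d["neurite_length_um"] = list(cfg.neurite_length_um)
    d["plaques"] = [
        {"center_um": list(p.center_um), "radius_um": p.radius_um} for p in cfg.plaques
    ]
    if cfg.gradient is not None:
        d["gradient"] = asdict(cfg.gradient)
    return d
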