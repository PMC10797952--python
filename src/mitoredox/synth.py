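"""Synthetic two-photon two-channel z-stacks with known ground truth.

The forward model ties a per-object true redox ratio R to the two excitation
channels so that the ratio is exactly invertible in the noise-free limit:

    E[ch800] = B · R/(1+R) + b800        E[ch900] = B/(1+R) + b900

with B the photon budget per object voxel.  Total object brightness
(B · R/(1+R) + B/(1+R) = B) is independent of R, so detection carries no
ratio bias and the background-corrected sum-ratio over any footprint equals
R.  An optional lateral Gaussian PSF is applied to the noise-free
expectation (optics first), then per-voxel Poisson noise (shot noise last).

Scenes emulate intravital cortical fields: short tubular mitochondria in
neurites, round mitochondria clustered in disc-shaped soma regions, optional
spherical amyloid plaques, and an optional plaque-proximity redox gradient
R(d) = r_far + (r_near − r_far)·exp(−d/λ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .config import ConfigError, GeneratorConfig
from .stacks import TwoChannelStack


class PlacementError(RuntimeError):
    """Requested objects cannot be placed in the field without overlap."""


def derive_seed(master: int, *keys: int) -> int:
    """Deterministic child seed from a master seed (fixed integer arithmetic, < 2^31)."""
    h = int(master) % 2_147_483_647
    for k in keys:
        h = (h * 1_000_003 + int(k) * 7_919 + 0x9E3779B1) % 2_147_483_647
    return h


@dataclass(frozen=True)
class TrueObject:
    """Ground truth for one mitochondrion."""

    object_id: int
    compartment: str  # "soma" | "neurite"
    voxels: tuple[np.ndarray, np.ndarray, np.ndarray]  # (z, y, x) index arrays
    centroid_um: tuple[float, float, float]
    true_ratio: float
    distance_um: float  # centroid to nearest plaque edge; inf if no plaques

    @property
    def n_voxels(self) -> int:
        return len(self.voxels[0])


@dataclass
class SceneTruth:
    """Generator ground truth: object geometry, true ratios, plaque geometry."""

    objects: list[TrueObject]
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    plaque_mask_truth: Optional[np.ndarray]  # bool (Z, Y, X) or None
    requested_counts: tuple[int, int]  # (neurite, soma)
    seed: int

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def true_ratios(self) -> np.ndarray:
        return np.array([o.true_ratio for o in self.objects])

    @property
    def distances(self) -> np.ndarray:
        return np.array([o.distance_um for o in self.objects])

    def label_volume(self) -> np.ndarray:
        """Truth label image: object_id at each footprint voxel."""
        lab = np.zeros(self.shape, dtype=np.int32)
        for o in self.objects:
            lab[o.voxels] = o.object_id
        return lab

    def scaled(self, fold: float) -> "SceneTruth":
        """Same geometry with every true ratio multiplied by ``fold``."""
        objs = [replace(o, true_ratio=o.true_ratio * fold) for o in self.objects]
        return SceneTruth(
            objs, self.shape, self.spacing, self.plaque_mask_truth,
            self.requested_counts, self.seed,
        )


# ---------------------------------------------------------------- footprints


def _disk_pixels(cy: float, cx: float, radius_px: float) -> tuple[np.ndarray, np.ndarray]:
    r = int(math.ceil(radius_px)) + 1
    y0, x0 = int(round(cy)), int(round(cx))
    yy, xx = np.mgrid[y0 - r : y0 + r + 1, x0 - r : x0 + r + 1]
    keep = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius_px**2
    return yy[keep], xx[keep]


def _capsule_pixels(
    cy: float, cx: float, angle: float, length_px: float, width_px: float
) -> tuple[np.ndarray, np.ndarray]:
    """Pixels within width/2 of a segment of given length centred on (cy, cx)."""
    half = length_px / 2.0
    dy, dx = math.sin(angle), math.cos(angle)
    r = int(math.ceil(half + width_px)) + 1
    y0, x0 = int(round(cy)), int(round(cx))
    yy, xx = np.mgrid[y0 - r : y0 + r + 1, x0 - r : x0 + r + 1]
    py, px_ = yy - cy, xx - cx
    t = np.clip(py * dy + px_ * dx, -half, half)
    d2 = (py - t * dy) ** 2 + (px_ - t * dx) ** 2
    keep = d2 <= (width_px / 2.0) ** 2
    return yy[keep], xx[keep]


def _plaque_truth_mask(config: GeneratorConfig) -> Optional[np.ndarray]:
    if not config.plaques:
        return None
    nz, ny, nx = config.n_slices, config.px, config.px
    sz, sy, sx = config.spacing
    zz = np.arange(nz)[:, None, None] * sz
    yy = np.arange(ny)[None, :, None] * sy
    xx = np.arange(nx)[None, None, :] * sx
    mask = np.zeros((nz, ny, nx), dtype=bool)
    for p in config.plaques:
        cz, cy, cx = p.center_um
        mask |= (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= p.radius_um**2
    return mask


def _plaque_edge_distance_analytic(centroid_um, config: GeneratorConfig) -> float:
    if not config.plaques:
        return math.inf
    cz, cy, cx = centroid_um
    best = math.inf
    for p in config.plaques:
        pz, py, px_ = p.center_um
        d = math.sqrt((cz - pz) ** 2 + (cy - py) ** 2 + (cx - px_) ** 2) - p.radius_um
        best = min(best, max(0.0, d))
    return best


# ---------------------------------------------------------------- build_scene


def build_scene(config: GeneratorConfig) -> SceneTruth:
    """Place mitochondria (and plaques) and draw their true redox ratios.

    Deterministic for a fixed ``config.seed``.  Object placement rejects
    overlaps — including a clearance margin of ``min_separation_um`` — so
    connected-component counts have unambiguous ground truth.  If placement
    repeatedly fails and the requested footprint area is a large fraction of
    the field, a :class:`PlacementError` names the realized count; minor
    shortfalls are reported with a warning instead.
    """
    rng = np.random.default_rng(derive_seed(config.seed, 0))
    pitch = config.pitch_um
    nz, ny, nx = config.n_slices, config.px, config.px
    margin_px = max(2, int(math.ceil(config.min_separation_um / pitch)))

    forbidden = np.zeros((nz, ny, nx), dtype=bool)
    plaque_mask = _plaque_truth_mask(config)
    if plaque_mask is not None:
        # keep objects clear of plaques (they are extracellular deposits)
        forbidden |= plaque_mask

    def mark(z: int, ys: np.ndarray, xs: np.ndarray) -> None:
        y0 = max(0, ys.min() - margin_px)
        y1 = min(ny, ys.max() + margin_px + 1)
        x0 = max(0, xs.min() - margin_px)
        x1 = min(nx, xs.max() + margin_px + 1)
        forbidden[z, y0:y1, x0:x1] = True

    def admissible(z: int, ys: np.ndarray, xs: np.ndarray) -> bool:
        if (
            ys.min() < margin_px
            or xs.min() < margin_px
            or ys.max() >= ny - margin_px
            or xs.max() >= nx - margin_px
        ):
            return False
        return not forbidden[z, ys, xs].any()

    # crude capacity check for the hard-failure path
    mean_len = sum(config.neurite_length_um) / 2.0
    neurite_area = (mean_len / pitch) * (config.neurite_width_um / pitch)
    soma_area = math.pi * (config.soma_radius_um / pitch) ** 2
    n_somas = (
        0
        if config.n_soma_objects == 0
        else max(1, math.ceil(config.n_soma_objects / config.mito_per_soma))
    )
    requested_area = (
        config.n_neurite_objects * (neurite_area + (2 * margin_px) ** 2)
        + n_somas * (soma_area + (2 * margin_px) ** 2)
    )
    capacity = nz * ny * nx

    max_attempts = 400
    placed: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []

    def fail(kind: str) -> None:
        realized = len(placed)
        msg = (
            f"placement of {kind} objects failed after {max_attempts} attempts; "
            f"realized count {realized}"
        )
        if requested_area > 0.5 * capacity:
            raise PlacementError(msg)
        warnings.warn(msg, stacklevel=3)

    # somas first: disc-shaped regions, each seeded with round mitochondria
    soma_regions: list[tuple[int, float, float]] = []
    soma_r_px = config.soma_radius_um / pitch
    for _ in range(n_somas):
        for _attempt in range(max_attempts):
            z = int(rng.integers(0, nz))
            cy = rng.uniform(margin_px + soma_r_px, ny - margin_px - soma_r_px)
            cx = rng.uniform(margin_px + soma_r_px, nx - margin_px - soma_r_px)
            ys, xs = _disk_pixels(cy, cx, soma_r_px)
            if admissible(z, ys, xs):
                soma_regions.append((z, cy, cx))
                mark(z, ys, xs)
                break
        else:
            fail("soma-region")
            break

    mito_r_px = config.soma_mito_radius_um / pitch
    intra_sep_px = 2 * mito_r_px + 0.6 / pitch  # keep intra-soma gaps resolvable
    n_soma_placed = 0
    for si, (z, scy, scx) in enumerate(soma_regions):
        quota = min(
            config.mito_per_soma, config.n_soma_objects - n_soma_placed
        )
        centres: list[tuple[float, float]] = []
        attempts = 0
        while len(centres) < quota and attempts < max_attempts:
            attempts += 1
            rad = (soma_r_px - mito_r_px - 1) * math.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * math.pi)
            cy, cx = scy + rad * math.sin(ang), scx + rad * math.cos(ang)
            if all(
                (cy - oy) ** 2 + (cx - ox) ** 2 >= intra_sep_px**2
                for oy, ox in centres
            ):
                centres.append((cy, cx))
        for cy, cx in centres:
            ys, xs = _disk_pixels(cy, cx, mito_r_px)
            zs = np.full(len(ys), z)
            placed.append(("soma", zs, ys, xs))
            n_soma_placed += 1
    if n_soma_placed < config.n_soma_objects and n_somas > 0:
        fail("soma-mitochondrion")

    # tubular neurite mitochondria
    lo, hi = config.neurite_length_um
    for _ in range(config.n_neurite_objects):
        for _attempt in range(max_attempts):
            z = int(rng.integers(0, nz))
            cy = rng.uniform(margin_px, ny - margin_px)
            cx = rng.uniform(margin_px, nx - margin_px)
            ang = rng.uniform(0, math.pi)
            length = rng.uniform(lo, hi) / pitch
            ys, xs = _capsule_pixels(cy, cx, ang, length, config.neurite_width_um / pitch)
            if admissible(z, ys, xs):
                zs = np.full(len(ys), z)
                placed.append(("neurite", zs, ys, xs))
                mark(z, ys, xs)
                break
        else:
            fail("neurite")
            break

    # true ratios: plaque-distance law in gradient mode, else truncated normal
    sz, sy, sx = config.spacing
    objects: list[TrueObject] = []
    for oid, (compartment, zs, ys, xs) in enumerate(placed, start=1):
        centroid = (float(zs.mean() * sz), float(ys.mean() * sy), float(xs.mean() * sx))
        d = _plaque_edge_distance_analytic(centroid, config)
        if config.gradient is not None:
            r_true = float(config.gradient.ratio_at(d))
        else:
            r_true = 0.0
            while r_true <= 0:
                r_true = float(rng.normal(config.ratio_mean, config.ratio_sd))
        objects.append(
            TrueObject(oid, compartment, (zs, ys, xs), centroid, r_true, d)
        )

    return SceneTruth(
        objects=objects,
        shape=(nz, ny, nx),
        spacing=config.spacing,
        plaque_mask_truth=plaque_mask,
        requested_counts=(config.n_neurite_objects, config.n_soma_objects),
        seed=config.seed,
    )


# --------------------------------------------------------------- render_stack


def render_stack(
    scene: SceneTruth,
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> TwoChannelStack:
    """Render a scene into a two-channel stack: expectation → PSF → Poisson noise."""
    if scene.shape != (config.n_slices, config.px, config.px):
        raise ConfigError("scene shape does not match config geometry")
    if rng is None:
        rng = np.random.default_rng(derive_seed(config.seed, 101))

    b800, b900 = config.background
    B = config.photon_budget
    sig800 = np.zeros(scene.shape, dtype=float)
    sig900 = np.zeros(scene.shape, dtype=float)
    for o in scene.objects:
        R = o.true_ratio
        sig800[o.voxels] = B * R / (1.0 + R)
        sig900[o.voxels] = B / (1.0 + R)

    sigma_px = config.psf_sigma_um / config.pitch_um if config.psf_sigma_um > 0 else 0.0
    if sigma_px > 0:  # lateral blur only: 2 µm z-steps undersample the axial PSF
        sig800 = gaussian_filter(sig800, sigma=(0, sigma_px, sigma_px))
        sig900 = gaussian_filter(sig900, sigma=(0, sigma_px, sigma_px))

    exp800 = sig800 + b800
    exp900 = sig900 + b900

    ch_plaque = None
    if scene.plaque_mask_truth is not None:
        expp = config.plaque_background + config.plaque_peak * scene.plaque_mask_truth
        if sigma_px > 0:
            expp = gaussian_filter(expp, sigma=(0, sigma_px, sigma_px))
        ch_plaque = rng.poisson(expp) if config.poisson_noise else expp

    if config.poisson_noise:
        ch800 = rng.poisson(exp800)
        ch900 = rng.poisson(exp900)
    else:
        ch800, ch900 = exp800, exp900

    return TwoChannelStack(
        ch800=ch800,
        ch900=ch900,
        ch_plaque=ch_plaque,
        spacing=config.spacing,
        metadata={"seed": config.seed},
    )


def generate_paired(
    scene: SceneTruth, fold: float, config: GeneratorConfig
) -> tuple[TwoChannelStack, TwoChannelStack]:
    """Before/after stacks of the same field with a multiplicative ratio change.

    Every after-timepoint true ratio equals ``fold`` × the before-timepoint
    ratio; footprints are identical; noise draws are independent.
    """
    if not fold > 0:
        raise ConfigError("fold must be positive")
    before = render_stack(
        scene, config, rng=np.random.default_rng(derive_seed(config.seed, 102))
    )
    after = render_stack(
        scene.scaled(fold),
        config,
        rng=np.random.default_rng(derive_seed(config.seed, 103)),
    )
    before.metadata["timepoint"] = "before"
    after.metadata["timepoint"] = "after"
    return before, after


def generate_cohort(
    config: GeneratorConfig,
    n_stacks: int,
    condition: str = "basal",
    stacks_per_subject: int = 6,
) -> list[tuple[TwoChannelStack, SceneTruth]]:
    """Independent stacks with per-stack seeds derived from the master seed.

    ``stacks_per_subject`` mimics acquiring several cortical volumes per
    mouse; condition and ids are stamped into stack metadata.
    """
    if n_stacks < 0:
        raise ConfigError("n_stacks must be nonnegative")
    out: list[tuple[TwoChannelStack, SceneTruth]] = []
    for i in range(n_stacks):
        cfg_i = config.replace(seed=derive_seed(config.seed, 1000 + i))
        scene = build_scene(cfg_i)
        stack = render_stack(scene, cfg_i)
        stack.metadata.update(
            condition=condition,
            stack_id=f"{condition}_stk{i:03d}",
            subject_id=f"{condition}_m{i // max(1, stacks_per_subject):02d}",
            timepoint="single",
        )
        out.append((stack, scene))
    return out
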