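"""Randomized paired thorax phantoms (with / without bone).

A phantom is a 3-D map of linear attenuation coefficients (1/cm) built from
analytic shapes: a body ellipsoid, two lung ellipsoids, a spherical lung
tumor, a spine cylinder with periodic vertebral bulges, and per-side rib
arcs modelled as partial elliptical tori. The "bone off" member of a pair
replaces every bone voxel with soft-tissue attenuation, so the two volumes
are voxel-identical everywhere outside the bone mask — the property that
makes bone suppression measurable against an exact ground truth.

Coordinates are in mm with the origin at the grid center; axis order is
(z, y, x) with z the cranio-caudal axis, y the posteroanterior (ray) axis
and x the left-right axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, GeometryError

__all__ = [
    "PhantomParams",
    "PhantomVolume",
    "PhantomPair",
    "NoiseConfig",
    "default_population",
    "sample_phantom_params",
    "build_phantom_pair",
    "add_imaging_noise",
    "lung_centers",
]

#: default linear attenuation coefficients, 1/cm, giving bone/soft contrast
#: comparable to a chest radiograph
DEFAULT_ATTENUATION = {"lung": 0.05, "soft": 0.20, "tumor": 0.25, "bone": 0.50}


@dataclass(frozen=True)
class PhantomParams:
    """Full parameterization of one phantom subject.

    Lengths are mm except ``voxel_size`` (cm, isotropic); attenuations 1/cm.
    ``tumor_center`` is relative to the grid center.
    """

    seed: int
    body_half_axes: tuple[float, float, float]  # (z, y, x) mm
    lung_half_axes: tuple[float, float, float]  # (z, y, x) mm, per lung
    rib_count: int  # per side
    rib_thickness: float  # mm
    rib_spacing: float  # mm, cranio-caudal
    spine_radius: float  # mm
    tumor_center: tuple[float, float, float]  # (z, y, x) mm
    tumor_radius: float  # mm
    attenuation_soft: float = DEFAULT_ATTENUATION["soft"]
    attenuation_bone: float = DEFAULT_ATTENUATION["bone"]
    attenuation_lung: float = DEFAULT_ATTENUATION["lung"]
    attenuation_tumor: float = DEFAULT_ATTENUATION["tumor"]
    lung_texture_amp: float = 0.04  # 1/cm, vessel-like parenchymal variation
    voxel_size: float = 0.03  # cm
    grid_shape: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self) -> None:
        if not (
            self.attenuation_bone
            > self.attenuation_tumor
            >= self.attenuation_soft
            > self.attenuation_lung
            >= 0.0
        ):
            raise ConfigurationError(
                "attenuations must satisfy bone > tumor >= soft > lung >= 0; got "
                f"bone={self.attenuation_bone}, tumor={self.attenuation_tumor}, "
                f"soft={self.attenuation_soft}, lung={self.attenuation_lung}"
            )
        if self.voxel_size <= 0:
            raise ConfigurationError("voxel_size must be positive")
        if any(n <= 0 for n in self.grid_shape):
            raise ConfigurationError("grid_shape entries must be positive")
        if self.rib_count < 0:
            raise ConfigurationError("rib_count must be >= 0")
        if self.rib_thickness <= 0 or self.rib_spacing <= 0:
            raise ConfigurationError("rib_thickness and rib_spacing must be positive")
        if self.spine_radius < 0:
            raise ConfigurationError("spine_radius must be >= 0")
        if self.tumor_radius <= 0:
            raise ConfigurationError("tumor_radius must be positive")
        if self.lung_texture_amp < 0:
            raise ConfigurationError("lung_texture_amp must be >= 0")
        _check_tumor_in_lung(self)


@dataclass
class PhantomVolume:
    """A rasterized phantom: attenuation voxels plus tissue label masks."""

    voxels: np.ndarray  # (nz, ny, nx) float, 1/cm
    voxel_size: float  # cm
    bone_mask: np.ndarray
    lung_mask: np.ndarray
    tumor_mask: np.ndarray
    params: PhantomParams

    def validate(self) -> None:
        for name in ("bone_mask", "lung_mask", "tumor_mask"):
            m = getattr(self, name)
            if m.shape != self.voxels.shape:
                raise GeometryError(f"{name} shape {m.shape} != voxels {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise GeometryError("voxels must be finite and non-negative")
        if np.any(self.bone_mask & self.tumor_mask):
            raise GeometryError("bone_mask and tumor_mask overlap")


@dataclass
class PhantomPair:
    """The same subject rasterized with bone present / bone replaced by soft tissue."""

    with_bone: PhantomVolume
    without_bone: PhantomVolume


@dataclass(frozen=True)
class NoiseConfig:
    """Quantum (Poisson) + electronic (additive Gaussian) noise in the 8-bit domain.

    ``poisson_scale`` is the photon count corresponding to one gray level;
    ``None`` (or ``inf``) disables the Poisson component. ``gaussian_sd`` is
    in gray levels; 0 disables it.
    """

    poisson_scale: float | None = 1.75
    gaussian_sd: float = 4.5

    def __post_init__(self) -> None:
        if self.poisson_scale is not None and self.poisson_scale <= 0:
            raise ConfigurationError("poisson_scale must be positive (or None to disable)")
        if self.gaussian_sd < 0:
            raise ConfigurationError("gaussian_sd must be >= 0")


def spine_center_y(params: "PhantomParams") -> float:
    """Posterior (-y) spine axis position derived from the body ellipsoid."""
    return -0.60 * params.body_half_axes[1]


def lung_centers(
    body_half_axes: tuple[float, float, float],
) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Deterministic lung placement (left, right) derived from the body ellipsoid."""
    bz, by, bx = body_half_axes
    # slightly anterior (+y) of center, clear of the posterior spine
    return ((0.0, +0.08 * by, -0.52 * bx), (0.0, +0.08 * by, +0.52 * bx))


def _check_tumor_in_lung(p: PhantomParams) -> None:
    """Sufficient containment test: the tumor sphere must fit in one lung ellipsoid."""
    lz, ly, lx = p.lung_half_axes
    r = p.tumor_radius
    if min(lz, ly, lx) <= r:
        raise ConfigurationError(
            f"tumor_radius {r} mm does not fit in lung half-axes {p.lung_half_axes}"
        )
    tc = np.asarray(p.tumor_center, dtype=float)
    for c in lung_centers(p.body_half_axes):
        d = (tc - np.asarray(c)) / (np.asarray([lz, ly, lx]) - r)
        if float(np.sum(d * d)) <= 1.0:
            return
    raise ConfigurationError(
        f"tumor_center {p.tumor_center} (radius {r} mm) lies outside both lung ellipsoids"
    )


def default_population(
    grid_shape: tuple[int, int, int] = (128, 128, 128), voxel_size: float = 0.03
) -> dict:
    """Population ranges emulating inter-subject anatomical variation.

    Sizes scale with the grid extent so the same relative anatomy is produced
    at any resolution. Ranges are (lo, hi) pairs; triples of ranges for the
    half-axis fields. Attenuations are fixed at chest-radiograph-like defaults.
    """
    ext = [n * voxel_size * 10.0 for n in grid_shape]  # mm per axis
    hz, hy, hx = ext[0] / 2, ext[1] / 2, ext[2] / 2
    return {
        "body_half_axes": (
            (0.86 * hz, 0.94 * hz),
            (0.58 * hy, 0.68 * hy),
            (0.74 * hx, 0.86 * hx),
        ),
        "lung_half_axes": (
            (0.52 * hz, 0.62 * hz),
            (0.36 * hy, 0.44 * hy),
            (0.25 * hx, 0.31 * hx),
        ),
        "rib_count": (4, 6),  # inclusive integer range, per side
        "rib_thickness": (0.035 * hz, 0.055 * hz),
        "rib_spacing": (0.26 * hz, 0.34 * hz),
        "spine_radius": (0.10 * hx, 0.14 * hx),
        "tumor_radius": (0.09 * hx, 0.13 * hx),
        # fractional tumor offset inside the (shrunken) lung ellipsoid, per axis
        "tumor_offset_frac": (-0.55, 0.55),
        "lung_texture_amp": (0.04,) * 2,
        "attenuation_soft": (DEFAULT_ATTENUATION["soft"],) * 2,
        "attenuation_bone": (DEFAULT_ATTENUATION["bone"],) * 2,
        "attenuation_lung": (DEFAULT_ATTENUATION["lung"],) * 2,
        "attenuation_tumor": (DEFAULT_ATTENUATION["tumor"],) * 2,
        "voxel_size": voxel_size,
        "grid_shape": tuple(grid_shape),
    }


def _uniform(rng: np.random.Generator, lo_hi) -> float:
    lo, hi = float(lo_hi[0]), float(lo_hi[1])
    if hi < lo:
        raise ConfigurationError(f"empty range ({lo}, {hi})")
    return lo if lo == hi else float(rng.uniform(lo, hi))


def sample_phantom_params(population_config: dict, seed: int) -> PhantomParams:
    """Draw one subject's parameters from the population ranges.

    Deterministic for a given (config, seed). The tumor center is drawn as a
    fractional offset inside the right lung ellipsoid shrunken by the tumor
    radius, so containment holds by construction; all other invariants are
    re-validated by :class:`PhantomParams`.
    """
    cfg = population_config
    rng = np.random.default_rng(seed)
    body = tuple(_uniform(rng, r) for r in cfg["body_half_axes"])
    lung = tuple(_uniform(rng, r) for r in cfg["lung_half_axes"])
    lo, hi = cfg["rib_count"]
    rib_count = int(lo) if lo == hi else int(rng.integers(int(lo), int(hi) + 1))
    rib_thickness = _uniform(rng, cfg["rib_thickness"])
    rib_spacing = _uniform(rng, cfg["rib_spacing"])
    spine_radius = _uniform(rng, cfg["spine_radius"])
    tumor_radius = _uniform(rng, cfg["tumor_radius"])

    if min(lung) <= tumor_radius:
        raise ConfigurationError(
            f"tumor_radius range {cfg['tumor_radius']} exceeds lung_half_axes range "
            f"{cfg['lung_half_axes']}: drawn radius {tumor_radius:.2f} mm vs lung {lung}"
        )
    frac = np.array([_uniform(rng, cfg["tumor_offset_frac"]) for _ in range(3)])
    if np.sum(frac**2) > 1.0:  # keep offsets safely inside the unit ball
        frac = frac / np.sqrt(np.sum(frac**2)) * 0.9
    right = np.asarray(lung_centers(body)[1])
    center = right + frac * (np.asarray(lung) - tumor_radius)

    return PhantomParams(
        seed=seed,
        body_half_axes=body,
        lung_half_axes=lung,
        rib_count=rib_count,
        rib_thickness=rib_thickness,
        rib_spacing=rib_spacing,
        spine_radius=spine_radius,
        tumor_center=tuple(float(c) for c in center),
        tumor_radius=tumor_radius,
        attenuation_soft=_uniform(rng, cfg["attenuation_soft"]),
        attenuation_bone=_uniform(rng, cfg["attenuation_bone"]),
        attenuation_lung=_uniform(rng, cfg["attenuation_lung"]),
        attenuation_tumor=_uniform(rng, cfg["attenuation_tumor"]),
        lung_texture_amp=_uniform(rng, cfg.get("lung_texture_amp", (0.04, 0.04))),
        voxel_size=float(cfg.get("voxel_size", 0.03)),
        grid_shape=tuple(cfg.get("grid_shape", (128, 128, 128))),
    )


def _grid_mm(params: PhantomParams):
    """Per-axis voxel-center coordinates in mm (broadcastable), origin at center."""
    vox_mm = params.voxel_size * 10.0
    axes = [
        ((np.arange(n, dtype=np.float32) - (n - 1) / 2.0) * vox_mm) for n in params.grid_shape
    ]
    nz, ny, nx = params.grid_shape
    return axes[0].reshape(nz, 1, 1), axes[1].reshape(1, ny, 1), axes[2].reshape(1, 1, nx)


def build_phantom_pair(params: PhantomParams) -> PhantomPair:
    """Rasterize one subject into a with-bone / without-bone volume pair.

    Purely deterministic given ``params``. The two volumes share their mask
    arrays; in the bone-off volume every bone voxel holds soft-tissue
    attenuation, leaving all other voxels bit-identical to the bone-on volume.
    """
    bz, by, bx = params.body_half_axes
    vox_mm = params.voxel_size * 10.0
    half_extent = [n * vox_mm / 2.0 for n in params.grid_shape]
    if bz > half_extent[0] or by > half_extent[1] or bx > half_extent[2]:
        raise GeometryError(
            f"body half-axes {params.body_half_axes} mm exceed grid half-extent "
            f"{tuple(round(h, 2) for h in half_extent)} mm"
        )

    Z, Y, X = _grid_mm(params)
    body = (Z / bz) ** 2 + (Y / by) ** 2 + (X / bx) ** 2 <= 1.0

    lung_mask = np.zeros_like(body)
    for cz, cy, cx in lung_centers(params.body_half_axes):
        lz, ly, lx = params.lung_half_axes
        lung_mask |= ((Z - cz) / lz) ** 2 + ((Y - cy) / ly) ** 2 + ((X - cx) / lx) ** 2 <= 1.0
    lung_mask &= body

    tz, ty, tx = params.tumor_center
    tumor_mask = (Z - tz) ** 2 + (Y - ty) ** 2 + (X - tx) ** 2 <= params.tumor_radius**2

    bone = np.zeros_like(body)
    # spine: posterior cylinder along z with periodic vertebral bulges
    # (posterior is -y; the oblique views then sweep the spine shadow toward
    # the mediastinum rather than across the tracked lung, as in a tracking-
    # eligible patient geometry)
    if params.spine_radius > 0:
        ys = spine_center_y(params)
        period = params.rib_spacing
        bulge = np.where((Z / period) % 1.0 < 0.55, 1.25, 1.0)
        r_spine = params.spine_radius * bulge
        bone |= ((X**2 + (Y - ys) ** 2) < r_spine**2) & (np.abs(Z) <= 0.88 * bz)
    # ribs: partial elliptical tori hugging the inside of the body wall
    if params.rib_count > 0:
        rx, ry = 0.90 * bx, 0.90 * by
        rho = np.sqrt((X / rx) ** 2 + (Y / ry) ** 2)
        t_rho = params.rib_thickness / (2.0 * min(rx, ry))
        shell = np.abs(rho - 1.0) <= t_rho
        droop = -0.35 * params.rib_spacing * (Y / ry)  # ribs slope caudally toward the front
        for side in (-1.0, 1.0):
            arc = side * X >= 0.08 * rx
            for k in range(params.rib_count):
                zk = (k - (params.rib_count - 1) / 2.0) * params.rib_spacing
                band = np.abs(Z - (zk + droop)) <= params.rib_thickness / 2.0
                bone |= shell & arc & band
    bone &= body & ~lung_mask & ~tumor_mask

    mu = np.zeros(params.grid_shape, dtype=np.float64)
    mu[body] = params.attenuation_soft
    mu[lung_mask] = params.attenuation_lung
    if params.lung_texture_amp > 0:
        # vessel-like parenchymal texture: band-limited noise shared by both
        # volumes of the pair, denser structures weighted positive
        from scipy import ndimage as _ndi

        trng = np.random.default_rng(params.seed + 2_000_003)
        sigma_vox = max(1.0, 1.2 / (params.voxel_size * 10.0))
        tex = _ndi.gaussian_filter(trng.standard_normal(params.grid_shape), sigma_vox)
        tex /= tex.std()
        tex = np.clip(tex, -1.5, 2.5) * params.lung_texture_amp
        mu[lung_mask] = np.maximum(mu[lung_mask] + tex[lung_mask], 0.0)
    mu[tumor_mask & body] = params.attenuation_tumor
    tumor_mask = tumor_mask & body

    with_vox = mu.copy()
    with_vox[bone] = params.attenuation_bone
    without_vox = mu.copy()
    without_vox[bone] = params.attenuation_soft

    kw = dict(
        voxel_size=params.voxel_size,
        bone_mask=bone,
        lung_mask=lung_mask,
        tumor_mask=tumor_mask,
        params=params,
    )
    pair = PhantomPair(
        with_bone=PhantomVolume(voxels=with_vox, **kw),
        without_bone=PhantomVolume(voxels=without_vox, **kw),
    )
    pair.with_bone.validate()
    pair.without_bone.validate()
    return pair


def add_imaging_noise(image, noise_config: NoiseConfig, seed: int):
    """Degrade an 8-bit projection into a treatment-like live image.

    Applies Poisson (quantum) noise in the intensity domain followed by
    additive Gaussian (electronic) noise, then clips back to [0, 255] and
    rounds half-up. Deterministic for a fixed seed.
    """
    from .projection import ProjectionImage  # local import to avoid a cycle

    pix = np.asarray(image.pixels, dtype=np.float64)
    if pix.min() < 0 or pix.max() > 255:
        raise ConfigurationError("add_imaging_noise expects pixels in [0, 255]")
    rng = np.random.default_rng(seed)
    out = pix
    scale = noise_config.poisson_scale
    if scale is not None and np.isfinite(scale):
        out = rng.poisson(out * scale).astype(np.float64) / scale
    if noise_config.gaussian_sd > 0:
        out = out + rng.normal(0.0, noise_config.gaussian_sd, size=out.shape)
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return ProjectionImage(
        pixels=out,
        value_domain="8bit",
        angle_deg=image.angle_deg,
        domain_tag="treatment_like",
        phantom_id=image.phantom_id,
        tile_index=image.tile_index,
    )
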