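"""Parallel-beam DRR projection, 8-bit windowing, 3x3 tiling, dataset assembly.

Radiograph-like images are produced as parallel ray sums of linear
attenuation (sum of mu * voxel length along the posteroanterior axis after
rotating the volume about the cranio-caudal axis). Paired with-bone /
without-bone projections are windowed with the SAME gray window (taken from
the with-bone image) so bone suppression remains measurable on the 8-bit
scale. Full images are split into nine tiles that serve as the training
images of the translation network.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateWindowError, SizeError
from .phantom import (
    PhantomVolume,
    build_phantom_pair,
    default_population,
    sample_phantom_params,
)

__all__ = [
    "ProjectionGeometry",
    "ProjectionImage",
    "TileGrid",
    "ImageDataset",
    "ImageRecord",
    "project_drr",
    "normalize_to_8bit",
    "normalize_pair",
    "tile_3x3",
    "reassemble",
    "build_dataset",
]


@dataclass(frozen=True)
class ProjectionGeometry:
    """Parallel-beam geometry: rotation about the cranio-caudal (z) axis."""

    angle_deg: float
    detector_shape: tuple[int, int] | None = None  # default: (nz, nx) of the volume
    pixel_pitch: float | None = None  # cm; default: voxel size

    def __post_init__(self) -> None:
        if not (-180.0 <= self.angle_deg < 180.0):
            raise ConfigurationError("angle_deg must lie in [-180, 180)")
        if self.detector_shape is not None and any(n <= 0 for n in self.detector_shape):
            raise ConfigurationError("detector_shape must be positive")


@dataclass
class ProjectionImage:
    """A 2-D radiograph-like image with provenance.

    ``value_domain`` is ``"raw"`` (line integrals, float) or ``"8bit"``.
    ``domain_tag`` is one of with_bone / without_bone / suppressed /
    treatment_like. ``tile_index`` is 0-8 in row-major order, or None for a
    full image.
    """

    pixels: np.ndarray
    value_domain: str
    angle_deg: float
    domain_tag: str
    phantom_id: int | str | None = None
    tile_index: int | None = None

    def validate(self) -> None:
        if self.value_domain == "8bit":
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ConfigurationError("8-bit image has pixels outside [0, 255]")
        elif self.value_domain == "raw":
            if not np.all(np.isfinite(self.pixels)) or np.any(self.pixels < 0):
                raise ConfigurationError("raw image must be finite and >= 0")
        else:
            raise ConfigurationError(f"unknown value_domain {self.value_domain!r}")


@dataclass
class TileGrid:
    tiles: list[ProjectionImage]  # nine, row-major
    parent_shape: tuple[int, int]


def project_drr(volume: PhantomVolume, geom: ProjectionGeometry) -> ProjectionImage:
    """Parallel ray-sum projection: each pixel is sum(mu * voxel_size) along y.

    The volume is rotated in the (y, x) plane by ``angle_deg`` with trilinear
    resampling, then summed along y. Angle 0 takes the exact axis-aligned
    summation path with no resampling.
    """
    vox = np.asarray(volume.voxels, dtype=np.float64)
    if geom.angle_deg == 0.0:
        rot = vox
    else:
        rot = ndimage.rotate(
            vox, geom.angle_deg, axes=(1, 2), reshape=False, order=1,
            mode="constant", cval=0.0, prefilter=False,
        )
        np.clip(rot, 0.0, None, out=rot)
    pixels = rot.sum(axis=1) * volume.voxel_size
    if geom.detector_shape is not None and tuple(geom.detector_shape) != pixels.shape:
        raise ConfigurationError(
            f"detector_shape {geom.detector_shape} != projected shape {pixels.shape}"
        )
    return ProjectionImage(
        pixels=pixels, value_domain="raw", angle_deg=geom.angle_deg, domain_tag="with_bone"
    )


def normalize_to_8bit(raw: ProjectionImage, window: tuple[float, float] | None = None) -> ProjectionImage:
    """Affine map of [window lo, hi] -> [0, 255], clipped, rounded half-up.

    ``window=None`` ("auto") uses the raw image's own min/max. For a
    with/without-bone pair use :func:`normalize_pair` so both images share
    the with-bone window.
    """
    if raw.value_domain != "raw":
        raise ConfigurationError("normalize_to_8bit expects a raw-domain image")
    pix = np.asarray(raw.pixels, dtype=np.float64)
    lo, hi = (float(pix.min()), float(pix.max())) if window is None else map(float, window)
    if hi == lo:
        raise DegenerateWindowError(f"degenerate window ({lo}, {hi})")
    scaled = (np.clip(pix, lo, hi) - lo) * (255.0 / (hi - lo))
    out = np.clip(np.floor(scaled + 0.5), 0, 255).astype(np.uint8)
    return ProjectionImage(
        pixels=out,
        value_domain="8bit",
        angle_deg=raw.angle_deg,
        domain_tag=raw.domain_tag,
        phantom_id=raw.phantom_id,
        tile_index=raw.tile_index,
    )


def normalize_pair(
    raw_with: ProjectionImage, raw_without: ProjectionImage
) -> tuple[ProjectionImage, ProjectionImage]:
    """Jointly window a paired projection using the with-bone image's min/max."""
    pix = np.asarray(raw_with.pixels, dtype=np.float64)
    window = (float(pix.min()), float(pix.max()))
    return normalize_to_8bit(raw_with, window), normalize_to_8bit(raw_without, window)


def _split_points(n: int) -> list[int]:
    # rows/cols split at floor(n/3); the last tile absorbs the remainder
    t = n // 3
    return [0, t, 2 * t, n]


def tile_3x3(image: ProjectionImage) -> TileGrid:
    """Split an image into nine tiles, row-major; reassembly is bit-exact."""
    h, w = image.pixels.shape
    if h < 3 or w < 3:
        raise SizeError(f"image {h}x{w} too small to tile 3x3")
    rs, cs = _split_points(h), _split_points(w)
    tiles = []
    for i in range(3):
        for j in range(3):
            tiles.append(
                ProjectionImage(
                    pixels=image.pixels[rs[i] : rs[i + 1], cs[j] : cs[j + 1]].copy(),
                    value_domain=image.value_domain,
                    angle_deg=image.angle_deg,
                    domain_tag=image.domain_tag,
                    phantom_id=image.phantom_id,
                    tile_index=3 * i + j,
                )
            )
    return TileGrid(tiles=tiles, parent_shape=(h, w))


def reassemble(grid: TileGrid) -> np.ndarray:
    """Invert :func:`tile_3x3` exactly."""
    rows = [
        np.concatenate([grid.tiles[3 * i + j].pixels for j in range(3)], axis=1)
        for i in range(3)
    ]
    return np.concatenate(rows, axis=0)


@dataclass
class ImageRecord:
    pixels: np.ndarray  # uint8 tile
    phantom_id: int
    angle_deg: float
    tile_index: int
    domain: str  # with_bone / without_bone
    split: str  # train / test

    def key(self) -> tuple:
        return (self.phantom_id, self.angle_deg, self.tile_index)


@dataclass
class ImageDataset:
    """Paired tile datasets for the two image domains with a phantom-level split."""

    domain_X: list[ImageRecord]  # with bone
    domain_Y: list[ImageRecord]  # without bone
    split: dict[int, str]  # phantom id -> train/test
    manifest: dict = field(default_factory=dict)

    def train_arrays(self, domain: str) -> np.ndarray:
        recs = self.domain_X if domain == "X" else self.domain_Y
        return np.stack([r.pixels for r in recs if r.split == "train"])

    def test_pairs(self) -> list[tuple[ImageRecord, ImageRecord]]:
        ys = {r.key(): r for r in self.domain_Y if r.split == "test"}
        return [(r, ys[r.key()]) for r in sorted(
            (r for r in self.domain_X if r.split == "test"), key=ImageRecord.key
        )]


def build_dataset(
    n_phantoms: int,
    angles: tuple[float, ...] = (40.0, 45.0, 50.0),
    test_fraction: float = 0.1,
    seed: int = 0,
    population: dict | None = None,
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    voxel_size: float = 0.03,
    out_dir: str | Path | None = None,
) -> ImageDataset:
    """Generate the full paired tile dataset from randomized phantoms.

    For every phantom and angle the with/without-bone pair is projected,
    jointly windowed, and tiled 3x3; tiles become the dataset images. The
    train/test split is at the phantom level so no subject leaks across
    splits. With ``out_dir`` set, tiles are written as PNG plus a JSON
    manifest.
    """
    if n_phantoms < 2:
        raise ConfigurationError("n_phantoms must be >= 2")
    if not angles:
        raise ConfigurationError("angles must be non-empty")
    pop = population or default_population(grid_shape, voxel_size)

    n_test = int(round(test_fraction * n_phantoms))
    if n_test == 0 or n_test == n_phantoms:
        raise ConfigurationError(
            f"test_fraction={test_fraction} leaves an empty split for {n_phantoms} phantoms"
        )
    order = np.random.default_rng(seed).permutation(n_phantoms)
    split = {int(pid): ("test" if i < n_test else "train") for i, pid in enumerate(order)}

    domain_X: list[ImageRecord] = []
    domain_Y: list[ImageRecord] = []
    entries = []
    for pid in range(n_phantoms):
        params = sample_phantom_params(pop, seed=seed * 100003 + pid)
        pair = build_phantom_pair(params)
        for angle in angles:
            geom = ProjectionGeometry(angle_deg=float(angle))
            raw_w = project_drr(pair.with_bone, geom)
            raw_wo = project_drr(pair.without_bone, geom)
            img_w, img_wo = normalize_pair(raw_w, raw_wo)
            for domain, img, sink in (("with_bone", img_w, domain_X), ("without_bone", img_wo, domain_Y)):
                img.domain_tag = domain
                img.phantom_id = pid
                for tile in tile_3x3(img).tiles:
                    rec = ImageRecord(
                        pixels=tile.pixels,
                        phantom_id=pid,
                        angle_deg=float(angle),
                        tile_index=tile.tile_index,
                        domain=domain,
                        split=split[pid],
                    )
                    sink.append(rec)
                    entries.append(
                        {
                            "phantom_id": pid,
                            "angle_deg": float(angle),
                            "tile_index": tile.tile_index,
                            "domain": domain,
                            "split": split[pid],
                            "sha256": hashlib.sha256(tile.pixels.tobytes()).hexdigest(),
                        }
                    )
    manifest = {
        "n_phantoms": n_phantoms,
        "angles": [float(a) for a in angles],
        "test_fraction": test_fraction,
        "seed": seed,
        "grid_shape": list(pop["grid_shape"]),
        "voxel_size": pop["voxel_size"],
        "n_images_per_domain": len(domain_X),
        "split": {str(k): v for k, v in split.items()},
        "images": entries,
    }
    ds = ImageDataset(domain_X=domain_X, domain_Y=domain_Y, split=split, manifest=manifest)
    if out_dir is not None:
        _write_dataset(ds, Path(out_dir))
    return ds


def _write_dataset(ds: ImageDataset, out_dir: Path) -> None:
    import imageio.v3 as iio

    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in ds.domain_X + ds.domain_Y:
        name = f"p{rec.phantom_id:03d}_a{rec.angle_deg:g}_t{rec.tile_index}_{rec.domain}.png"
        sub = out_dir / rec.split / rec.domain
        sub.mkdir(parents=True, exist_ok=True)
        iio.imwrite(sub / name, rec.pixels)
    (out_dir / "manifest.json").write_text(json.dumps(ds.manifest, indent=1))
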