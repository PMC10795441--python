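"""End-to-end study protocols built from the library pieces.

Two experiments mirror the study design at desk scale:

* suppression quality — generate a population of paired phantoms, project
  at 40/45/50 degrees, window jointly, tile 3x3, train the CycleGAN on the
  training phantoms' tiles, and score MSSIM / PSNR of suppressed vs
  ground-truth bone-free tiles on held-out phantoms;
* tracking benefit — degrade held-out with-bone projections into noisy
  treatment-like images, suppress them with the trained model, and compare
  ZNCC template matching (template cut from the clean bone-free projection
  around the projected tumor, 20% margin) between the two conditions,
  including the Welch t-test on the peak-ZNCC groups.

All randomness derives from a single base seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cyclegan import GanConfig, TrainedModel, suppress_bone, train
from .errors import ConfigurationError
from .metrics import SimilarityResult, SsimParams, evaluate_pairs
from .phantom import (
    NoiseConfig,
    add_imaging_noise,
    build_phantom_pair,
    default_population,
    sample_phantom_params,
)
from .projection import (
    ImageDataset,
    ImageRecord,
    ProjectionGeometry,
    build_dataset,
    normalize_pair,
    project_drr,
)
from .tracking import extract_template, independent_t_test, tracking_report

__all__ = [
    "HeadlineConfig",
    "make_headline_dataset",
    "train_headline_model",
    "evaluate_suppression",
    "make_treatment_like_case",
    "tracking_experiment",
    "run_headline",
]

ANGLES = (40.0, 45.0, 50.0)


@dataclass(frozen=True)
class HeadlineConfig:
    """Desk-scale twin of the study conditions.

    40 phantom pairs at 96 cubed voxels (0.03 cm), three oblique angles,
    nine 32x32 tiles per projection, a 0.1 phantom-level test fraction
    (>= 30 held-out tile pairs), <= 3000 generator updates, and >= 200
    treatment-like images for the tracking comparison.
    """

    n_phantoms: int = 40
    grid: int = 96
    voxel_size: float = 0.03
    angles: tuple[float, ...] = ANGLES
    test_fraction: float = 0.1
    tile_size: int = 32
    base_channels: int = 16
    n_res_blocks: int = 2
    batch_size: int = 1
    max_updates: int = 3000
    n_tracking_images: int = 201
    noise: NoiseConfig = field(default_factory=NoiseConfig)


def make_headline_dataset(cfg: HeadlineConfig, seed: int) -> ImageDataset:
    g = (cfg.grid,) * 3
    return build_dataset(
        n_phantoms=cfg.n_phantoms,
        angles=cfg.angles,
        test_fraction=cfg.test_fraction,
        seed=seed,
        grid_shape=g,
        voxel_size=cfg.voxel_size,
    )


def train_headline_model(dataset: ImageDataset, cfg: HeadlineConfig, seed: int,
                         out_dir=None) -> TrainedModel:
    gan = GanConfig(
        image_size=cfg.tile_size,
        base_channels=cfg.base_channels,
        n_res_blocks=cfg.n_res_blocks,
        batch_size=cfg.batch_size,
        n_epochs=10_000,  # capped by max_updates
        max_updates=cfg.max_updates,
        seed=seed,
    )
    # validation probe pairs come from the TRAIN split (never the held-out
    # phantoms), stride-sampled across phantoms/angles/tiles, capped for speed
    ys = {r.key(): r for r in dataset.domain_Y if r.split == "train"}
    xs = sorted((r for r in dataset.domain_X if r.split == "train"),
                key=ImageRecord.key)
    stride = max(1, len(xs) // 45)
    val_pairs = [(xr.pixels, ys[xr.key()].pixels) for xr in xs[::stride]]
    return train(dataset, gan, out_dir=out_dir, val_pairs=val_pairs)


def evaluate_suppression(model: TrainedModel, dataset: ImageDataset,
                         params: SsimParams = SsimParams()) -> SimilarityResult:
    return evaluate_pairs(model, dataset.test_pairs(), params)


def _tumor_bbox(tumor_projection: np.ndarray) -> tuple[int, int, int, int]:
    rows = np.any(tumor_projection > 0, axis=1)
    cols = np.any(tumor_projection > 0, axis=0)
    r = np.where(rows)[0]
    c = np.where(cols)[0]
    if len(r) == 0:
        raise ConfigurationError("tumor does not project onto the detector")
    return int(r[0]), int(r[-1]) + 1, int(c[0]), int(c[-1]) + 1


#: minimum rib path length (cm) through the tumor box that counts as overlap
RIB_OVERLAP_MIN_PATH = 0.05


def _rib_mask(volume) -> np.ndarray:
    """Bone voxels excluding the spine neighborhood (rib arcs only)."""
    from .phantom import spine_center_y

    p = volume.params
    vox_mm = p.voxel_size * 10.0
    nz, ny, nx = p.grid_shape
    X = ((np.arange(nx) - (nx - 1) / 2) * vox_mm).reshape(1, 1, nx)
    Y = ((np.arange(ny) - (ny - 1) / 2) * vox_mm).reshape(1, ny, 1)
    r = max(p.spine_radius, 1e-6)
    zone = (np.abs(X) < 2.5 * r) & (np.abs(Y - spine_center_y(p)) < 2.5 * r)
    return volume.bone_mask & ~np.broadcast_to(zone, p.grid_shape)


def make_treatment_like_case(population: dict, phantom_seed: int, angle: float,
                             noise: NoiseConfig, noise_seed: int):
    """One tracking case: noisy with-bone image, its suppressible twin, template.

    Returns (noisy_with_bone, clean_without_bone, template, rib_overlaps_tumor):
    the template is cut from the clean bone-free projection around the
    projected tumor mask with a 20% margin; the overlap flag says whether a
    rib arc casts at least RIB_OVERLAP_MIN_PATH cm of bone across the tumor's
    bounding box (the stratum in which suppression can matter).
    """
    params = sample_phantom_params(population, seed=phantom_seed)
    pair = build_phantom_pair(params)
    geom = ProjectionGeometry(angle_deg=float(angle))
    raw_w = project_drr(pair.with_bone, geom)
    raw_wo = project_drr(pair.without_bone, geom)
    img_w, img_wo = normalize_pair(raw_w, raw_wo)
    img_w.domain_tag, img_wo.domain_tag = "with_bone", "without_bone"
    img_w.phantom_id = img_wo.phantom_id = phantom_seed

    tumor_vol = pair.with_bone
    tproj = project_drr(
        _mask_volume(tumor_vol, tumor_vol.tumor_mask), geom
    ).pixels
    bbox = _tumor_bbox(tproj)
    template = extract_template(img_wo, bbox, margin=0.2)

    rib_proj = project_drr(_mask_volume(tumor_vol, _rib_mask(tumor_vol)), geom).pixels
    r0, r1, c0, c1 = bbox
    overlap = bool(np.any(rib_proj[r0:r1, c0:c1] > RIB_OVERLAP_MIN_PATH))

    noisy = add_imaging_noise(img_w, noise, seed=noise_seed)
    return noisy, img_wo, template, overlap


def _mask_volume(vol, mask):
    from .phantom import PhantomVolume

    return PhantomVolume(
        voxels=mask.astype(np.float64),
        voxel_size=vol.voxel_size,
        bone_mask=vol.bone_mask,
        lung_mask=vol.lung_mask,
        tumor_mask=vol.tumor_mask,
        params=vol.params,
    )


def tracking_experiment(model: TrainedModel, cfg: HeadlineConfig, seed: int,
                        require_overlap: bool = True) -> dict:
    """Table-style comparison of with-bone vs suppressed treatment-like images.

    Generates fresh phantoms (disjoint seed stream from the training set),
    keeps cases whose rib/spine shadow crosses the tumor box, matches the
    bone-free-derived template in both conditions, and reports per-condition
    detection rate and ZNCC statistics plus the Welch t-test between the
    identified-image ZNCC groups.
    """
    pop = default_population((cfg.grid,) * 3, cfg.voxel_size)
    cases = []
    i = 0
    # phantom seeds offset far from the dataset stream to keep subjects disjoint
    while len(cases) < cfg.n_tracking_images and i < 10 * cfg.n_tracking_images:
        angle = cfg.angles[i % len(cfg.angles)]
        c = make_treatment_like_case(
            pop, phantom_seed=seed * 100003 + 500_000 + i, angle=angle,
            noise=cfg.noise, noise_seed=seed + 7919 * i,
        )
        i += 1
        if c[3] or not require_overlap:
            cases.append(c)
    if len(cases) < cfg.n_tracking_images:
        raise ConfigurationError("could not generate enough rib-overlap cases")

    noisy_imgs = [c[0] for c in cases]
    templates = [c[2] for c in cases]
    suppressed = [suppress_bone(model, img) for img in noisy_imgs]

    rep_bone = tracking_report(noisy_imgs, templates, condition="with_bone")
    rep_sup = tracking_report(suppressed, templates, condition="suppressed")
    try:
        t, p = independent_t_test(rep_bone.zncc_identified, rep_sup.zncc_identified)
        sig = bool(p < rep_bone.alpha)
    except ConfigurationError:  # too few identified images in a group
        t = p = sig = None
    for rep in (rep_bone, rep_sup):
        rep.t_statistic, rep.p_value, rep.significant = t, p, sig
    return {"with_bone": rep_bone, "suppressed": rep_sup, "t": t, "p": p,
            "n_cases": len(cases)}


def run_headline(seed: int, cfg: HeadlineConfig = HeadlineConfig(),
                 out_dir=None) -> dict:
    """Full desk-scale reproduction: returns the four headline quantities.

    Keys: mssim (mean MSSIM suppressed vs bone-free), psnr (dB),
    pct_identified and zncc_mean for the suppressed condition, plus the full
    reports and the held-out test size.
    """
    dataset = make_headline_dataset(cfg, seed=seed)
    model = train_headline_model(dataset, cfg, seed=seed, out_dir=out_dir)
    sim = evaluate_suppression(model, dataset)
    track = tracking_experiment(model, cfg, seed=seed)
    return {
        "mssim": sim.ssim_mean,
        "psnr": sim.psnr_mean,
        "pct_identified": track["suppressed"].pct_identified,
        "zncc_mean": track["suppressed"].zncc_mean,
        "n_test_pairs": len(sim.per_image),
        "similarity": sim,
        "tracking": track,
        "model": model,
        "dataset": dataset,
    }
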