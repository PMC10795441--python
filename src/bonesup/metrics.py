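"""Image-quality metrics on the 8-bit gray scale: SSIM / MSSIM, MSE, PSNR.

The local structural similarity of two co-located blocks x, y is

    SSIM(x, y) = (2 mu_x mu_y + C1)(2 sigma_xy + C2)
                 / ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))

with Gaussian-weighted means/variances/covariance, C1 = (0.01*255)^2 and
C2 = (0.03*255)^2. MSSIM averages SSIM over all M window positions (dense
sliding window, symmetric boundary padding). PSNR = 10 log10(PS^2 / MSE)
with PS = 255; identical images raise :class:`IdenticalImagesError` instead
of returning +inf.

Images are converted to float on the 0-255 scale before any metric,
whatever their storage dtype, because C1/C2/PS are defined on that scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, IdenticalImagesError, SizeError

__all__ = [
    "SsimParams",
    "SimilarityResult",
    "gaussian_window",
    "ssim_local",
    "ssim_map",
    "mssim",
    "mse",
    "psnr",
    "evaluate_pairs",
]


@dataclass(frozen=True)
class SsimParams:
    C1: float = (0.01 * 255) ** 2  # 6.5025
    C2: float = (0.03 * 255) ** 2  # 58.5225
    window_size: int = 11
    sigma: float = 1.5
    dynamic_range: float = 255.0
    tile_wise: bool = False  # evaluate per 3x3 tile instead of whole-image

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0:
            raise ConfigurationError("C1 and C2 must be positive")
        if self.window_size < 1 or self.window_size % 2 == 0:
            raise ConfigurationError("window_size must be odd and >= 1")
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")


def gaussian_window(shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Centered 2-D Gaussian weights normalized to sum 1."""
    gy = np.arange(shape[0], dtype=np.float64) - (shape[0] - 1) / 2.0
    gx = np.arange(shape[1], dtype=np.float64) - (shape[1] - 1) / 2.0
    w = np.exp(-(gy[:, None] ** 2 + gx[None, :] ** 2) / (2.0 * sigma**2))
    return w / w.sum()


def _as_float(img) -> np.ndarray:
    a = np.asarray(getattr(img, "pixels", img), dtype=np.float64)
    if a.ndim != 2:
        raise ConfigurationError("metrics expect 2-D grayscale images")
    return a


def ssim_local(x_block, y_block, params: SsimParams = SsimParams()) -> float:
    """SSIM of a single pair of co-located blocks (Gaussian-weighted moments)."""
    x, y = _as_float(x_block), _as_float(y_block)
    if x.shape != y.shape:
        raise ConfigurationError(f"block shapes differ: {x.shape} vs {y.shape}")
    w = gaussian_window(x.shape, params.sigma)
    mx, my = float((w * x).sum()), float((w * y).sum())
    vx = float((w * x * x).sum()) - mx * mx
    vy = float((w * y * y).sum()) - my * my
    cxy = float((w * x * y).sum()) - mx * my
    c1, c2 = params.C1, params.C2
    return ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx * mx + my * my + c1) * (vx + vy + c2))


def ssim_map(x, y, params: SsimParams = SsimParams()) -> np.ndarray:
    """Dense per-pixel SSIM map (one window centered at every pixel).

    Boundary handling is symmetric padding; moments are computed by
    correlating with the normalized Gaussian kernel.
    """
    xa, ya = _as_float(x), _as_float(y)
    if xa.shape != ya.shape:
        raise ConfigurationError(f"image shapes differ: {xa.shape} vs {ya.shape}")
    if min(xa.shape) < params.window_size:
        raise SizeError(f"image {xa.shape} smaller than the {params.window_size}-pixel window")
    k = gaussian_window((params.window_size, params.window_size), params.sigma)

    def smooth(a):
        return ndimage.correlate(a, k, mode="reflect")  # 'reflect' == symmetric padding

    mx, my = smooth(xa), smooth(ya)
    vx = smooth(xa * xa) - mx * mx
    vy = smooth(ya * ya) - my * my
    cxy = smooth(xa * ya) - mx * my
    c1, c2 = params.C1, params.C2
    return ((2 * mx * my + c1) * (2 * cxy + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


def mssim(x, y, params: SsimParams = SsimParams()) -> float:
    """Mean SSIM over all window positions; 1.0 iff the images are identical."""
    return float(ssim_map(x, y, params).mean())


def mse(x, y) -> float:
    """Mean squared pixel difference."""
    xa, ya = _as_float(x), _as_float(y)
    if xa.shape != ya.shape:
        raise ConfigurationError(f"image shapes differ: {xa.shape} vs {ya.shape}")
    return float(np.mean((xa - ya) ** 2))


def psnr(x, y, peak: float = 255.0) -> float:
    """Peak signal-to-noise ratio in dB: 10 log10(peak^2 / MSE).

    Raises :class:`IdenticalImagesError` when MSE is zero (infinite PSNR).
    """
    m = mse(x, y)
    if m == 0.0:
        raise IdenticalImagesError("images are identical: PSNR is unbounded")
    return 10.0 * math.log10(peak * peak / m)


@dataclass
class SimilarityResult:
    """Per-image and aggregate suppressed-vs-ground-truth similarity."""

    per_image: list[dict] = field(default_factory=list)
    ssim_mean: float = float("nan")
    ssim_sd: float = float("nan")
    psnr_mean: float = float("nan")
    psnr_sd: float = float("nan")
    n_infinite_psnr: int = 0

    @classmethod
    def from_rows(cls, rows: list[dict]) -> "SimilarityResult":
        ssims = np.array([r["ssim"] for r in rows], dtype=float)
        psnrs = np.array([r["psnr"] for r in rows if r["psnr"] is not None], dtype=float)
        return cls(
            per_image=rows,
            ssim_mean=float(ssims.mean()),
            ssim_sd=float(ssims.std(ddof=1)) if len(ssims) > 1 else 0.0,
            psnr_mean=float(psnrs.mean()) if len(psnrs) else float("nan"),
            psnr_sd=float(psnrs.std(ddof=1)) if len(psnrs) > 1 else 0.0,
            n_infinite_psnr=sum(1 for r in rows if r["psnr"] is None),
        )


def evaluate_pairs(model, test_pairs, params: SsimParams = SsimParams()) -> SimilarityResult:
    """Suppress each with-bone image and score it against its bone-free twin.

    ``test_pairs`` is a list of aligned (with_bone, without_bone) items —
    :class:`~bonesup.projection.ImageRecord` pairs or plain arrays. A PSNR of
    None (with ``infinite_psnr`` flagged) marks an exact match.
    """
    from .cyclegan import suppress_bone
    from .projection import ProjectionImage

    if not test_pairs:
        raise ConfigurationError("empty test set")
    rows = []
    for i, (xb, yb) in enumerate(test_pairs):
        xpix = np.asarray(getattr(xb, "pixels", xb))
        ypix = np.asarray(getattr(yb, "pixels", yb))
        img = ProjectionImage(pixels=xpix, value_domain="8bit", angle_deg=float("nan"),
                              domain_tag="with_bone")
        sup = suppress_bone(model, img).pixels
        try:
            p = psnr(sup, ypix)
            inf = False
        except IdenticalImagesError:
            p, inf = None, True
        rows.append({
            "image_id": getattr(xb, "key", lambda: i)(),
            "ssim": mssim(sup, ypix, params),
            "psnr": p,
            "infinite_psnr": inf,
        })
    return SimilarityResult.from_rows(rows)
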