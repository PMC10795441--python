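"""Tumor localization by ZNCC template matching and the group comparison.

Zero-mean normalized cross-correlation of a template T against a same-size
window I is

    ZNCC = sum((T - mean T)(I - mean I))
           / sqrt(sum((T - mean T)^2) * sum((I - mean I)^2)),

a gain/offset-invariant similarity in [-1, 1] (1 at an exact match). The
search area is the entire image: a heatmap holds the ZNCC at every valid
template offset and the peak gives the matched tumor position. A match
counts as "identified correctly" when the matched center falls within a
pixel tolerance of the true center (default: half the template's larger
side). Group ZNCC statistics are aggregated over identified images only,
and conditions are compared with a two-sided Welch independent t-test at
alpha 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .errors import ConfigurationError, SizeError

__all__ = [
    "Template",
    "MatchResult",
    "TrackingReport",
    "zncc",
    "match_template",
    "detection_success",
    "default_tolerance",
    "tracking_report",
    "independent_t_test",
    "extract_template",
]


@dataclass
class Template:
    patch: np.ndarray  # 2-D 8-bit tumor region plus margin
    true_center: tuple[float, float]  # (row, col) in the search image
    source_tag: str = "without_bone"

    def __post_init__(self) -> None:
        if np.asarray(self.patch).std() == 0:
            raise ConfigurationError("template patch has zero variance")


@dataclass
class MatchResult:
    heatmap: np.ndarray  # ZNCC at every valid top-left offset
    peak_offset: tuple[int, int]
    peak_zncc: float
    matched_center: tuple[float, float]


@dataclass
class TrackingReport:
    condition: str  # with_bone / suppressed
    n_total: int
    n_identified: int
    pct_identified: float
    zncc_mean: float  # over identified images only
    zncc_sd: float
    zncc_identified: list[float] = field(default_factory=list)
    t_statistic: float | None = None
    p_value: float | None = None
    significant: bool | None = None
    alpha: float = 0.05


def _as2d(a) -> np.ndarray:
    return np.asarray(getattr(a, "pixels", a), dtype=np.float64)


def zncc(template, window) -> float:
    """ZNCC of two same-size patches; zero-variance patches score 0."""
    t, w = _as2d(template), _as2d(window)
    if t.shape != w.shape:
        raise ConfigurationError(f"shapes differ: {t.shape} vs {w.shape}")
    t0 = t - t.mean()
    w0 = w - w.mean()
    denom = np.sqrt((t0 * t0).sum() * (w0 * w0).sum())
    if denom == 0.0:
        return 0.0
    return float(np.clip((t0 * w0).sum() / denom, -1.0, 1.0))


def match_template(image, template: Template) -> MatchResult:
    """ZNCC heatmap over every valid offset of the whole image; peak = match.

    Ties at the peak break toward the smallest row, then smallest column
    (row-major argmax). The matched center is the peak offset plus half the
    template size.
    """
    img = _as2d(image)
    pat = _as2d(template.patch)
    th, tw = pat.shape
    if th >= img.shape[0] or tw >= img.shape[1]:
        raise SizeError(f"template {pat.shape} not smaller than image {img.shape}")

    t0 = pat - pat.mean()
    t_energy = float((t0 * t0).sum())
    n = th * tw
    # exact direct sums over all windows (no FFT roundoff)
    windows = sliding_window_view(img, (th, tw))
    s1 = windows.sum(axis=(2, 3))
    s2 = np.einsum("ijkl,ijkl->ij", windows, windows)
    num = np.einsum("ijkl,kl->ij", windows, t0)
    win_var = np.maximum(s2 - s1 * s1 / n, 0.0)  # sum of squared deviations
    denom = np.sqrt(t_energy * win_var)
    with np.errstate(invalid="ignore", divide="ignore"):
        heat = np.where(denom > 0.0, num / np.maximum(denom, 1e-300), 0.0)
    if t_energy == 0.0:
        heat = np.zeros_like(heat)
    heat = np.clip(heat, -1.0, 1.0)

    flat = int(np.argmax(heat))
    peak = (flat // heat.shape[1], flat % heat.shape[1])
    center = (peak[0] + (th - 1) / 2.0, peak[1] + (tw - 1) / 2.0)
    return MatchResult(
        heatmap=heat,
        peak_offset=peak,
        peak_zncc=float(heat[peak]),
        matched_center=center,
    )


def default_tolerance(template: Template) -> float:
    """Half the template's larger side, in pixels."""
    return max(template.patch.shape) / 2.0


def detection_success(result: MatchResult, true_center: tuple[float, float],
                      tolerance: float) -> bool:
    """True iff the matched center lies within ``tolerance`` px (inclusive)."""
    if tolerance < 0:
        raise ConfigurationError("tolerance must be >= 0")
    d = np.hypot(result.matched_center[0] - true_center[0],
                 result.matched_center[1] - true_center[1])
    return bool(d <= tolerance)


def tracking_report(images, templates, true_centers=None, tolerance: float | None = None,
                    condition: str = "with_bone") -> TrackingReport:
    """Run template matching over one image condition and tabulate the outcome.

    ``images``, ``templates`` (and optionally ``true_centers``, defaulting to
    each template's own) are aligned by index. ZNCC mean/sd are computed over
    correctly identified images only; the percentage identified is reported
    alongside.
    """
    if len(images) == 0:
        raise ConfigurationError("empty image list")
    if len(images) != len(templates):
        raise ConfigurationError("images and templates must align")
    centers = true_centers or [t.true_center for t in templates]
    hits = []
    for img, tpl, tc in zip(images, templates, centers):
        res = match_template(img, tpl)
        tol = default_tolerance(tpl) if tolerance is None else tolerance
        if detection_success(res, tc, tol):
            hits.append(res.peak_zncc)
    n_total = len(images)
    n_id = len(hits)
    arr = np.asarray(hits, dtype=float)
    return TrackingReport(
        condition=condition,
        n_total=n_total,
        n_identified=n_id,
        pct_identified=100.0 * n_id / n_total,
        zncc_mean=float(arr.mean()) if n_id else float("nan"),
        zncc_sd=float(arr.std(ddof=1)) if n_id > 1 else 0.0,
        zncc_identified=hits,
    )


def independent_t_test(group_a, group_b, alpha: float = 0.05):
    """Two-sided Welch independent t-test; returns (t, p).

    Requires two groups of >= 2 finite values with nonzero pooled variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigurationError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ConfigurationError("groups must be finite")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if np.array_equal(np.sort(a), np.sort(b)) and a.mean() == b.mean():
            return 0.0, 1.0
        raise ConfigurationError("both groups degenerate (zero variance)")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def extract_template(bone_free_image, tumor_bbox: tuple[int, int, int, int],
                     margin: float = 0.2) -> Template:
    """Cut the matching template from a bone-free projection.

    ``tumor_bbox`` is (row0, row1, col0, col1) of the projected tumor mask;
    the patch is the box grown by ``margin`` (fraction of each side) and
    clipped to the image, mimicking a DRR-derived tumor tracking volume.
    """
    img = _as2d(bone_free_image)
    r0, r1, c0, c1 = tumor_bbox
    mr = int(round(margin * (r1 - r0)))
    mc = int(round(margin * (c1 - c0)))
    rr0, rr1 = max(0, r0 - mr), min(img.shape[0], r1 + mr)
    cc0, cc1 = max(0, c0 - mc), min(img.shape[1], c1 + mc)
    patch = np.asarray(getattr(bone_free_image, "pixels", bone_free_image))[rr0:rr1, cc0:cc1]
    center = ((rr0 + rr1 - 1) / 2.0, (cc0 + cc1 - 1) / 2.0)
    return Template(patch=patch.copy(), true_center=center, source_tag="without_bone")
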