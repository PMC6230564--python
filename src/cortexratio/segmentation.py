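"""Cerebrum-mask construction and GM/WM tissue segmentation from T1w.

The segmentation chain works on a *locally normalized* copy of the T1w
image (division by a smoothed local-maximum field) so that smooth
radiofrequency bias does not shift tissue intensities across the image.
The normalized image is used **only** for masking and segmentation; the
ratio analysis always consumes original intensities, because dividing by
a local field would also normalize away the very signal under study.

The cerebrum mask is built with a fixed morphological recipe
(threshold from the intensity histogram, small-object removal,
erode/dilate, re-threshold) and tissue classes are separated with a
spatially regularized fuzzy c-means (two classes: GM and WM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters as sk_filters
from skimage import morphology as sk_morph

from .volume import BinaryMask, ScalarVolume

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # = 1/2.3548


class DegenerateInput(ValueError):
    pass


class SegmentationFailure(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# local intensity normalization
# ---------------------------------------------------------------------------

def local_intensity_normalize(
    t1: ScalarVolume,
    window: int = 3,
    smooth_fwhm_mm: float = 10.0,
    floor_frac: float = 0.05,
) -> tuple[ScalarVolume, np.ndarray]:
    """Divide the T1w image by a smoothed local-maximum intensity field.

    A sliding ``window``^3 maximum filter estimates the local bright
    reference (WM near the cortex); a 10 mm FWHM Gaussian smooths it
    into an intensity field map and dividing by the field yields a
    dimensionless image, predominantly in (0, 1].  The smoothing is
    confined to the bright-reference support (max-filter values above an
    Otsu split of the positive values, with renormalized weights) so
    that dark CSF/background regions do not drag the field down near
    tissue boundaries — the field tracks the local white-matter
    brightness envelope, which is exactly what a multiplicative
    transmit/receive bias modulates.  Voxels where the smoothed support
    weight is negligible or the field falls below ``floor_frac`` times
    its median (far background) are flagged and excluded from
    downstream masks.

    Returns the normalized volume and the boolean flag array of
    below-floor voxels.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if np.all(t1.data == 0):
        raise DegenerateInput("all-zero image")
    if np.any(t1.data < 0):
        raise ValueError("T1w intensities must be nonnegative")

    mx = ndimage.maximum_filter(t1.data, size=window)
    sigma_vox = [smooth_fwhm_mm * FWHM_TO_SIGMA / s for s in t1.spacing]

    pos = mx > 0
    vals = mx[pos]
    if vals.size and np.unique(vals).size > 1:
        support = pos & (mx >= sk_filters.threshold_otsu(vals))
    else:
        support = pos
    num = ndimage.gaussian_filter(mx * support, sigma_vox)
    den = ndimage.gaussian_filter(support.astype(float), sigma_vox)
    fieldmap = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-6)

    floor = floor_frac * np.median(fieldmap)
    flagged = fieldmap <= floor
    safe = np.where(flagged, np.inf, fieldmap)
    return t1.like(t1.data / safe), flagged


# ---------------------------------------------------------------------------
# histogram CSF threshold
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    value: float
    method: str          # "valley" or "otsu"
    fallback: bool


def estimate_csf_threshold(intensities: np.ndarray, n_bins: int = 256,
                           smooth_bins: float = 3.0) -> ThresholdResult:
    """Histogram threshold separating dark CSF/background from tissue.

    Finds the deepest local minimum of a kernel-smoothed histogram
    between the darkest mode and the next mode; falls back to Otsu's
    two-class variance-maximizing split when no interior valley exists
    (e.g. a unimodal histogram).
    """
    x = np.asarray(intensities, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size < 1000:
        raise DegenerateInput(f"need >= 1000 voxels, got {x.size}")

    hist, edges = np.histogram(x, bins=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    smooth = ndimage.gaussian_filter1d(hist.astype(float), smooth_bins)

    interior = np.arange(1, n_bins - 1)
    is_max = (smooth[interior] >= smooth[interior - 1]) & (smooth[interior] >= smooth[interior + 1])
    peaks = interior[is_max & (smooth[interior] > 0.05 * smooth.max())]
    # collapse plateau peaks
    modes = []
    for p in peaks:
        if not modes or p - modes[-1] > 2:
            modes.append(p)
    if len(modes) >= 2:
        lo, hi = modes[0], modes[1]
        seg = smooth[lo:hi + 1]
        valley = lo + int(np.argmin(seg))
        # a genuine valley dips well below both flanking modes; shallow dips
        # on a unimodal histogram fall through to Otsu
        if lo < valley < hi and smooth[valley] < 0.75 * min(smooth[lo], smooth[hi]):
            return ThresholdResult(float(centers[valley]), "valley", False)
    return ThresholdResult(float(sk_filters.threshold_otsu(x)), "otsu", True)


# ---------------------------------------------------------------------------
# skull strip / cerebrum mask
# ---------------------------------------------------------------------------

def skull_strip(
    norm_t1: ScalarVolume,
    head_mask: BinaryMask,
    threshold: float | None = None,
    min_object_voxels: int = 100,
    sharpen_amount: float = 1.0,
    sharpen_radius_vox: float = 1.0,
) -> tuple[BinaryMask, ThresholdResult]:
    """Build the cerebrum (GM+WM) mask from the normalized T1w image.

    Fixed pipeline: apply head mask -> upsample 2x (linear) -> unsharp
    sharpening -> CSF threshold -> remove small connected components
    (dura fragments) -> erode -> dilate (same 6-connected element) ->
    downsample to the original grid -> re-apply the same CSF threshold
    -> keep the dominant connected component.
    """
    masked = norm_t1.data * head_mask.data
    if threshold is None:
        thr = estimate_csf_threshold(masked[head_mask.data])
    else:
        thr = ThresholdResult(float(threshold), "given", False)

    up = ndimage.zoom(masked, 2.0, order=1, grid_mode=True, mode="nearest")
    sharp = up + sharpen_amount * (up - ndimage.gaussian_filter(up, sharpen_radius_vox))
    mask_up = sharp > thr.value
    mask_up = sk_morph.remove_small_objects(mask_up, max_size=min_object_voxels - 1)

    elem = ndimage.generate_binary_structure(3, 1)  # 6-connectivity cross
    mask_up = ndimage.binary_erosion(mask_up, elem)
    mask_up = ndimage.binary_dilation(mask_up, elem)

    # inclusive downsampling: keep any voxel with substantial overlap and
    # let the final threshold trim CSF the dilation pulled in
    down = ndimage.zoom(mask_up.astype(float), 0.5, order=1, grid_mode=True, mode="nearest") > 0.25
    final = down & (norm_t1.data > thr.value) & head_mask.data

    lab, n = ndimage.label(final)
    if n == 0:
        raise SegmentationFailure("empty cerebrum mask")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    final = lab == (1 + int(np.argmax(sizes)))
    return BinaryMask(final, norm_t1.spacing, tag="cerebrum"), thr


# ---------------------------------------------------------------------------
# spatially regularized fuzzy c-means (two tissue classes)
# ---------------------------------------------------------------------------

@dataclass
class MembershipVolume:
    """Per-class fuzzy memberships over a mask, plus class centroids.

    Class 0 is the darker class (GM in normalized T1w), class 1 the
    brighter (WM); centroids are kept sorted ascending.
    """

    memberships: np.ndarray          # (2, *grid), zero outside mask
    centroids: np.ndarray            # (2,), ascending
    mask: np.ndarray
    hard_labels: np.ndarray          # 0 outside mask, 1 = class0 (GM), 2 = class1 (WM)
    converged: bool
    n_iter: int
    objective_history: list[float] = field(default_factory=list)


def fuzzy_segment(
    vol: ScalarVolume,
    mask: np.ndarray,
    n_classes: int = 2,
    m: float = 2.0,
    spatial_beta: float = 0.3,
    tol: float = 1e-4,
    max_iter: int = 200,
    init: str = "percentile",
    seed: int | None = None,
) -> MembershipVolume:
    """Fuzzy c-means with a neighbourhood membership-smoothness penalty.

    Minimizes ``sum_ik u_ik^m d_ik^2 + (beta/2) sum_ik u_ik^m sum_{j in
    N(i)} sum_{l != k} u_jl^m`` by alternating centroid and membership
    updates (6-neighbour stencil).  ``spatial_beta`` is scaled by the
    squared intensity spread so its effect is invariant to intensity
    units.  With ``spatial_beta=0`` this is classical FCM.

    Initialization is deterministic from histogram percentiles
    (25th/75th); ``init="random"`` draws centroids with ``seed``.
    """
    if n_classes != 2:
        raise NotImplementedError("the pipeline segments exactly two classes (GM, WM)")
    x = vol.data[mask]
    if x.size == 0:
        raise DegenerateInput("empty mask")
    if np.unique(x).size < n_classes:
        raise DegenerateInput("fewer distinct intensities than classes")

    if init == "percentile":
        c = np.percentile(x, [25, 75]).astype(float)
    elif init == "random":
        rng = np.random.default_rng(seed)
        c = np.sort(rng.choice(x, size=2, replace=False).astype(float))
    else:
        raise ValueError(f"unknown init {init!r}")
    if c[0] == c[1]:
        c = np.array([x.min(), x.max()], dtype=float)

    beta_abs = spatial_beta * float(np.var(x))
    shape = vol.shape
    expo = 1.0 / (m - 1.0)

    u = np.zeros((2,) + shape)
    # initial memberships from plain FCM distances
    d2 = np.stack([(vol.data - ck) ** 2 for ck in c])
    d2 = np.maximum(d2, 1e-30)
    w = d2 ** (-expo)
    u_init = w / w.sum(axis=0)
    for k in range(2):
        u[k][mask] = u_init[k][mask]

    kernel = np.zeros((3, 3, 3))
    kernel[1, 1, 0] = kernel[1, 1, 2] = 1
    kernel[1, 0, 1] = kernel[1, 2, 1] = 1
    kernel[0, 1, 1] = kernel[2, 1, 1] = 1

    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        um = u**m
        # centroids
        c_new = np.array([
            float((um[k][mask] * x).sum() / max(um[k][mask].sum(), 1e-30))
            for k in range(2)
        ])
        order = np.argsort(c_new)
        c_new = c_new[order]
        u = u[order]
        um = um[order]

        # spatial penalty: sum over neighbours of other-class memberships^m
        neigh = np.stack([ndimage.convolve(um[k], kernel, mode="constant") for k in range(2)])
        other = neigh[::-1]  # for class k, neighbours' membership in the other class

        d2 = np.stack([(vol.data - ck) ** 2 for ck in c_new])
        cost = d2 + beta_abs * other
        cost = np.maximum(cost, 1e-30)
        w = cost ** (-expo)
        u_new = w / w.sum(axis=0)
        for k in range(2):
            u_new[k][~mask] = 0.0

        history.append(float(((u_new**m) * d2)[:, mask].sum()
                             + 0.5 * beta_abs * ((u_new**m) * other)[:, mask].sum()))

        shift = float(np.max(np.abs(c_new - c)))
        c = c_new
        u = u_new
        if shift < tol:
            converged = True
            break

    hard = np.zeros(shape, dtype=np.int16)
    hard[mask] = 1 + np.argmax(u[:, mask], axis=0).astype(np.int16)
    return MembershipVolume(u, c, mask, hard, converged, it, history)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / float(denom)


def segment_t1(
    t1: ScalarVolume,
    head_mask: np.ndarray | None = None,
    spatial_beta: float = 0.3,
) -> dict:
    """Full chain: normalize -> threshold/strip -> fuzzy GM/WM segment.

    Returns a dict with the normalized volume, cerebrum mask, GM and WM
    masks, the membership volume and the threshold report.  The GM/WM
    masks come from the hard FCM labels restricted to the cerebrum mask.
    """
    # magnitude images are nonnegative; additive-noise simulations can dip
    # slightly below zero in the background
    t1 = t1.like(np.maximum(t1.data, 0.0))
    if head_mask is None:
        head_mask = t1.data > 0
    norm, flagged = local_intensity_normalize(t1)
    head = BinaryMask(head_mask & ~flagged, t1.spacing, tag="head")
    cerebrum, thr = skull_strip(norm, head)
    memb = fuzzy_segment(norm, cerebrum.data, spatial_beta=spatial_beta)
    gm = memb.hard_labels == 1
    wm = memb.hard_labels == 2
    return {
        "normalized": norm,
        "flagged": flagged,
        "cerebrum": cerebrum,
        "threshold": thr,
        "membership": memb,
        "gm_mask": BinaryMask(gm, t1.spacing, tag="GM"),
        "wm_mask": BinaryMask(wm, t1.spacing, tag="WM"),
    }
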