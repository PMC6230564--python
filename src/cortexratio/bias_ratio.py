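"""Residual bias estimation (sqrt-product method) and the corrected ratio.

Without measured B1 maps, the residual multiplicative bias common to the
two contrasts is estimated from the images themselves: myelin-sensitive
contrast is *inverted* between T1w and T2w, so the square root of their
product cancels tissue contrast to first order and leaves the smooth
shared bias.  The estimate is normalized to unit mean inside the
cerebrum mask and smoothed within the mask (Gaussian, sigma 5 mm —
sigma, not FWHM).  Dividing both contrasts by it and then dividing T1w
by T2w yields the corrected ratio image.  Note the shared (receive)
bias cancels in the ratio identically, with or without this step; the
sqrt-product field additionally flattens each contrast individually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import BinaryMask, ScalarVolume


class InsufficientSupport(ValueError):
    pass


class RatioQualityError(RuntimeError):
    pass


@dataclass
class BiasField:
    """Positive multiplicative field, unit mean inside its mask."""

    field: ScalarVolume
    mask: np.ndarray
    sigma_mm: float

    def __post_init__(self) -> None:
        inside = self.field.data[self.mask]
        if np.any(inside <= 0):
            raise ValueError("bias field must be strictly positive in the mask")
        if abs(inside.mean() - 1.0) > 1e-6:
            raise ValueError("bias field must have unit mean in the mask")


def masked_gaussian(data: np.ndarray, mask: np.ndarray, sigma_vox) -> np.ndarray:
    """Gaussian smoothing confined to a mask with renormalized weights.

    smooth(f*mask)/smooth(mask): background voxels contribute no weight,
    so values at the mask edge are averages over in-mask neighbours
    only.
    """
    m = mask.astype(float)
    num = ndimage.gaussian_filter(data * m, sigma_vox)
    den = ndimage.gaussian_filter(m, sigma_vox)
    out = np.zeros_like(data, dtype=float)
    good = den > 1e-12
    out[good] = num[good] / den[good]
    return out


def estimate_bias_field(
    t1: ScalarVolume,
    t2: ScalarVolume,
    cerebrum: BinaryMask,
    sigma_mm: float = 5.0,
    floor: float = 1e-3,
) -> BiasField:
    """sqrt(T1w * T2w) inside the mask, unit-normalized then mask-smoothed.

    The smoothing kernel uses a standard deviation of ``sigma_mm``
    (taken literally as sigma).  A final renormalization restores unit
    mean after smoothing; a positivity floor guards downstream
    divisions.
    """
    if not (t1.same_grid(t2) and t1.shape == cerebrum.shape):
        raise ValueError("inputs must share one grid")
    mask = cerebrum.data
    if mask.sum() < 100:
        raise InsufficientSupport(f"mask has {int(mask.sum())} voxels (< 100)")
    if np.any(t1.data[mask] < 0) or np.any(t2.data[mask] < 0):
        raise ValueError("intensities must be nonnegative")

    raw = np.sqrt(np.maximum(t1.data * t2.data, 0.0))
    mean_in = raw[mask].mean()
    if mean_in <= 0:
        raise InsufficientSupport("zero mean intensity inside the mask")
    raw = raw / mean_in

    sigma_vox = [sigma_mm / s for s in t1.spacing]
    sm = masked_gaussian(raw, mask, sigma_vox)
    sm = np.maximum(sm, floor)
    sm = sm / sm[mask].mean()  # unit mean in mask, enforced post-smoothing
    out = np.ones_like(sm)
    out[mask] = sm[mask]
    return BiasField(t1.like(out), mask, sigma_mm)


def correct_bias(vol: ScalarVolume, field: BiasField,
                 floor: float = 1e-6) -> tuple[ScalarVolume, np.ndarray]:
    """Divide by the bias field inside its mask; outside is left unchanged.

    Returns the corrected volume and a flag array: True where the voxel
    is outside the mask or the field fell below the floor (excluded).
    """
    if vol.shape != field.field.shape:
        raise ValueError("volume and field grids differ")
    f = field.field.data
    flagged = ~field.mask | (f < floor)
    out = vol.data.copy()
    ok = field.mask & (f >= floor)
    out[ok] = vol.data[ok] / f[ok]
    return vol.like(out), flagged


def compute_ratio(
    t1c: ScalarVolume,
    t2c: ScalarVolume,
    mask: np.ndarray,
    floor_quantile: float = 0.01,
    max_excluded_frac: float = 0.20,
) -> tuple[ScalarVolume, np.ndarray]:
    """Voxelwise T1w/T2w inside the mask with a denominator floor.

    The floor is the ``floor_quantile`` quantile of T2w inside the mask;
    voxels at or below it get NaN (a missing-value marker) and are
    excluded from every downstream mean.  Raises
    :class:`RatioQualityError` if more than ``max_excluded_frac`` of the
    mask is excluded.
    """
    if not t1c.same_grid(t2c):
        raise ValueError("grids differ")
    t2_in = t2c.data[mask]
    if t2_in.size == 0:
        raise ValueError("empty mask")
    floor = np.quantile(t2_in, floor_quantile)
    floor = max(floor, 0.0)

    ratio = np.full(t1c.shape, np.nan)
    ok = mask & (t2c.data >= floor) & (t2c.data > 0)
    ratio[ok] = t1c.data[ok] / t2c.data[ok]
    excluded = mask & ~ok
    frac = excluded.sum() / mask.sum()
    if frac > max_excluded_frac:
        raise RatioQualityError(
            f"{frac:.1%} of mask voxels excluded by the denominator floor"
        )
    return ScalarVolume(ratio, t1c.spacing), excluded


def corrected_ratio(
    t1: ScalarVolume,
    t2: ScalarVolume,
    cerebrum: BinaryMask,
    sigma_mm: float = 5.0,
    floor_quantile: float = 0.01,
) -> tuple[ScalarVolume, BiasField, np.ndarray]:
    """Convenience chain: estimate field, correct both contrasts, divide."""
    field = estimate_bias_field(t1, t2, cerebrum, sigma_mm)
    t1c, _ = correct_bias(t1, field)
    t2c, _ = correct_bias(t2, field)
    ratio, excluded = compute_ratio(t1c, t2c, cerebrum.data, floor_quantile)
    return ratio, field, excluded
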