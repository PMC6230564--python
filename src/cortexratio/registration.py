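"""Rigid intra-subject registration of the T2w image to the T1w image.

Both contrasts are acquired in the same session but on slightly offset
grids; the pipeline brings them onto one grid with a 6-parameter rigid
transform before any ratio is formed.  The similarity metric is
normalized cross-correlation (NCC) over the fixed-image foreground,
optimized coarse-to-fine with a derivative-free Powell search — robust
for the small offsets (a few mm / a few degrees) seen within a session.

Transform convention: a :class:`RigidTransform` maps *output/reference*
world coordinates to *moving* world coordinates (pull-back), so
``resample(moving, T, reference)`` evaluates ``moving(T(x))`` at every
reference voxel ``x``.  World coordinates are ``index * spacing`` (see
:mod:`cortexratio.volume`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .volume import BinaryMask, ScalarVolume


class RegistrationFailure(RuntimeError):
    """Optimizer did not converge; carries the best transform found."""

    def __init__(self, message: str, best: "RigidTransform"):
        super().__init__(message)
        self.best = best


@dataclass
class RigidTransform:
    """Rotation (deg, about RAS axes) + translation (mm) about a center (mm).

    ``T(x) = R @ (x - center) + center + translation`` with
    ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` (extrinsic xyz order).
    """

    rotations_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translations_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotations_deg = tuple(float(v) for v in self.rotations_deg)
        self.translations_mm = tuple(float(v) for v in self.translations_mm)
        self.center_mm = tuple(float(v) for v in self.center_mm)
        if not all(np.isfinite(self.rotations_deg + self.translations_mm + self.center_mm)):
            raise ValueError("non-finite transform parameters")

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotations_deg, degrees=True).as_matrix()

    def as_matrix(self) -> np.ndarray:
        """Homogeneous 4x4 world-coordinate matrix."""
        R = self.rotation_matrix
        c = np.asarray(self.center_mm)
        t = np.asarray(self.translations_mm)
        M = np.eye(4)
        M[:3, :3] = R
        M[:3, 3] = c + t - R @ c
        return M

    @classmethod
    def from_matrix(cls, M: np.ndarray, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        R = np.asarray(M)[:3, :3]
        rot = Rotation.from_matrix(R).as_euler("xyz", degrees=True)
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(M)[:3, 3] - c + R @ c
        return cls(tuple(rot), tuple(t), tuple(c))

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        """Apply to an (N, 3) array of world coordinates."""
        M = self.as_matrix()
        pts = np.atleast_2d(points_mm)
        return pts @ M[:3, :3].T + M[:3, 3]

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        return RigidTransform.from_matrix(self.as_matrix() @ other.as_matrix(), self.center_mm)

    def inverse(self) -> "RigidTransform":
        return RigidTransform.from_matrix(np.linalg.inv(self.as_matrix()), self.center_mm)

    @property
    def is_identity(self) -> bool:
        return np.allclose(self.as_matrix(), np.eye(4), atol=1e-12)

    # --- serialization ----------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "rotations_deg": list(self.rotations_deg),
            "translations_mm": list(self.translations_mm),
            "center_mm": list(self.center_mm),
            "convention": "pullback; T(x)=Rz*Ry*Rx@(x-c)+c+t; world=index*spacing (RAS)",
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "RigidTransform":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            tuple(payload["rotations_deg"]),
            tuple(payload["translations_mm"]),
            tuple(payload["center_mm"]),
        )


def resample(
    vol: ScalarVolume,
    transform: RigidTransform,
    reference: ScalarVolume | None = None,
    interpolation: str = "linear",
) -> tuple[ScalarVolume, BinaryMask]:
    """Resample ``vol`` under ``transform`` onto the ``reference`` grid.

    Returns the resampled volume and a validity mask that is False where
    the sampled location fell outside ``vol``'s field of view (those
    voxels are set to 0).
    """
    if reference is None:
        reference = vol
    order = {"linear": 1, "nearest": 0}[interpolation]
    M = transform.as_matrix()
    S_in = np.diag(vol.spacing)
    S_out = np.diag(reference.spacing)
    # output index -> input index: S_in^-1 @ (R @ S_out @ i + b)
    A = np.linalg.inv(S_in) @ M[:3, :3] @ S_out
    b = np.linalg.inv(S_in) @ M[:3, 3]
    out = ndimage.affine_transform(
        vol.data, A, offset=b, output_shape=reference.shape, order=order,
        mode="constant", cval=0.0, prefilter=False,
    )
    valid = ndimage.affine_transform(
        np.ones(vol.shape), A, offset=b, output_shape=reference.shape, order=0,
        mode="constant", cval=0.0, prefilter=False,
    ) > 0.5
    out[~valid] = 0.0
    return ScalarVolume(out, reference.spacing), BinaryMask(valid, reference.spacing, tag="fov")


def _foreground_mask(vol: ScalarVolume, frac: float = 0.1) -> np.ndarray:
    lo, hi = np.percentile(vol.data, [1, 99])
    return vol.data > lo + frac * (hi - lo)


def _ncc(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    av = a[mask]
    bv = b[mask]
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av @ av) * (bv @ bv))
    if denom == 0:
        return 0.0
    return float((av @ bv) / denom)


def _downsample(vol: ScalarVolume, factor: int) -> ScalarVolume:
    if factor == 1:
        return vol
    sigma = 0.5 * factor  # anti-alias before decimation
    sm = ndimage.gaussian_filter(vol.data, sigma)
    data = sm[::factor, ::factor, ::factor]
    return ScalarVolume(data, tuple(s * factor for s in vol.spacing))


def rigid_register(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    levels: tuple[int, ...] = (4, 2, 1),
    xtol: float = 1e-3,
    ftol: float = 1e-7,
    maxiter: int = 200,
    initial: RigidTransform | None = None,
) -> tuple[RigidTransform, float]:
    """Recover the rigid transform aligning ``moving`` to ``fixed``.

    Maximizes NCC over the fixed-image foreground with a multi-resolution
    Powell search.  Returns the transform (pull-back convention: feed it
    to :func:`resample` to bring ``moving`` onto ``fixed``'s grid) and
    the NCC value at the optimum.

    Raises :class:`RegistrationFailure` (carrying the best-so-far
    transform) if Powell exhausts its iteration cap at the finest level.
    """
    if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
        raise ValueError("cannot register constant images")

    fg_full = _foreground_mask(fixed)
    com_idx = ndimage.center_of_mass(fg_full.astype(float))
    center = tuple(float(i * s) for i, s in zip(com_idx, fixed.spacing))

    params = np.zeros(6)
    if initial is not None:
        params = np.array(initial.rotations_deg + initial.translations_mm, dtype=float)

    converged = True
    for level in levels:
        fx = _downsample(fixed, level)
        mv = _downsample(moving, level)
        fg = _foreground_mask(fx)
        if fg.sum() < 32:
            fg = fx.data > fx.data.mean()

        def neg_ncc(p, fx=fx, mv=mv, fg=fg):
            T = RigidTransform(tuple(p[:3]), tuple(p[3:]), center)
            res, valid = resample(mv, T, fx, "linear")
            m = fg & valid.data
            if m.sum() < 16:
                return 1.0
            return -_ncc(res.data, fx.data, m)

        res = optimize.minimize(
            neg_ncc, params, method="Powell",
            options={"xtol": xtol, "ftol": ftol, "maxiter": maxiter},
        )
        params = res.x
        if level == levels[-1]:
            converged = bool(res.success) or res.status == 0
            metric = -float(res.fun)

    best = RigidTransform(tuple(params[:3]), tuple(params[3:]), center)
    if not converged:
        raise RegistrationFailure("Powell search hit its iteration cap", best)
    return best, metric
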