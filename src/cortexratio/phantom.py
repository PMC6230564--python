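"""Synthetic multi-subject T1w/T2w phantom cohorts with full ground truth.

The real study images (multi-site structural MRI of Huntington's disease
gene carriers and controls) are not publicly deposited, so the pipeline
is exercised on phantoms that reproduce the statistical and artifactual
structure the analysis assumes:

* a cortical grey-matter ribbon wrapped around a white-matter core,
  separated from a thin dura shell by CSF — modelled as nested
  ellipsoids with an optional sinusoidal surface perturbation so the
  ribbon has non-trivial curvature;
* group-dependent multiplicative increases of the T1w/T2w ratio
  localized to chosen ROIs (the disease effect), realized by scaling
  the T2w signal down inside those ROIs;
* smooth multiplicative bias fields: a receive field shared by both
  contrasts (it cancels in the ratio) and contrast-specific transmit
  fields (they do not);
* per-site global intensity scales and site-specific bias-field styles;
* an age trend on the clean grey-matter ratio;
* additive Gaussian (or Rician) noise and a small rigid misalignment of
  the T2w grid.

Every generated quantity is recorded in a :class:`PhantomTruth` so each
pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .registration import RigidTransform, resample
from .volume import ScalarVolume, save_labels

BACKGROUND = 0  # CSF shares label 0 with background
GM = 1
WM = 2
DURA = 3

GROUP_LEVELS = ("Control", "PreHD-A", "PreHD-B", "HD1", "HD2")


class InvalidGeometry(ValueError):
    pass


class InvalidEffect(ValueError):
    pass


class InvalidField(ValueError):
    pass


class OutOfFOV(ValueError):
    pass


# ---------------------------------------------------------------------------
# geometry & truth containers
# ---------------------------------------------------------------------------

@dataclass
class PhantomGeometry:
    """Nested-ellipsoid head model.  All lengths in mm.

    ``wm_radii`` are the semi-axes of the white-matter surface; the GM
    ribbon, a CSF gap and a dura shell are stacked outward from it with
    the given thicknesses.  ``perturb_amp`` modulates the surfaces with
    a sinusoid in the angular coordinates (fraction of radius) so the
    cortex is curved rather than exactly ellipsoidal.
    """

    wm_radii: tuple[float, float, float] = (14.0, 16.0, 15.0)
    ribbon_thickness: float = 3.0
    csf_gap: float = 2.0
    dura_thickness: float = 1.0
    perturb_amp: float = 0.03
    perturb_freq: int = 3


@dataclass
class TissueMeans:
    """Clean per-tissue intensity for each contrast (arbitrary units)."""

    t1: dict[str, float] = field(
        default_factory=lambda: {"wm": 1.0, "gm": 0.55, "csf": 0.18, "dura": 0.30}
    )
    t2: dict[str, float] = field(
        default_factory=lambda: {"wm": 0.35, "gm": 0.60, "csf": 1.0, "dura": 0.30}
    )


@dataclass
class PhantomTruth:
    """Ground truth for one synthetic subject."""

    tissue_labels: np.ndarray      # {0: background/CSF, 1: GM, 2: WM, 3: dura}
    roi_labels: np.ndarray         # 0 outside GM, 1..R inside
    csf_mask: np.ndarray           # distinguishes CSF from background within label 0
    spacing: tuple[float, float, float]
    receive_field: ScalarVolume | None = None
    transmit_field_t1: ScalarVolume | None = None
    transmit_field_t2: ScalarVolume | None = None
    true_rigid: RigidTransform | None = None
    effect_map: dict[int, float] = field(default_factory=dict)  # roi_id -> delta applied
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if np.any((self.roi_labels > 0) & (self.tissue_labels != GM)):
            raise ValueError("roi_labels must be zero outside GM")
        for f in (self.receive_field, self.transmit_field_t1, self.transmit_field_t2):
            if f is not None and np.any(f.data <= 0):
                raise InvalidField("bias fields must be strictly positive")

    @property
    def n_rois(self) -> int:
        return int(self.roi_labels.max())

    def gm_mask(self) -> np.ndarray:
        return self.tissue_labels == GM

    def wm_mask(self) -> np.ndarray:
        return self.tissue_labels == WM


# ---------------------------------------------------------------------------
# sphere sectorization (ROI parcellation stand-in)
# ---------------------------------------------------------------------------

def sector_partition(theta: np.ndarray, phi: np.ndarray, n_rois: int) -> np.ndarray:
    """Partition directions into ``n_rois`` contiguous angular sectors.

    Rings of equal area in cos(theta), each ring split into equal
    azimuthal bins; bins per ring allocated by largest remainder so the
    sector count is exactly ``n_rois``.  Deterministic.
    """
    if n_rois < 1:
        raise ValueError("n_rois must be >= 1")
    n_rings = max(1, int(round(np.sqrt(n_rois / 2.0))))
    base = n_rois // n_rings
    counts = np.full(n_rings, base)
    counts[: n_rois - base * n_rings] += 1
    assert counts.sum() == n_rois

    ct = np.clip(np.cos(theta), -1.0, 1.0)
    # ring index from equal-area bands of cos(theta) in [-1, 1]
    ring = np.minimum(((1.0 - ct) / 2.0 * n_rings).astype(int), n_rings - 1)
    labels = np.zeros(theta.shape, dtype=np.int32)
    offset = 0
    ph = np.mod(phi, 2 * np.pi)
    for r in range(n_rings):
        sel = ring == r
        nb = counts[r]
        b = np.minimum((ph[sel] / (2 * np.pi) * nb).astype(int), nb - 1)
        labels[sel] = offset + 1 + b
        offset += nb
    return labels


# ---------------------------------------------------------------------------
# phantom construction
# ---------------------------------------------------------------------------

def make_brain_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    geometry: PhantomGeometry | None = None,
    tissue_means: TissueMeans | None = None,
    n_rois: int = 82,
    seed: int | None = None,
) -> tuple[ScalarVolume, ScalarVolume, PhantomTruth]:
    """Build one clean (noise- and bias-free) phantom subject.

    Returns piecewise-constant T1w and T2w volumes plus the ground
    truth.  The construction is fully deterministic given its arguments;
    ``seed`` is accepted for interface symmetry with the noisy stages
    but the clean phantom does not draw random numbers.
    """
    geometry = geometry or PhantomGeometry()
    tissue_means = tissue_means or TissueMeans()
    g = geometry
    spacing = tuple(float(s) for s in spacing)

    if min(g.wm_radii) <= 0 or g.ribbon_thickness <= 0:
        raise InvalidGeometry("radii and ribbon thickness must be positive")
    if g.ribbon_thickness < 2 * min(spacing):
        raise InvalidGeometry("ribbon thinner than 2 voxels at this spacing")

    center = tuple((n - 1) / 2.0 * s for n, s in zip(shape, spacing))
    ax = [np.arange(n) * s - c for n, s, c in zip(shape, spacing, center)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")

    a, b, c = g.wm_radii
    m = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    rho = np.sqrt(X**2 + Y**2 + Z**2)
    zn = np.divide(Z, rho, out=np.zeros_like(Z), where=rho > 0)
    theta = np.arccos(np.clip(zn, -1, 1))
    phi = np.arctan2(Y, X)

    if g.perturb_amp:
        m = m / (1.0 + g.perturb_amp * np.sin(g.perturb_freq * theta) * np.cos(g.perturb_freq * phi))

    # signed distance (mm, approximate for anisotropic radii) from the WM surface
    r_eff = 3.0 / (1.0 / a + 1.0 / b + 1.0 / c)
    d = (m - 1.0) * r_eff

    labels = np.zeros(shape, dtype=np.int16)
    labels[d < 0] = WM
    gm = (d >= 0) & (d < g.ribbon_thickness)
    labels[gm] = GM
    csf = (d >= g.ribbon_thickness) & (d < g.ribbon_thickness + g.csf_gap)
    dura = (d >= g.ribbon_thickness + g.csf_gap) & (
        d < g.ribbon_thickness + g.csf_gap + g.dura_thickness
    )
    labels[dura] = DURA

    if not gm.any():
        raise InvalidGeometry("geometry leaves no GM voxels")

    roi = np.zeros(shape, dtype=np.int32)
    roi[gm] = sector_partition(theta[gm], phi[gm], n_rois)

    def paint(means: dict[str, float]) -> np.ndarray:
        out = np.zeros(shape)
        out[labels == WM] = means["wm"]
        out[labels == GM] = means["gm"]
        out[csf] = means["csf"]
        out[labels == DURA] = means["dura"]
        return out

    t1 = ScalarVolume(paint(tissue_means.t1), spacing)
    t2 = ScalarVolume(paint(tissue_means.t2), spacing)
    truth = PhantomTruth(labels, roi, csf, spacing)
    return t1, t2, truth


def standard_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    n_rois: int = 82,
    **kwargs,
) -> tuple[ScalarVolume, ScalarVolume, PhantomTruth]:
    """The default test subject: radii scaled to fill ~2/3 of the FOV.

    Keeps the cortical ribbon, CSF gap and dura at their default
    millimetre thicknesses while the brain occupies as much of the grid
    as the outer shells allow, mirroring the real-data regime where the
    normalization and smoothing kernels are small relative to the head.
    """
    fov = min(n * s for n, s in zip(shape, spacing))
    r = 0.32 * fov
    geometry = PhantomGeometry(wm_radii=(0.95 * r, 1.05 * r, r))
    return make_brain_phantom(shape, spacing, geometry, n_rois=n_rois, **kwargs)


def apply_group_effect(
    t2_clean: ScalarVolume, truth: PhantomTruth, effect_map: dict[int, float]
) -> ScalarVolume:
    """Inject the disease effect: raise the clean ratio by (1 + delta) per ROI.

    The ratio increase is realized by dividing the T2w signal of GM
    voxels inside each targeted ROI by ``1 + delta`` — exact truth
    bookkeeping with T1w untouched.
    """
    out = t2_clean.data.copy()
    for roi_id, delta in effect_map.items():
        if delta <= -1:
            raise InvalidEffect(f"delta={delta} for ROI {roi_id} is <= -1")
        if delta == 0:
            continue
        sel = truth.roi_labels == roi_id
        out[sel] = out[sel] / (1.0 + delta)
    truth.effect_map = dict(effect_map)
    return t2_clean.like(out)


# ---------------------------------------------------------------------------
# bias fields & noise
# ---------------------------------------------------------------------------

def polynomial_bias_field(
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    amplitude: float,
    rng: np.random.Generator,
    degree: int = 2,
) -> ScalarVolume:
    """Smooth positive field: exp of a random low-order 3D polynomial.

    Coefficients are drawn N(0, amplitude^2) for every monomial of total
    degree 1..``degree`` in coordinates normalized to [-1, 1]; the
    exponential keeps the field strictly positive and multiplicative.
    """
    ax = [np.linspace(-1, 1, n) for n in shape]
    U, V, W = np.meshgrid(*ax, indexing="ij")
    terms = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                if 1 <= i + j + k <= degree:
                    terms.append(U**i * V**j * W**k)
    coeffs = rng.normal(0.0, amplitude, size=len(terms))
    poly = np.zeros(shape)
    for cf, t in zip(coeffs, terms):
        poly += cf * t
    return ScalarVolume(np.exp(poly), spacing)


def apply_bias_and_noise(
    t1: ScalarVolume,
    t2: ScalarVolume,
    truth: PhantomTruth,
    seed: int,
    noise_sigma_frac: float = 0.02,
    noise_model: str = "gaussian",
) -> tuple[ScalarVolume, ScalarVolume]:
    """Multiply by the truth's bias fields and add measurement noise.

    ``t1_obs = t1 * receive * transmit_t1 + noise`` and likewise for
    T2w with its own transmit field; the receive field is shared.  The
    noise standard deviation is ``noise_sigma_frac`` times the mean
    clean GM T1w intensity, drawn independently for the two contrasts.
    Rician noise (magnitude of a complex signal with i.i.d. Gaussian
    components) is available as ``noise_model="rician"``.
    """
    recv = truth.receive_field
    tx1 = truth.transmit_field_t1
    tx2 = truth.transmit_field_t2
    ones = ScalarVolume(np.ones(t1.shape), t1.spacing)
    recv = recv if recv is not None else ones
    tx1 = tx1 if tx1 is not None else ones
    tx2 = tx2 if tx2 is not None else ones
    for f in (recv, tx1, tx2):
        if np.any(f.data <= 0):
            raise InvalidField("bias fields must be strictly positive")

    gm = truth.gm_mask()
    sigma = float(noise_sigma_frac) * float(t1.data[gm].mean()) if gm.any() else 0.0
    truth.noise_sigma = sigma
    rng = np.random.default_rng(seed)

    def corrupt(vol: ScalarVolume, tx: ScalarVolume) -> ScalarVolume:
        biased = vol.data * recv.data * tx.data
        if sigma == 0:
            return vol.like(biased)
        if noise_model == "gaussian":
            noisy = biased + rng.normal(0.0, sigma, vol.shape)
        elif noise_model == "rician":
            n1 = rng.normal(0.0, sigma, vol.shape)
            n2 = rng.normal(0.0, sigma, vol.shape)
            noisy = np.sqrt((biased + n1) ** 2 + n2**2)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
        return vol.like(noisy)

    return corrupt(t1, tx1), corrupt(t2, tx2)


def apply_misalignment(t2_obs: ScalarVolume, rigid: RigidTransform,
                       brain_mask: np.ndarray | None = None) -> ScalarVolume:
    """Resample the observed T2w under a small rigid map (linear interp).

    Simulates the T2w scan sitting on a slightly different grid than the
    T1w.  Raises :class:`OutOfFOV` if the transform pushes brain voxels
    outside the field of view.
    """
    rot = np.abs(rigid.rotations_deg)
    tr = np.abs(rigid.translations_mm)
    if np.any(rot > 15) or np.any(tr > 10):
        raise ValueError("misalignment outside the phantom regime (<=15 deg, <=10 mm)")
    moved, valid = resample(t2_obs, rigid, t2_obs, "linear")
    if brain_mask is not None and np.any(brain_mask & ~valid.data):
        raise OutOfFOV("transform moves brain voxels outside the field of view")
    return moved


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

# age means/SDs chosen to mirror a staged HD observational cohort
DEFAULT_AGE_DIST = {
    "Control": (46.1, 10.5),
    "PreHD-A": (40.6, 8.7),
    "PreHD-B": (39.6, 8.8),
    "HD1": (47.1, 10.2),
    "HD2": (50.9, 8.8),
}


@dataclass
class CohortSpec:
    """Everything needed to simulate a cohort deterministically."""

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    geometry: PhantomGeometry = field(default_factory=PhantomGeometry)
    tissue_means: TissueMeans = field(default_factory=TissueMeans)
    n_rois: int = 82
    groups: tuple[str, ...] = GROUP_LEVELS
    sites: tuple[str, ...] = ("site1", "site2")
    # either one count for every cell or a per-group mapping (per site)
    n_per_group_per_site: int | dict[str, int] = 6
    age_dist: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AGE_DIST)
    )
    age_slope_per_year: float = -0.001   # fractional clean-ratio change per year
    age_reference: float = 45.0
    site_scale_sd: float = 0.05          # lognormal SD of per-site global scale, per contrast
    receive_amp: float = 0.15            # polynomial coefficient scale, receive field
    transmit_amp: float = 0.0075           # polynomial coefficient scale, transmit fields
    effect_map: dict[str, dict[int, float]] = field(default_factory=dict)
    noise_model: str = "gaussian"
    noise_sigma_frac: float = 0.02
    # per-subject artifact severity: a lognormal factor that jointly scales
    # the noise level and the transmit-field amplitude, emulating subjects
    # whose scans are globally worse (motion, coil loading); this is the
    # variance structure the 1/SD regression weights are meant to capture
    artifact_log_sd: float = 0.4
    misalign_rot_deg: float = 0.0        # max |rotation| per axis drawn per subject
    misalign_trans_mm: float = 0.0       # max |translation| per axis
    seed: int = 0

    def group_counts(self) -> dict[str, int]:
        """Subjects per group per site, normalized to a mapping."""
        if isinstance(self.n_per_group_per_site, dict):
            return dict(self.n_per_group_per_site)
        return {g: int(self.n_per_group_per_site) for g in self.groups}

    def validate(self) -> None:
        if "Control" not in self.groups:
            raise ValueError("cohort must contain a Control group")
        counts = self.group_counts()
        if any(counts.get(g, 0) < 1 for g in self.groups):
            raise ValueError("need at least one subject per group per site")
        for grp in self.effect_map:
            if grp not in self.groups:
                raise ValueError(f"effect_map group {grp!r} not in groups")
            for roi_id, delta in self.effect_map[grp].items():
                if delta <= -1:
                    raise InvalidEffect(f"delta={delta} <= -1 in group {grp}")

    # YAML round trip -------------------------------------------------

    def to_yaml(self, path: str) -> None:
        payload = asdict(self)
        payload["geometry"] = asdict(self.geometry)
        payload["tissue_means"] = asdict(self.tissue_means)
        with open(path, "w") as fh:
            yaml.safe_dump(_plain(payload), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["geometry"] = PhantomGeometry(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in payload.get("geometry", {}).items()
        })
        payload["tissue_means"] = TissueMeans(**payload.get("tissue_means", {}))
        for key in ("shape", "spacing", "groups", "sites"):
            if key in payload:
                payload[key] = tuple(payload[key])
        if "age_dist" in payload:
            payload["age_dist"] = {k: tuple(v) for k, v in payload["age_dist"].items()}
        if "effect_map" in payload:
            payload["effect_map"] = {
                g: {int(r): float(d) for r, d in rois.items()}
                for g, rois in payload["effect_map"].items()
            }
        return cls(**payload)


def _plain(obj):
    """Recursively convert tuples/np scalars for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


@dataclass
class SubjectRecord:
    """Covariates plus QC status for one subject."""

    subject_id: str
    group: str
    age: float
    site: str
    qc_excluded: bool = False
    qc_reason: str = ""


@dataclass
class SimulatedSubject:
    record: SubjectRecord
    t1_obs: ScalarVolume
    t2_obs: ScalarVolume
    truth: PhantomTruth


def iter_cohort(spec: CohortSpec, seed: int | None = None):
    """Yield :class:`SimulatedSubject` objects for a cohort, in manifest order.

    All subjects share the clean phantom geometry (phantoms come with
    known anatomical correspondence); per-subject variation enters
    through site scales, bias-field draws, the age trend, group effects,
    noise and misalignment.  Deterministic for a given spec and seed.
    """
    spec.validate()
    master = spec.seed if seed is None else seed
    t1_clean, t2_clean, truth0 = make_brain_phantom(
        spec.shape, spec.spacing, spec.geometry, spec.tissue_means, spec.n_rois
    )
    gm = truth0.gm_mask()
    site_rng = np.random.default_rng((master, 0xBEEF))
    site_scales = {
        s: (float(np.exp(site_rng.normal(0, spec.site_scale_sd))),
            float(np.exp(site_rng.normal(0, spec.site_scale_sd))))
        for s in spec.sites
    }
    # scanner character per site: a site-level bias-field component shared
    # by all its subjects (the Site regressor's job to absorb), with the
    # remaining half of the field variance drawn per subject
    half = 1.0 / np.sqrt(2.0)
    site_fields = {
        s: (
            polynomial_bias_field(spec.shape, spec.spacing,
                                  half * spec.receive_amp, site_rng),
            polynomial_bias_field(spec.shape, spec.spacing,
                                  half * spec.transmit_amp, site_rng),
            polynomial_bias_field(spec.shape, spec.spacing,
                                  half * spec.transmit_amp, site_rng),
        )
        for s in spec.sites
    }

    idx = 0
    for site in spec.sites:
        for group in spec.groups:
            for k in range(spec.group_counts()[group]):
                sid = f"sub-{idx:03d}"
                rng = np.random.default_rng((master, 1, idx))
                mu, sd = spec.age_dist.get(group, (45.0, 10.0))
                age = float(np.clip(rng.normal(mu, sd), 18.0, 90.0))

                # clean volumes for this subject: site scale + age trend + effect
                s1, s2 = site_scales[site]
                t1 = t1_clean.like(t1_clean.data * s1)
                t2v = t2_clean.data * s2
                # age trend on the clean GM ratio, realized through T2w
                age_factor = 1.0 + spec.age_slope_per_year * (age - spec.age_reference)
                age_factor = max(age_factor, 0.05)
                t2v = t2v.copy()
                t2v[gm] = t2v[gm] / age_factor
                t2 = t2_clean.like(t2v)

                effect = spec.effect_map.get(group, {})
                artifact = float(np.exp(rng.normal(0.0, spec.artifact_log_sd)))
                recv_s, tx1_s, tx2_s = site_fields[site]
                recv = polynomial_bias_field(
                    spec.shape, spec.spacing, half * spec.receive_amp, rng)
                tx1 = polynomial_bias_field(
                    spec.shape, spec.spacing, half * artifact * spec.transmit_amp, rng)
                tx2 = polynomial_bias_field(
                    spec.shape, spec.spacing, half * artifact * spec.transmit_amp, rng)
                truth = PhantomTruth(
                    truth0.tissue_labels, truth0.roi_labels, truth0.csf_mask,
                    truth0.spacing,
                    receive_field=recv.like(recv.data * recv_s.data),
                    transmit_field_t1=tx1.like(tx1.data * tx1_s.data),
                    transmit_field_t2=tx2.like(tx2.data * tx2_s.data),
                )
                t2 = apply_group_effect(t2, truth, effect)
                t1o, t2o = apply_bias_and_noise(
                    t1, t2, truth, seed=int(rng.integers(2**31)),
                    noise_sigma_frac=artifact * spec.noise_sigma_frac,
                    noise_model=spec.noise_model,
                )
                if spec.misalign_rot_deg > 0 or spec.misalign_trans_mm > 0:
                    rigid = RigidTransform(
                        tuple(rng.uniform(-spec.misalign_rot_deg, spec.misalign_rot_deg, 3)),
                        tuple(rng.uniform(-spec.misalign_trans_mm, spec.misalign_trans_mm, 3)),
                        tuple((n - 1) / 2.0 * s for n, s in zip(spec.shape, spec.spacing)),
                    )
                    truth.true_rigid = rigid
                    t2o = apply_misalignment(t2o, rigid)
                else:
                    truth.true_rigid = RigidTransform()

                yield SimulatedSubject(SubjectRecord(sid, group, age, site), t1o, t2o, truth)
                idx += 1


def simulate_cohort(spec: CohortSpec, out_dir: str, seed: int | None = None) -> pd.DataFrame:
    """Simulate a cohort to disk; returns (and writes) the manifest.

    Writes one T1w and one T2w NIfTI per subject, the shared truth label
    volumes, the per-group effect map, the cohort spec and a manifest
    CSV listing every file, each subject's covariates, the true rigid
    parameters and the master seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = spec.seed if seed is None else seed

    rows = []
    truth_written = False
    for subj in iter_cohort(spec, master):
        rec = subj.record
        t1_path = out / f"{rec.subject_id}_T1w.nii.gz"
        t2_path = out / f"{rec.subject_id}_T2w.nii.gz"
        subj.t1_obs.to_nifti(str(t1_path))
        subj.t2_obs.to_nifti(str(t2_path))
        if not truth_written:
            save_labels(subj.truth.tissue_labels, spec.spacing, str(out / "truth_tissue_labels.nii.gz"))
            save_labels(subj.truth.roi_labels, spec.spacing, str(out / "truth_roi_labels.nii.gz"))
            truth_written = True
        rows.append({
            "subject_id": rec.subject_id,
            "group": rec.group,
            "age": rec.age,
            "site": rec.site,
            "t1_path": t1_path.name,
            "t2_path": t2_path.name,
            "rigid_rot_deg": ";".join(f"{v:.6f}" for v in subj.truth.true_rigid.rotations_deg),
            "rigid_trans_mm": ";".join(f"{v:.6f}" for v in subj.truth.true_rigid.translations_mm),
            "seed": master,
        })

    effect_rows = [
        {"group": g, "roi_id": r, "delta": d}
        for g, rois in spec.effect_map.items() for r, d in rois.items()
    ]
    pd.DataFrame(effect_rows, columns=["group", "roi_id", "delta"]).to_csv(
        out / "truth_effect_map.csv", index=False
    )
    spec.to_yaml(str(out / "cohort_spec.yaml"))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def manifest_checksum(out_dir: str) -> str:
    """SHA-256 over the manifest and all listed image files (determinism checks)."""
    out = Path(out_dir)
    h = hashlib.sha256()
    manifest = pd.read_csv(out / "manifest.csv")
    h.update(manifest.to_csv(index=False).encode())
    for _, row in manifest.iterrows():
        for col in ("t1_path", "t2_path"):
            vol = ScalarVolume.from_nifti(str(out / row[col]))
            h.update(np.ascontiguousarray(vol.data).tobytes())
    return h.hexdigest()
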