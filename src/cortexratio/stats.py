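"""ROI aggregation, QC exclusion, weighted regression and Holm correction.

Per subject, the smoothed mid-depth ratio signal is averaged within each
ROI; subjects whose whole-cortex mean is more than 1.5 cohort standard
deviations from the cohort mean are excluded (a gain difference between
the two contrasts).  Each ROI is then fit with a weighted least-squares
model

    Signal ~ Age + Study_site + Disease_group

with treatment coding (Control as reference) and weights 1/SD of the
within-ROI voxel signal — subjects with noisier images count less.
Family-wise error over ROIs is controlled per disease-group level with
the Holm-Bonferroni stepdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

CONTROL = "Control"


# ---------------------------------------------------------------------------
# QC exclusion
# ---------------------------------------------------------------------------

def qc_exclude(mean_intensity: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Flag subjects whose mean cortical intensity is outside mean +/- k*SD.

    The mean and (population-free, ddof=1) standard deviation are
    computed once over the full cohort; there is no iteration.  Returns
    a boolean exclusion array.
    """
    x = np.asarray(mean_intensity, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 subjects for the QC rule")
    if not np.isfinite(k):
        return np.zeros(x.size, dtype=bool)
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("zero cohort SD; no exclusions")
        return np.zeros(x.size, dtype=bool)
    return np.abs(x - x.mean()) > k * sd


# ---------------------------------------------------------------------------
# ROI table
# ---------------------------------------------------------------------------

def build_roi_table(
    shell_values: dict[str, np.ndarray],
    shell_roi_ids: np.ndarray,
    n_rois: int | None = None,
) -> pd.DataFrame:
    """Per subject x ROI mean, within-ROI SD and voxel count.

    ``shell_values`` maps subject id to the 1D vector of (smoothed)
    shell values in shell-voxel order; ``shell_roi_ids`` is the matching
    ROI id per shell voxel.  NaN values (excluded voxels) are ignored;
    an ROI with no valid voxels for a subject yields a row with NaN
    mean/SD and ``n_voxels = 0`` (dropped from fits, logged by caller).
    """
    roi_ids = np.asarray(shell_roi_ids)
    R = int(n_rois or roi_ids.max())
    rows = []
    for sid, vals in shell_values.items():
        v = np.asarray(vals, dtype=float)
        if v.size != roi_ids.size:
            raise ValueError(f"value vector of {sid} does not match shell")
        for r in range(1, R + 1):
            sel = (roi_ids == r) & np.isfinite(v)
            n = int(sel.sum())
            if n == 0:
                rows.append({"subject_id": sid, "roi_id": r, "mean_signal": np.nan,
                             "sd_signal": np.nan, "n_voxels": 0})
            else:
                x = v[sel]
                sd = float(x.std(ddof=1)) if n > 1 else 0.0
                rows.append({"subject_id": sid, "roi_id": r, "mean_signal": float(x.mean()),
                             "sd_signal": sd, "n_voxels": n})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# weighted regression per ROI
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    """Fit summary for one ROI."""

    roi_id: int
    group_coef: dict[str, float]
    group_se: dict[str, float]
    group_t: dict[str, float]
    group_p: dict[str, float]
    age_coef: float
    site_coef: dict[str, float]
    intercept: float
    n_obs: int
    failed: bool = False
    holm_p: dict[str, float] = field(default_factory=dict)
    significant: dict[str, bool] = field(default_factory=dict)


def _design_matrix(cov: pd.DataFrame, groups: list[str], sites: list[str]) -> np.ndarray:
    n = len(cov)
    cols = [np.ones(n), cov["age"].to_numpy(dtype=float)]
    for s in sites[1:]:
        cols.append((cov["site"] == s).to_numpy(dtype=float))
    for g in groups:
        if g != CONTROL:
            cols.append((cov["group"] == g).to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_roi_wls(
    table: pd.DataFrame,
    covariates: pd.DataFrame,
    sd_floor_quantile: float = 0.05,
    weight_scheme: str = "per_subject",
) -> list[RegressionResult]:
    """One WLS fit per ROI: Signal ~ Age + Site + Group (Control reference).

    Weight schemes (all floored at the cohort ``sd_floor_quantile``
    quantile of the within-ROI SDs to bound the largest weight):

    * ``"per_subject"`` (default): one weight per subject, the inverse
      of that subject's *median* within-ROI voxel SD across ROIs —
      subjects whose images carry more artifacts count less everywhere.
      Pooling across ROIs keeps the weights nearly noise-free, which a
      weight estimated from a single ROI's handful of voxels is not.
    * ``"per_subject_roi"``: the literal per-cell reading, ``1 /
      sd_signal`` of each (subject, ROI) row.
    * ``"per_roi"``: one weight per ROI, the inverse across-subject SD
      of its mean signal (constant within an ROI, hence identical to
      OLS coefficients).

    Singular or deficient designs are recorded as failed ROIs and
    skipped by the correction step.
    """
    cov = covariates.set_index("subject_id")
    groups = [CONTROL] + [g for g in cov["group"].unique() if g != CONTROL]
    sites = sorted(cov["site"].unique())

    valid = table[(table["n_voxels"] > 0) & np.isfinite(table["mean_signal"])]
    sd_all = valid["sd_signal"].to_numpy(dtype=float)
    floor = np.quantile(sd_all[sd_all > 0], sd_floor_quantile) if np.any(sd_all > 0) else 1.0
    subject_sd = valid.groupby("subject_id")["sd_signal"].median()

    results: list[RegressionResult] = []
    for roi_id, sub in valid.groupby("roi_id"):
        c = cov.loc[sub["subject_id"]].reset_index()
        X = _design_matrix(c, groups, sites)
        y = sub["mean_signal"].to_numpy(dtype=float)
        if weight_scheme == "per_subject":
            sd = subject_sd.loc[sub["subject_id"]].to_numpy(dtype=float)
            w = 1.0 / np.maximum(sd, floor)
        elif weight_scheme == "per_subject_roi":
            w = 1.0 / np.maximum(sub["sd_signal"].to_numpy(dtype=float), floor)
        elif weight_scheme == "per_roi":
            s = y.std(ddof=1)
            w = np.full(len(y), 1.0 / max(s, 1e-12))
        else:
            raise ValueError(f"unknown weight scheme {weight_scheme!r}")

        res = RegressionResult(int(roi_id), {}, {}, {}, {}, np.nan, {}, np.nan, len(y))
        if len(y) <= X.shape[1] or np.linalg.matrix_rank(X) < X.shape[1]:
            res.failed = True
            results.append(res)
            continue
        fit = sm.WLS(y, X, weights=w).fit()
        names = (["intercept", "age"]
                 + [f"site[{s}]" for s in sites[1:]]
                 + [f"group[{g}]" for g in groups if g != CONTROL])
        res.intercept = float(fit.params[0])
        res.age_coef = float(fit.params[1])
        res.site_coef = {s: float(fit.params[2 + i]) for i, s in enumerate(sites[1:])}
        off = 2 + len(sites) - 1
        for i, g in enumerate([g for g in groups if g != CONTROL]):
            res.group_coef[g] = float(fit.params[off + i])
            res.group_se[g] = float(fit.bse[off + i])
            res.group_t[g] = float(fit.tvalues[off + i])
            res.group_p[g] = float(fit.pvalues[off + i])
        results.append(res)
    return results


# ---------------------------------------------------------------------------
# Holm-Bonferroni stepdown
# ---------------------------------------------------------------------------

def holm_bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Stepdown-adjusted p-values and significance flags.

    Sort ascending; ``p_adj_(i) = max_{j<=i} min(1, (m-j+1) p_(j))``;
    hypothesis ``i`` is rejected when ``p_adj_(i) < alpha`` (the
    stepdown stopping rule is equivalent to thresholding the monotone
    adjusted values).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(scaled)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj < alpha


def apply_holm(results: list[RegressionResult], alpha: float = 0.05) -> None:
    """Holm correction across ROIs, separately within each group level."""
    ok = [r for r in results if not r.failed]
    if not ok:
        return
    group_levels = sorted({g for r in ok for g in r.group_p})
    for g in group_levels:
        ps = np.array([r.group_p[g] for r in ok])
        adj, sig = holm_bonferroni(ps, alpha)
        for r, a, s in zip(ok, adj, sig):
            r.holm_p[g] = float(a)
            r.significant[g] = bool(s)


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if r.failed:
            rows.append({"roi_id": r.roi_id, "group": None, "failed": True})
            continue
        for g in r.group_coef:
            rows.append({
                "roi_id": r.roi_id, "group": g, "failed": False,
                "coef": r.group_coef[g], "se": r.group_se[g],
                "t": r.group_t[g], "p": r.group_p[g],
                "holm_p": r.holm_p.get(g, np.nan),
                "significant": r.significant.get(g, False),
                "age_coef": r.age_coef, "n_obs": r.n_obs,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-voxel (vertexwise analogue) group maps
# ---------------------------------------------------------------------------

def vertexwise_group_maps(
    shell_values: dict[str, np.ndarray],
    covariates: pd.DataFrame,
) -> dict[str, dict[str, np.ndarray]]:
    """Covariate-adjusted per-group mean maps and coefficient maps.

    Fits ``Signal ~ Age + Site + Group`` independently at every shell
    voxel (OLS, all voxels solved in one least-squares call).  Returns

    * ``"adjusted_mean"``: per group, intercept + group coefficient with
      age at the cohort mean and the reference site — the average map
      with age and site regressed out;
    * ``"coef"``: per non-control group, the coefficient map relative to
      Control (zero map for Control by treatment coding).
    """
    cov = covariates.set_index("subject_id")
    sids = list(shell_values.keys())
    c = cov.loc[sids].reset_index()
    groups = [CONTROL] + [g for g in c["group"].unique() if g != CONTROL]
    sites = sorted(c["site"].unique())

    c_centered = c.copy()
    age_mean = c["age"].mean()
    c_centered["age"] = c["age"] - age_mean
    X = _design_matrix(c_centered, groups, sites)
    Y = np.stack([np.asarray(shell_values[s], dtype=float) for s in sids])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    intercept = beta[0]
    off = 2 + len(sites) - 1
    out = {"adjusted_mean": {CONTROL: intercept.copy()}, "coef": {CONTROL: np.zeros_like(intercept)}}
    for i, g in enumerate([g for g in groups if g != CONTROL]):
        out["coef"][g] = beta[off + i]
        out["adjusted_mean"][g] = intercept + beta[off + i]
    return out
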