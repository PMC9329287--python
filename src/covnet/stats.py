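"""Patient-control comparisons across sites.

Global metrics are compared density-by-density with paired two-tailed t-tests
across sites (each site contributes a matched patient and control network),
FDR-corrected across densities.  Nodal metrics are summarized as Cohen's d
effect sizes across sites and combined into a multivariate topology-change
map: per region, a paired Hotelling T^2 on the site-wise (clustering, path
length) difference vectors, FDR-corrected across regions.  The scalar used
for spatial correlation is T^2 signed by the dominant direction of change
(positive when the mean difference projects onto (1, 1): joint increase of
clustering and path length, i.e. regularization; negative toward (-1, -1):
randomization).  Atrophy maps are two-sample Cohen's d on subject-level
z-scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .parcellation import ValidationError
from .preprocess import PreprocessedCohort

__all__ = [
    "GlobalComparison",
    "TopologyChangeMap",
    "AtrophyMap",
    "bh_fdr",
    "global_density_tests",
    "cohens_d",
    "cohens_d_map",
    "hotelling_map",
    "atrophy_map",
]

log = logging.getLogger("covnet")


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (NaNs passed through)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


@dataclass
class GlobalComparison:
    """Density-wise paired t-tests of a global metric (patients vs controls)."""

    metric: str
    table: pd.DataFrame     # density, t, p, p_fdr, mean_diff, degenerate flags
    patient_values: pd.DataFrame    # site x density
    control_values: pd.DataFrame


def global_density_tests(patient_values: pd.DataFrame,
                         control_values: pd.DataFrame,
                         metric: str = "",
                         fdr_alpha: float = 0.1) -> GlobalComparison:
    """Paired two-tailed t-test per density across sites, BH-FDR across densities.

    Inputs are site x density frames with identical indexing.  Zero-variance
    differences are flagged: all-zero gives t = 0, p = 1; a constant nonzero
    shift gives the degenerate exact-difference result (p = 0, flagged).
    """
    if not patient_values.index.equals(control_values.index):
        raise ValidationError("patient/control site indices differ")
    if len(patient_values) < 3:
        raise ValidationError("need >= 3 paired sites")
    rows = []
    for K in patient_values.columns:
        diff = (patient_values[K] - control_values[K]).to_numpy(dtype=float)
        degenerate = False
        if np.allclose(diff.std(ddof=1), 0.0):
            degenerate = True
            if np.allclose(diff, 0.0):
                t, p = 0.0, 1.0
            else:
                t = np.inf if diff.mean() > 0 else -np.inf
                p = 0.0
        else:
            t, p = sps.ttest_rel(patient_values[K], control_values[K])
        rows.append({"density": K, "t": float(t), "p": float(p),
                     "mean_diff": float(diff.mean()), "degenerate": degenerate})
    table = pd.DataFrame(rows)
    table["p_fdr"] = bh_fdr(table["p"].to_numpy())
    table["sig_fdr"] = table["p_fdr"] < fdr_alpha
    table["sig_uncorr"] = table["p"] < 0.05
    return GlobalComparison(metric=metric, table=table,
                            patient_values=patient_values,
                            control_values=control_values)


def cohens_d(patients: np.ndarray, controls: np.ndarray, axis: int = 0) -> np.ndarray:
    """Two-sample Cohen's d with pooled (n-1) SD; NaN where pooled SD is 0."""
    patients = np.asarray(patients, dtype=float)
    controls = np.asarray(controls, dtype=float)
    # missing site-level values (e.g. isolated-node path length) are excluded
    n1 = np.isfinite(patients).sum(axis=axis)
    n2 = np.isfinite(controls).sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1 = np.nanmean(patients, axis=axis)
        m2 = np.nanmean(controls, axis=axis)
        s1 = np.nanstd(patients, axis=axis, ddof=1)
        s2 = np.nanstd(controls, axis=axis, ddof=1)
        pooled = np.sqrt(((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2)
                         / np.maximum(n1 + n2 - 2, 1))
    pooled = np.where((n1 >= 2) & (n2 >= 2), pooled, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(pooled > 0, (m1 - m2) / pooled, np.nan)
    if np.any(~np.isfinite(d)):
        log.warning("cohens_d: %d region(s) with zero pooled SD flagged NaN",
                    int(np.sum(~np.isfinite(d))))
    return d


def cohens_d_map(patient_metric: np.ndarray,
                 control_metric: np.ndarray) -> np.ndarray:
    """Per-region Cohen's d of a nodal metric across sites.

    Inputs are (n_sites, n_regions) arrays of per-site group-level nodal
    values; requires >= 2 sites.
    """
    if patient_metric.shape[0] < 2:
        raise ValidationError("need >= 2 sites")
    return cohens_d(patient_metric, control_metric, axis=0)


@dataclass
class TopologyChangeMap:
    """Multivariate (clustering + path length) regional change, patients vs controls."""

    d_clustering: np.ndarray
    d_path_length: np.ndarray
    d_small_world: np.ndarray | None
    t2: np.ndarray
    F: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    signed_change: np.ndarray    # T^2 signed by the dominant direction
    n_sites: int


def hotelling_map(delta_clustering: np.ndarray, delta_path: np.ndarray,
                  d_clustering: np.ndarray | None = None,
                  d_path_length: np.ndarray | None = None,
                  d_small_world: np.ndarray | None = None,
                  signed: bool = True) -> TopologyChangeMap:
    """Paired Hotelling T^2 per region on site-wise metric differences.

    delta_* are (n_sites, n_regions) arrays of patient-minus-control nodal
    metric differences per site.  T^2 = n * dbar' S^-1 dbar with S the sample
    covariance of the differences; F = ((n - 2) / (2 (n - 1))) T^2 with
    (2, n - 2) degrees of freedom.  BH-FDR across regions.  The scalar
    exported for spatial correlation is T^2 signed by the sign of dbar
    projected onto (1, 1) (set signed=False for the magnitude-only variant).
    """
    dc = np.asarray(delta_clustering, dtype=float)
    dl = np.asarray(delta_path, dtype=float)
    if dc.shape != dl.shape:
        raise ValidationError("difference arrays must have identical shape")
    n, n_regions = dc.shape
    if n < 4:
        raise ValidationError("need >= 4 sites for the bivariate Hotelling test")
    t2 = np.full(n_regions, np.nan)
    F = np.full(n_regions, np.nan)
    p = np.full(n_regions, np.nan)
    sign = np.ones(n_regions)
    for r in range(n_regions):
        D = np.column_stack([dc[:, r], dl[:, r]])
        D = D[np.isfinite(D).all(axis=1)]       # drop sites with missing values
        nr = D.shape[0]
        if nr < 4:
            log.info("hotelling_map: region %d has %d usable sites; flagged", r, nr)
            continue
        dbar = D.mean(axis=0)
        S = np.cov(D, rowvar=False, ddof=1)
        det = np.linalg.det(S)
        if not np.isfinite(det) or abs(det) < 1e-300:
            S = S + 1e-10 * np.eye(2)
            log.info("hotelling_map: singular covariance at region %d; "
                     "ridge fallback", r)
        t2[r] = nr * dbar @ np.linalg.solve(S, dbar)
        F[r] = ((nr - 2) / (2.0 * (nr - 1))) * t2[r]
        p[r] = sps.f.sf(F[r], 2, nr - 2)
        proj = dbar.sum()     # projection onto (1, 1) up to scale
        sign[r] = 1.0 if proj >= 0 else -1.0
    p_fdr = bh_fdr(p)
    # default effect sizes: paired Cohen's d of the site-wise differences
    with np.errstate(invalid="ignore", divide="ignore"):
        if d_clustering is None:
            d_clustering = np.nanmean(dc, axis=0) / np.nanstd(dc, axis=0, ddof=1)
        if d_path_length is None:
            d_path_length = np.nanmean(dl, axis=0) / np.nanstd(dl, axis=0, ddof=1)
    signed_change = sign * t2 if signed else t2.copy()
    return TopologyChangeMap(
        d_clustering=np.asarray(d_clustering, dtype=float),
        d_path_length=np.asarray(d_path_length, dtype=float),
        d_small_world=(np.asarray(d_small_world, dtype=float)
                       if d_small_world is not None else None),
        t2=t2, F=F, p=p, p_fdr=p_fdr, signed_change=signed_change, n_sites=n)


@dataclass
class AtrophyMap:
    """Per-region patient-vs-control effect size on subject-level z-scores."""

    d: np.ndarray
    t: np.ndarray
    p: np.ndarray
    p_fdr: np.ndarray
    n_patients: int
    n_controls: int


def atrophy_map(cohort: PreprocessedCohort, patient_group: str = "TLE",
                sites: list[str] | None = None) -> AtrophyMap:
    """Two-sample Cohen's d + t-test per region (patients vs site-matched controls).

    Lower thickness/volume in patients gives negative d.  BH-FDR across
    regions.  `sites` restricts both groups to the listed sites (the
    site-matched control pool).
    """
    meta = cohort.meta
    mask_site = np.ones(len(meta), dtype=bool) if sites is None \
        else meta["site"].isin(sites).to_numpy()
    pat = cohort.values[((meta["group"] == patient_group).to_numpy()) & mask_site]
    ctl = cohort.values[((meta["group"] == "HC").to_numpy()) & mask_site]
    if len(pat) == 0 or len(ctl) == 0:
        raise ValidationError("both patients and controls are required")
    d = cohens_d(pat, ctl, axis=0)
    t, p = sps.ttest_ind(pat, ctl, axis=0)
    return AtrophyMap(d=d, t=np.asarray(t), p=np.asarray(p),
                      p_fdr=bh_fdr(np.asarray(p)),
                      n_patients=len(pat), n_controls=len(ctl))
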