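"""Subject-level morphometry preprocessing.

Raw regional cortical thickness (mm) and subcortical volume (mm^3) values are
turned into residualized, control-referenced z-scores:

1. exclusion of subjects missing at least half of the cortical or at least
   half of the subcortical measures, and mean-imputation (within site and
   diagnostic group) of the remaining gaps;
2. per-site ordinary least-squares correction for age and sex, with residuals
   z-scored against the mean/SD of that site's healthy-control residuals;
3. optional re-sorting of right-focus patients so region indices mean
   ipsilateral/contralateral to the seizure focus instead of left/right.

Controls are not hemisphere-flipped (left counts as "ipsilateral" by
convention), so control matrices are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .parcellation import RegionTable, ValidationError, hemisphere_swap_order

__all__ = [
    "SubjectMorphometry",
    "PreprocessedCohort",
    "impute_and_filter",
    "residualize_and_zscore",
    "sort_ipsi_contra",
    "load_subject_table",
    "save_subject_table",
]

GROUPS = ("TLE", "IGE", "HC")


@dataclass
class SubjectMorphometry:
    """One subject's regional values plus demographics."""

    subject_id: str
    site: str
    group: str            # TLE, IGE or HC
    age: float
    sex: str              # male / female
    focus_side: str       # left / right / none (none iff group != TLE)
    values: np.ndarray    # length n_regions
    missing_mask: np.ndarray | None = None
    duration: float | None = None   # years since onset, optional

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.group not in GROUPS:
            raise ValidationError(f"unknown group {self.group!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"unknown sex {self.sex!r}")
        if self.group == "TLE":
            if self.focus_side not in ("left", "right"):
                raise ValidationError(
                    f"TLE subject {self.subject_id} needs focus_side left/right")
        elif self.focus_side != "none":
            raise ValidationError(
                f"non-TLE subject {self.subject_id} must have focus_side 'none'")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError(
                f"subject {self.subject_id}: non-finite value outside missing mask")


@dataclass
class PreprocessedCohort:
    """Residualized, control-referenced z-scores for a cohort.

    values[i] is subject i's z-score vector; meta carries subject_id, site,
    group, focus alignment state; coefficients records the per-site OLS fits
    and control reference moments for provenance.
    """

    values: np.ndarray            # subjects x regions
    meta: pd.DataFrame            # subject_id, site, group, age, sex, focus_side, duration
    coefficients: dict = field(default_factory=dict)
    focus_aligned: bool = False

    def subset(self, mask: np.ndarray) -> "PreprocessedCohort":
        return PreprocessedCohort(
            self.values[mask], self.meta.loc[mask].reset_index(drop=True),
            self.coefficients, self.focus_aligned)


def impute_and_filter(cohort: list[SubjectMorphometry],
                      table: RegionTable) -> list[SubjectMorphometry]:
    """Apply the missing-data rule: exclude, then mean-impute.

    Subjects missing at least half of the cortical measures or at least half of
    the subcortical measures are dropped.  Remaining missing entries are
    replaced with the per-region mean over non-missing values of subjects in
    the same site and diagnostic group.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    cort = table.cortical_mask
    sub = table.subcortical_mask
    kept = [s for s in cohort
            if s.missing_mask[cort].sum() < 0.5 * cort.sum()
            and s.missing_mask[sub].sum() < 0.5 * max(sub.sum(), 1)]

    out: list[SubjectMorphometry] = []
    groups: dict[tuple[str, str], list[SubjectMorphometry]] = {}
    for s in kept:
        groups.setdefault((s.site, s.group), []).append(s)
    for (site, grp), members in groups.items():
        vals = np.array([m.values for m in members])
        mask = np.array([m.missing_mask for m in members])
        vals = np.where(mask, np.nan, vals)
        import warnings
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            # all-NaN columns are handled explicitly just below
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(vals, axis=0)
        dead = np.isnan(means) & mask.any(axis=0)
        if dead.any():
            regs = [table.names[i] for i in np.flatnonzero(dead)]
            raise ValidationError(
                f"region(s) {regs} missing in every subject of {site}/{grp}; "
                "imputation mean undefined")
        for m in members:
            filled = np.where(m.missing_mask, means, m.values)
            out.append(replace(m, values=filled,
                               missing_mask=np.zeros_like(m.missing_mask)))
    # preserve input order
    order = {s.subject_id: i for i, s in enumerate(cohort)}
    out.sort(key=lambda s: order[s.subject_id])
    return out


def _design(ages: np.ndarray, sexes: np.ndarray) -> np.ndarray:
    sex01 = (sexes == "male").astype(float)
    return np.column_stack([np.ones_like(ages), ages, sex01])


def residualize_and_zscore(cohort: list[SubjectMorphometry]) -> PreprocessedCohort:
    """Correct for age and sex per site, z-score against site-matched controls.

    Per site and region, values are regressed on [1, age, sex] using the
    site's pooled sample (patients and controls); residuals are then z-scored
    with the mean and SD of that site's control residuals.  By construction
    the control rows of every site have column mean 0 and SD 1.
    """
    if not cohort:
        raise ValidationError("empty cohort")
    if any(s.missing_mask.any() for s in cohort):
        raise ValidationError("run impute_and_filter before residualization")

    sites = sorted({s.site for s in cohort})
    n_regions = cohort[0].values.size
    values = np.empty((len(cohort), n_regions))
    meta = pd.DataFrame({
        "subject_id": [s.subject_id for s in cohort],
        "site": [s.site for s in cohort],
        "group": [s.group for s in cohort],
        "age": [s.age for s in cohort],
        "sex": [s.sex for s in cohort],
        "focus_side": [s.focus_side for s in cohort],
        "duration": [s.duration for s in cohort],
    })
    coefficients: dict = {}

    for site in sites:
        idx = np.flatnonzero((meta["site"] == site).to_numpy())
        ctrl = idx[(meta.loc[idx, "group"] == "HC").to_numpy()]
        if ctrl.size < 2:
            raise ValidationError(f"site {site}: need >= 2 controls, got {ctrl.size}")
        ages = meta.loc[idx, "age"].to_numpy(dtype=float)
        sexes = meta.loc[idx, "sex"].to_numpy()
        X = _design(ages, sexes)
        # drop constant covariate columns (keeps the design nonsingular when a
        # site is single-sex); residuals are invariant to the dropped column
        keep = [0] + [c for c in (1, 2) if np.ptp(X[:, c]) > 0]
        Xk = X[:, keep]
        if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
            raise ValidationError(f"site {site}: singular covariate design")
        Y = np.array([cohort[i].values for i in idx])
        beta, *_ = np.linalg.lstsq(Xk, Y, rcond=None)
        resid = Y - Xk @ beta
        ctrl_rows = np.isin(idx, ctrl)
        mu = resid[ctrl_rows].mean(axis=0)
        sd = resid[ctrl_rows].std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValidationError(
                f"site {site}: control residual SD is zero for region {bad}")
        values[idx] = (resid - mu) / sd
        coefficients[site] = {"columns": keep, "beta": beta,
                              "control_mean": mu, "control_sd": sd}

    return PreprocessedCohort(values=values, meta=meta,
                              coefficients=coefficients)


def sort_ipsi_contra(cohort: PreprocessedCohort,
                     table: RegionTable) -> PreprocessedCohort:
    """Re-sort right-focus patients by the hemisphere swap permutation.

    After sorting, index semantics are ipsilateral/contralateral to the
    seizure focus; left-focus patients and controls (left = ipsilateral by
    convention) are unchanged.  The operation is an involution.
    """
    perm = hemisphere_swap_order(table)
    tle = (cohort.meta["group"] == "TLE").to_numpy()
    side = cohort.meta["focus_side"].to_numpy()
    if np.any(tle & ~np.isin(side, ["left", "right"])):
        raise ValidationError("TLE subject without focus side")
    values = cohort.values.copy()
    flip = tle & (side == "right")
    values[flip] = values[flip][:, perm]
    return PreprocessedCohort(values=values, meta=cohort.meta,
                              coefficients=cohort.coefficients,
                              focus_aligned=not cohort.focus_aligned)


# -- CSV interface -------------------------------------------------------------

def load_subject_table(path, table: RegionTable) -> list[SubjectMorphometry]:
    """Read the subject CSV: demographic columns then one column per region."""
    df = pd.read_csv(path)
    required = ["subject_id", "site", "group", "age", "sex", "focus_side"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"subject table missing columns: {missing}")
    absent = [n for n in table.names if n not in df.columns]
    if absent:
        raise ValidationError(f"subject table missing region columns: {absent}")
    vals = df[table.names].to_numpy(dtype=float)
    out = []
    for i, row in df.iterrows():
        out.append(SubjectMorphometry(
            subject_id=str(row["subject_id"]), site=str(row["site"]),
            group=str(row["group"]), age=float(row["age"]), sex=str(row["sex"]),
            focus_side=str(row["focus_side"]), values=vals[i],
            duration=float(row["duration"]) if "duration" in df.columns
            and np.isfinite(row.get("duration", np.nan)) else None))
    return out


def save_subject_table(cohort: list[SubjectMorphometry], table: RegionTable,
                       path) -> None:
    rows = []
    for s in cohort:
        row = {"subject_id": s.subject_id, "site": s.site, "group": s.group,
               "age": s.age, "sex": s.sex, "focus_side": s.focus_side,
               "duration": s.duration}
        vals = np.where(s.missing_mask, np.nan, s.values)
        row.update(dict(zip(table.names, vals)))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
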