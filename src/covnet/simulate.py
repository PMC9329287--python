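"""Synthetic multisite morphometry, expression and cell-type data.

The generator emulates the study conditions every stage of the pipeline
needs, with no download:

* multisite cohorts drawn from multivariate normals with block ("module")
  correlation structure; patients differ from controls by a planted
  within-module correlation increment (regularization) or a decrement spread
  across modules (randomization), plus linear age/sex effects, site-specific
  offsets and scales, and ~1% missingness;
* spatially autocorrelated expression maps: Gaussian-process draws with a
  squared-exponential kernel over great-circle distances, with a planted gene
  set constructed to correlate at a target level with a supplied topology
  map;
* a nonnegative gene x cell-type specificity matrix with planted gene sets
  loading on designated cell types.

Defaults are sized to the study layout at desk scale: 82 regions, 14 sites
with a focal-epilepsy (TLE) group and controls, the first 10 of which also
carry a generalized-epilepsy (IGE) group, 40 subjects per group per site, and
a 500-gene universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import RegionTable, ValidationError, default_region_table
from .preprocess import SubjectMorphometry
from .transcriptomics import GeneSet

__all__ = [
    "SimulationConfig",
    "simulate_cohort",
    "simulate_expression",
    "simulate_celltype_matrix",
    "nearest_psd_correlation",
]

log = logging.getLogger("covnet")


@dataclass
class SimulationConfig:
    """Generator settings; defaults define the standard synthetic study."""

    n_sites_tle: int = 14
    n_sites_ige: int = 10          # first n_sites_ige sites also have IGE
    n_per_group: int = 40
    n_regions: int = 82
    module_sizes: tuple = (10, 10, 10, 10, 10, 10, 11, 11)
    within_module_r: float = 0.4
    between_module_r: float = 0.1
    # planted effects
    regularization_delta: float = 0.2   # added to module 0 correlations (TLE)
    randomization_delta: float = 0.1    # subtracted within all modules (IGE)
    planted_module: int = 0
    # demographics and site effects
    age_range: tuple = (18.0, 50.0)
    age_slope_sd_per_year: float = -0.01   # in units of region SD
    sex_effect_sd: float = 0.1             # male minus female, region-SD units
    site_offset_sd: float = 0.3            # region-SD units
    site_scale_sd: float = 0.05            # lognormal sigma of site scaling
    missing_rate: float = 0.01
    # expression
    n_genes: int = 500
    expression_length_scale: float = 30.0  # mm on the 100 mm sphere
    planted_set_size: int = 20
    planted_rho: float = 0.5
    n_celltypes: int = 29

    def __post_init__(self) -> None:
        if sum(self.module_sizes) != self.n_regions:
            raise ValidationError("module sizes must sum to n_regions")
        if not 0.0 < self.planted_rho < 1.0:
            raise ValidationError("planted_rho must be in (0, 1)")
        if self.n_per_group < 10:
            raise ValidationError("n_per_group must be >= 10")


def nearest_psd_correlation(C: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the nearest PSD correlation matrix.

    Eigenvalues are clipped at eps and the unit diagonal restored; logs when
    the projection changes the matrix.
    """
    C = (C + C.T) / 2.0
    w, V = np.linalg.eigh(C)
    if w.min() < eps:
        log.info("nearest_psd_correlation: clipping min eigenvalue %.3g", w.min())
        w = np.clip(w, eps, None)
        C = (V * w) @ V.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
    if np.linalg.eigvalsh(C).min() < 0:
        raise ValidationError("correlation matrix not PSD after projection")
    return C


def _module_labels(cfg: SimulationConfig) -> np.ndarray:
    labels = np.concatenate([
        np.full(sz, m) for m, sz in enumerate(cfg.module_sizes)])
    return labels


def _base_correlation(cfg: SimulationConfig) -> np.ndarray:
    labels = _module_labels(cfg)
    same = labels[:, None] == labels[None, :]
    C = np.where(same, cfg.within_module_r, cfg.between_module_r)
    np.fill_diagonal(C, 1.0)
    return C


def group_correlation(cfg: SimulationConfig, group: str) -> np.ndarray:
    """Generating correlation matrix for one diagnostic group."""
    C = _base_correlation(cfg)
    labels = _module_labels(cfg)
    if group == "TLE" and cfg.regularization_delta != 0.0:
        inmod = labels == cfg.planted_module
        block = np.outer(inmod, inmod)
        np.fill_diagonal(block, False)
        C = np.where(block, np.clip(C + cfg.regularization_delta, -0.99, 0.99), C)
    elif group == "IGE" and cfg.randomization_delta != 0.0:
        same = labels[:, None] == labels[None, :]
        np.fill_diagonal(same, False)
        C = np.where(same, np.clip(C - cfg.randomization_delta, -0.99, 0.99), C)
    return nearest_psd_correlation(C)


def planted_region_mask(cfg: SimulationConfig) -> np.ndarray:
    """Boolean mask of the regions carrying the planted TLE effect."""
    return _module_labels(cfg) == cfg.planted_module


def _region_scales(cfg: SimulationConfig, table: RegionTable | None):
    """Per-region mean and SD in measurement units (mm / mm^3)."""
    if table is not None and len(table) == cfg.n_regions:
        cort = table.cortical_mask
    else:
        cort = np.ones(cfg.n_regions, dtype=bool)
    mean = np.where(cort, 2.5, 4000.0)
    sd = np.where(cort, 0.15, 400.0)
    return mean, sd


def simulate_cohort(cfg: SimulationConfig, seed: int,
                    table: RegionTable | None = None
                    ) -> list[SubjectMorphometry]:
    """Draw the full multisite cohort (HC + TLE everywhere, IGE at a subset).

    Each site gets its own additive offset and multiplicative scale; subjects
    get linear age and sex effects; ~missing_rate of entries are masked.
    Deterministic under seed.
    """
    rng = np.random.default_rng(seed)
    if table is None and cfg.n_regions == 82:
        table = default_region_table()
    mean, sd = _region_scales(cfg, table)
    chol = {g: np.linalg.cholesky(group_correlation(cfg, g))
            for g in ("HC", "TLE", "IGE")}
    mid_age = 0.5 * (cfg.age_range[0] + cfg.age_range[1])

    cohort: list[SubjectMorphometry] = []
    for s in range(cfg.n_sites_tle):
        site = f"site{s + 1:02d}"
        offset = rng.normal(0.0, cfg.site_offset_sd, size=cfg.n_regions) * sd
        scale = np.exp(rng.normal(0.0, cfg.site_scale_sd, size=cfg.n_regions))
        groups = ["HC", "TLE"] + (["IGE"] if s < cfg.n_sites_ige else [])
        for group in groups:
            L = chol[group]
            for k in range(cfg.n_per_group):
                age = rng.uniform(*cfg.age_range)
                sex = "male" if rng.random() < 0.5 else "female"
                z = L @ rng.standard_normal(cfg.n_regions)
                vals = mean + sd * scale * z + offset
                vals = vals + sd * cfg.age_slope_sd_per_year * (age - mid_age)
                if sex == "male":
                    vals = vals + sd * cfg.sex_effect_sd
                mask = rng.random(cfg.n_regions) < cfg.missing_rate
                vals = np.where(mask, np.nan, vals)
                focus = "none"
                duration = None
                if group == "TLE":
                    focus = "left" if k % 2 == 0 else "right"
                    duration = float(max(rng.normal(20.0, 10.0), 0.5))
                elif group == "IGE":
                    duration = float(max(rng.normal(15.0, 10.0), 0.5))
                cohort.append(SubjectMorphometry(
                    subject_id=f"{site}_{group}_{k:03d}", site=site,
                    group=group, age=age, sex=sex, focus_side=focus,
                    values=vals, missing_mask=mask, duration=duration))
    return cohort


def _gp_cholesky(sphere_xyz: np.ndarray, length_scale: float,
                 radius: float = 100.0) -> np.ndarray:
    dots = np.clip(sphere_xyz @ sphere_xyz.T, -1.0, 1.0)
    d = radius * np.arccos(dots)
    K = np.exp(-0.5 * (d / length_scale) ** 2)
    K[np.diag_indices_from(K)] += 1e-8
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(K)
        w = np.clip(w, 1e-10, None)
        return V * np.sqrt(w)


def _standardize(v: np.ndarray) -> np.ndarray:
    s = v.std()
    if s == 0:
        raise ValidationError("degenerate (constant) map")
    return (v - v.mean()) / s


def simulate_expression(sphere_xyz: np.ndarray, n_genes: int,
                        length_scale: float,
                        planted: tuple[np.ndarray, float, int] | None,
                        seed: int,
                        set_name: str = "planted"
                        ) -> tuple[pd.DataFrame, GeneSet | None]:
    """Region x gene expression matrix with optional planted gene set.

    Background genes are Gaussian-process draws (squared-exponential kernel
    over great-circle distances).  Planted genes are
    rho * standardized(target_map) + sqrt(1 - rho^2) * GP noise.  All columns
    are min-max scaled to [0, 1].  `planted` is (target_map, rho, set_size).
    """
    rng = np.random.default_rng(seed)
    n_regions = sphere_xyz.shape[0]
    L = _gp_cholesky(sphere_xyz, length_scale)
    X = L @ rng.standard_normal((n_regions, n_genes))
    gene_names = [f"g{j + 1:05d}" for j in range(n_genes)]
    gs = None
    if planted is not None:
        target, rho, set_size = planted
        if not 0.0 < rho <= 1.0:
            raise ValidationError("planted rho must be in (0, 1]")
        t = _standardize(np.asarray(target, float))
        cols = rng.choice(n_genes, size=set_size, replace=False)
        for j in cols:
            noise = _standardize(L @ rng.standard_normal(n_regions))
            X[:, j] = rho * t + np.sqrt(1.0 - rho ** 2) * noise
        gs = GeneSet(name=set_name, symbols=[gene_names[j] for j in sorted(cols)],
                     note="synthetic planted set")
    lo = X.min(axis=0)
    rng_span = X.max(axis=0) - lo
    rng_span[rng_span == 0] = 1.0
    X = (X - lo) / rng_span
    expr = pd.DataFrame(X, columns=gene_names)
    return expr, gs


def simulate_celltype_matrix(gene_names: list[str], n_celltypes: int = 29,
                             planted: dict[int, list[str]] | None = None,
                             seed: int = 0) -> pd.DataFrame:
    """Nonnegative gene x cell-type specificity matrix.

    `planted` maps a cell-type column index to the gene symbols that should
    load on it (their scores in that column are boosted).
    """
    rng = np.random.default_rng(seed)
    n_genes = len(gene_names)
    S = rng.gamma(shape=2.0, scale=0.25, size=(n_genes, n_celltypes))
    df = pd.DataFrame(S, index=gene_names,
                      columns=[f"celltype{c + 1:02d}" for c in range(n_celltypes)])
    if planted:
        for col_idx, genes in planted.items():
            col = df.columns[col_idx]
            df.loc[[g for g in genes if g in df.index], col] += 1.5
    return df
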