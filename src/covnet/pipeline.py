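"""End-to-end orchestration: preprocess -> networks -> metrics -> stats ->
transcriptomics, with per-site reruns and threshold-stability sweeps.

The pipeline mirrors the multisite study design: for each patient group
(TLE-like focal, IGE-like generalized) it builds one covariance matrix per
site for patients and one for site-matched controls (sites need at least 10
subjects per diagnostic group), screens the density grid for connectedness,
runs density-wise global comparisons, computes the regional multivariate
topology-change map at the smallest admissible density, and correlates that
map with gene-set expression maps under spin and random-gene nulls.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import RegionTable, default_region_table
from .preprocess import (PreprocessedCohort, impute_and_filter,
                         residualize_and_zscore, sort_ipsi_contra)
from .networks import (DENSITY_GRID, CohortTooSmallError, CovarianceNetwork,
                       build_covariance, connectedness_range,
                       mean_positive_strength, threshold)
from .metrics import normalized_topology
from .stats import (GlobalComparison, TopologyChangeMap, atrophy_map,
                    cohens_d_map, global_density_tests, hotelling_map)
from .transcriptomics import GeneSet, imaging_transcriptomic_assoc

__all__ = [
    "PipelineConfig",
    "ComparisonResult",
    "PipelineResult",
    "build_site_networks",
    "run_comparison",
    "run_pipeline",
    "threshold_stability",
    "per_site_maps",
]

log = logging.getLogger("covnet")


@dataclass
class PipelineConfig:
    """Declarative settings; every printed constant of the method is a default."""

    densities: np.ndarray = field(default_factory=lambda: DENSITY_GRID.copy())
    n_nulls: int = 1000            # null networks per empirical network
    n_perm: int = 10000            # spin / random-gene permutations
    seed: int = 0
    min_subjects: int = 10
    node_frac: float = 0.75        # connectedness: nodes in largest component
    site_frac: float = 0.90        # ... in at least this fraction of sites
    fdr_alpha_global: float = 0.1
    fdr_alpha_regional: float = 0.05
    analysis_density: float | None = None   # None -> smallest passing density
    normalize_global_sweep: bool = False    # raw metrics for the density sweep
    comparisons: tuple = ("TLE", "IGE")
    subgroup: str | None = None    # None | "laterality" | "duration"


@dataclass
class ComparisonResult:
    patient_group: str
    sites: list[str]
    n_matrices: int
    passes: dict
    valid_range: tuple | None
    analysis_density: float
    global_tests: dict[str, GlobalComparison]
    topology: TopologyChangeMap
    d_clustering: np.ndarray
    d_path_length: np.ndarray
    d_small_world: np.ndarray
    atrophy: object
    site_delta_clustering: np.ndarray   # sites x regions
    site_delta_path: np.ndarray


@dataclass
class PipelineResult:
    table: RegionTable
    cohort: PreprocessedCohort
    comparisons: dict[str, ComparisonResult]
    associations: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)


def build_site_networks(cohort: PreprocessedCohort, patient_group: str,
                        min_subjects: int = 10
                        ) -> dict[str, tuple[CovarianceNetwork, CovarianceNetwork]]:
    """Per-site (patient, control) covariance matrices; small sites skipped."""
    out = {}
    for site in sorted(cohort.meta["site"].unique()):
        try:
            pat = build_covariance(cohort, site, patient_group,
                                   min_subjects=min_subjects)
            ctl = build_covariance(cohort, site, "HC", min_subjects=min_subjects)
        except CohortTooSmallError as exc:
            log.info("skipping %s for %s: %s", site, patient_group, exc)
            continue
        out[site] = (pat, ctl)
    return out


def _site_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_comparison(cohort: PreprocessedCohort, table: RegionTable,
                   patient_group: str, cfg: PipelineConfig) -> ComparisonResult:
    """Full patient-vs-control analysis for one diagnostic group."""
    nets = build_site_networks(cohort, patient_group, cfg.min_subjects)
    if len(nets) < 3:
        raise CohortTooSmallError(
            f"{patient_group}: only {len(nets)} usable sites")
    sites = list(nets)
    n_matrices = 2 * len(sites)

    # threshold every network over the grid; screen connectedness
    thr = {K: [threshold(net, K) for pair in nets.values() for net in pair]
           for K in cfg.densities}
    passes, valid_range = connectedness_range(
        thr, node_frac=cfg.node_frac, site_frac=cfg.site_frac)
    if valid_range is None:
        raise ValueError(f"{patient_group}: no density passes connectedness")
    K0 = cfg.analysis_density if cfg.analysis_density is not None else valid_range[0]

    # density-wise global metrics (raw by default for the sweep)
    sweep_nulls = cfg.n_nulls if cfg.normalize_global_sweep else 0
    seeds = _site_seeds(cfg.seed, 4 * len(sites))
    rows_c, rows_l, rows_s, rows_w = {}, {}, {}, {}
    valid_ks = [K for K in cfg.densities if valid_range[0] <= K <= valid_range[1]]
    for si, site in enumerate(sites):
        pat_net, ctl_net = nets[site]
        for gi, net in enumerate((pat_net, ctl_net)):
            col = "patient" if gi == 0 else "control"
            for K in valid_ks:
                t = threshold(net, K)
                topo = normalized_topology(
                    t.W, n_nulls=sweep_nulls,
                    rng=seeds[2 * si + gi], density=K)
                rows_c.setdefault((col, site), {})[K] = topo.global_clustering
                rows_l.setdefault((col, site), {})[K] = topo.global_path_length
                rows_s.setdefault((col, site), {})[K] = (
                    topo.global_clustering / topo.global_path_length
                    if sweep_nulls == 0 else topo.global_small_world)
                rows_w.setdefault((col, site), {})[K] = mean_positive_strength(t)

    def _frames(rows):
        pat = pd.DataFrame({K: {s: rows[("patient", s)][K] for s in sites}
                            for K in valid_ks})
        ctl = pd.DataFrame({K: {s: rows[("control", s)][K] for s in sites}
                            for K in valid_ks})
        return pat, ctl

    global_tests = {}
    for name, rows in (("clustering", rows_c), ("path_length", rows_l),
                       ("small_world", rows_s), ("strength", rows_w)):
        pat, ctl = _frames(rows)
        global_tests[name] = global_density_tests(
            pat, ctl, metric=name, fdr_alpha=cfg.fdr_alpha_global)

    # regional topology at the analysis density, null-normalized
    n = table.n_regions
    dC = np.zeros((len(sites), n))
    dL = np.zeros((len(sites), n))
    pat_C = np.zeros((len(sites), n)); ctl_C = np.zeros((len(sites), n))
    pat_L = np.zeros((len(sites), n)); ctl_L = np.zeros((len(sites), n))
    pat_S = np.zeros((len(sites), n)); ctl_S = np.zeros((len(sites), n))
    for si, site in enumerate(sites):
        pat_net, ctl_net = nets[site]
        tp = threshold(pat_net, K0)
        tc = threshold(ctl_net, K0)
        topo_p = normalized_topology(tp.W, n_nulls=cfg.n_nulls,
                                     rng=seeds[2 * len(sites) + 2 * si],
                                     density=K0)
        topo_c = normalized_topology(tc.W, n_nulls=cfg.n_nulls,
                                     rng=seeds[2 * len(sites) + 2 * si + 1],
                                     density=K0)
        if cfg.n_nulls > 0:
            cp, lp = topo_p.clustering_norm, topo_p.path_length_norm
            cc, lc = topo_c.clustering_norm, topo_c.path_length_norm
            sp, sc = topo_p.small_world, topo_c.small_world
        else:
            cp, lp = topo_p.clustering, topo_p.path_length
            cc, lc = topo_c.clustering, topo_c.path_length
            with np.errstate(invalid="ignore", divide="ignore"):
                sp = cp / lp
                sc = cc / lc
        pat_C[si], ctl_C[si] = cp, cc
        pat_L[si], ctl_L[si] = lp, lc
        pat_S[si], ctl_S[si] = sp, sc
        dC[si] = cp - cc
        dL[si] = lp - lc

    d_clust = cohens_d_map(pat_C, ctl_C)
    d_path = cohens_d_map(pat_L, ctl_L)
    d_sw = cohens_d_map(pat_S, ctl_S)
    topology = hotelling_map(dC, dL, d_clustering=d_clust,
                             d_path_length=d_path, d_small_world=d_sw)
    atro = atrophy_map(cohort, patient_group=patient_group, sites=sites)

    return ComparisonResult(
        patient_group=patient_group, sites=sites, n_matrices=n_matrices,
        passes=passes, valid_range=valid_range, analysis_density=float(K0),
        global_tests=global_tests, topology=topology,
        d_clustering=d_clust, d_path_length=d_path, d_small_world=d_sw,
        atrophy=atro, site_delta_clustering=dC, site_delta_path=dL)


def preprocess_cohort(raw, table: RegionTable) -> PreprocessedCohort:
    """impute/filter -> residualize/z-score -> ipsi/contra sorting."""
    filtered = impute_and_filter(raw, table)
    pre = residualize_and_zscore(filtered)
    return sort_ipsi_contra(pre, table)


def run_pipeline(raw_cohort, table: RegionTable | None, cfg: PipelineConfig,
                 expression: pd.DataFrame | None = None,
                 gene_sets: dict[str, GeneSet] | None = None,
                 outdir=None) -> PipelineResult:
    """Execute all stages on an in-memory cohort; optionally write outputs.

    `raw_cohort` is a list of SubjectMorphometry; `gene_sets` maps a set name
    to the patient group whose topology map it is tested against via the
    "<group>:<name>" key convention, or is tested against every comparison
    when the name carries no group prefix.
    """
    if table is None:
        table = default_region_table()
    pre = preprocess_cohort(raw_cohort, table)

    comparisons: dict[str, ComparisonResult] = {}
    for group in cfg.comparisons:
        comparisons[group] = run_comparison(pre, table, group, cfg)

    associations: dict[str, object] = {}
    if expression is not None and gene_sets:
        ss = np.random.SeedSequence([cfg.seed, 7])
        seeds = [int(s.generate_state(1)[0] % (2 ** 31))
                 for s in ss.spawn(len(gene_sets) * len(comparisons))]
        i = 0
        for group, comp in comparisons.items():
            topo_map = comp.topology.signed_change
            bad = ~np.isfinite(topo_map)
            if bad.any():
                log.info("%s: %d region(s) without a usable multivariate "
                         "estimate set to 0 for spatial correlation",
                         group, int(bad.sum()))
                topo_map = np.where(bad, 0.0, topo_map)
            for name, gs in gene_sets.items():
                if ":" in name and not name.startswith(f"{group}:"):
                    i += 1
                    continue
                associations[f"{group}:{gs.name}"] = imaging_transcriptomic_assoc(
                    topo_map, expression, gs,
                    table.sphere_xyz, n_perm=cfg.n_perm, rng=seeds[i])
                i += 1

    summary = {
        "n_subjects": int(len(pre.meta)),
        "n_regions": int(table.n_regions),
        "n_cortical": int(table.cortical_mask.sum()),
        "n_subcortical": int(table.subcortical_mask.sum()),
        "n_covariance_matrices": int(sum(c.n_matrices
                                         for c in comparisons.values())),
        "seed": cfg.seed,
        "n_nulls": cfg.n_nulls,
        "n_perm": cfg.n_perm,
    }
    for group, comp in comparisons.items():
        top = np.argsort(-np.abs(comp.topology.signed_change))[:5]
        summary[group] = {
            "sites": comp.sites,
            "n_matrices": comp.n_matrices,
            "valid_density_range": [float(v) for v in comp.valid_range],
            "analysis_density": comp.analysis_density,
            "n_regions_fdr_significant": int(
                np.nansum(comp.topology.p_fdr < cfg.fdr_alpha_regional)),
            "top_regions": [table.names[i] for i in top],
        }
    for key, assoc in associations.items():
        summary.setdefault("associations", {})[key] = {
            "r": assoc.r, "p_spin": assoc.p_spin, "p_rand": assoc.p_rand,
            "n_genes_used": assoc.n_genes_used,
        }

    result = PipelineResult(table=table, cohort=pre, comparisons=comparisons,
                            associations=associations, summary=summary)
    if outdir is not None:
        _write_outputs(result, cfg, outdir)
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig, outdir) -> None:
    from pathlib import Path
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    names = result.table.names
    for group, comp in result.comparisons.items():
        rows = pd.DataFrame({
            "region": names,
            "d_clustering": comp.d_clustering,
            "d_path_length": comp.d_path_length,
            "d_small_world": comp.d_small_world,
            "t2": comp.topology.t2,
            "p": comp.topology.p,
            "p_fdr": comp.topology.p_fdr,
            "signed_change": comp.topology.signed_change,
            "atrophy_d": comp.atrophy.d,
            "atrophy_p_fdr": comp.atrophy.p_fdr,
        })
        rows.to_csv(out / f"regional_{group}.csv", index=False)
        for metric, gc in comp.global_tests.items():
            gc.table.to_csv(out / f"global_{group}_{metric}.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=2, default=str)
    log.info("pipeline outputs written to %s", out)


def threshold_stability(cohort: PreprocessedCohort, table: RegionTable,
                        patient_group: str, cfg: PipelineConfig,
                        densities=None) -> pd.DataFrame:
    """Pairwise correlation of multivariate change maps across densities.

    Hotelling signed-change maps are recomputed from networks thresholded at
    every density of the grid (raw nodal metrics); the result is the density x
    density Pearson correlation matrix of those maps.
    """
    nets = build_site_networks(cohort, patient_group, cfg.min_subjects)
    sites = list(nets)
    ks = list(cfg.densities if densities is None else densities)
    n = table.n_regions
    maps = []
    for K in ks:
        dC = np.zeros((len(sites), n))
        dL = np.zeros((len(sites), n))
        for si, site in enumerate(sites):
            pat_net, ctl_net = nets[site]
            tp = threshold(pat_net, K)
            tc = threshold(ctl_net, K)
            topo_p = normalized_topology(tp.W, n_nulls=0)
            topo_c = normalized_topology(tc.W, n_nulls=0)
            dC[si] = topo_p.clustering - topo_c.clustering
            dL[si] = np.nan_to_num(topo_p.path_length - topo_c.path_length)
        maps.append(hotelling_map(dC, dL).signed_change)
    M = np.corrcoef(np.array(maps))
    return pd.DataFrame(M, index=ks, columns=ks)


def per_site_maps(cohort: PreprocessedCohort, table: RegionTable,
                  patient_group: str, cfg: PipelineConfig,
                  density: float) -> pd.DataFrame:
    """Per-site nodal metric differences (patient minus control) at one density."""
    nets = build_site_networks(cohort, patient_group, cfg.min_subjects)
    rows = []
    for site, (pat_net, ctl_net) in nets.items():
        tp = threshold(pat_net, density)
        tc = threshold(ctl_net, density)
        topo_p = normalized_topology(tp.W, n_nulls=0)
        topo_c = normalized_topology(tc.W, n_nulls=0)
        for r, name in enumerate(table.names):
            rows.append({
                "site": site, "region": name,
                "delta_clustering": topo_p.clustering[r] - topo_c.clustering[r],
                "delta_path_length": topo_p.path_length[r] - topo_c.path_length[r],
            })
    return pd.DataFrame(rows)
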