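# covnet

Structural covariance network analysis for multisite brain-morphometry
studies, with imaging–transcriptomic association testing.

## The problem

In the common epilepsies (temporal lobe epilepsy, TLE, and idiopathic
generalized epilepsy, IGE), regional cortical thinning and subcortical volume
loss are well documented, but the *coordination* of morphology across regions
— structural covariance — carries complementary information about network
organization. Large consortia aggregate per-site summary data from many
scanners, so the analysis must operate on group- and site-specific networks
rather than pooled subject-level data. `covnet` implements that workflow as a
tested, reusable library:

1. **Preprocessing** — regional cortical thickness (68 Desikan–Killiany
   parcels) and subcortical volumes (14 structures) are mean-imputed,
   residualized for age and sex per site, z-scored against site-matched
   controls, and re-sorted into ipsilateral/contralateral order for focal
   patients.
2. **Covariance networks** — for each diagnostic group and site with at
   least 10 subjects per group, the matrix *R* holds Pearson correlations
   *R*ᵢⱼ of regional morphometry across subjects. Negative entries are
   zeroed and *R* is thresholded over a density grid *K* = 0.05–0.50
   (step 0.01), retaining the round(*K·n(n−1)/2*) strongest positive weights
   so that all groups have identical edge counts. Densities are screened for
   connectedness (≥75 % of nodes in the largest component in ≥90 % of
   sites).
3. **Graph metrics** — weighted clustering coefficient *C* (Onnela
   formulation), characteristic path length *L* (Dijkstra with edge length
   1/*w*), and the small-world index σ = *C*norm/*L*norm, where "norm"
   divides by the mean over degree- and weight-preserving rewired null
   networks (Maslov–Sneppen swaps, weights re-assigned).
4. **Group statistics** — density-wise paired t-tests across sites with
   BH-FDR; nodal Cohen's *d* maps; and a per-region paired Hotelling *T*²
   combining clustering and path-length changes, signed by the dominant
   direction (positive = regularization: *C* and *L* jointly increased;
   negative = randomization).
5. **Transcriptomic association** — the signed topology-change map is
   correlated with gene-set expression maps (region × gene matrix averaged
   over the set). Significance is one-tailed against (i) spin permutations
   of the map on the merged cortical/subcortical sphere (*p*spin), with a
   variogram-matching surrogate model as cross-check, and (ii) random
   equal-size gene sets (*p*rand). Cell-type specificity enrichment uses the
   same random-gene machinery.
6. **Synthetic data** — a generator produces every input at desk scale
   (multisite cohorts with planted covariance effects, spatially
   autocorrelated expression with a planted gene set, cell-type matrices),
   so the full pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from covnet import (SimulationConfig, PipelineConfig, default_region_table,
                    simulate_cohort, simulate_expression, run_pipeline,
                    imaging_transcriptomic_assoc)

table = default_region_table()           # 82 regions, merged sphere coords
raw = simulate_cohort(SimulationConfig(), seed=7, table=table)

cfg = PipelineConfig(n_nulls=50, n_perm=1000, seed=7)
result = run_pipeline(raw, table, cfg)

tle = result.comparisons["TLE"]
print("covariance matrices:", result.summary["n_covariance_matrices"])
print("valid density range:", tle.valid_range)
print("planted-module mean clustering d:", np.nanmean(tle.d_clustering[:10]))

topo_map = np.nan_to_num(tle.topology.signed_change)
expr, gs = simulate_expression(table.sphere_xyz, 500, 30.0,
                               planted=(topo_map, 0.5, 20), seed=8)
assoc = imaging_transcriptomic_assoc(topo_map, expr, gs, table.sphere_xyz,
                                     n_perm=1000, rng=9)
print(f"r={assoc.r:.2f} p_spin={assoc.p_spin:.4f} p_rand={assoc.p_rand:.4f}")
```

Output:

```
covariance matrices: 48
valid density range: (0.05, 0.5)
planted-module mean clustering d: 1.49
r=0.91 p_spin=0.0020 p_rand=0.0010
```

The 14 + 10 site layout yields 48 group/site covariance matrices (patients
and site-matched controls for each comparison). The planted within-module
correlation increase surfaces as a large positive clustering effect size in
the planted regions (*d* ≈ 1.5 versus ≈ −0.2 elsewhere), and the gene set
planted at target correlation ρ* = 0.5 with the topology map is detected at
*r* = 0.91 with both nulls far below α = 0.05 (20 averaged genes with
individual correlation 0.5 give a set-mean map correlating ≈ 0.9).

A CLI mirrors the stages (`covnet simulate`, `covnet preprocess`,
`covnet run`, `covnet spin`, `covnet stability`, `covnet regions validate`);
see `covnet --help`.

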