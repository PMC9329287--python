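import numpy as np
import pytest

from covnet import (SimulationConfig, ValidationError, simulate_celltype_matrix,
                    simulate_cohort, simulate_expression)
from covnet.simulate import (group_correlation, nearest_psd_correlation,
                             planted_region_mask)


def test_config_validation():
    with pytest.raises(ValidationError, match="sum to n_regions"):
        SimulationConfig(module_sizes=(10, 10))
    with pytest.raises(ValidationError, match="planted_rho"):
        SimulationConfig(planted_rho=1.5)


def test_group_covariances_psd_and_planted_effect(sim_config):
    for g in ("HC", "TLE", "IGE"):
        C = group_correlation(sim_config, g)
        assert np.linalg.eigvalsh(C).min() >= -1e-12
        assert np.allclose(np.diag(C), 1.0)
    mask = planted_region_mask(sim_config)
    C_hc = group_correlation(sim_config, "HC")
    C_tle = group_correlation(sim_config, "TLE")
    block = np.ix_(mask, mask)
    off = ~np.eye(int(mask.sum()), dtype=bool)
    assert np.all(C_tle[block][off] > C_hc[block][off])
    # no planted effect -> identical generating covariances
    cfg0 = SimulationConfig(regularization_delta=0.0)
    assert np.allclose(group_correlation(cfg0, "TLE"),
                       group_correlation(cfg0, "HC"))


def test_nearest_psd_projection():
    C = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
    P = nearest_psd_correlation(C)
    assert np.linalg.eigvalsh(P).min() >= -1e-12
    assert np.allclose(np.diag(P), 1.0)


def test_cohort_determinism_and_layout(sim_config, table):
    a = simulate_cohort(sim_config, 3, table)
    b = simulate_cohort(sim_config, 3, table)
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert sa.subject_id == sb.subject_id
        assert np.array_equal(np.nan_to_num(sa.values), np.nan_to_num(sb.values))
    sites = {s.site for s in a}
    assert len(sites) == 14
    ige_sites = {s.site for s in a if s.group == "IGE"}
    assert len(ige_sites) == 10
    tle = [s for s in a if s.group == "TLE"]
    assert all(s.focus_side in ("left", "right") for s in tle)


def test_planted_correlation_increase_in_samples(sim_config, table):
    """Sample within-module correlations are higher in patients (per site)."""
    mask = planted_region_mask(sim_config)
    wins = 0
    for seed in range(10):
        cohort = simulate_cohort(sim_config, 100 + seed, table)
        vals = {}
        for g in ("HC", "TLE"):
            X = np.array([s.values for s in cohort
                          if s.site == "site01" and s.group == g])
            X = np.where(np.isnan(X), np.nanmean(X, axis=0), X)
            R = np.corrcoef(X[:, mask], rowvar=False)
            vals[g] = R[np.triu_indices_from(R, 1)].mean()
        wins += vals["TLE"] > vals["HC"]
    assert wins >= 9


def test_expression_planted_correlation(table):
    rng = np.random.default_rng(0)
    target = rng.standard_normal(82)
    # rho = 1: planted genes correlate perfectly with the target
    expr, gs = simulate_expression(table.sphere_xyz, 50, 30.0,
                                   (target, 0.999999, 5), seed=1)
    for g in gs.symbols:
        assert abs(np.corrcoef(expr[g], target)[0, 1]) > 0.999
    assert ((expr.min() >= 0) & (expr.max() <= 1)).all()
    # rho = 0.5: mean planted correlation within 0.5 +/- 0.1 across seeds
    rs = []
    for seed in range(25):
        expr, gs = simulate_expression(table.sphere_xyz, 60, 30.0,
                                       (target, 0.5, 20), seed=seed)
        rs.extend(np.corrcoef(expr[g], target)[0, 1] for g in gs.symbols)
    assert abs(np.mean(rs) - 0.5) < 0.1


def test_expression_smoothness_limit(table):
    rng = np.random.default_rng(2)
    coords = table.sphere_xyz
    smooth, _ = simulate_expression(coords, 40, 60.0, None, seed=3)
    rough, _ = simulate_expression(coords, 40, 0.01, None, seed=3)

    def moran_like(df):
        d = np.arccos(np.clip(coords @ coords.T, -1, 1))
        wgt = (d < 0.5) & (d > 0)
        vals = []
        for c in df:
            x = df[c] - df[c].mean()
            vals.append((wgt * np.outer(x, x)).sum()
                        / (wgt.sum() * x.var()))
        return np.mean(vals)

    assert moran_like(smooth) > 0.3
    assert abs(moran_like(rough)) < 0.1


def test_celltype_matrix_properties():
    genes = [f"g{i}" for i in range(100)]
    spec = simulate_celltype_matrix(genes, seed=4)
    assert spec.shape == (100, 29)
    assert (spec.to_numpy() >= 0).all()
    means = spec.mean(axis=0)
    assert means.std() / means.mean() < 0.2      # balanced without planting
    spec_p = simulate_celltype_matrix(genes, planted={3: genes[:10]}, seed=4)
    assert spec_p.iloc[:10, 3].mean() > spec_p.to_numpy().mean() + 1.0
    assert np.array_equal(simulate_celltype_matrix(genes, seed=5).to_numpy(),
                          simulate_celltype_matrix(genes, seed=5).to_numpy())
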