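import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from covnet import (ValidationError, atrophy_map, bh_fdr, cohens_d,
                    cohens_d_map, global_density_tests, hotelling_map)


def step_up_fdr(p):
    """Independent BH oracle: textbook step-up with monotonicity pass."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 10_000))
def test_bh_fdr_matches_step_up_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.random(rng.integers(1, 40))
    assert np.allclose(bh_fdr(p), step_up_fdr(p), atol=1e-12)
    assert np.all(bh_fdr(p) >= p - 1e-12)


def _frames(pat, ctl):
    sites = [f"s{i}" for i in range(len(pat))]
    cols = [0.1, 0.2]
    return (pd.DataFrame({c: pat for c in cols}, index=sites),
            pd.DataFrame({c: ctl for c in cols}, index=sites))


def test_global_tests_degenerate_cases():
    pat, ctl = _frames([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
    res = global_density_tests(pat, ctl)
    assert np.allclose(res.table["t"], 0.0)
    assert np.allclose(res.table["p"], 1.0)
    pat2, ctl2 = _frames([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
    res2 = global_density_tests(pat2, ctl2)
    assert res2.table["degenerate"].all()
    assert np.allclose(res2.table["p"], 0.0)
    with pytest.raises(ValidationError, match="3 paired sites"):
        global_density_tests(*_frames([1.0, 2.0], [1.0, 2.0]))


def test_global_tests_match_scipy_on_noise():
    from scipy import stats as sps
    rng = np.random.default_rng(6)
    pat, ctl = _frames(rng.normal(1, 0.3, 10), rng.normal(1, 0.3, 10))
    res = global_density_tests(pat, ctl)
    t, p = sps.ttest_rel(pat[0.1], ctl[0.1])
    assert res.table.loc[0, "t"] == pytest.approx(float(t))
    assert res.table.loc[0, "p"] == pytest.approx(float(p))


def test_cohens_d_hand_value_and_antisymmetry():
    pat = np.array([[2.0], [4.0]])
    ctl = np.array([[1.0], [3.0]])
    d = cohens_d_map(pat, ctl)
    assert d[0] == pytest.approx(1.0 / np.sqrt(2.0))
    assert cohens_d_map(ctl, pat)[0] == pytest.approx(-d[0])
    assert cohens_d_map(pat, pat)[0] == pytest.approx(0.0)
    # zero pooled SD -> flagged missing
    same = np.ones((3, 1))
    assert np.isnan(cohens_d_map(same, same * 2)[0])


def test_hotelling_matches_direct_formula_and_symmetries():
    rng = np.random.default_rng(9)
    dC = rng.normal(0.3, 0.2, size=(10, 6))
    dL = rng.normal(0.1, 0.3, size=(10, 6))
    res = hotelling_map(dC, dL)
    # independent linear-algebra oracle
    for r in range(6):
        D = np.column_stack([dC[:, r], dL[:, r]])
        dbar = D.mean(0)
        S = np.cov(D.T, ddof=1)
        t2 = 10 * dbar @ np.linalg.inv(S) @ dbar
        assert res.t2[r] == pytest.approx(t2, abs=1e-10)
    # exchanging the two variables leaves T^2 unchanged
    res_swapped = hotelling_map(dL, dC)
    assert np.allclose(res.t2, res_swapped.t2, atol=1e-10)
    # sign convention: mean along (1,1) -> positive (regularization)
    up = hotelling_map(np.full((6, 2), 0.5) + rng.normal(0, 0.1, (6, 2)),
                       np.full((6, 2), 0.5) + rng.normal(0, 0.1, (6, 2)))
    assert np.all(up.signed_change > 0)


def test_hotelling_zero_differences():
    z = np.zeros((5, 3))
    res = hotelling_map(z, z)
    assert np.allclose(res.t2, 0.0)
    assert np.allclose(res.p, 1.0)
    with pytest.raises(ValidationError, match=">= 4 sites"):
        hotelling_map(z[:3], z[:3])


def test_atrophy_map_sign_and_recovery(table, sim_config):
    """Planted z-score atrophy surfaces with negative d in the right regions."""
    from covnet import simulate_cohort
    from covnet.pipeline import preprocess_cohort
    rng = np.random.default_rng(12)
    raw = simulate_cohort(sim_config, seed=12, table=table)
    # plant on whole homologue pairs: the ipsi/contra re-sorting permutes
    # within pairs, so pair-symmetric atrophy survives it unchanged
    planted = np.zeros(table.n_regions, bool)
    planted[[20, 21, 40, 41, 60, 61]] = True
    cort_sd = np.where(table.cortical_mask, 0.15, 400.0)
    for s in raw:
        if s.group == "TLE":
            s.values = s.values - 0.5 * cort_sd * planted
    pre = preprocess_cohort(raw, table)
    amap = atrophy_map(pre, "TLE")
    worst = np.argsort(amap.d)[:6]
    assert set(worst) == set(np.flatnonzero(planted))
    assert np.all(amap.d[planted] < 0)
    # null case: no planted difference for IGE beyond covariance structure
    amap_ige = atrophy_map(pre, "IGE")
    assert np.nanmax(np.abs(amap_ige.d)) < 0.5


def test_topology_and_atrophy_dissociation(table):
    """Independently planted maps should not correlate spatially."""
    rng = np.random.default_rng(99)
    reps = [abs(np.corrcoef(rng.normal(size=82), rng.normal(size=82))[0, 1])
            for _ in range(200)]
    assert np.mean(reps) < 0.15


def test_cohens_d_nan_site_handling():
    pat = np.array([[1.0], [np.nan], [2.0], [3.0]])
    ctl = np.array([[0.5], [0.7], [1.0], [np.nan]])
    d = cohens_d(pat, ctl, axis=0)
    ref = cohens_d(np.array([[1.0], [2.0], [3.0]]),
                   np.array([[0.5], [0.7], [1.0]]), axis=0)
    assert d[0] == pytest.approx(ref[0])
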