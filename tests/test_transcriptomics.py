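import numpy as np
import pandas as pd
import pytest

from covnet import (GeneSet, ValidationError, celltype_difference,
                    celltype_specificity, geneset_expression_map,
                    imaging_transcriptomic_assoc, random_gene_null,
                    simulate_celltype_matrix)


@pytest.fixture()
def expr():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.random((10, 6)),
                        columns=[f"g{i}" for i in range(6)])


def test_geneset_map_trivial_cases(expr):
    one = geneset_expression_map(expr, GeneSet("one", ["g2"]))
    assert np.allclose(one, expr["g2"])
    two = geneset_expression_map(expr, GeneSet("two", ["g1", "g3"]))
    assert np.allclose(two, (expr["g1"] + expr["g3"]) / 2)
    full = geneset_expression_map(expr, GeneSet("all", list(expr.columns)))
    assert np.allclose(full, expr.mean(axis=1))


def test_geneset_map_missing_symbols(expr):
    m = geneset_expression_map(expr, GeneSet("mix", ["g1", "nope"]))
    assert np.allclose(m, expr["g1"])
    with pytest.raises(ValidationError, match="no overlap"):
        geneset_expression_map(expr, GeneSet("none", ["zz"]))


def test_geneset_map_permutation_equivariance(expr):
    perm = np.random.default_rng(1).permutation(len(expr))
    gs = GeneSet("two", ["g0", "g5"])
    m = geneset_expression_map(expr, gs)
    mp = geneset_expression_map(expr.iloc[perm].reset_index(drop=True), gs)
    assert np.allclose(mp, m[perm])


def test_random_gene_null_degenerate_and_deterministic(expr):
    topo = np.arange(10, dtype=float)
    full = expr.mean(axis=1).to_numpy()
    r_emp = np.corrcoef(topo, full)[0, 1]
    nulls, p = random_gene_null(topo, expr, 6, n_perm=50, rng=1, r_emp=r_emp)
    assert p == 1.0                       # full-universe set: every null ties
    n1, _ = random_gene_null(topo, expr, 3, n_perm=30, rng=5)
    n2, _ = random_gene_null(topo, expr, 3, n_perm=30, rng=5)
    assert np.array_equal(n1, n2)
    with pytest.raises(ValidationError, match="exceeds"):
        random_gene_null(topo, expr, 7, n_perm=10, rng=0)


def test_random_gene_null_size_one_is_per_gene_distribution(expr):
    topo = np.arange(10, dtype=float)
    nulls, _ = random_gene_null(topo, expr, 1, n_perm=400, rng=2)
    per_gene = np.array([np.corrcoef(topo, expr[g])[0, 1] for g in expr])
    assert set(np.round(np.unique(nulls), 12)) <= set(np.round(per_gene, 12))


def test_association_self_map(table):
    from covnet import simulate_expression
    rng = np.random.default_rng(3)
    target = rng.standard_normal(82)
    expr82, gs = simulate_expression(table.sphere_xyz, 100, 30.0,
                                     (target, 0.999, 10), seed=4)
    gmap = geneset_expression_map(expr82, gs)
    res = imaging_transcriptomic_assoc(gmap, expr82, gs, table.sphere_xyz,
                                       n_perm=100, rng=5)
    assert res.r == pytest.approx(1.0)
    assert res.p_spin < 0.05 and res.p_rand < 0.05
    assert res.n_genes_used == 10


def test_celltype_specificity_planted_and_discard():
    genes = [f"g{i}" for i in range(60)]
    planted = genes[:8]
    spec = simulate_celltype_matrix(genes, n_celltypes=5,
                                   planted={2: planted}, seed=6)
    res = celltype_specificity(GeneSet("p", planted), spec, n_perm=400, rng=7)
    assert int(np.nanargmin(res.p_rand)) == 2
    assert res.mean_specificity[2] > res.mean_specificity.mean()
    # full-universe set ties every null -> p = 1
    res_full = celltype_specificity(GeneSet("all", genes), spec,
                                    n_perm=100, rng=8)
    assert np.allclose(res_full.p_rand, 1.0)
    # an all-zero specificity column is discarded and counted
    spec0 = spec.copy()
    spec0.iloc[:, 4] = 0.0
    res0 = celltype_specificity(GeneSet("p", planted), spec0, n_perm=50, rng=9)
    assert res0.empirical_discarded[4]
    assert np.isnan(res0.p_rand[4])
    assert res0.n_discarded[4] == 50


def test_celltype_difference_zero_and_planted():
    genes = [f"g{i}" for i in range(80)]
    a = genes[:10]
    b = genes[10:20]
    spec = simulate_celltype_matrix(genes, n_celltypes=6,
                                   planted={1: a, 3: b}, seed=10)
    same = celltype_difference(GeneSet("a", a), GeneSet("a2", a), spec,
                               n_perm=100, rng=11)
    assert np.allclose(same["delta"], 0.0)
    diff = celltype_difference(GeneSet("a", a), GeneSet("b", b), spec,
                               n_perm=400, rng=12)
    # where only A loads, the delta is extreme relative to "random stands in
    # for A" (and vice versa); the complementary null is centred on the
    # observed delta and cannot flag it
    assert diff.nsmallest(1, "p_vs_randA")["cell_type"].item() == "celltype02"
    assert diff.nsmallest(1, "p_vs_randB")["cell_type"].item() == "celltype04"
    d = dict(zip(diff["cell_type"], diff["delta"]))
    assert d["celltype02"] > 0 > d["celltype04"]
    assert (diff["p_combined"] >= diff[["p_vs_randA", "p_vs_randB"]]
            .max(axis=1) - 1e-12).all()
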