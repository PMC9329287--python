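"""Imaging-transcriptomic association and cell-type specificity.

Consumes an already-built region x gene expression matrix (regions indexed
identically to the parcellation).  A gene set's expression map is the
per-region mean over its available gene columns.  The spatial correlation
between a topology-change map and a gene-set map is tested one-tailed
(positive) against two nulls: spin permutations of the topology map, and
"random-gene" nulls built from equally sized gene sets drawn without
replacement from the full gene universe.  Cell-type specificity of a gene set
is its mean specificity score per cell type, compared two-tailed against
random equal-size gene sets; empirical or null gene lists whose mean
specificity is exactly zero are discarded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import ValidationError
from .nulls import SpinResult, p_spin

__all__ = [
    "GeneSet",
    "AssociationResult",
    "CellTypeResult",
    "load_gene_set",
    "geneset_expression_map",
    "random_gene_null",
    "imaging_transcriptomic_assoc",
    "celltype_specificity",
    "celltype_difference",
]


@dataclass
class GeneSet:
    """Named list of gene symbols (e.g. a GWAS risk-gene list)."""

    name: str
    symbols: list[str]
    note: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValidationError(f"gene set {self.name!r} has duplicate symbols")


def load_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a newline-delimited gene-symbol file."""
    with open(path) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    return GeneSet(name=name or str(path), symbols=symbols)


def _overlap(expr: pd.DataFrame, gs: GeneSet) -> tuple[list[str], list[str]]:
    present = [g for g in gs.symbols if g in expr.columns]
    missing = [g for g in gs.symbols if g not in expr.columns]
    if not present:
        raise ValidationError(
            f"gene set {gs.name!r} has no overlap with the expression matrix; "
            f"missing symbols: {missing}")
    return present, missing


def geneset_expression_map(expr: pd.DataFrame, gs: GeneSet) -> np.ndarray:
    """Per-region mean expression over the set's available genes.

    Missing entries are excluded pairwise; genes absent from the matrix are
    dropped (an error is raised only when no gene overlaps).
    """
    present, _ = _overlap(expr, gs)
    return expr[present].mean(axis=1, skipna=True).to_numpy(dtype=float)


def _null_maps(expr_values: np.ndarray, set_size: int, n_perm: int,
               rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_regions) maps of random equal-size gene-set means."""
    n_genes = expr_values.shape[1]
    idx = np.empty((n_perm, set_size), dtype=int)
    for t in range(n_perm):
        idx[t] = rng.choice(n_genes, size=set_size, replace=False)
    # mean over chosen columns, vectorized: gather then average
    return expr_values[:, idx].mean(axis=2).T


def _one_tailed(nulls: np.ndarray, emp: float, tol: float = 1e-12) -> float:
    # tol guards ties that differ only by floating-point summation order
    # (e.g. the degenerate full-universe draw, where every null equals r_emp)
    return (1.0 + np.sum(nulls >= emp - tol)) / (1.0 + nulls.size)


def random_gene_null(topo_map: np.ndarray, expr: pd.DataFrame, set_size: int,
                     n_perm: int = 10000,
                     rng: np.random.Generator | int | None = None,
                     r_emp: float | None = None):
    """Null r distribution from random equal-size gene sets, and p_rand.

    Each draw takes `set_size` genes without replacement from the full
    universe, averages them to a map and correlates it with topo_map.
    p_rand (one-tailed positive, add-one corrected) is computed when the
    empirical correlation `r_emp` is supplied, else None.
    """
    n_genes = expr.shape[1]
    if set_size > n_genes:
        raise ValidationError(
            f"set_size {set_size} exceeds gene universe {n_genes}")
    rng = np.random.default_rng(rng)
    topo = np.asarray(topo_map, dtype=float)
    values = expr.to_numpy(dtype=float)
    maps = _null_maps(values, set_size, n_perm, rng)
    tm = topo - topo.mean()
    mm = maps - maps.mean(axis=1, keepdims=True)
    denom = np.sqrt((mm ** 2).sum(axis=1) * (tm ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        nulls = (mm @ tm) / denom
    nulls = np.where(np.isfinite(nulls), nulls, -np.inf)
    p_rand = _one_tailed(nulls, r_emp) if r_emp is not None else None
    return nulls, p_rand


@dataclass
class AssociationResult:
    """Spatial correlation of a topology map with a gene-set expression map."""

    r: float
    p_spin: float
    p_rand: float
    n_genes_used: int
    n_genes_missing: int
    n_perm: int
    spin: SpinResult = field(repr=False, default=None)
    rand_nulls: np.ndarray = field(repr=False, default=None)


def imaging_transcriptomic_assoc(topo_map: np.ndarray, expr: pd.DataFrame,
                                 gs: GeneSet, sphere_xyz: np.ndarray,
                                 n_perm: int = 10000,
                                 rng: np.random.Generator | int | None = None
                                 ) -> AssociationResult:
    """Test a topology-change map against a gene-set expression map.

    One-tailed positive: p_spin spins the topology map over the merged
    sphere; p_rand redraws equally sized random gene sets.
    """
    rng = np.random.default_rng(rng)
    present, missing = _overlap(expr, gs)
    gmap = geneset_expression_map(expr, gs)
    spin = p_spin(np.asarray(topo_map, float), gmap, sphere_xyz,
                  n_perm=n_perm, rng=rng)
    nulls, p_rand = random_gene_null(topo_map, expr, len(present),
                                     n_perm=n_perm, rng=rng, r_emp=spin.r)
    return AssociationResult(r=spin.r, p_spin=spin.p, p_rand=p_rand,
                             n_genes_used=len(present),
                             n_genes_missing=len(missing),
                             n_perm=n_perm, spin=spin, rand_nulls=nulls)


# -- cell-type specificity ----------------------------------------------------

@dataclass
class CellTypeResult:
    """Mean specificity per cell type with random-gene two-tailed p-values."""

    cell_types: list[str]
    mean_specificity: np.ndarray
    p_rand: np.ndarray
    n_discarded: np.ndarray       # zero-mean null lists dropped per cell type
    empirical_discarded: np.ndarray   # bool per cell type


def _two_tailed(nulls: np.ndarray, emp: float, tol: float = 1e-12) -> float:
    m = nulls.size
    hi = (1.0 + np.sum(nulls >= emp - tol)) / (1.0 + m)
    lo = (1.0 + np.sum(nulls <= emp + tol)) / (1.0 + m)
    return min(1.0, 2.0 * min(hi, lo))


def _null_spec_means(values: np.ndarray, set_size: int, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n_celltypes) mean specificity of random gene sets."""
    n_genes = values.shape[0]
    out = np.empty((n_perm, values.shape[1]))
    for t in range(n_perm):
        rows = rng.choice(n_genes, size=set_size, replace=False)
        out[t] = values[rows].mean(axis=0)
    return out


def celltype_specificity(gs: GeneSet, specificity: pd.DataFrame,
                         n_perm: int = 10000,
                         rng: np.random.Generator | int | None = None
                         ) -> CellTypeResult:
    """Mean specificity of a gene set per cell type vs random-gene nulls.

    `specificity` is a gene x cell-type frame.  Two-tailed p with add-one
    correction; zero-mean empirical or null lists are discarded and counted.
    """
    rng = np.random.default_rng(rng)
    present = [g for g in gs.symbols if g in specificity.index]
    if not present:
        raise ValidationError(f"gene set {gs.name!r} absent from specificity matrix")
    values = specificity.to_numpy(dtype=float)
    emp = specificity.loc[present].mean(axis=0).to_numpy(dtype=float)
    nulls = _null_spec_means(values, len(present), n_perm, rng)

    n_types = values.shape[1]
    p = np.full(n_types, np.nan)
    discarded = np.zeros(n_types, dtype=int)
    emp_discarded = emp == 0.0
    for c in range(n_types):
        col = nulls[:, c]
        zero = col == 0.0
        discarded[c] = int(zero.sum())
        if emp_discarded[c]:
            continue
        p[c] = _two_tailed(col[~zero], emp[c])
    return CellTypeResult(cell_types=list(specificity.columns),
                          mean_specificity=emp, p_rand=p,
                          n_discarded=discarded,
                          empirical_discarded=emp_discarded)


def celltype_difference(gsA: GeneSet, gsB: GeneSet, specificity: pd.DataFrame,
                        n_perm: int = 10000,
                        rng: np.random.Generator | int | None = None
                        ) -> pd.DataFrame:
    """Per-cell-type difference in mean specificity between two gene sets.

    delta = meanSpec(A) - meanSpec(B), tested two-tailed against two null
    difference distributions: A minus random sets of |B| genes, and random
    sets of |A| genes minus B.  The combined p is the maximum of the two
    (conservative).
    """
    rng = np.random.default_rng(rng)
    presA = [g for g in gsA.symbols if g in specificity.index]
    presB = [g for g in gsB.symbols if g in specificity.index]
    if not presA or not presB:
        raise ValidationError("both gene sets must overlap the specificity matrix")
    values = specificity.to_numpy(dtype=float)
    meanA = specificity.loc[presA].mean(axis=0).to_numpy(dtype=float)
    meanB = specificity.loc[presB].mean(axis=0).to_numpy(dtype=float)
    delta = meanA - meanB
    nullB = _null_spec_means(values, len(presB), n_perm, rng)   # stands in for B
    nullA = _null_spec_means(values, len(presA), n_perm, rng)   # stands in for A
    rows = []
    for c, name in enumerate(specificity.columns):
        d1 = meanA[c] - nullB[:, c]
        d2 = nullA[:, c] - meanB[c]
        p1 = _two_tailed(d1, delta[c])
        p2 = _two_tailed(d2, delta[c])
        rows.append({"cell_type": name, "delta": delta[c],
                     "p_vs_randB": p1, "p_vs_randA": p2,
                     "p_combined": max(p1, p2)})
    return pd.DataFrame(rows)
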