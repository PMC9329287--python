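"""Structural covariance networks.

For each diagnostic group and site, the inter-regional association matrix R
holds the pairwise Pearson correlation of regional morphometry across that
group's subjects.  Negative correlations are zeroed and the matrix is
thresholded over a density grid K = 0.05-0.50 (step 0.01) by retaining, at
each density, the edge_count(K) = round(K * n(n-1)/2) strongest positive
correlations as a weighted network; this guarantees the same edge count in
every group at a given density.  A density is usable if, in at least 90% of
sites, at least 75% of nodes belong to the largest connected component.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .parcellation import ValidationError

__all__ = [
    "CovarianceNetwork",
    "ThresholdedNetwork",
    "CohortTooSmallError",
    "DENSITY_GRID",
    "density_grid",
    "edge_count",
    "build_covariance",
    "threshold",
    "largest_component_fraction",
    "density_passes",
    "connectedness_range",
    "mean_positive_strength",
]

log = logging.getLogger("covnet")

MIN_SUBJECTS = 10
DENSITY_GRID = np.round(np.arange(5, 51) / 100.0, 2)  # 0.05 .. 0.50, 46 values


def density_grid() -> np.ndarray:
    """The 46-value density grid K = 0.05, 0.06, ..., 0.50."""
    return DENSITY_GRID.copy()


class CohortTooSmallError(ValidationError):
    """A site-group has fewer subjects than the minimum for a covariance matrix."""


@dataclass
class CovarianceNetwork:
    """Group- and site-specific inter-regional correlation matrix."""

    site: str
    group: str
    R: np.ndarray
    n_subjects: int


@dataclass
class ThresholdedNetwork:
    """Weighted adjacency retained at density K (nonnegative, zero diagonal)."""

    W: np.ndarray
    K: float
    site: str = ""
    group: str = ""
    insufficient_positive: bool = False


def edge_count(K: float, n_nodes: int) -> int:
    """Number of edges retained at density K (round half away from zero)."""
    m = n_nodes * (n_nodes - 1) // 2
    return int(math.floor(K * m + 0.5))


def build_covariance(cohort, site: str, group: str, *,
                     min_subjects: int = MIN_SUBJECTS,
                     validate: bool = True) -> CovarianceNetwork:
    """Pearson correlation matrix across the subjects of one site-group.

    Parameters
    ----------
    cohort
        PreprocessedCohort; rows are selected by site and group labels.
    validate
        When True (default), site-groups below `min_subjects` raise
        CohortTooSmallError (callers building many networks catch and log it).
    """
    mask = ((cohort.meta["site"] == site) & (cohort.meta["group"] == group)).to_numpy()
    X = cohort.values[mask]
    n = X.shape[0]
    if validate and n < min_subjects:
        raise CohortTooSmallError(
            f"{site}/{group}: {n} subjects < {min_subjects}; skipped")
    sd = X.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"{site}/{group}: region {bad} has zero variance")
    R = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(R, 1.0)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    return CovarianceNetwork(site=site, group=group, R=R, n_subjects=n)


def _edge_order(R: np.ndarray):
    """Upper-triangle edges sorted by descending weight, ties by (i, j)."""
    n = R.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    w = R[iu, ju]
    order = np.lexsort((ju, iu, -w))
    return iu[order], ju[order], w[order]


def threshold(network: CovarianceNetwork, K: float) -> ThresholdedNetwork:
    """Retain the edge_count(K) strongest positive correlations as weights.

    Negative correlations are zeroed first; ties at equal weight are broken by
    (i, j) lexicographic order so that retained edge sets are nested across
    the density grid.  If fewer positive correlations exist than the density
    asks for, all positives are kept and the network is flagged.
    """
    R = network.R
    n = R.shape[0]
    m = edge_count(K, n)
    iu, ju, w = _edge_order(R)
    pos = w > 0
    avail = int(pos.sum())
    keep = min(m, avail)
    W = np.zeros_like(R)
    ik, jk, wk = iu[:keep], ju[:keep], w[:keep]
    W[ik, jk] = wk
    W[jk, ik] = wk
    return ThresholdedNetwork(W=W, K=K, site=network.site, group=network.group,
                              insufficient_positive=avail < m)


def largest_component_fraction(W: np.ndarray) -> float:
    """Fraction of nodes in the largest connected component of W."""
    n = W.shape[0]
    _, labels = connected_components(csr_matrix(W != 0), directed=False)
    counts = np.bincount(labels)
    return counts.max() / n


def density_passes(networks: list[ThresholdedNetwork], *,
                   node_frac: float = 0.75, site_frac: float = 0.90) -> bool:
    """Connectedness screen at one density.

    Passes when, in at least `site_frac` of the site networks, at least
    `node_frac` of the nodes lie in the largest connected component.
    """
    if not networks:
        raise ValidationError("no networks supplied")
    good = sum(largest_component_fraction(t.W) >= node_frac for t in networks)
    return good / len(networks) >= site_frac


def connectedness_range(networks_by_density: dict[float, list[ThresholdedNetwork]],
                        *, node_frac: float = 0.75, site_frac: float = 0.90):
    """Screen the whole grid; return per-density flags and the valid range.

    Returns (passes, valid_range) where passes maps density -> bool and
    valid_range is the longest contiguous passing run (lo, hi) or None.  The
    regional analyses use the smallest density of the valid range.
    """
    if not networks_by_density:
        raise ValidationError("no networks supplied")
    ks = sorted(networks_by_density)
    passes = {K: density_passes(networks_by_density[K],
                                node_frac=node_frac, site_frac=site_frac)
              for K in ks}
    best, cur = [], []
    for K in ks:
        if passes[K]:
            cur.append(K)
            if len(cur) > len(best):
                best = list(cur)
        else:
            cur = []
    valid_range = (best[0], best[-1]) if best else None
    return passes, valid_range


def mean_positive_strength(network: ThresholdedNetwork) -> float:
    """Mean of the retained positive correlation weights (NaN if empty)."""
    iu, ju = np.triu_indices(network.W.shape[0], k=1)
    w = network.W[iu, ju]
    w = w[w > 0]
    if w.size == 0:
        log.warning("mean_positive_strength: empty network %s/%s at K=%.2f",
                    network.site, network.group, network.K)
        return float("nan")
    return float(w.mean())
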