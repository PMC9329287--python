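"""Weighted graph metrics and degree/weight-preserving null networks.

Clustering uses the Onnela geometric-mean formulation on max-normalized
weights; path length uses Dijkstra shortest paths with edge length 1/weight,
averaging each node's distance to the nodes it can reach.  The small-world
index is the null-normalized mean clustering divided by the null-normalized
mean path length, where nulls are Maslov-Sneppen rewirings of the binary
topology (degree sequence preserved exactly) with the original weight
multiset re-assigned to the rewired edges in random order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .parcellation import ValidationError

__all__ = [
    "TopologyResult",
    "clustering_coefficient",
    "path_length",
    "make_null",
    "normalized_topology",
]

log = logging.getLogger("covnet")


@dataclass
class TopologyResult:
    """Raw and null-normalized clustering, path length and small-worldness."""

    clustering: np.ndarray          # per-node C_i
    path_length: np.ndarray         # per-node L_i (NaN for isolated nodes)
    clustering_norm: np.ndarray     # C_i / mean null C_i (NaN if no nulls)
    path_length_norm: np.ndarray
    small_world: np.ndarray         # per-node C_norm / L_norm
    density: float
    n_nulls: int

    @property
    def global_clustering(self) -> float:
        return float(np.nanmean(self.clustering))

    @property
    def global_path_length(self) -> float:
        return float(np.nanmean(self.path_length))

    @property
    def global_clustering_norm(self) -> float:
        return float(np.nanmean(self.clustering_norm))

    @property
    def global_path_length_norm(self) -> float:
        return float(np.nanmean(self.path_length_norm))

    @property
    def global_small_world(self) -> float:
        return self.global_clustering_norm / self.global_path_length_norm

    def class_means(self, mask: np.ndarray) -> dict:
        """Global means restricted to a node subset (e.g. cortical only)."""
        return {
            "clustering": float(np.nanmean(self.clustering[mask])),
            "path_length": float(np.nanmean(self.path_length[mask])),
            "clustering_norm": float(np.nanmean(self.clustering_norm[mask])),
            "path_length_norm": float(np.nanmean(self.path_length_norm[mask])),
        }


def _check_weights(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValidationError("adjacency must be square")
    if np.any(W < 0):
        raise ValidationError("negative edge weight")
    if not np.allclose(W, W.T):
        raise ValidationError("adjacency must be symmetric")
    return W


def clustering_coefficient(W: np.ndarray) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    With w_hat = W / max(W):
    C_i = (2 / (k_i (k_i - 1))) * sum_{j<h} (w_hat_ij w_hat_ih w_hat_jh)^(1/3),
    and C_i = 0 for degree k_i < 2.
    """
    W = _check_weights(W)
    wmax = W.max()
    if wmax == 0:
        return np.zeros(W.shape[0])
    cw = np.cbrt(W / wmax)
    num = np.diagonal(cw @ cw @ cw)          # 2 * sum of cube-root triangles
    k = (W > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        C = np.where(denom > 0, num / denom, 0.0)
    return C


def path_length(W: np.ndarray) -> np.ndarray:
    """Mean shortest-path distance from each node to the nodes it reaches.

    Edge length is 1/weight; unreachable pairs are excluded from the mean and
    fully isolated nodes get NaN.
    """
    W = _check_weights(W)
    n = W.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(W > 0, 1.0 / W, 0.0)
    D = dijkstra(csr_matrix(lengths), directed=False)
    np.fill_diagonal(D, np.inf)
    finite = np.isfinite(D)
    counts = finite.sum(axis=1)
    sums = np.where(finite, D, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        L = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return L


def _edges_of(W: np.ndarray):
    iu, ju = np.triu_indices(W.shape[0], k=1)
    nz = W[iu, ju] > 0
    return iu[nz], ju[nz], W[iu[nz], ju[nz]]


def make_null(W: np.ndarray, rng: np.random.Generator | int,
              swap_factor: int = 10) -> np.ndarray:
    """Degree- and weight-preserving random network.

    Maslov-Sneppen double-edge swaps on the binary topology (swap_factor *
    n_edges attempted swaps), then the original weight multiset is assigned to
    the rewired edges in random order.  If no swap is ever possible (e.g. a
    complete graph) the result is a weight-shuffled copy of the input.
    """
    rng = np.random.default_rng(rng)
    W = _check_weights(W)
    iu, ju, weights = _edges_of(W)
    m = iu.size
    if m < 2:
        raise ValidationError("need at least 2 edges to rewire")
    edges = list(zip(iu.tolist(), ju.tolist()))
    edge_set = set(edges)
    attempts = swap_factor * m
    pairs = rng.integers(0, m, size=(attempts, 2))
    orient = rng.random(attempts) < 0.5
    swapped = 0
    for t in range(attempts):
        e1, e2 = pairs[t]
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if orient[t]:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        n1 = (min(a, d), max(a, d))
        n2 = (min(c, b), max(c, b))
        if n1 in edge_set or n2 in edge_set or n1 == n2:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edges[e1], edges[e2] = n1, n2
        edge_set.add(n1)
        edge_set.add(n2)
        swapped += 1
    if swapped == 0:
        log.info("make_null: no valid double-edge swap; weight-shuffled copy")
    null = np.zeros_like(W)
    perm = rng.permutation(m)
    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    null[ei, ej] = weights[perm]
    null[ej, ei] = weights[perm]
    return null


def normalized_topology(W: np.ndarray, n_nulls: int = 1000,
                        rng: np.random.Generator | int | None = None,
                        density: float = float("nan")) -> TopologyResult:
    """Nodal clustering/path length, normalized against rewired nulls.

    C_norm and L_norm are the ratios of the empirical nodal metrics to the
    null-ensemble means; the small-world index is their ratio.  With
    n_nulls = 0 the raw metrics are returned and the normalized fields are
    NaN (used where group contrasts only need the raw values).
    """
    rng = np.random.default_rng(rng)
    W = _check_weights(W)
    C = clustering_coefficient(W)
    L = path_length(W)
    if n_nulls > 0:
        null_C = np.zeros_like(C)
        null_L = np.zeros_like(L)
        null_L_count = np.zeros_like(L)
        for _ in range(n_nulls):
            Wn = make_null(W, rng)
            null_C += clustering_coefficient(Wn)
            Ln = path_length(Wn)
            ok = np.isfinite(Ln)
            null_L[ok] += Ln[ok]
            null_L_count += ok
        mean_C = null_C / n_nulls
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_L = np.where(null_L_count > 0, null_L / np.maximum(null_L_count, 1),
                              np.nan)
            C_norm = np.where(mean_C > 0, C / mean_C, np.nan)
            L_norm = np.where(mean_L > 0, L / mean_L, np.nan)
    else:
        C_norm = np.full_like(C, np.nan)
        L_norm = np.full_like(L, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sw = C_norm / L_norm
    return TopologyResult(clustering=C, path_length=L, clustering_norm=C_norm,
                          path_length_norm=L_norm, small_world=sw,
                          density=density, n_nulls=n_nulls)
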