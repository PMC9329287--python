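"""Spatial null models for parcellated brain maps.

Two families of nulls guard spatial correlations against inflation by
spatial autocorrelation:

* Spin permutations: the merged cortical/subcortical sphere is rotated by
  three uniform angles (x, then y, then z axis); each rotated region is
  matched to the nearest original region by Euclidean distance (many-to-one
  allowed), giving a relabelling that preserves the map's autocorrelation.
  One map is spun while the other stays fixed, and the one-tailed p-value is
  (1 + #{r_null >= r_emp}) / (1 + n_perm).

* Variogram-matching surrogates: a shuffled copy of the map is re-smoothed by
  an exponential kernel over each region's k nearest neighbours, with k chosen
  from a grid so that the surrogate's binned variogram best matches the
  empirical one (least squares over 25 uniform distance bins), then
  affine-rescaled onto the empirical variogram.

Distances combine great-circle arcs on the sphere (scaled to a 100 mm radius)
for cortical-cortical pairs with 3-D Euclidean distances for any pair
involving a subcortical region; a precomputed distance matrix may be supplied
instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .parcellation import RegionTable, ValidationError

__all__ = [
    "Rotation",
    "SpinResult",
    "random_rotation",
    "rotation_matrix",
    "spin_assignment",
    "spin_permutations",
    "p_spin",
    "region_distance_matrix",
    "variogram",
    "variogram_surrogates",
    "p_variogram",
]


@dataclass
class Rotation:
    """Rotation by angles (theta_x, theta_y, theta_z), applied in x, y, z order."""

    angles: tuple[float, float, float]
    matrix: np.ndarray


@dataclass
class SpinResult:
    """Empirical spatial correlation with its spin-null distribution."""

    r: float
    nulls: np.ndarray
    p: float
    n_perm: int
    seed: object = None


def rotation_matrix(tx: float, ty: float, tz: float) -> np.ndarray:
    """3x3 rotation: product of axis rotations applied in x, y, z order."""
    cx, sx = np.cos(tx), np.sin(tx)
    cy, sy = np.cos(ty), np.sin(ty)
    cz, sz = np.cos(tz), np.sin(tz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def random_rotation(rng: np.random.Generator | int) -> Rotation:
    """Uniform angles about x, y, z in [0, 2pi); deterministic under seed."""
    rng = np.random.default_rng(rng)
    tx, ty, tz = rng.uniform(0.0, 2.0 * np.pi, size=3)
    return Rotation(angles=(tx, ty, tz), matrix=rotation_matrix(tx, ty, tz))


def spin_assignment(sphere_xyz: np.ndarray, rotation: Rotation) -> np.ndarray:
    """Nearest-original-region index for each rotated region.

    assignment[i] = argmin_j ||R x_i - x_j||; the identity rotation yields the
    identity mapping (for coordinate sets without duplicates).  A spun map is
    map[assignment].
    """
    coords = np.asarray(sphere_xyz, dtype=float)
    rotated = coords @ rotation.matrix.T
    d = cdist(rotated, coords)
    return d.argmin(axis=1)


def spin_permutations(sphere_xyz: np.ndarray, n_perm: int,
                      rng: np.random.Generator | int) -> np.ndarray:
    """(n_perm, n_regions) array of spin assignments (batched for speed)."""
    rng = np.random.default_rng(rng)
    coords = np.asarray(sphere_xyz, dtype=float)
    angles = rng.uniform(0.0, 2.0 * np.pi, size=(n_perm, 3))
    mats = np.stack([rotation_matrix(*a) for a in angles])
    rotated = np.einsum("pij,nj->pni", mats, coords)
    # squared distances (p, n, n): |r|^2 + |c|^2 - 2 r.c ; unit norms drop out
    dots = np.einsum("pni,mi->pnm", rotated, coords)
    return dots.argmax(axis=2)   # nearest neighbour = max dot product on sphere


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _tail_p(nulls: np.ndarray, r_emp: float, tol: float = 1e-12) -> float:
    # tol absorbs pure floating-point ties (identical maps up to summation order)
    return (1.0 + np.sum(nulls >= r_emp - tol)) / (1.0 + nulls.size)


def p_spin(map_x: np.ndarray, map_y: np.ndarray, sphere_xyz: np.ndarray,
           n_perm: int = 10000, rng: np.random.Generator | int | None = None,
           method: str = "pearson") -> SpinResult:
    """Spin permutation test of the spatial correlation of two maps.

    map_x is spun; map_y stays fixed.  One-tailed toward positive correlation.
    """
    x = np.asarray(map_x, dtype=float)
    y = np.asarray(map_y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("maps must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant map: correlation undefined")
    if method == "spearman":
        from scipy.stats import rankdata
        x = rankdata(x)
        y = rankdata(y)
    elif method != "pearson":
        raise ValidationError(f"unknown method {method!r}")
    rng = np.random.default_rng(rng)
    r_emp = _corr(x, y)
    perms = spin_permutations(sphere_xyz, n_perm, rng)
    spun = x[perms]                              # (n_perm, n)
    sx = spun - spun.mean(axis=1, keepdims=True)
    sy = y - y.mean()
    denom = np.sqrt((sx ** 2).sum(axis=1) * (sy ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        nulls = (sx @ sy) / denom
    nulls = nulls[np.isfinite(nulls)]
    return SpinResult(r=r_emp, nulls=nulls, p=_tail_p(nulls, r_emp),
                      n_perm=n_perm)


# -- variogram-matching surrogates --------------------------------------------

def region_distance_matrix(table: RegionTable, radius: float = 100.0) -> np.ndarray:
    """Inter-regional distances for variogram models.

    Great-circle distance on the merged sphere (scaled to `radius` mm) between
    cortical pairs; 3-D Euclidean distance for any pair involving a
    subcortical region.
    """
    sphere = table.sphere_xyz
    dots = np.clip(sphere @ sphere.T, -1.0, 1.0)
    geo = radius * np.arccos(dots)
    euc = cdist(table.xyz, table.xyz)
    cort = table.cortical_mask
    both_cortical = np.outer(cort, cort)
    D = np.where(both_cortical, geo, euc)
    np.fill_diagonal(D, 0.0)
    return D


def variogram(x: np.ndarray, distances: np.ndarray, n_bins: int = 25):
    """Binned empirical variogram: gamma(h) = 0.5 E[(x_i - x_j)^2] per bin."""
    iu, ju = np.triu_indices(len(x), k=1)
    d = distances[iu, ju]
    sq = 0.5 * (x[iu] - x[ju]) ** 2
    edges = np.linspace(0.0, d.max(), n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=sq, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        gamma = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, gamma


class _SmootherBank:
    """Precomputed k-NN exponential-kernel smoothers for one distance matrix."""

    def __init__(self, distances: np.ndarray, k_grid) -> None:
        n = distances.shape[0]
        self.k_grid = [k for k in k_grid if 0 < k < n]
        if not self.k_grid and any(k > 0 for k in k_grid):
            raise ValidationError("fewer regions than the smallest kernel size")
        self.weights = []
        order = np.argsort(distances, axis=1)
        for k in self.k_grid:
            nn = order[:, 1:k + 1]                       # exclude self
            dk = distances[np.arange(n)[:, None], nn]
            scale = dk[:, -1][:, None]                   # distance to kth nbr
            w = np.exp(-dk / np.maximum(scale, 1e-12))
            w /= w.sum(axis=1, keepdims=True)
            M = np.zeros((n, n))
            np.put_along_axis(M, nn, w, axis=1)
            self.weights.append(M)


def variogram_surrogates(x: np.ndarray, distances: np.ndarray, n_surr: int,
                         rng: np.random.Generator | int | None = None,
                         k_grid=(3, 5, 8, 12, 16, 20, 30, 40),
                         n_bins: int = 25) -> np.ndarray:
    """Surrogate maps with spatial autocorrelation matched to x.

    Per surrogate: randomly permute x; smooth with an exponential kernel over
    each region's k nearest neighbours for every k in the grid; pick the k
    whose affine-rescaled binned variogram best matches the empirical one;
    return the rescaled surrogate (alpha + beta * smoothed variogram fit,
    applied as sqrt(beta) * smoothed + sqrt(alpha) * white noise).

    With k_grid=(0,) the surrogates degenerate to plain shuffles.
    """
    rng = np.random.default_rng(rng)
    x = np.asarray(x, dtype=float)
    n = x.size
    if set(k_grid) == {0}:
        return np.stack([x[rng.permutation(n)] for _ in range(n_surr)])
    bank = _SmootherBank(distances, k_grid)
    _, gamma_emp = variogram(x, distances, n_bins)
    ok_bins = np.isfinite(gamma_emp)
    ge = gamma_emp[ok_bins]

    out = np.empty((n_surr, n))
    for s in range(n_surr):
        perm = x[rng.permutation(n)]
        noise = rng.standard_normal(n)
        best = None
        for M in bank.weights:
            sm = M @ perm
            _, gamma_s = variogram(sm, distances, n_bins)
            gs = gamma_s[ok_bins]
            A = np.column_stack([np.ones_like(gs), gs])
            coef, *_ = np.linalg.lstsq(A, ge, rcond=None)
            alpha, beta = coef
            resid = ge - A @ coef
            sse = float(resid @ resid)
            if best is None or sse < best[0]:
                best = (sse, sm, alpha, beta)
        _, sm, alpha, beta = best
        # unit-variance white noise contributes alpha to the variogram at all
        # lags; beta rescales the smoothed component's variogram
        surr = np.sqrt(abs(beta)) * sm + np.sqrt(abs(alpha)) * noise
        out[s] = surr
    return out


def p_variogram(map_x: np.ndarray, map_y: np.ndarray, distances: np.ndarray,
                n_surr: int = 1000,
                rng: np.random.Generator | int | None = None) -> SpinResult:
    """Variogram-surrogate analogue of p_spin (surrogates of map_x)."""
    x = np.asarray(map_x, dtype=float)
    y = np.asarray(map_y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant map: correlation undefined")
    r_emp = _corr(x, y)
    surr = variogram_surrogates(x, distances, n_surr, rng)
    sx = surr - surr.mean(axis=1, keepdims=True)
    sy = y - y.mean()
    denom = np.sqrt((sx ** 2).sum(axis=1) * (sy ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        nulls = (sx @ sy) / denom
    nulls = nulls[np.isfinite(nulls)]
    return SpinResult(r=r_emp, nulls=nulls, p=_tail_p(nulls, r_emp),
                      n_perm=n_surr)
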