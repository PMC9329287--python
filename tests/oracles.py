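"""Independent brute-force oracles shared by the metric test suites."""

import numpy as np


def brute_clustering(W):
    """Onnela clustering by explicit triple enumeration."""
    n = W.shape[0]
    wh = W / W.max() if W.max() > 0 else W
    C = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(W[i] > 0)
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        C[i] = 2.0 * s / (k * (k - 1))
    return C


def brute_path_length(W):
    """Nodal mean shortest-path length via Floyd-Warshall on 1/w lengths."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    L = np.full(n, np.nan)
    for i in range(n):
        d = np.delete(D[i], i)
        d = d[np.isfinite(d)]
        if d.size:
            L[i] = d.mean()
    return L
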