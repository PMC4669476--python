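"""Brute-force graph-metric oracles by exhaustive enumeration.

Independent of the package implementation: clustering by explicit triple
enumeration, shortest paths and betweenness by enumerating every simple
path.  Only feasible for tiny graphs (<= ~7 nodes), which is the point.
"""

from itertools import permutations

import numpy as np


def cc_brute(A: np.ndarray, directed: bool) -> np.ndarray:
    n = A.shape[0]
    wmax = A.max()
    if wmax == 0:
        return np.zeros(n)
    W = np.cbrt(A / wmax)
    B = (A > 0).astype(float)
    cc = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for h in range(n):
                if len({i, j, h}) < 3:
                    continue
                if directed:
                    num += ((W[i, j] + W[j, i]) * (W[i, h] + W[h, i])
                            * (W[j, h] + W[h, j]))
                else:
                    num += W[i, j] * W[i, h] * W[j, h]
        if directed:
            # t_i = num / 2 triangle intensity; C_i = t_i / (d(d-1) - 2 d_bi)
            d_tot = B[i].sum() + B[:, i].sum()
            d_bi = (B[i] * B[:, i]).sum()
            denom = d_tot * (d_tot - 1) - 2.0 * d_bi
            cc[i] = num / (2.0 * denom) if denom > 0 else 0.0
        else:
            k = B[i].sum()
            cc[i] = num / (k * (k - 1)) if k > 1 else 0.0
    return cc


def _all_paths(A: np.ndarray, s: int, t: int, directed: bool):
    """(length, interior-node tuple) of every simple path s -> t."""
    n = A.shape[0]
    others = [v for v in range(n) if v not in (s, t)]
    out = []
    for r in range(len(others) + 1):
        for mid in permutations(others, r):
            nodes = (s, *mid, t)
            length = 0.0
            ok = True
            for a, b in zip(nodes[:-1], nodes[1:]):
                w = A[a, b] if directed else A[min(a, b), max(a, b)]
                if w <= 0:
                    ok = False
                    break
                length += 1.0 / w
            if ok:
                out.append((length, mid))
    return out


def ge_brute(A: np.ndarray, directed: bool) -> float:
    n = A.shape[0]
    if not directed:
        A = np.triu(A, 1) + np.triu(A, 1).T
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = _all_paths(A, s, t, directed=True)
            if paths:
                total += 1.0 / min(p[0] for p in paths)
    return total / (n * (n - 1))


def bc_brute(A: np.ndarray, directed: bool, tol: float = 1e-12) -> np.ndarray:
    n = A.shape[0]
    if not directed:
        A = np.triu(A, 1) + np.triu(A, 1).T
    bc = np.zeros(n)
    pairs = [(s, t) for s in range(n) for t in range(n) if s != t]
    if not directed:
        pairs = [(s, t) for s, t in pairs if s < t]
    for s, t in pairs:
        paths = _all_paths(A, s, t, directed=True)
        if not paths:
            continue
        dmin = min(p[0] for p in paths)
        shortest = [p for p in paths if p[0] <= dmin * (1 + tol)]
        sigma = len(shortest)
        for _, mid in shortest:
            for v in mid:
                bc[v] += 1.0 / sigma
    return bc
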