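"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — direct enumeration, repeated
relaxation, dense pseudoinverses — and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


# ------------------------------------------------------------- sequence stats

def pi_bruteforce(seqs: list[str]) -> float:
    """Mean pairwise per-site difference over all pairs, by direct loops."""
    n = len(seqs)
    L = len(seqs[0])
    total = 0.0
    for i, j in combinations(range(n), 2):
        total += sum(a != b for a, b in zip(seqs[i], seqs[j])) / L
    return total / (n * (n - 1) / 2)


def s_bruteforce(seqs: list[str]) -> int:
    return sum(len({s[c] for s in seqs}) > 1 for c in range(len(seqs[0])))


def nh_bruteforce(seqs: list[str]) -> int:
    return len(set(seqs))


def hd_bruteforce(seqs: list[str]) -> float:
    n = len(seqs)
    freqs = [seqs.count(h) / n for h in set(seqs)]
    return n / (n - 1) * (1 - sum(f * f for f in freqs))


def gamma_st_bruteforce(seqs1: list[str], seqs2: list[str]) -> float:
    def h(seqs):
        n = len(seqs)
        return n / (n - 1) * (1 - sum((seqs.count(x) / n) ** 2
                                      for x in set(seqs)))

    h_s = (h(seqs1) + h(seqs2)) / 2
    h_t = h(seqs1 + seqs2)
    return (h_t - h_s) / h_t


def snn_bruteforce(seqs: list[str], groups: list[str]) -> float:
    """Hudson's Snn by explicit nearest-neighbour enumeration."""
    n = len(seqs)
    d = [[sum(a != b for a, b in zip(seqs[i], seqs[j])) for j in range(n)]
         for i in range(n)]
    xs = []
    for j in range(n):
        others = [k for k in range(n) if k != j]
        dmin = min(d[j][k] for k in others)
        nn = [k for k in others if d[j][k] == dmin]
        xs.append(sum(groups[k] == groups[j] for k in nn) / len(nn))
    return sum(xs) / n


def snn_exhaustive_p(seqs: list[str], groups: list[str]) -> float:
    """Exact permutation p over all n! label arrangements (tiny n only)."""
    obs = snn_bruteforce(seqs, groups)
    count = 0
    total = 0
    for perm in permutations(groups):
        total += 1
        if snn_bruteforce(seqs, list(perm)) >= obs - 1e-12:
            count += 1
    return count / total


# ------------------------------------------------------------------- graphs

def relaxation_shortest_paths(W) -> np.ndarray:
    """All-pairs least-cost distances with edge cost 1/w by exhaustive
    repeated relaxation (Bellman-Ford style; no priority queue)."""
    W = np.asarray(W.todense() if hasattr(W, "todense") else W, dtype=float)
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    edges = [(i, j, 1.0 / W[i, j]) for i in range(n) for j in range(n)
             if W[i, j] > 0]
    changed = True
    while changed:
        changed = False
        for i, j, c in edges:
            relax = D[:, i] + c
            better = relax < D[:, j] - 1e-15
            if better.any():
                D[better, j] = relax[better]
                changed = True
    return D


def enumerate_simple_paths_cost(W, origin: int, dest: int) -> float:
    """Minimum cost over ALL simple paths (complete DFS enumeration)."""
    W = np.asarray(W.todense() if hasattr(W, "todense") else W, dtype=float)
    n = W.shape[0]
    best = [np.inf]

    def dfs(node, visited, cost):
        if node == dest:
            best[0] = min(best[0], cost)
            return
        for nxt in range(n):
            if W[node, nxt] > 0 and nxt not in visited:
                dfs(nxt, visited | {nxt}, cost + 1.0 / W[node, nxt])

    dfs(origin, {origin}, 0.0)
    return best[0]


def effective_resistance_pinv(W) -> np.ndarray:
    """All-pairs effective resistance via the dense Laplacian pseudoinverse."""
    W = np.asarray(W.todense() if hasattr(W, "todense") else W, dtype=float)
    L = np.diag(W.sum(axis=1)) - W
    Lp = np.linalg.pinv(L)
    d = np.diag(Lp)
    return d[:, None] + d[None, :] - 2 * Lp


def commute_pinv(W) -> np.ndarray:
    W = np.asarray(W.todense() if hasattr(W, "todense") else W, dtype=float)
    return W.sum() * effective_resistance_pinv(W)


# -------------------------------------------------------------------- mantel

def mantel_exhaustive_oracle(A, B, alternative="greater"):
    """(r_obs, exact p) by explicit enumeration of all relabelings."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    k = A.shape[0]
    tril = np.tril_indices(k, -1)

    def corr(x, y):
        return np.corrcoef(x, y)[0, 1]

    x = A[tril]
    r_obs = corr(x, B[tril])
    stats = []
    for perm in permutations(range(k)):
        p = list(perm)
        stats.append(corr(x, B[np.ix_(p, p)][tril]))
    stats = np.asarray(stats)
    if alternative == "greater":
        extreme = stats >= r_obs - 1e-12
    elif alternative == "less":
        extreme = stats <= r_obs + 1e-12
    else:
        extreme = np.abs(stats) >= abs(r_obs) - 1e-12
    return r_obs, extreme.mean()
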