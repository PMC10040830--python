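"""Independent oracles used by the test suite.

Each oracle is written from the mathematical definition, independently of the
package's implementation path: a brute-force affine-gap dynamic program for
alignment scores, a path-enumeration check for pathway completeness, explicit
rank-then-Pearson Spearman, step-up BH, and full-enumeration Mann-Whitney.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices


def brute_local_score(a: str, b: str, matrix_name: str, gap_open: float, gap_extend: float) -> float:
    """Three-state Gotoh DP written directly from the recurrences.

    Gap of length k costs gap_open + k * gap_extend.
    """
    mat = substitution_matrices.load(matrix_name)
    la, lb = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Ix = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Iy = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - (gap_open + gap_extend), Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - (gap_open + gap_extend), Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def brute_global_score(a: str, b: str, matrix_name: str, gap_open: float, gap_extend: float) -> float:
    mat = substitution_matrices.load(matrix_name)
    la, lb = len(a), len(b)
    NEG = float("-inf")
    go = gap_open + gap_extend
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Ix = [[NEG] * (lb + 1) for _ in range(la + 1)]
    Iy = [[NEG] * (lb + 1) for _ in range(la + 1)]
    M[0][0] = 0.0
    for i in range(1, la + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, lb + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - go, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - go, Iy[i][j - 1] - gap_extend)
    return max(M[la][lb], Ix[la][lb], Iy[la][lb])


def reachable_by_path_enumeration(present: frozenset[str], network) -> frozenset[str]:
    """Enumerate every directed Trp-path and check requirements edge by edge."""
    paths: list[list] = []

    def walk(node: str, path: list) -> None:
        for e in network.edges:
            if e.substrate == node and e not in path:
                paths.append(path + [e])
                walk(e.product, path + [e])

    walk(network.root, [])
    producible = set()
    for path in paths:
        if all(e.requirement.satisfied_by(present) for e in path):
            producible.add(path[-1].product)
    return frozenset(producible & network.predictable)


def spearman_rank_then_pearson(x, y) -> float:
    """Mid-ranks computed by explicit sorting, then the Pearson formula."""
    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def bh_stepup(pvals) -> list[float]:
    """Literal step-up: q_(i) = min_{j>=i} m p_(j) / j on the sorted scale."""
    m = len(pvals)
    indexed = sorted(range(m), key=lambda i: pvals[i])
    q_sorted = [min(1.0, pvals[indexed[i]] * m / (i + 1)) for i in range(m)]
    for i in range(m - 2, -1, -1):
        q_sorted[i] = min(q_sorted[i], q_sorted[i + 1])
    out = [0.0] * m
    for rank, idx in enumerate(indexed):
        out[idx] = q_sorted[rank]
    return out


def mann_whitney_enumeration(a, b) -> tuple[float, float]:
    """U and two-sided p by enumerating every group assignment of the pooled values."""
    a, b = list(a), list(b)
    n_a, n_b = len(a), len(b)
    pooled = a + b
    ranks = _midranks(pooled)

    def u_of(idx_set):
        ra = sum(ranks[i] for i in idx_set)
        ua = ra - n_a * (n_a + 1) / 2.0
        return min(ua, n_a * n_b - ua)

    u_obs = u_of(tuple(range(n_a)))
    total = count = 0
    for comb in itertools.combinations(range(n_a + n_b), n_a):
        total += 1
        if u_of(comb) <= u_obs + 1e-12:
            count += 1
    return u_obs, count / total


def _midranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """A random unrooted binary tree with positive branch lengths, returned as
    (leaf labels, pairwise path-distance matrix, set of non-trivial bipartitions).
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    # grow by random leaf attachment on an edge-subdivided tree
    adjacency = {l: {} for l in labels[:3]}
    center = "I0"
    adjacency[center] = {}
    inner = itertools.count(1)
    for l in labels[:3]:
        w = rng.uniform(0.05, 1.0)
        adjacency[center][l] = w
        adjacency[l][center] = w
    for l in labels[3:]:
        edges = [(u, v) for u in adjacency for v in adjacency[u] if u < v]
        u, v = edges[rng.integers(len(edges))]
        w = adjacency[u][v]
        split = rng.uniform(0.2, 0.8) * w
        mid = f"I{next(inner)}"
        del adjacency[u][v]
        del adjacency[v][u]
        adjacency[mid] = {u: split, v: w - split}
        adjacency[u][mid] = split
        adjacency[v][mid] = w - split
        lw = rng.uniform(0.05, 1.0)
        adjacency[mid][l] = lw
        adjacency[l] = {mid: lw}

    def dist(a, b):
        stack = [(a, 0.0, None)]
        while stack:
            node, d, prev = stack.pop()
            if node == b:
                return d
            for nbr, w in adjacency[node].items():
                if nbr != prev:
                    stack.append((nbr, d + w, node))
        raise KeyError

    d = np.zeros((n_leaves, n_leaves))
    for i, j in itertools.combinations(range(n_leaves), 2):
        d[i, j] = d[j, i] = dist(labels[i], labels[j])

    def leafset_away(u, v):
        seen = set()
        stack = [(v, u)]
        while stack:
            node, prev = stack.pop()
            if node in labels:
                seen.add(node)
            for nbr in adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node))
        return frozenset(seen)

    bips = set()
    for u in adjacency:
        for v in adjacency[u]:
            if u < v:
                side = leafset_away(u, v)
                if 2 <= len(side) <= n_leaves - 2:
                    bips.add(min(side, frozenset(labels) - side, key=sorted))
    return labels, d, bips
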