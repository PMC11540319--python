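"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (enumeration, exact fractions, linear
least squares over all topologies) and shares no code with the package
implementations it cross-checks.
"""

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# Exact-test oracles (exact rational arithmetic)


def hwe_exact_oracle(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """HWE exact p by enumerating heterozygote counts with Fraction weights."""
    n = n_AA + n_Aa + n_aa
    n_A = 2 * n_AA + n_Aa
    n_a = 2 * n_aa + n_Aa
    rare = min(n_A, n_a)
    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        homr = (rare - het) // 2
        homc = n - het - homr
        # multinomial count of genotype configurations x 2^het orderings
        weights[het] = Fraction(
            comb(n, het) * comb(n - het, homr) * (2**het)
        )
    total = sum(weights.values())
    obs = weights[n_Aa]
    p = sum(w for w in weights.values() if w <= obs) / total
    return float(p)


def fisher_one_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """One-sided ('greater' on the a cell) Fisher p by hypergeometric tail."""
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, col1)
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    tail = sum(
        Fraction(comb(row1, x) * comb(n - row1, col1 - x), denom)
        for x in range(a, hi + 1)
    )
    return float(tail)


def mann_whitney_exact_oracle(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group labelings."""
    a, b = list(a), list(b)
    pooled = a + b
    na = len(a)
    idx = range(len(pooled))

    def u_stat(sel):
        xs = [pooled[i] for i in sel]
        ys = [pooled[i] for i in idx if i not in sel]
        return sum(1 for x in xs for y in ys if x > y) + 0.5 * sum(
            1 for x in xs for y in ys if x == y
        )

    u_obs = u_stat(set(range(na)))
    n_total = comb(len(pooled), na)
    mean_u = na * (len(pooled) - na) / 2
    dev = abs(u_obs - mean_u)
    extreme = sum(
        1
        for sel in combinations(idx, na)
        if abs(u_stat(set(sel)) - mean_u) >= dev - 1e-12
    )
    return extreme / n_total


def bh_oracle(pvalues):
    """Textbook BH step-up by explicit min-over-j loop."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order):
        j_values = [
            m * p[order[jj]] / (jj + 1) for jj in range(rank_pos, m)
        ]
        q[i] = min(1.0, min(j_values))
    return q


# ---------------------------------------------------------------------------
# Least-squares topology oracle for neighbor joining


def _enumerate_topologies(labels):
    """All unrooted binary topologies as edge lists; nodes are labels/ints."""
    labels = list(labels)
    if len(labels) < 3:
        raise ValueError("need >= 3 taxa")
    base = [(labels[0], "i0"), (labels[1], "i0"), (labels[2], "i0")]
    topologies = [(base, 1)]  # (edges, next internal index)
    for leaf in labels[3:]:
        new_topologies = []
        for edges, k in topologies:
            for ei, (u, v) in enumerate(edges):
                node = f"i{k}"
                new_edges = edges[:ei] + edges[ei + 1:]
                new_edges += [(u, node), (v, node), (leaf, node)]
                new_topologies.append((new_edges, k + 1))
        topologies = new_topologies
    return [e for e, _ in topologies]


def _paths(edges, labels):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path_edges(src, dst):
        stack = [(src, None, [])]
        while stack:
            node, prev, trail = stack.pop()
            if node == dst:
                return trail
            for nbr in adj[node]:
                if nbr != prev:
                    e = frozenset((node, nbr))
                    stack.append((nbr, node, trail + [e]))
        raise RuntimeError

    return {
        (a, b): path_edges(a, b)
        for a, b in combinations(labels, 2)
    }


def least_squares_tree_oracle(D: np.ndarray, labels):
    """Best-fit unrooted tree by brute force over all topologies.

    For each topology, branch lengths are fit by ordinary least squares on
    the path-edge incidence system; the topology with the smallest residual
    sum of squares wins.  Returns (splits, fitted leaf-distance matrix, sse).
    """
    labels = list(labels)
    best = None
    for edges in _enumerate_topologies(labels):
        edge_list = [frozenset(e) for e in edges]
        pairs = list(combinations(range(len(labels)), 2))
        paths = _paths(edges, labels)
        X = np.zeros((len(pairs), len(edge_list)))
        y = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            y[r] = D[i, j]
            for e in paths[(labels[i], labels[j])]:
                X[r, edge_list.index(e)] = 1.0
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        fitted_pairs = X @ beta
        sse = float(((fitted_pairs - y) ** 2).sum())
        fitted = np.zeros_like(D)
        for r, (i, j) in enumerate(pairs):
            fitted[i, j] = fitted[j, i] = fitted_pairs[r]
        if best is None or sse < best[2] - 1e-15:
            best = (edges, fitted, sse)
    edges, fitted, sse = best
    return tree_splits(edges, labels), fitted, sse


def tree_splits(edges, labels):
    """Set of nontrivial leaf bipartitions induced by a tree's edges."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    label_set = frozenset(labels)

    def side(u, v):
        seen = {v, u}
        stack = [u]
        leaves = set()
        while stack:
            node = stack.pop()
            if node in label_set:
                leaves.add(node)
            for nbr in adj[node]:
                if nbr not in seen or nbr == u:
                    if nbr not in seen:
                        seen.add(nbr)
                        stack.append(nbr)
        return frozenset(leaves)

    splits = set()
    for u, v in edges:
        s = side(u, v)
        if 1 < len(s) < len(labels) - 1:
            splits.add(frozenset((s, label_set - s)))
    return splits


def random_additive_matrix(labels, rng):
    """A random unrooted binary tree and its exact leaf-distance matrix."""
    topo = _enumerate_topologies(labels)
    edges = topo[rng.integers(len(topo))]
    lengths = {frozenset(e): rng.uniform(0.05, 0.5) for e in edges}
    paths = _paths(edges, labels)
    n = len(labels)
    D = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d = sum(lengths[e] for e in paths[(labels[i], labels[j])])
        D[i, j] = D[j, i] = d
    return D, edges, lengths
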