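"""Pairwise Hamming distances (ignoring missingness) and unrooted
neighbor-joining trees.

The distance between two haplotypes is the fraction of mismatching calls
among the sites called in *both* -- missing data shrinks the denominator
instead of biasing the numerator.  Trees are built with the classical
neighbor-joining agglomeration (Saitou & Nei): repeatedly join the pair
minimising the Q criterion, with ties broken deterministically by the
lexicographically smallest pair of clade labels (a clade is labelled by its
smallest leaf).  Negative branch lengths, which NJ can produce on
non-additive inputs, are kept but flagged; ``clamp_negative=True`` instead
clamps them to zero and transfers the deficit to the sister branch.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .genotype_io import ALT, MISSING, REF, GenotypeMatrix


@dataclasses.dataclass
class DistanceMatrix:
    """Symmetric normalised Hamming distances with per-pair site counts."""

    labels: list[str]
    matrix: np.ndarray  # distances on [0, 1], zero diagonal
    comparable: np.ndarray | None = None  # per-pair comparable-site counts

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix is not symmetric")
        if (self.matrix < 0).any():
            raise ValueError("negative distances")
        if not np.allclose(np.diag(self.matrix), 0):
            raise ValueError("nonzero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def hamming_distance_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """d(i,j) = mismatches / comparable sites, over sites non-MISSING in both.

    Raises if any pair of samples shares no called site (its distance would
    be undefined).
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least two samples")
    is_ref = (matrix.calls == REF).astype(np.float64)
    is_alt = (matrix.calls == ALT).astype(np.float64)
    is_het = (matrix.calls == 1).astype(np.float64)
    called = is_ref + is_alt + is_het
    comparable = called @ called.T
    # mismatch iff the two calls differ; with three call states this is the
    # sum over ordered cross products of distinct states
    same = is_ref @ is_ref.T + is_alt @ is_alt.T + is_het @ is_het.T
    mismatches = comparable - same
    off = ~np.eye(matrix.n_samples, dtype=bool)
    if (comparable[off] == 0).any():
        i, j = np.argwhere((comparable == 0) & off)[0]
        raise ValueError(
            f"samples {matrix.sample_ids[i]!r} and {matrix.sample_ids[j]!r} "
            "share no called site"
        )
    with np.errstate(invalid="ignore"):
        d = np.where(comparable > 0, mismatches / np.maximum(comparable, 1), 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # exact symmetry
    return DistanceMatrix(
        labels=list(matrix.sample_ids),
        matrix=d,
        comparable=comparable.astype(np.int64),
    )


@dataclasses.dataclass
class UnrootedTree:
    """Leaf-labelled unrooted tree as an adjacency map.

    ``adjacency`` maps node -> list of (neighbor, branch length).  Leaves
    are their label strings; internal nodes are integers.  For >= 3 leaves
    the topology is unrooted binary (internal degree 3).
    """

    adjacency: dict
    leaves: list[str]
    negative_branches: list[tuple] = dataclasses.field(default_factory=list)

    def path_lengths(self) -> DistanceMatrix:
        """Leaf-to-leaf path-length matrix (additivity check for tests)."""
        n = len(self.leaves)
        out = np.zeros((n, n))
        for a, b in itertools.combinations(range(n), 2):
            out[a, b] = out[b, a] = self._path(self.leaves[a], self.leaves[b])
        return DistanceMatrix(labels=list(self.leaves), matrix=np.abs(out))

    def _path(self, src, dst) -> float:
        stack = [(src, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node == dst:
                return dist
            for nbr, length in self.adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node, dist + length))
        raise RuntimeError("disconnected tree")

    def newick(self) -> str:
        return write_newick(self)


def neighbor_joining(
    dm: DistanceMatrix, clamp_negative: bool = False
) -> UnrootedTree:
    """Build an unrooted NJ tree from a distance matrix.

    Standard Q-criterion agglomeration; deterministic under label
    permutation because join ties are resolved by the smallest (sorted)
    pair of clade labels.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.astype(float).copy()

    adjacency: dict = {lab: [] for lab in labels}
    negative: list[tuple] = []
    # active nodes; clade key = smallest leaf label, for tie-breaking
    nodes: list = list(labels)
    keys: dict = {lab: lab for lab in labels}
    next_internal = 0

    def add_edge(u, v, length):
        nonlocal negative
        if length < 0:
            negative.append((u, v, length))
        adjacency.setdefault(u, []).append((v, length))
        adjacency.setdefault(v, []).append((u, length))

    active = D
    while len(nodes) > 3:
        r = len(nodes)
        totals = active.sum(axis=1)
        Q = (r - 2) * active - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cands = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cands = [(i, j) for i, j in cands if i < j]
        i, j = min(cands, key=lambda p: tuple(sorted((keys[nodes[p[0]]], keys[nodes[p[1]]]))))
        d_ij = active[i, j]
        li = d_ij / 2 + (totals[i] - totals[j]) / (2 * (r - 2))
        lj = d_ij - li
        if clamp_negative:
            li, lj = _clamp_pair(li, lj)
        new = next_internal
        next_internal += 1
        add_edge(nodes[i], new, li)
        add_edge(nodes[j], new, lj)
        keys[new] = min(keys[nodes[i]], keys[nodes[j]])
        # distances from the new node to every remaining node
        rest = [k for k in range(r) if k not in (i, j)]
        d_new = (active[i, rest] + active[j, rest] - d_ij) / 2
        new_nodes = [nodes[k] for k in rest] + [new]
        m = len(rest)
        nd = np.zeros((m + 1, m + 1))
        nd[:m, :m] = active[np.ix_(rest, rest)]
        nd[m, :m] = d_new
        nd[:m, m] = d_new
        nodes = new_nodes
        active = nd

    # final: three nodes joined at one internal vertex (three-point formulas)
    a, b, c = nodes
    dab, dac, dbc = active[0, 1], active[0, 2], active[1, 2]
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    center = next_internal
    add_edge(a, center, la)
    add_edge(b, center, lb)
    add_edge(c, center, lc)

    return UnrootedTree(adjacency=adjacency, leaves=labels, negative_branches=negative)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp a negative branch to 0, moving the deficit to its sister."""
    if li < 0:
        return 0.0, max(lj + li, 0.0)
    if lj < 0:
        return max(li + lj, 0.0), 0.0
    return li, lj


def write_newick(tree: UnrootedTree) -> str:
    """Serialise as a Newick string with branch lengths.

    The tree is written rooted at an internal node (trifurcating), the usual
    convention for unrooted trees; parsing it back yields an isomorphic
    topology.  A single leaf has no unrooted representation and raises.
    """
    if len(tree.leaves) == 1:
        raise ValueError("cannot serialise a single-leaf tree")
    if len(tree.leaves) == 2:
        a, b = tree.leaves
        (nbr, length), = tree.adjacency[a]
        return f"({a}:{length / 2:.10g},{b}:{length / 2:.10g});"
    root = next(n for n in tree.adjacency if not isinstance(n, str))

    def render(node, parent) -> str:
        children = [(nbr, ln) for nbr, ln in tree.adjacency[node] if nbr != parent]
        if not children:
            return str(node)
        parts = [f"{render(nbr, node)}:{ln:.10g}" for nbr, ln in children]
        return "(" + ",".join(parts) + ")"

    return render(root, None) + ";"
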