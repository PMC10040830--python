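"""Distance-based phylogenetics of enzyme homologs.

Pairwise global-alignment identities give distances d = 1 - identity/100;
neighbor-joining (Saitou-Nei, Q-criterion) builds an unrooted tree; and
species-exclusive clades — bipartition sides whose leaves all carry the same
species label — operationalize "independently clustered" homolog groups such
as the divergent indolelactate-dehydrogenase types carried by a single
species.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import align as _al

__all__ = [
    "DistanceMatrix",
    "UnrootedTree",
    "ClusterReport",
    "global_identity",
    "distance_matrix",
    "neighbor_joining",
    "exclusive_clades",
    "read_newick",
]


def global_identity(
    a: str,
    b: str,
    matrix: str = _al.DEFAULT_MATRIX,
    gap_open: float = _al.DEFAULT_GAP_OPEN,
    gap_extend: float = _al.DEFAULT_GAP_EXTEND,
) -> float:
    """Percent identity over the columns of the optimal global alignment."""
    return _al.global_align(a, b, matrix, gap_open, gap_extend).identity_pct


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes}")
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.diag(self.d).any():
            raise ValueError("distance matrix diagonal must be zero")
        if (self.d < 0).any():
            raise ValueError("distances must be >= 0")

    def to_phylip(self, path: str | Path | None = None) -> str:
        lines = [f"{len(self.labels)}"]
        for i, lab in enumerate(self.labels):
            row = " ".join(f"{x:.6f}" for x in self.d[i])
            lines.append(f"{lab}  {row}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text


def distance_matrix(
    seqs: dict[str, str],
    matrix: str = _al.DEFAULT_MATRIX,
    gap_open: float = _al.DEFAULT_GAP_OPEN,
    gap_extend: float = _al.DEFAULT_GAP_EXTEND,
) -> DistanceMatrix:
    """d[i][j] = 1 - global identity / 100 for every sequence pair."""
    labels = list(seqs)
    if len(labels) < 3:
        raise ValueError("need at least 3 sequences")
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ident = global_identity(seqs[labels[i]], seqs[labels[j]], matrix, gap_open, gap_extend)
        d[i, j] = d[j, i] = 1.0 - ident / 100.0
    return DistanceMatrix(labels=labels, d=d)


@dataclass
class UnrootedTree:
    """Unrooted tree as an adjacency map with branch lengths.

    Leaves are labelled by sequence id; internal nodes carry synthetic
    ``_inner<i>`` names.
    """

    adjacency: dict[str, dict[str, float]]
    leaves: list[str]
    species_of: dict[str, str] = field(default_factory=dict)

    def edges(self) -> list[tuple[str, str, float]]:
        out = []
        for u, nbrs in self.adjacency.items():
            for v, w in nbrs.items():
                if u < v:
                    out.append((u, v, w))
        return out

    def leaf_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        stack = [(a, 0.0, None)]
        while stack:
            node, dist, prev = stack.pop()
            if node == b:
                return dist
            for nbr, w in self.adjacency[node].items():
                if nbr != prev:
                    stack.append((nbr, dist + w, node))
        raise KeyError(f"no path between {a!r} and {b!r}")

    def bipartitions(self) -> list[frozenset[str]]:
        """Leaf sets induced by removing each internal edge (both sides)."""
        out = []
        for u, v, _ in self.edges():
            side = self._leafset_away(u, v)
            out.append(frozenset(side))
            out.append(frozenset(self.leaves) - frozenset(side))
        return out

    def _leafset_away(self, u: str, v: str) -> set[str]:
        # leaves reachable from v without crossing back through u
        seen = set()
        stack = [(v, u)]
        while stack:
            node, prev = stack.pop()
            if node in self.leaves:
                seen.add(node)
            for nbr in self.adjacency[node]:
                if nbr != prev:
                    stack.append((nbr, node))
        return seen

    def to_newick(self, path: str | Path | None = None) -> str:
        # root the traversal at the last internal node (or a leaf for tiny trees)
        internal = [n for n in self.adjacency if n not in self.leaves]
        root = internal[-1] if internal else self.leaves[0]

        def sub(node: str, prev: str | None) -> str:
            children = [n for n in self.adjacency[node] if n != prev]
            if not children:
                return node
            parts = [f"{sub(c, node)}:{self.adjacency[node][c]:.10g}" for c in children]
            return "(" + ",".join(parts) + ")"

        text = sub(root, None) + ";"
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def neighbor_joining(dm: DistanceMatrix) -> UnrootedTree:
    """Classical neighbor joining (Saitou-Nei) on a distance matrix.

    Ties in the Q-criterion are broken by the lowest index pair; negative
    branch lengths are clamped to zero with the deficit transferred to the
    sibling branch, preserving the joined pair's summed length.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = list(dm.labels)
    D = {a: {b: dm.d[i, j] for j, b in enumerate(dm.labels)} for i, a in enumerate(dm.labels)}
    adjacency: dict[str, dict[str, float]] = {lab: {} for lab in dm.labels}
    inner = itertools.count(1)
    order = {lab: i for i, lab in enumerate(dm.labels)}

    while len(nodes) > 3:
        r = len(nodes)
        sums = {a: sum(D[a][b] for b in nodes if b != a) for a in nodes}
        best = None
        best_q = None
        for ia, ib in itertools.combinations(range(r), 2):
            a, b = nodes[ia], nodes[ib]
            q = (r - 2) * D[a][b] - sums[a] - sums[b]
            if best_q is None or q < best_q - 1e-15:
                best_q, best = q, (a, b)
        a, b = best
        new = f"_inner{next(inner)}"
        la = 0.5 * D[a][b] + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = D[a][b] - la
        # clamp negatives, transferring the deficit to the sibling branch
        if la < 0:
            lb += la
            la = 0.0
        if lb < 0:
            la += lb
            lb = 0.0
        adjacency[new] = {}
        adjacency[new][a] = la
        adjacency[a][new] = la
        adjacency[new][b] = lb
        adjacency[b][new] = lb
        D[new] = {}
        for c in nodes:
            if c in (a, b):
                continue
            dnc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
            D[new][c] = D[c][new] = dnc
        nodes = [c for c in nodes if c not in (a, b)] + [new]
        order[new] = max(order.values()) + 1

    # connect the final three nodes through one central node
    a, b, c = nodes
    center = f"_inner{next(inner)}"
    la = 0.5 * (D[a][b] + D[a][c] - D[b][c])
    lb = 0.5 * (D[a][b] + D[b][c] - D[a][c])
    lc = 0.5 * (D[a][c] + D[b][c] - D[a][b])
    adjacency[center] = {}
    for node, ln in ((a, la), (b, lb), (c, lc)):
        ln = max(ln, 0.0)
        adjacency[center][node] = ln
        adjacency[node][center] = ln
    return UnrootedTree(adjacency=adjacency, leaves=list(dm.labels))


@dataclass
class ClusterReport:
    clades: list[tuple[frozenset[str], str, str]]  # (leaf set, species, support note)

    @property
    def exclusive(self) -> list[frozenset[str]]:
        return [leaves for leaves, _, _ in self.clades]


def exclusive_clades(tree: UnrootedTree, species_of: dict[str, str]) -> ClusterReport:
    """Maximal single-species clades (>= 2 leaves) among all bipartition sides.

    Every leaf must be labelled.  A clade contained in a larger reported clade
    of the same species is dropped (maximality).  Invariant under leaf
    reordering.
    """
    unlabeled = sorted(set(tree.leaves) - set(species_of))
    if unlabeled:
        raise ValueError(f"unlabeled leaves: {unlabeled}")
    candidates = []
    for side in tree.bipartitions():
        if len(side) < 2 or len(side) == len(tree.leaves):
            continue
        species = {species_of[leaf] for leaf in side}
        if len(species) == 1:
            candidates.append((side, species.pop()))
    candidates.sort(key=lambda t: (-len(t[0]), sorted(t[0])))
    kept: list[tuple[frozenset[str], str, str]] = []
    for side, sp in candidates:
        if any(side <= bigger for bigger, _, _ in kept):
            continue
        kept.append((side, sp, "no support"))
    return ClusterReport(clades=kept)


def read_newick(path: str | Path) -> UnrootedTree:
    """Read a newick tree (for externally built phylogenies) via scikit-bio."""
    from skbio import TreeNode

    t = TreeNode.read(str(path))
    adjacency: dict[str, dict[str, float]] = {}
    leaves: list[str] = []
    counter = itertools.count(1)
    names: dict[int, str] = {}

    def name_of(node) -> str:
        key = id(node)
        if key not in names:
            if node.is_tip():
                names[key] = node.name
            else:
                names[key] = node.name or f"_inner{next(counter)}"
        return names[key]

    for node in t.traverse(include_self=True):
        nm = name_of(node)
        adjacency.setdefault(nm, {})
        if node.is_tip():
            leaves.append(nm)
        for child in node.children:
            cn = name_of(child)
            w = float(child.length or 0.0)
            adjacency[nm][cn] = w
            adjacency.setdefault(cn, {})[nm] = w
    return UnrootedTree(adjacency=adjacency, leaves=leaves)
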