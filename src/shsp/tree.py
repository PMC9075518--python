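"""p-distances, neighbor-joining trees and bootstrap supports.

The tree machinery is deliberately simple and self-contained: uncorrected
p-distances on the anchored core alignment (pairwise deletion of gapped
columns), classic Saitou–Nei neighbor joining, and non-parametric bootstrap
over alignment columns.  This replaces model-based ML/Bayesian inference:
it is sufficient to recover the coarse subcluster structure the downstream
analyses need, at desk scale, with exact determinism under a fixed seed.

Negative NJ branch lengths (a well-known artefact of the algebra) are
clamped to zero with the deficit moved to the sibling edge, preserving the
path length between the joined pair.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .align import AnchoredAlignment


@dataclass
class _Node:
    name: str | None = None
    children: list = field(default_factory=list)  # (child, branch_length)
    support: float | None = None

    def leaves(self) -> frozenset:
        if not self.children:
            return frozenset([self.name])
        out = frozenset()
        for c, _ in self.children:
            out |= c.leaves()
        return out


@dataclass
class DistanceTree:
    """An unrooted tree (stored with an arbitrary trifurcating root)."""

    root: _Node
    leaf_names: list[str]

    def newick(self) -> str:
        return _to_newick(self.root) + ";"

    def splits(self) -> set[frozenset]:
        """Non-trivial bipartitions, each given as the smaller-side leaf set
        (by frozenset of names; ties resolved by sorted-name order)."""
        all_leaves = frozenset(self.leaf_names)
        out: set[frozenset] = set()

        def walk(node):
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(all_leaves) - 1:
                    out.add(_canon_split(side, all_leaves))
                walk(child)

        walk(self.root)
        return out

    def supports(self) -> dict[frozenset, float]:
        all_leaves = frozenset(self.leaf_names)
        out = {}

        def walk(node):
            for child, _ in node.children:
                side = child.leaves()
                if 1 < len(side) < len(all_leaves) - 1 and child.support is not None:
                    out[_canon_split(side, all_leaves)] = child.support
                walk(child)

        walk(self.root)
        return out


def _canon_split(side: frozenset, universe: frozenset) -> frozenset:
    other = universe - side
    if len(side) < len(other):
        return side
    if len(other) < len(side):
        return other
    return min(side, other, key=lambda s: tuple(sorted(s)))


def _to_newick(node: _Node) -> str:
    if not node.children:
        return _quote(node.name)
    inner = ",".join(
        f"{_to_newick(c)}:{bl:.6f}" for c, bl in node.children
    )
    label = ""
    if node.support is not None:
        label = f"{node.support:g}"
    return f"({inner}){label}"


def _quote(name: str) -> str:
    return name if re.fullmatch(r"[\w.|-]+", name) else f"'{name}'"


# ---------------------------------------------------------------------------

def p_distance_matrix(msa: AnchoredAlignment) -> np.ndarray:
    """Pairwise p-distances: mismatches / compared columns.

    Columns where either row is gapped (or X) are excluded pairwise.  A
    pair with zero comparable columns gets distance NaN and a warning.
    """
    rows = msa.rows
    n = len(rows)
    arr = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(n, -1)
    valid = (arr != b"-") & (arr != b"X")
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        comparable = both.sum(axis=1)
        mism = ((arr[i] != arr) & both).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            d[i] = np.where(comparable > 0, mism / np.maximum(comparable, 1), np.nan)
    np.fill_diagonal(d, 0.0)
    if np.isnan(d).any():
        bad = [
            (msa.ids[i], msa.ids[j])
            for i, j in zip(*np.where(np.isnan(d)))
            if i < j
        ]
        warnings.warn(f"pairs with no comparable columns: {bad}")
    return d


def neighbor_joining(matrix: np.ndarray, names: list[str]) -> DistanceTree:
    """Saitou–Nei neighbor joining on a symmetric non-negative matrix.

    With fewer than 3 taxa a degenerate (star/pair) tree is returned with a
    warning.  Negative branch lengths are clamped to 0, the deficit moved to
    the sibling edge.
    """
    d = np.array(matrix, dtype=float)
    if d.shape[0] != d.shape[1] or d.shape[0] != len(names):
        raise ValueError("matrix/names size mismatch")
    if not np.allclose(d, d.T, equal_nan=True):
        raise ValueError("matrix not symmetric")
    n = len(names)
    nodes = [_Node(name=nm) for nm in names]
    if n < 3:
        warnings.warn("fewer than 3 taxa: degenerate tree")
        root = _Node(children=[(nd, float(d[0, i]) if i else 0.0) for i, nd in enumerate(nodes)])
        return DistanceTree(root=root, leaf_names=list(names))

    active = list(range(n))
    dist = d.copy()
    while len(active) > 3:
        m = len(active)
        sub = dist[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(q), q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        i, j = active[i_], active[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        new = _Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node to the remaining taxa
        newrow = 0.5 * (dist[i, :] + dist[j, :] - dij)
        dist = np.vstack([dist, newrow])
        newcol = np.append(newrow, 0.0)
        dist = np.column_stack([dist, newcol])
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = 0.5 * (dist[a, b] + dist[a, c] - dist[b, c])
    lb = 0.5 * (dist[a, b] + dist[b, c] - dist[a, c])
    lc = 0.5 * (dist[a, c] + dist[b, c] - dist[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = _Node(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return DistanceTree(root=root, leaf_names=list(names))


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li  # move the deficit to the sibling edge
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def tree_path_distances(tree: DistanceTree) -> tuple[np.ndarray, list[str]]:
    """Leaf-to-leaf path-length matrix implied by the tree."""
    names = tree.leaf_names
    idx = {nm: i for i, nm in enumerate(names)}
    n = len(names)
    d = np.zeros((n, n))

    # accumulate depths from the root; combine pairs at every internal node
    def walk2(node, depth):
        if not node.children:
            return {idx[node.name]: depth}
        subsets = []
        for child, bl in node.children:
            subsets.append(walk2(child, depth + bl))
        for gi in range(len(subsets)):
            for gj in range(gi + 1, len(subsets)):
                for u, du in subsets[gi].items():
                    for v, dv in subsets[gj].items():
                        d[u, v] = d[v, u] = du + dv - 2 * depth
        out = {}
        for s in subsets:
            out.update(s)
        return out

    walk2(tree.root, 0.0)
    return d, names


def bootstrap_supports(
    msa: AnchoredAlignment, n_reps: int = 100, seed: int = 0
) -> DistanceTree:
    """NJ tree from the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate; each internal
    split's support is the percentage of replicate NJ trees containing it.
    Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    base = neighbor_joining(p_distance_matrix(msa), msa.ids)
    rng = np.random.default_rng(seed)
    width = msa.n_columns
    counts: dict[frozenset, int] = {s: 0 for s in base.splits()}
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep_rows = ["".join(r[c] for c in cols) for r in msa.rows]
        rep = AnchoredAlignment(
            ids=msa.ids, rows=rep_rows,
            column_labels=[msa.column_labels[c] for c in cols],
        )
        rep_tree = neighbor_joining(p_distance_matrix(rep), rep.ids)
        for s in rep_tree.splits():
            if s in counts:
                counts[s] += 1

    def annotate(node):
        all_leaves = frozenset(base.leaf_names)
        for child, _ in node.children:
            side = child.leaves()
            if 1 < len(side) < len(all_leaves) - 1:
                child.support = 100.0 * counts[_canon_split(side, all_leaves)] / n_reps
            annotate(child)

    annotate(base.root)
    return base
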