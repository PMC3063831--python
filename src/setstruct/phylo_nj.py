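"""Distance-based phylogenetics: p-distance, neighbor joining, bootstrap.

The distance model is the p-distance (proportion of differing sites) with
pairwise deletion: for each sequence pair, alignment columns where either
sequence has a gap or an ambiguity character (X for protein, N for DNA) are
excluded before counting. A Poisson correction, -ln(1 - p), is available as
an option for multiple hits.

Trees are built with the Saitou–Nei neighbor-joining agglomeration; negative
branch lengths are clamped to zero, and ties in the Q-criterion are broken
by the lexicographically smallest pair of cluster labels (a cluster is
labelled by its smallest leaf), making the topology deterministic.

Bootstrap supports resample alignment columns with replacement, rebuild the
distance matrix and NJ tree per replicate, and map the percentage of
replicates containing each internal bipartition onto the full-data tree.
Support strength is categorized as weak (50–75%), moderate (76–85%) or
strong (86–100%); values below 50% are unsupported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from setstruct.io_formats import GAP, AlignmentBlock

_AMBIGUOUS = {"protein": {"X", GAP}, "dna": {"N", GAP}}


class ZeroOverlapError(ValueError):
    """A sequence pair has no column where both are unambiguous non-gaps."""


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray          # symmetric, zero diagonal
    overlap: np.ndarray    # compared-site counts per pair

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T) or np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")

    def value(self, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.d[i, j])


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: int | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    """Unrooted tree represented with a degree-3 (or star) root node."""

    root: TreeNode

    @property
    def leaf_names(self) -> tuple[str, ...]:
        return tuple(leaf.name for leaf in self.root.leaves())

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                if not node.name:
                    raise ValueError("tree has an unlabeled leaf")
                return f"{node.name}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else str(int(node.support))
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each canonicalized as the leaf set on
        the far side of an internal edge from the first taxon."""
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                parts.add(frozenset(side))
            return below

        walk(self.root)
        return parts

    def annotate_supports(self, percents: dict[frozenset[str], int]) -> None:
        """Attach bootstrap percentages to the internal nodes whose edges
        realize the given bipartitions."""
        all_leaves = set(self.leaf_names)
        ref = min(all_leaves)

        def walk(node: TreeNode) -> set[str]:
            if node.is_leaf:
                return {node.name}
            below: set[str] = set()
            for c in node.children:
                below |= walk(c)
            if node is not self.root and 2 <= len(below) <= len(all_leaves) - 2:
                side = below if ref not in below else all_leaves - below
                key = frozenset(side)
                if key in percents:
                    node.support = percents[key]
            return below

        walk(self.root)


def p_distance_matrix(
    alignment: AlignmentBlock, model: str = "p"
) -> DistanceMatrix:
    """Pairwise p-distances with pairwise deletion of gaps/ambiguities.

    ``model="poisson"`` applies the multiple-hit correction -ln(1 - p).
    Raises :class:`ZeroOverlapError` when a pair shares no comparable column.
    """
    if len(alignment.rows) < 2:
        raise ValueError("need at least 2 rows")
    skip = _AMBIGUOUS[alignment.alphabet]
    ids = alignment.ids
    mat = np.array(
        [list(seq) for _, seq in alignment.rows], dtype="U1"
    )
    ok = np.ones(mat.shape, dtype=bool)
    for ch in skip:
        ok &= mat != ch
    n = len(ids)
    d = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=int)
    for i in range(n):
        overlap[i, i] = int(ok[i].sum())
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            if m == 0:
                raise ZeroOverlapError(
                    f"no comparable sites between {ids[i]!r} and {ids[j]!r}"
                )
            p = float((mat[i, both] != mat[j, both]).sum()) / m
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson correction undefined at p=1 for "
                        f"({ids[i]}, {ids[j]})"
                    )
                p = -math.log1p(-p)
            d[i, j] = d[j, i] = p
            overlap[i, j] = overlap[j, i] = m
    return DistanceMatrix(ids=tuple(ids), d=d, overlap=overlap)


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Requires >= 3 taxa. Negative branch lengths are clamped to zero.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")

    # active clusters: label -> (node, smallest-leaf label for tie-breaks)
    nodes: dict[str, TreeNode] = {
        name: TreeNode(name=name) for name in dm.ids
    }
    labels = list(dm.ids)
    dist = {
        (a, b): float(dm.d[i, j])
        for i, a in enumerate(dm.ids)
        for j, b in enumerate(dm.ids)
        if i != j
    }

    def get(a: str, b: str) -> float:
        return dist[(a, b)]

    while len(labels) > 3:
        m = len(labels)
        r = {a: sum(get(a, b) for b in labels if b != a) for a in labels}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                q = (m - 2) * get(a, b) - r[a] - r[b]
                pair = tuple(sorted((a, b)))
                key = (q, pair[0], pair[1])
                if best is None or key < (best[0], best[1], best[2]):
                    best = key
        _q, a, b = best
        va = 0.5 * get(a, b) + (r[a] - r[b]) / (2 * (m - 2))
        vb = get(a, b) - va
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = max(va, 0.0), max(vb, 0.0)
        new = TreeNode(children=[na, nb])
        new_label = min(a, b)
        for c in labels:
            if c in (a, b):
                continue
            duc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
            dist[(new_label, c)] = dist[(c, new_label)] = duc
        labels = [c for c in labels if c not in (a, b)]
        labels.append(new_label)
        labels.sort()
        nodes[new_label] = new

    a, b, c = labels
    va = 0.5 * (get(a, b) + get(a, c) - get(b, c))
    vb = 0.5 * (get(a, b) + get(b, c) - get(a, c))
    vc = 0.5 * (get(a, c) + get(b, c) - get(a, b))
    for label, v in ((a, va), (b, vb), (c, vc)):
        nodes[label].length = max(v, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return Tree(root=root)


def bootstrap_support(
    alignment: AlignmentBlock,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "p",
) -> Tree:
    """NJ tree from the full alignment with bootstrap percentages.

    Columns are resampled with replacement ``n_reps`` times; each replicate's
    NJ tree contributes its bipartitions. Supports (integer percent of
    retained replicates) are mapped onto the full-data tree. Replicates in
    which some pair loses all comparable sites are discarded and counted; a
    warning is issued when more than 1% are discarded.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = nj_tree(p_distance_matrix(alignment, model=model))
    target = full.bipartitions()
    counts = {bp: 0 for bp in target}
    rng = np.random.default_rng(seed)
    length = alignment.length
    ids = alignment.ids
    discarded = 0
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rows = tuple(
            (rid, "".join(seq[c] for c in cols)) for rid, seq in alignment.rows
        )
        rep_aln = AlignmentBlock(rows=rows, alphabet=alignment.alphabet)
        try:
            rep_tree = nj_tree(p_distance_matrix(rep_aln, model=model))
        except ZeroOverlapError:
            discarded += 1
            continue
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1
    kept = n_reps - discarded
    if kept == 0:
        raise ZeroOverlapError("all bootstrap replicates were discarded")
    if discarded > 0.01 * n_reps:
        warnings.warn(
            f"{discarded}/{n_reps} bootstrap replicates discarded "
            "(zero-overlap pairs)", stacklevel=2)
    percents = {bp: round(100 * c / kept) for bp, c in counts.items()}
    full.annotate_supports(percents)
    return full


def support_category(bp: int) -> str:
    """Categorize a bootstrap percentage: unsupported (<50), weak (50–75),
    moderate (76–85) or strong (86–100)."""
    if not 0 <= bp <= 100:
        raise ValueError(f"bootstrap percent out of range: {bp}")
    if bp < 50:
        return "unsupported"
    if bp <= 75:
        return "weak"
    if bp <= 85:
        return "moderate"
    return "strong"


def tree_path_lengths(tree: Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    # accumulate distances from root, then combine through LCA
    dist_to_root: dict[str, float] = {}
    paths: dict[str, list[TreeNode]] = {}

    def walk(node: TreeNode, acc: float, path: list[TreeNode]) -> None:
        if node.is_leaf:
            dist_to_root[node.name] = acc + node.length
            paths[node.name] = path + [node]
            return
        for c in node.children:
            walk(c, acc + node.length, path + [node])

    walk(tree.root, -tree.root.length, [])
    out: dict[tuple[str, str], float] = {}
    names = sorted(dist_to_root)
    node_depth: dict[int, float] = {}

    def depth_of(path: list[TreeNode]) -> list[float]:
        acc, out_d = 0.0, []
        for nd in path:
            acc += nd.length
            out_d.append(acc)
        return out_d

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pa, pb = paths[a], paths[b]
            da, db = depth_of(pa), depth_of(pb)
            k = 0
            while k < min(len(pa), len(pb)) and pa[k] is pb[k]:
                k += 1
            lca_depth = da[k - 1]
            out[(a, b)] = (da[-1] - lca_depth) + (db[-1] - lca_depth)
    return out
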