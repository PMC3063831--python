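import itertools
import math

import numpy as np
import pytest

from setstruct.io_formats import AlignmentBlock
from setstruct.phylo_nj import (
    DistanceMatrix,
    Tree,
    TreeNode,
    ZeroOverlapError,
    bootstrap_support,
    nj_tree,
    p_distance_matrix,
    support_category,
    tree_path_lengths,
)


def dm_from_dict(ids, pairs):
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in pairs.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return DistanceMatrix(ids=tuple(ids), d=d,
                          overlap=np.ones((n, n), dtype=int))


# ---------------------------------------------------------------------------
# oracles


def random_additive_tree(rng, taxa):
    """Random unrooted binary tree over taxa with positive branch lengths;
    returns (bipartitions, path-length DistanceMatrix)."""
    nodes = [TreeNode(name=t, length=float(rng.uniform(0.1, 2.0)))
             for t in taxa[:3]]
    root = TreeNode(children=nodes)
    edges = list(nodes)
    for t in taxa[3:]:
        # split a random edge with a new internal node
        target = edges[rng.integers(0, len(edges))]
        parent = _parent_of(root, target)
        new_leaf = TreeNode(name=t, length=float(rng.uniform(0.1, 2.0)))
        half = target.length / 2
        inner = TreeNode(children=[target, new_leaf],
                         length=max(half, 0.05))
        target.length = max(half, 0.05)
        parent.children[parent.children.index(target)] = inner
        edges += [new_leaf, inner]
    tree = Tree(root=root)
    paths = tree_path_lengths(tree)
    ids = tuple(sorted(taxa))
    n = len(ids)
    d = np.zeros((n, n))
    for (a, b), v in paths.items():
        i, j = ids.index(a), ids.index(b)
        d[i, j] = d[j, i] = v
    return tree.bipartitions(), DistanceMatrix(
        ids=ids, d=d, overlap=np.ones((n, n), dtype=int))


def _parent_of(node, target):
    for c in node.children:
        if c is target:
            return node
        found = _parent_of(c, target)
        if found is not None:
            return found
    return None


def _descendants(node):
    out = []
    for c in node.children:
        out.append(c)
        out.extend(_descendants(c))
    return out


def enumerate_topologies(taxa):
    """All unrooted binary topologies as sets of bipartitions, by sequential
    edge insertion on explicit tree copies (independent of NJ)."""
    import copy

    trees = [TreeNode(children=[TreeNode(name=t, length=1.0)
                                for t in taxa[:3]])]
    for t in taxa[3:]:
        grown = []
        for root in trees:
            n_edges = len(_descendants(root))
            for k in range(n_edges):
                r2 = copy.deepcopy(root)
                target = _descendants(r2)[k]
                parent = _parent_of(r2, target)
                inner = TreeNode(
                    children=[target, TreeNode(name=t, length=1.0)],
                    length=1.0)
                parent.children[parent.children.index(target)] = inner
                grown.append(r2)
        trees = grown
    return [frozenset(Tree(root=r).bipartitions()) for r in trees]


def least_squares_fit(bips, taxa, dm):
    """Ordinary least-squares branch lengths for a topology; returns residual."""
    all_t = set(taxa)
    ref = min(all_t)
    edges = [frozenset([t]) for t in taxa] + [set(b) for b in bips]
    pairs = list(itertools.combinations(sorted(taxa), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (a, b) in enumerate(pairs):
        y[r] = dm.value(a, b)
        for c, e in enumerate(edges):
            e = set(e)
            side = e if ref not in e else all_t - e
            # edge on path a-b iff it separates a from b
            if (a in side) != (b in side):
                A[r, c] = 1
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.linalg.norm(A @ x - y))


# ---------------------------------------------------------------------------


class TestPDistance:
    def test_identical_rows_zero(self):
        aln = AlignmentBlock(rows=(("a", "ACDE"), ("b", "ACDE")))
        dm = p_distance_matrix(aln)
        assert dm.value("a", "b") == 0.0

    def test_one_in_four(self):
        aln = AlignmentBlock(rows=(("a", "ACDE"), ("b", "ACDF")))
        assert p_distance_matrix(aln).value("a", "b") == 0.25

    def test_pairwise_deletion_hand_count(self):
        aln = AlignmentBlock(rows=(("a", "AC-DE"), ("b", "AGFD-")))
        dm = p_distance_matrix(aln)
        assert dm.value("a", "b") == pytest.approx(1 / 3)
        assert dm.overlap[0, 1] == 3

    def test_x_treated_as_gap(self):
        aln = AlignmentBlock(rows=(("a", "AXDE"), ("b", "ACDF")))
        dm = p_distance_matrix(aln)
        assert dm.overlap[0, 1] == 3
        assert dm.value("a", "b") == pytest.approx(1 / 3)

    def test_zero_overlap_names_pair(self):
        aln = AlignmentBlock(rows=(("a", "AC--"), ("b", "--DE")))
        with pytest.raises(ZeroOverlapError, match="'a'.*'b'"):
            p_distance_matrix(aln)

    def test_poisson_correction(self):
        aln = AlignmentBlock(rows=(("a", "ACDE"), ("b", "ACDF")))
        dm = p_distance_matrix(aln, model="poisson")
        assert dm.value("a", "b") == pytest.approx(-math.log(1 - 0.25))


class TestNJ:
    def test_three_taxon_analytic_branch_lengths(self):
        dm = dm_from_dict(["t1", "t2", "t3"],
                          {("t1", "t2"): 5, ("t1", "t3"): 9, ("t2", "t3"): 10})
        tree = nj_tree(dm)
        lengths = {l.name: l.length for l in tree.root.leaves()}
        assert lengths == {"t1": 2.0, "t2": 3.0, "t3": 7.0}

    def test_additive_four_taxon_split_and_lengths(self):
        dm = dm_from_dict(
            list("ABCD"),
            {("A", "B"): 3, ("A", "C"): 5, ("A", "D"): 6,
             ("B", "C"): 6, ("B", "D"): 7, ("C", "D"): 7})
        tree = nj_tree(dm)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        paths = tree_path_lengths(tree)
        for (a, b), v in paths.items():
            assert v == pytest.approx(dm.value(a, b), abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        dm = dm_from_dict(["a", "b"], {("a", "b"): 1})
        with pytest.raises(ValueError):
            nj_tree(dm)

    def test_all_equal_distances_deterministic(self):
        ids = list("abcde")
        pairs = {(x, y): 1.0 for x, y in itertools.combinations(ids, 2)}
        t1 = nj_tree(dm_from_dict(ids, pairs))
        t2 = nj_tree(dm_from_dict(ids, pairs))
        assert t1.to_newick() == t2.to_newick()

    @pytest.mark.parametrize("n_taxa,seed", [(4, 0), (5, 1), (6, 2), (7, 3), (8, 4)])
    def test_recovers_additive_topology_and_path_lengths(self, n_taxa, seed):
        rng = np.random.default_rng(seed)
        taxa = [f"t{k}" for k in range(n_taxa)]
        true_bips, dm = random_additive_tree(rng, taxa)
        tree = nj_tree(dm)
        assert tree.bipartitions() == true_bips
        paths = tree_path_lengths(tree)
        for (a, b), v in paths.items():
            assert v == pytest.approx(dm.value(a, b), abs=1e-9)

    @pytest.mark.parametrize("n_taxa,seed", [(5, 10), (6, 11)])
    def test_matches_exhaustive_least_squares_search(self, n_taxa, seed):
        """Independent oracle: among all unrooted topologies, only the true
        additive one has zero least-squares residual; NJ must return it."""
        rng = np.random.default_rng(seed)
        taxa = [f"t{k}" for k in range(n_taxa)]
        _bips, dm = random_additive_tree(rng, taxa)
        zero_residual = [
            bips for bips in enumerate_topologies(taxa)
            if least_squares_fit(bips, taxa, dm) < 1e-8
        ]
        assert len(zero_residual) == 1
        assert frozenset(nj_tree(dm).bipartitions()) == zero_residual[0]

    def test_agrees_with_skbio_on_additive_input(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as skbio_nj
        rng = np.random.default_rng(5)
        taxa = [f"t{k}" for k in range(6)]
        _bips, dm = random_additive_tree(rng, taxa)
        sk_dm = skbio.DistanceMatrix(dm.d, ids=list(dm.ids))
        sk_tree = skbio_nj(sk_dm)
        ref = min(dm.ids)
        all_t = set(dm.ids)
        sk_bips = set()
        for node in sk_tree.non_tips():
            below = {t.name for t in node.tips()}
            if 2 <= len(below) <= len(all_t) - 2:
                side = below if ref not in below else all_t - below
                sk_bips.add(frozenset(side))
        assert nj_tree(dm).bipartitions() == sk_bips

    def test_negative_branch_lengths_clamped(self):
        dm = dm_from_dict(["a", "b", "c"],
                          {("a", "b"): 1, ("a", "c"): 1, ("b", "c"): 3})
        tree = nj_tree(dm)  # three-point formula gives a negative length
        assert all(l.length >= 0 for l in tree.root.leaves())


class TestBootstrap:
    @staticmethod
    def signal_alignment(n_cols=40):
        # A,B identical; C,D identical; the two blocks maximally distant
        return AlignmentBlock(rows=(
            ("A", "A" * n_cols), ("B", "A" * n_cols),
            ("C", "W" * n_cols), ("D", "W" * n_cols)))

    def test_fixed_seed_reproducible(self, suvh_family):
        aln = suvh_family.protein_alignment
        t1 = bootstrap_support(aln, n_reps=30, seed=42)
        t2 = bootstrap_support(aln, n_reps=30, seed=42)
        assert t1.to_newick() == t2.to_newick()

    def test_unambiguous_signal_gets_full_support(self):
        tree = bootstrap_support(self.signal_alignment(), n_reps=100, seed=0)
        supports = [n.support for n in _internal_nodes(tree.root)
                    if n.support is not None]
        assert supports == [100]

    def test_zero_reps_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_support(self.signal_alignment(), n_reps=0, seed=0)

    def test_support_monotone_in_duplicated_signal(self):
        """Appending duplicated signal columns never decreases the supported
        split's bootstrap percentage (fixed seed, nested column sets)."""
        base = AlignmentBlock(rows=(
            ("A", "AAAAWCDE"), ("B", "AAAAWCDF"),
            ("C", "WWWWACDE"), ("D", "WWWWACDF")))
        prev = 0
        for extra in (0, 4, 8):
            rows = tuple((rid, seq + seq[:4] * (extra // 4))
                         for rid, seq in base.rows)
            aln = AlignmentBlock(rows=rows)
            tree = bootstrap_support(aln, n_reps=200, seed=7)
            sup = {n.support for n in _internal_nodes(tree.root)
                   if n.support is not None}
            cur = max(sup) if sup else 0
            assert cur >= prev
            prev = cur


def _internal_nodes(node):
    for c in node.children:
        if not c.is_leaf:
            yield c
            yield from _internal_nodes(c)


class TestSupportCategory:
    @pytest.mark.parametrize("bp,cat", [
        (0, "unsupported"), (49, "unsupported"),
        (50, "weak"), (75, "weak"),
        (76, "moderate"), (80, "moderate"), (85, "moderate"),
        (86, "strong"), (100, "strong"),
    ])
    def test_published_ranges(self, bp, cat):
        assert support_category(bp) == cat

    @pytest.mark.parametrize("bad", [-1, 101])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            support_category(bad)
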