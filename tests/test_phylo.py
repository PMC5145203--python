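import itertools
import math

import numpy as np
import pytest

from gh2arch.msa import MSA
from gh2arch.phylo import (
    DistanceMatrix,
    bipartitions,
    bootstrap_support,
    canonical_split,
    concordance,
    condense,
    correct_distance,
    distance_matrix,
    nj,
    p_distance,
    separating_edge_support,
    subcluster_and_select,
    tree_distance_matrix,
    union_monophyletic,
)
from gh2arch.synth import sample_tree


class TestPDistance:
    MSA4 = MSA(["a", "b", "c"], ["AAAA", "AAGG", "A-AA"])

    def test_identical_rows_zero(self):
        msa = MSA(["a", "b"], ["AAAA", "AAAA"])
        assert p_distance(msa, ("a", "b")) == 0.0

    def test_hand_count(self):
        assert p_distance(self.MSA4, ("a", "b")) == 0.5

    def test_pairwise_deletion_skips_gapped_columns(self):
        msa = MSA(["a", "b"], ["A-AA", "AGAA"])
        assert p_distance(msa, ("a", "b"), "pairwise") == 0.0

    def test_complete_deletion_uses_global_gap_mask(self):
        # row c has a gap at the second column, so that column is
        # excluded for every pair; a vs b differ at 2 of the 3 kept
        assert p_distance(self.MSA4, ("a", "b"), "complete") == pytest.approx(2 / 3)

    def test_all_gap_pair_is_error(self):
        msa = MSA(["a", "b"], ["A-", "-A"])
        with pytest.raises(ValueError, match="comparable"):
            p_distance(msa, ("a", "b"))


class TestCorrection:
    @pytest.mark.parametrize("method", ["none", "poisson", "kimura"])
    def test_zero_p_gives_zero(self, method):
        assert correct_distance(0.0, method) == 0.0

    def test_kimura_closed_form(self):
        assert correct_distance(0.1, "kimura") == pytest.approx(
            -math.log(1 - 0.1 - 0.2 * 0.01), abs=1e-9
        )
        assert correct_distance(0.1, "kimura") == pytest.approx(0.107585, abs=1e-6)

    def test_poisson_closed_form(self):
        assert correct_distance(0.2, "poisson") == pytest.approx(-math.log(0.8))

    def test_kimura_saturates(self):
        # 1 - 0.95 - 0.2*0.9025 = -0.1305 < 0
        assert math.isinf(correct_distance(0.95, "kimura"))

    def test_none_is_identity(self):
        assert correct_distance(0.37, "none") == 0.37


def _dm(ids, rows):
    return DistanceMatrix(ids, np.array(rows, dtype=float))


class TestNJ:
    def test_four_taxon_additive_recovery(self):
        # tree (a:1,b:2,(c:3,d:4):5); path lengths computed by hand
        dm = _dm(
            list("abcd"),
            [[0, 3, 9, 10],
             [3, 0, 10, 11],
             [9, 10, 0, 7],
             [10, 11, 7, 0]],
        )
        tree = nj(dm)
        splits = set(bipartitions(tree))
        all_tips = frozenset("abcd")
        assert canonical_split(frozenset("ab"), all_tips) in splits
        recovered = tree_distance_matrix(tree)
        np.testing.assert_allclose(recovered.matrix, dm.matrix, atol=1e-9)

    def test_three_taxon_closed_form(self):
        dm = _dm(list("abc"), [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_random_additive_matrices_recovered_exactly(self):
        for seed in range(10):
            true = sample_tree(4 + seed % 9, seed=seed, branch_mean=0.5,
                               branch_floor=0.1)
            dm = tree_distance_matrix(true)
            est = nj(dm)
            assert set(bipartitions(est)) == set(bipartitions(true))
            np.testing.assert_allclose(
                tree_distance_matrix(est).matrix, dm.matrix, atol=1e-8
            )

    def test_agrees_with_independent_nj_implementation(self):
        # cross-check against scikit-bio's neighbor joining on noisy
        # (non-additive) matrices: same splits when signal is clear
        import skbio
        rng = np.random.default_rng(12)
        for trial in range(5):
            true = sample_tree(7, seed=40 + trial, branch_mean=0.6,
                               branch_floor=0.3)
            base = tree_distance_matrix(true)
            noise = rng.uniform(-0.03, 0.03, size=base.matrix.shape)
            mat = np.abs(base.matrix + noise + noise.T)
            mat = (mat + mat.T) / 2.0  # exact symmetry
            np.fill_diagonal(mat, 0.0)
            ours = nj(DistanceMatrix(base.ids, mat))
            theirs = skbio.tree.nj(
                skbio.DistanceMatrix(mat, ids=base.ids)
            )
            assert set(bipartitions(ours)) == set(bipartitions(theirs))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj(_dm(list("ab"), [[0, 1], [1, 0]]))

    def test_saturated_matrix_rejected(self):
        dm = _dm(list("abc"), [[0, 1, math.inf], [1, 0, 1], [math.inf, 1, 0]])
        with pytest.raises(ValueError, match="saturated"):
            nj(dm)


def five_taxon_topologies():
    """All 15 unrooted 5-leaf topologies as (split1, split2) cherry pairs."""
    leaves = list(range(5))
    seen = set()
    for cherry1 in itertools.combinations(leaves, 2):
        rest = [x for x in leaves if x not in cherry1]
        for cherry2 in itertools.combinations(rest, 2):
            key = frozenset([frozenset(cherry1), frozenset(cherry2)])
            seen.add(key)
    return seen


def ls_fit_sse(dm, cherry1, cherry2):
    """Least-squares branch fit for the 5-taxon topology with two
    cherries; returns the SSE of fitted path lengths vs the matrix."""
    leaves = list(range(5))
    middle = [x for x in leaves if x not in cherry1 and x not in cherry2][0]
    # edges: 5 pendant + 2 internal (cherry1-junction, cherry2-junction)
    pairs = list(itertools.combinations(leaves, 2))
    A = np.zeros((len(pairs), 7))
    for row, (i, j) in enumerate(pairs):
        for leaf in (i, j):
            A[row, leaf] = 1.0
        side_i = 0 if i in cherry1 else (1 if i in cherry2 else 2)
        side_j = 0 if j in cherry1 else (1 if j in cherry2 else 2)
        if side_i != side_j:
            if 0 in (side_i, side_j):
                A[row, 5] = 1.0
            if 1 in (side_i, side_j):
                A[row, 6] = 1.0
    y = np.array([dm.matrix[i, j] for i, j in pairs])
    x, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(((A @ x - y) ** 2).sum())


def test_nj_finds_least_squares_topology_on_five_taxa():
    """On near-additive 5-taxon matrices the NJ topology minimises the
    least-squares fit among all 15 possible topologies."""
    rng = np.random.default_rng(42)
    for trial in range(5):
        true = sample_tree(5, seed=100 + trial, branch_mean=0.5, branch_floor=0.3)
        dm = tree_distance_matrix(true)
        noise = rng.uniform(-0.02, 0.02, size=dm.matrix.shape)
        noisy = dm.matrix + noise + noise.T
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(dm.ids, np.abs(noisy))
        est = nj(dm)
        est_splits = set(bipartitions(est))
        index = {sid: k for k, sid in enumerate(dm.ids)}
        best = min(
            five_taxon_topologies(),
            key=lambda topo: ls_fit_sse(dm, *[tuple(sorted(c)) for c in topo]),
        )
        for cherry in best:
            names = frozenset(dm.ids[i] for i in cherry)
            assert canonical_split(names, frozenset(dm.ids)) in est_splits


class TestBootstrap:
    @staticmethod
    def _two_clade_msa():
        # 8 taxa, two clearly separated 4-leaf clades: clade A rows share
        # one motif, clade B another, with within-clade variation on top
        base_a = "AAAAAAAAAA" * 20
        base_b = "CCCCCCCCCC" * 20
        rows, ids = [], []
        for k in range(4):
            row = list(base_a)
            row[k] = "D"
            ids.append(f"a{k}")
            rows.append("".join(row))
        for k in range(4):
            row = list(base_b)
            row[k] = "E"
            ids.append(f"b{k}")
            rows.append("".join(row))
        return MSA(ids, rows)

    def test_separating_edge_support_unanimous(self):
        msa = self._two_clade_msa()
        tree = bootstrap_support(msa, n_replicates=100, seed=4, method="none")
        labels = {t.name: t.name[0] for t in tree.tips()}
        assert separating_edge_support(tree, labels, ["a"]) == 1.0

    def test_same_seed_identical_supports(self):
        msa = self._two_clade_msa()
        t1 = bootstrap_support(msa, n_replicates=20, seed=9, method="none")
        t2 = bootstrap_support(msa, n_replicates=20, seed=9, method="none")
        s1 = sorted(n.support for n in t1.non_tips() if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips() if n.support is not None)
        assert s1 == s2

    def test_single_replicate_supports_binary(self):
        msa = self._two_clade_msa()
        tree = bootstrap_support(msa, n_replicates=1, seed=2, method="none")
        supports = {n.support for n in tree.non_tips() if n.support is not None}
        assert supports <= {0.0, 1.0}

    def test_separating_support_invariant_to_row_order(self):
        # the well-supported split is insensitive to input row order
        # (ties among the near-identical within-clade rows are not)
        msa = self._two_clade_msa()
        perm = MSA(list(reversed(msa.ids)), list(reversed(msa.rows)))
        labels = {sid: sid[0] for sid in msa.ids}
        t1 = bootstrap_support(msa, n_replicates=30, seed=5, method="none")
        t2 = bootstrap_support(perm, n_replicates=30, seed=5, method="none")
        assert separating_edge_support(t1, labels, ["a"]) == 1.0
        assert separating_edge_support(t2, labels, ["a"]) == 1.0


class TestCondense:
    @staticmethod
    def _tree_with_support(s):
        from gh2arch.annot_io import read_newick
        return read_newick(f"(((a:1,b:1){s}:1,c:1)0.9:1,d:1,e:1);")

    def test_edge_below_threshold_collapsed(self):
        tree = condense(self._tree_with_support(0.49), 0.5)
        assert len(list(tree.non_tips())) == 1  # only the 0.9 node left

    def test_edge_at_threshold_retained(self):
        tree = condense(self._tree_with_support(0.50), 0.5)
        assert len(list(tree.non_tips())) == 2

    def test_full_support_unchanged(self):
        before = self._tree_with_support(1.0)
        after = condense(before, 0.5)
        assert len(list(after.non_tips())) == len(list(before.non_tips()))

    def test_idempotent_and_never_adds_edges(self):
        tree = self._tree_with_support(0.3)
        once = condense(tree, 0.5)
        twice = condense(once, 0.5)
        n_once = len(list(once.non_tips()))
        assert n_once <= len(list(tree.non_tips()))
        assert len(list(twice.non_tips())) == n_once

    def test_collapsed_edge_length_removed(self):
        # contracting the weak edge shortens only the paths crossing it
        tree = self._tree_with_support(0.2)
        before = tree_distance_matrix(tree)
        after = tree_distance_matrix(condense(tree, 0.5))
        ia, ic = before.ids.index("a"), before.ids.index("c")
        assert after.matrix[ia, ic] == pytest.approx(before.matrix[ia, ic] - 1.0)


class TestConcordance:
    from gh2arch.annot_io import read_newick
    TREE = read_newick("(((a1:1,a2:1):1,(b1:1,b2:1):1):1,(c1:1,c2:1):1,d1:1);")

    def test_cladal_labels_monophyletic_pure(self):
        labels = {n: n[0] for n in
                  ["a1", "a2", "b1", "b2", "c1", "c2", "d1"]}
        rep = concordance(self.TREE, labels)
        for label in "abc":
            assert rep.per_label[label].monophyletic
            assert rep.per_label[label].purity == 1.0

    def test_singleton_label_monophyletic_by_convention(self):
        labels = {n: n[0] for n in
                  ["a1", "a2", "b1", "b2", "c1", "c2", "d1"]}
        rep = concordance(self.TREE, labels)
        assert rep.per_label["d"].monophyletic

    def test_nested_label_reported(self):
        # b leaves sit inside the {a, b} clade: a is paraphyletic wrt b
        labels = {"a1": "x", "a2": "x", "b1": "y", "b2": "y",
                  "c1": "z", "c2": "z", "d1": "z"}
        rep = concordance(self.TREE, labels)
        assert rep.per_label["y"].monophyletic
        assert rep.is_nested("y", "x") is False  # x is itself a clade here
        labels2 = dict(labels, a2="y")  # now x={a1} inside the ab clade
        rep2 = concordance(self.TREE, labels2)
        assert rep2.is_nested("x", "y")

    def test_union_monophyly_helper(self):
        labels = {"a1": "x", "a2": "x", "b1": "y", "b2": "y",
                  "c1": "z", "c2": "z", "d1": "z"}
        assert union_monophyletic(self.TREE, labels, ["x", "y"])
        # a scattered union (one leaf from each cherry) is no clade
        scattered = {"a1": "x", "a2": "o", "b1": "x", "b2": "o",
                     "c1": "o", "c2": "o", "d1": "o"}
        assert not union_monophyletic(self.TREE, scattered, ["x"])

    def test_unlabeled_leaf_rejected(self):
        with pytest.raises(ValueError, match="unlabeled"):
            concordance(self.TREE, {"a1": "x"})


class TestSubclusterSelect:
    DM = _dm(
        ["p", "q", "r", "s"],
        [[0, 0.1, 0.9, 0.9],
         [0.1, 0, 0.9, 0.9],
         [0.9, 0.9, 0, 0.1],
         [0.9, 0.9, 0.1, 0]],
    )

    def test_quota_at_least_pool_returns_all(self):
        chosen, subclusters = subcluster_and_select(self.DM, 0.2, 10, seed=0)
        assert chosen == ["p", "q", "r", "s"]

    def test_each_subcluster_represented(self):
        chosen, subclusters = subcluster_and_select(self.DM, 0.2, 3, seed=1)
        assert len(chosen) == 3
        assert {subclusters[c] for c in chosen} == {"SC1", "SC2"}

    def test_deterministic_given_seed(self):
        a, _ = subcluster_and_select(self.DM, 0.2, 3, seed=7)
        b, _ = subcluster_and_select(self.DM, 0.2, 3, seed=7)
        assert a == b


def test_distance_matrix_validation():
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(ValueError, match="diagonal"):
        DistanceMatrix(["a", "b"], np.array([[1.0, 1.0], [1.0, 0.0]]))


def test_distance_matrix_from_alignment_matches_scalar_path():
    msa = MSA(["a", "b", "c"], ["AAAA", "AAGG", "AGGG"])
    dm = distance_matrix(msa, method="kimura")
    expected = correct_distance(p_distance(msa, ("a", "b")), "kimura")
    i, j = dm.ids.index("a"), dm.ids.index("b")
    assert dm.matrix[i, j] == pytest.approx(expected)
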