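import math

import numpy as np
import pytest

from coevscreen.core_io import (
    AlignmentShapeError,
    DistanceMatrix,
    DuplicateLabelError,
    EmptyInputError,
    IncomparablePairError,
    Msa,
    PhyloTree,
    TooFewTaxaError,
    UnknownLabelError,
    nj_tree,
    patristic_distances,
    protein_distance_matrix,
    prune_tree,
    read_msa,
    read_newick,
    root_min_height,
    write_msa,
    write_newick,
)

from conftest import random_binary_tree


class TestMsaIO:
    def test_read_preserves_shape_and_order(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">spB x\nACDEFGHIKLMN\n>spA\nACDEFGHIKLMN\n>spC\nACDEFGHIKLMY\n")
        msa = read_msa(p, "prot")
        assert msa.n_rows == 3 and msa.length == 12
        assert msa.species == ["spB", "spA", "spC"]  # file order

    def test_ragged_alignment_rejected(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">a\nACDEFGHIKL\n>b\nACDEFGHIKLM\n")
        with pytest.raises(AlignmentShapeError):
            read_msa(p)

    def test_duplicate_species_rejected(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">a\nACDE\n>a\nACDE\n")
        with pytest.raises(DuplicateLabelError):
            read_msa(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(EmptyInputError):
            read_msa(p)

    def test_roundtrip_identity_and_canonical_bytes(self, tmp_path, toy_msa):
        p1 = tmp_path / "one.fasta"
        write_msa(toy_msa, p1)
        again = read_msa(p1, "toy")
        assert again.rows == toy_msa.rows
        p2 = tmp_path / "two.fasta"
        write_msa(again, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            Msa("bad", [("a", "ACDB")])  # 'B' not in the residue alphabet

    def test_case_folded(self):
        msa = Msa("x", [("a", "acde")])
        assert msa.rows[0][1] == "ACDE"


class TestNewick:
    def test_parse_lengths_and_paths(self):
        t = PhyloTree.from_newick("((A:1,B:2):0.5,C:3);")
        d = t.patristic_distances()
        assert d.get("A", "B") == pytest.approx(3.0)
        assert d.get("A", "C") == pytest.approx(4.5)

    def test_roundtrip(self, tmp_path):
        s = "((A:1,B:2):0.5,C:3);"
        t = PhyloTree.from_newick(s)
        p = tmp_path / "t.nwk"
        write_newick(t, p)
        t2 = read_newick(p)
        assert t2.to_newick() == t.to_newick()
        np.testing.assert_allclose(
            t2.patristic_distances().values, t.patristic_distances().values
        )

    def test_duplicate_leaves_rejected(self):
        with pytest.raises(DuplicateLabelError):
            PhyloTree.from_newick("((A:1,B:1):1,(A:1,C:1):1);")

    def test_unbalanced_parentheses_rejected(self):
        with pytest.raises(ValueError):
            PhyloTree.from_newick("((A:1,B:2:0.5,C:3);")

    def test_missing_lengths_default_zero(self):
        t = PhyloTree.from_newick("((A,B),C);")
        assert t.total_length() == 0.0


class TestDistanceMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b"], np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_protein_distances_match_hand_computation(self):
        # pairwise p-distances counted by hand over gap-free columns
        msa = Msa(
            "h",
            [
                ("s1", "ACDEFG"),
                ("s2", "ACDEYG"),  # 1/6 mismatch vs s1
                ("s3", "ACD-YG"),  # vs s1: 1/5; vs s2: 0/5
            ],
        )
        d = protein_distance_matrix(msa)
        assert d.get("s1", "s2") == pytest.approx(-math.log(1 - 1 / 6))
        assert d.get("s1", "s3") == pytest.approx(-math.log(1 - 1 / 5))
        assert d.get("s2", "s3") == pytest.approx(0.0)

    def test_identical_sequences_zero_distance(self):
        msa = Msa("i", [("a", "ACDE"), ("b", "ACDE")])
        assert protein_distance_matrix(msa).get("a", "b") == 0.0

    def test_half_mismatch_poisson_closed_form(self):
        msa = Msa("p", [("a", "ACDE"), ("b", "ACYW")])
        assert protein_distance_matrix(msa).get("a", "b") == pytest.approx(
            -math.log(0.5)
        )

    def test_saturated_pair_capped_with_warning(self):
        msa = Msa("s", [("a", "AAAA"), ("b", "CCCC")])
        with pytest.warns(UserWarning, match="cap"):
            d = protein_distance_matrix(msa)
        assert d.get("a", "b") == pytest.approx(-math.log(1 - 0.95))

    def test_no_shared_columns_rejected(self):
        msa = Msa("n", [("a", "AC--"), ("b", "--DE")])
        with pytest.raises(IncomparablePairError):
            protein_distance_matrix(msa)


class TestNeighborJoining:
    def test_exact_recovery_four_taxa(self):
        # additive matrix computed by hand from ((A:1,B:2):1,C:3,D:4)
        dist = DistanceMatrix(
            ["A", "B", "C", "D"],
            np.array(
                [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], float
            ),
        )
        tree = nj_tree(dist)
        np.testing.assert_allclose(
            tree.patristic_distances().values, dist.values, atol=1e-12
        )

    def test_three_taxon_closed_form(self):
        dist = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        tree = nj_tree(dist)
        np.testing.assert_allclose(
            tree.patristic_distances().values, dist.values, atol=1e-12
        )

    def test_label_order_invariance(self):
        rng = np.random.default_rng(0)
        tree, dist = random_binary_tree(7, rng)
        perm = rng.permutation(len(dist.labels))
        shuffled = DistanceMatrix(
            [dist.labels[i] for i in perm], dist.values[np.ix_(perm, perm)]
        )
        t1 = nj_tree(dist).patristic_distances()
        t2 = nj_tree(shuffled).patristic_distances()
        assert t1.labels == t2.labels  # both sorted
        np.testing.assert_allclose(t1.values, t2.values, atol=1e-9)

    def test_too_few_taxa(self):
        with pytest.raises(TooFewTaxaError):
            nj_tree(DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_recovery_random_trees(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            tree, dist = random_binary_tree(n, rng)
            rebuilt = nj_tree(dist)
            np.testing.assert_allclose(
                rebuilt.patristic_distances().values, dist.values, atol=1e-9
            )

    def test_matches_scikit_bio_on_additive_matrix(self):
        """Independent NJ oracle: scikit-bio's implementation."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(7)
        tree, dist = random_binary_tree(8, rng)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(dist.values, dist.labels))
        sk_d = sk_tree.tip_tip_distances(dist.labels)
        mine = nj_tree(dist).patristic_distances()
        np.testing.assert_allclose(
            mine.values, np.asarray(sk_d.data), atol=1e-6
        )


class TestRooting:
    def test_two_leaf_midpoint(self):
        t = PhyloTree.from_newick("(A:1,B:3);")
        rooted = root_min_height(t)
        assert rooted.height() == pytest.approx(2.0)

    def test_height_equals_half_diameter(self):
        # the minimiser of the maximum root-to-leaf distance is the tree
        # centre, whose eccentricity is half the diameter
        rng = np.random.default_rng(3)
        for _ in range(10):
            tree, dist = random_binary_tree(int(rng.integers(4, 10)), rng)
            rooted = root_min_height(tree)
            assert rooted.height() == pytest.approx(dist.values.max() / 2, rel=1e-9)

    def test_grid_search_oracle_caterpillar(self):
        t = PhyloTree.from_newick("(((A:1,B:2):1,C:0.5):2,D:3);")
        rooted = root_min_height(t)
        # brute force: the minimal achievable height is half the diameter;
        # scan all leaf pairs for the diameter
        d = t.patristic_distances().values
        assert rooted.height() == pytest.approx(d.max() / 2, abs=1e-9)

    def test_balanced_tree_unchanged_height(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert root_min_height(t).height() == pytest.approx(2.0)


class TestPruning:
    def test_identity_prune(self, four_taxon_tree):
        pruned = prune_tree(four_taxon_tree, ["A", "B", "C", "D"])
        np.testing.assert_allclose(
            pruned.patristic_distances().values,
            four_taxon_tree.patristic_distances().values,
        )

    def test_path_length_preserved(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        pruned = prune_tree(t, ["A", "C"])
        assert pruned.patristic_distances().get("A", "C") == pytest.approx(4.0)

    def test_random_subset_preserves_metric(self):
        rng = np.random.default_rng(11)
        tree, dist = random_binary_tree(20, rng)
        keep = sorted(rng.choice(dist.labels, size=8, replace=False))
        pruned = prune_tree(tree, keep)
        sub = dist.submatrix(keep)
        np.testing.assert_allclose(
            pruned.patristic_distances().values, sub.values, atol=1e-9
        )

    def test_unknown_label_rejected(self, four_taxon_tree):
        with pytest.raises(UnknownLabelError):
            prune_tree(four_taxon_tree, ["A", "Z"])


class TestPatristic:
    def test_star_tree(self):
        t = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        vals = t.patristic_distances().values
        off = vals[~np.eye(4, dtype=bool)]
        assert np.all(off == 2.0)

    def test_symmetric_zero_diagonal(self, four_taxon_tree):
        d = four_taxon_tree.patristic_distances()
        np.testing.assert_allclose(d.values, d.values.T)
        assert np.all(np.diag(d.values) == 0)
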