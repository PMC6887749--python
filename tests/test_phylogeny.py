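import math

import numpy as np
import pytest

from famsurvey.exceptions import FamSurveyError, UndefinedDistanceError
from famsurvey.io import AMINO_ACIDS
from famsurvey.phylogeny import (DistanceMatrix, assign_subfamilies,
                                 bootstrap_supports, distance_matrix,
                                 neighbor_joining, progressive_msa)

from oracles import random_additive_matrix


def degap(s):
    return s.replace("-", "")


class TestProgressiveMsa:
    def test_identical_pair_gap_free(self):
        aln = progressive_msa({"a": "MKVLT", "b": "MKVLT"})
        assert aln == {"a": "MKVLT", "b": "MKVLT"}

    def test_unit_matrix_single_gap(self):
        # match +1 / mismatch -1, linear gap cost 2 per position
        unit = np.full((21, 21), -1.0)
        np.fill_diagonal(unit, 1.0)
        unit[20, :] = unit[:, 20] = 0.0
        aln = progressive_msa({"r1": "ACDE", "r2": "ACE"}, matrix=unit,
                              gap_open=0.0, gap_extend=2.0)
        assert len(aln["r1"]) == len(aln["r2"]) == 4
        assert aln["r1"] == "ACDE"
        assert aln["r2"].count("-") == 1

    def test_degapping_restores_inputs(self):
        rng = np.random.default_rng(4)
        seqs = {
            f"s{i}": "".join(rng.choice(list(AMINO_ACIDS),
                                        size=int(rng.integers(30, 60))))
            for i in range(6)
        }
        aln = progressive_msa(seqs)
        lengths = {len(s) for s in aln.values()}
        assert len(lengths) == 1
        for name, seq in seqs.items():
            assert degap(aln[name]) == seq

    def test_single_sequence_degenerate(self):
        assert progressive_msa({"only": "MKV"}) == {"only": "MKV"}


class TestDistanceMatrix:
    def test_p_distance(self):
        dm = distance_matrix({"a": "AAAA", "b": "AAAT"})
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_identical_rows_zero(self):
        dm = distance_matrix({"a": "MKVL", "b": "MKVL"})
        assert dm.d[0, 1] == 0.0

    def test_poisson_correction(self):
        dm = distance_matrix({"a": "AAAA", "b": "AAAT"}, model="poisson")
        assert dm.d[0, 1] == pytest.approx(-math.log(0.75))

    def test_poisson_dominates_p(self):
        rng = np.random.default_rng(9)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACDEF"), size=50))
            for i in range(4)
        }
        p = distance_matrix(seqs).d
        poisson = distance_matrix(seqs, model="poisson").d
        assert np.all(poisson >= p - 1e-12)

    def test_gapped_sites_excluded(self):
        dm = distance_matrix({"a": "A-AA", "b": "ATAT"})
        assert dm.d[0, 1] == pytest.approx(1 / 3)

    def test_no_shared_sites_rejected(self):
        with pytest.raises(UndefinedDistanceError, match="a.*b"):
            distance_matrix({"a": "A--", "b": "-TT"})


SPEC_4TAXON = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([
        [0.0, 3.0, 5.0, 6.0],
        [3.0, 0.0, 6.0, 7.0],
        [5.0, 6.0, 0.0, 7.0],
        [6.0, 7.0, 7.0, 0.0],
    ]),
)


class TestNeighborJoining:
    def test_additive_four_taxon_case(self):
        """The additive matrix of ((A:1,B:2):1,(C:3,D:4)) is recovered
        exactly: topology AB|CD and all path lengths reproduced."""
        tree = neighbor_joining(SPEC_4TAXON)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        labels, dist = tree.path_length_matrix()
        pos = {l: i for i, l in enumerate(labels)}
        for (x, y), expected in [(("A", "B"), 3), (("A", "C"), 5),
                                 (("A", "D"), 6), (("B", "C"), 6),
                                 (("B", "D"), 7), (("C", "D"), 7)]:
            assert dist[pos[x], pos[y]] == pytest.approx(expected)

    def test_three_taxa_three_point_formulas(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0.0, 3.0, 4.0],
                                      [3.0, 0.0, 5.0],
                                      [4.0, 5.0, 0.0]]))
        tree = neighbor_joining(dm)
        lengths = {child.name: length for child, length in tree.root.children}
        assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 3.0})

    def test_recovers_random_additive_matrices(self):
        """Path lengths of the NJ tree reproduce random 8-taxon additive
        inputs to 1e-9 over 50 seeded cases."""
        rng = np.random.default_rng(100)
        for _ in range(50):
            labels, d = random_additive_matrix(8, rng)
            tree = neighbor_joining(DistanceMatrix(labels, d))
            out_labels, out = tree.path_length_matrix()
            order = [out_labels.index(l) for l in labels]
            assert np.allclose(out[np.ix_(order, order)], d, atol=1e-9)

    def test_label_order_invariance(self):
        rng = np.random.default_rng(55)
        labels, d = random_additive_matrix(6, rng)
        tree1 = neighbor_joining(DistanceMatrix(labels, d))
        perm = [3, 1, 5, 0, 4, 2]
        tree2 = neighbor_joining(DistanceMatrix(
            [labels[i] for i in perm], d[np.ix_(perm, perm)]))
        assert tree1.bipartitions() == tree2.bipartitions()
        l1, d1 = tree1.path_length_matrix()
        l2, d2 = tree2.path_length_matrix()
        assert l1 == l2
        assert np.allclose(d1, d2, atol=1e-9)

    def test_agrees_with_scikit_bio(self):
        """Independent cross-check: scikit-bio's NJ yields the same
        leaf-to-leaf path lengths on an additive matrix."""
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj

        rng = np.random.default_rng(77)
        labels, d = random_additive_matrix(8, rng)
        ours = neighbor_joining(DistanceMatrix(labels, d))
        _, our_dist = ours.path_length_matrix()

        sk_tree = nj(skbio.DistanceMatrix(d, ids=labels))
        sk = sk_tree.tip_tip_distances(sorted(labels))
        assert np.allclose(our_dist, sk.data, atol=1e-6)

    def test_too_few_labels_rejected(self):
        with pytest.raises(FamSurveyError):
            neighbor_joining(DistanceMatrix(["a", "b"],
                                            np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_negative_branch_lengths_clamped(self):
        dm = DistanceMatrix(["a", "b", "c"],
                            np.array([[0.0, 1.0, 10.0],
                                      [1.0, 0.0, 1.0],
                                      [10.0, 1.0, 0.0]]))
        tree = neighbor_joining(dm)
        for child, length in tree.root.children:
            assert length >= 0.0


def _two_group_alignment():
    """Two clearly separated 4-taxon groups with 20 diagnostic columns."""
    rng = np.random.default_rng(2)
    rows = {}
    for g, (base, names) in enumerate(
            [("A", ["a1", "a2", "a3", "a4"]), ("W", ["b1", "b2", "b3", "b4"])]):
        for i, name in enumerate(names):
            noise = "".join(rng.choice(list("DEKR"), size=8))
            rows[name] = base * 20 + noise
    return rows


class TestBootstrap:
    def test_diagnostic_split_high_support(self):
        tree = bootstrap_supports(_two_group_alignment(), 100, seed=5)
        split = frozenset({"b1", "b2", "b3", "b4"})
        assert split in tree.supports
        assert tree.supports[split] >= 95.0

    def test_single_replicate_supports_binary(self):
        tree = bootstrap_supports(_two_group_alignment(), 1, seed=5)
        assert set(tree.supports.values()) <= {0.0, 100.0}

    def test_same_seed_reproducible(self):
        aln = _two_group_alignment()
        t1 = bootstrap_supports(aln, 50, seed=9)
        t2 = bootstrap_supports(aln, 50, seed=9)
        assert t1.supports == t2.supports

    def test_leaf_order_invariance(self):
        aln = _two_group_alignment()
        shuffled = {k: aln[k] for k in reversed(list(aln))}
        t1 = bootstrap_supports(aln, 50, seed=9)
        t2 = bootstrap_supports(shuffled, 50, seed=9)
        assert t1.supports == t2.supports

    def test_newick_export_with_supports(self):
        tree = bootstrap_supports(_two_group_alignment(), 20, seed=1)
        newick = tree.to_newick(with_supports=True)
        assert newick.endswith(";")
        for leaf in ("a1", "b4"):
            assert leaf in newick


class TestAssignSubfamilies:
    def test_nearest_reference_wins(self):
        dm = DistanceMatrix(
            ["q", "refG", "refB", "far"],
            np.array([
                [0.0, 0.1, 0.9, 1.0],
                [0.1, 0.0, 0.9, 1.0],
                [0.9, 0.9, 0.0, 0.4],
                [1.0, 1.0, 0.4, 0.0],
            ]))
        tree = neighbor_joining(dm)
        result = assign_subfamilies(tree, {"refG": "ABCG", "refB": "ABCB"})
        assert result["q"] == "ABCG"
        assert result["far"] == "ABCB"

    def test_all_leaves_referenced_identity(self):
        tree = neighbor_joining(SPEC_4TAXON)
        refs = {"A": "x", "B": "y", "C": "z", "D": "w"}
        assert assign_subfamilies(tree, refs) == refs

    def test_no_references_rejected(self):
        tree = neighbor_joining(SPEC_4TAXON)
        with pytest.raises(FamSurveyError):
            assign_subfamilies(tree, {})
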