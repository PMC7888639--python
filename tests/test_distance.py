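"""Allele-sharing and Nei distances; neighbor-joining reconstruction."""
import numpy as np
import pytest

from durumdiv.distance import (
    DistanceMatrix,
    allele_sharing_dissimilarity,
    nei_distance,
    nei_distance_matrix,
    nj_tree,
    tree_path_lengths,
)
from durumdiv.diversity import PopAlleleFreqs
from durumdiv.io import MISSING

from conftest import make_matrix


class TestAlleleSharing:
    def test_identical_accessions_zero(self):
        m = make_matrix([[0, 1, 2], [0, 1, 2]])
        d = allele_sharing_dissimilarity(m)
        assert d.values[0, 1] == 0.0

    def test_opposite_homozygotes_one(self):
        m = make_matrix([[0, 0, 0], [2, 2, 2]])
        assert allele_sharing_dissimilarity(m).values[0, 1] == 1.0

    def test_het_vs_hom_half(self):
        m = make_matrix([[0], [1]])
        assert allele_sharing_dissimilarity(m).values[0, 1] == 0.5

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        calls = rng.integers(0, 3, (6, 20)).astype(np.int8)
        d = allele_sharing_dissimilarity(make_matrix(calls))
        perm = rng.permutation(20)
        d_perm = allele_sharing_dissimilarity(make_matrix(calls[:, perm]))
        assert np.allclose(d.values, d_perm.values)

    def test_missing_overlap_error(self):
        m = make_matrix([[0, MISSING], [MISSING, 2]])
        with pytest.raises(ValueError, match="no loci"):
            allele_sharing_dissimilarity(m)

    def test_missing_pairs_use_shared_loci_only(self):
        m = make_matrix([[0, 0, MISSING], [2, MISSING, 2], [0, 0, 0]])
        d = allele_sharing_dissimilarity(m)
        assert d.values[0, 1] == 1.0  # only locus 1 shared: 0 vs 2


class TestNeiDistance:
    def test_identical_frequencies_zero(self):
        p = np.array([0.2, 0.7, 0.5])
        assert nei_distance(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_infinite(self):
        with pytest.warns(UserWarning, match="no alleles"):
            assert nei_distance(np.array([1.0, 1.0]), np.array([0.0, 0.0])) == np.inf

    def test_single_locus_half_half(self):
        assert nei_distance(np.array([0.5]), np.array([0.5])) == pytest.approx(0.0)

    def test_nonnegative_random(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x, y = rng.random(30), rng.random(30)
            assert nei_distance(x, y) >= -1e-12

    def test_matrix_symmetry(self):
        f = {
            1: PopAlleleFreqs("1", np.array([0.1, 0.9]), np.array([10, 10])),
            2: PopAlleleFreqs("2", np.array([0.8, 0.2]), np.array([10, 10])),
            3: PopAlleleFreqs("3", np.array([0.5, 0.5]), np.array([10, 10])),
        }
        dm = nei_distance_matrix(f)
        assert dm.n == 3
        assert np.allclose(dm.values, dm.values.T)


def additive_four_taxon():
    # tree ((A:1,B:2):1,(C:3,D:4)): AB=3 AC=5 AD=6 BC=6 BD=7 CD=7
    labels = ["A", "B", "C", "D"]
    vals = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    return DistanceMatrix(labels=labels, values=vals)


class TestNeighborJoining:
    def test_four_taxon_additive_reconstruction(self):
        d = additive_four_taxon()
        tree = nj_tree(d)
        paths = tree_path_lengths(tree)
        assert paths.labels == ["A", "B", "C", "D"]
        assert np.allclose(paths.values, d.values, atol=1e-9)
        # topology AB|CD: A and B are sisters
        taxa = {t.label: t for t in tree.taxon_namespace}
        leaf_a = tree.find_node_with_taxon_label("A")
        siblings = [
            c.taxon.label for c in leaf_a.parent_node.child_nodes() if c.taxon
        ]
        assert set(siblings) == {"A", "B"}

    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            labels=["A", "B", "C"],
            values=np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float),
        )
        paths = tree_path_lengths(nj_tree(d))
        assert np.allclose(paths.values, d.values, atol=1e-9)

    def test_random_additive_matrices_reconstructed(self):
        # random caterpillar trees with random branch lengths are additive
        rng = np.random.default_rng(7)
        for trial in range(5):
            n = int(rng.integers(4, 8))
            lengths = rng.uniform(0.5, 3.0, size=2 * n - 3)
            d = _caterpillar_distances(n, lengths)
            paths = tree_path_lengths(nj_tree(d))
            assert np.allclose(paths.values, d.values, atol=1e-9)

    def test_matches_independent_nj_implementation(self):
        # same topology and path lengths as scikit-bio's NJ on a perturbed
        # (non-additive) matrix
        import skbio

        rng = np.random.default_rng(11)
        d = _caterpillar_distances(6, rng.uniform(0.5, 2.0, size=9))
        noisy = d.values + rng.uniform(0, 0.01, size=d.values.shape)
        noisy = 0.5 * (noisy + noisy.T)
        np.fill_diagonal(noisy, 0.0)
        dm = DistanceMatrix(labels=d.labels, values=noisy)
        mine = tree_path_lengths(nj_tree(dm))
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=d.labels))
        sk_vals = np.zeros_like(noisy)
        for a, la in enumerate(mine.labels):
            for b in range(a + 1, len(mine.labels)):
                sk_vals[a, b] = sk_vals[b, a] = sk_tree.find(la).distance(
                    sk_tree.find(mine.labels[b])
                )
        assert np.allclose(mine.values, sk_vals, atol=1e-6)

    def test_ultrametric_matches_upgma_grouping(self):
        d = DistanceMatrix(
            labels=["A", "B", "C", "D"],
            values=np.array(
                [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]], float
            ),
        )
        tree = nj_tree(d)
        leaf_a = tree.find_node_with_taxon_label("A")
        siblings = [c.taxon.label for c in leaf_a.parent_node.child_nodes() if c.taxon]
        assert set(siblings) == {"A", "B"}

    def test_newick_serialization(self):
        tree = nj_tree(additive_four_taxon())
        newick = tree.as_string(schema="newick")
        for lab in "ABCD":
            assert lab in newick

    def test_too_few_labels(self):
        d = DistanceMatrix(labels=["A", "B"], values=np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(d)


def _caterpillar_distances(n, lengths):
    """Additive distances from a caterpillar tree with given branch lengths.

    Leaves hang off a backbone: leaf i attaches at backbone node min(i, n-2).
    """
    labels = [f"t{i}" for i in range(n)]
    leaf_edge = lengths[:n]
    backbone = lengths[n:2 * n - 3]  # n-3 internal edges
    attach = [0] + list(range(n - 2)) + [n - 3]
    cum = np.concatenate([[0.0], np.cumsum(backbone)])
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            span = abs(cum[attach[i]] - cum[attach[j]])
            vals[i, j] = vals[j, i] = leaf_edge[i] + leaf_edge[j] + span
    return DistanceMatrix(labels=labels, values=vals)


class TestDistanceMatrixValidation:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, 1], [2, 0]], float))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(labels=["a", "b"], values=np.array([[0, -1], [-1, 0]], float))

    def test_tsv_round_trip(self, tmp_path):
        d = additive_four_taxon()
        path = tmp_path / "d.tsv"
        d.to_tsv(path)
        back = DistanceMatrix.from_tsv(path)
        assert back.labels == d.labels
        assert np.allclose(back.values, d.values)
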