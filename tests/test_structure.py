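import numpy as np
import pytest

from cloverpop.diversity import allele_frequencies, diversity_summary, FrequencyTable
from cloverpop.io_formats import MISSING, GenotypeMatrix, Locus, PopulationMap
from cloverpop.structure import (
    DistanceMatrix,
    _tn93_from_counts,
    nei_distance,
    neighbor_joining,
    pairwise_fst,
    pcoa,
    tamura_nei_distance,
)

from oracles import newick_bipartitions, random_additive_tree, tn93_oracle


def _matrix(dosage, loci=None):
    dosage = np.asarray(dosage, dtype=np.int8)
    loci = loci or [
        Locus(f"L{j}", f"g{j}", j + 1, "A", "C") for j in range(dosage.shape[1])
    ]
    return GenotypeMatrix([f"I{i}" for i in range(dosage.shape[0])], loci, dosage)


def _map(pop_of_ind):
    accs = sorted(set(pop_of_ind))
    return PopulationMap(
        {f"I{i}": f"P{p}" for i, p in enumerate(pop_of_ind)},
        {f"P{p}": "o" for p in accs},
        {f"P{p}": "W" for p in accs},
        {f"P{p}": "diploid" for p in accs},
    )


def _freq_table(freqs, n=50):
    freqs = np.asarray(freqs, dtype=float)
    return FrequencyTable(
        populations=[f"P{k}" for k in range(freqs.shape[0])],
        locus_ids=[f"L{j}" for j in range(freqs.shape[1])],
        freq=freqs,
        n_called=np.full(freqs.shape, n, dtype=int),
        het_fraction=2 * freqs * (1 - freqs),
    )


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self):
        d = nei_distance(_freq_table([[0.3, 0.7], [0.3, 0.7]]), "standard")
        assert d.matrix[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_worked_single_locus(self):
        # p_x = 1.0, p_y = 0.5 -> D = -ln(0.5/sqrt(0.5)) = 0.34657
        d = nei_distance(_freq_table([[1.0], [0.5]]), "standard")
        assert d.matrix[0, 1] == pytest.approx(np.log(2) / 2, abs=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        d = nei_distance(_freq_table(rng.uniform(0.05, 0.95, (4, 30))), "unbiased")
        np.testing.assert_allclose(d.matrix, d.matrix.T)
        assert np.diag(d.matrix).max() == 0.0

    def test_unbiased_removes_sample_size_inflation(self):
        # same true frequencies, finite sample: unbiased distance is smaller
        rng = np.random.default_rng(1)
        f = rng.uniform(0.2, 0.8, (2, 80))
        std = nei_distance(_freq_table(f, n=10), "standard").matrix[0, 1]
        unb = nei_distance(_freq_table(f, n=10), "unbiased").matrix[0, 1]
        assert unb < std


class TestPairwiseFst:
    def test_null_pair_fst_near_zero(self):
        rng = np.random.default_rng(2)
        dosage = rng.binomial(2, 0.4, size=(40, 60)).astype(np.int8)
        res = pairwise_fst(_matrix(dosage), _map([0] * 20 + [1] * 20),
                           n_permutations=99, seed=3)
        assert res.raw[0, 1] == pytest.approx(0.0, abs=0.03)
        assert res.p_values[0, 1] > 0.05

    def test_fixed_populations_give_fst_one_and_tiny_p(self):
        dosage = np.vstack([np.zeros((10, 40)), np.full((10, 40), 2)]).astype(np.int8)
        res = pairwise_fst(_matrix(dosage), _map([0] * 10 + [1] * 10),
                           n_permutations=99, seed=4)
        assert res.matrix[0, 1] == pytest.approx(1.0, abs=0.01)
        assert res.p_values[0, 1] == pytest.approx(1 / 100)

    def test_two_population_panel_matches_diversity_summary(self, small_sim):
        _, m, _, pm = small_sim
        two = [a for a in pm.accessions[:2]]
        inds = [i for i in m.individual_ids if pm.accession_of(i) in two]
        sub = m.subset_individuals(inds)
        res = pairwise_fst(sub, pm, n_permutations=5, seed=0)
        ds = diversity_summary(sub, pm)
        assert res.raw[0, 1] == pytest.approx(ds.overall["F_ST"], abs=1e-12)

    def test_diagonal_zero(self, small_sim):
        _, m, _, pm = small_sim
        res = pairwise_fst(m, pm, n_permutations=5, seed=0)
        assert np.diag(res.matrix).max() == 0.0


class TestNeighborJoining:
    def test_recovers_worked_additive_example(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> distances below
        ids = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(ids, d, "nei_unbiased"))
        bip = newick_bipartitions(tree.to_newick(), ids)
        assert bip == {frozenset({"A", "B"})}
        lengths = sorted(
            round(bl, 9) for _, bl in _walk_edges(tree.root) if bl > 0
        )
        assert lengths == [1.0, 1.0, 2.0, 3.0, 4.0]

    def test_three_leaves(self):
        d = np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d, "fst"))
        assert sorted(tree.leaf_names()) == ["A", "B", "C"]

    def test_equidistant_matrix_is_deterministic(self):
        d = np.ones((5, 5)) - np.eye(5)
        ids = list("ABCDE")
        t1 = neighbor_joining(DistanceMatrix(ids, d, "fst")).to_newick()
        t2 = neighbor_joining(DistanceMatrix(ids, d, "fst")).to_newick()
        assert t1 == t2

    def test_infinite_entries_rejected(self):
        d = np.array([[0, np.inf, 1], [np.inf, 0, 1], [1, 1, 0]])
        with pytest.raises(ValueError, match="pairwise deletion"):
            neighbor_joining(DistanceMatrix(list("ABC"), d, "fst"))

    @pytest.mark.parametrize("seed", range(8))
    def test_recovers_random_additive_topologies(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        d, labels, true_bip = random_additive_tree(n, rng)
        tree = neighbor_joining(DistanceMatrix(labels, d, "nei_unbiased"))
        assert newick_bipartitions(tree.to_newick(), labels) == true_bip

    def test_agrees_with_skbio_on_additive_matrix(self):
        import skbio

        rng = np.random.default_rng(99)
        d, labels, true_bip = random_additive_tree(8, rng)
        d = (d + d.T) / 2  # symmetrise float round-off from path summation
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        sk_bip = newick_bipartitions(str(sk_tree), labels)
        ours = neighbor_joining(DistanceMatrix(labels, d, "nei_unbiased"))
        assert newick_bipartitions(ours.to_newick(), labels) == sk_bip == true_bip


def _walk_edges(node):
    for child, bl in node.children:
        yield child, bl
        yield from _walk_edges(child)


class TestTamuraNei:
    def test_identical_sequences_zero(self):
        m = _matrix([[0, 0, 2], [0, 0, 2]])
        d = tamura_nei_distance(m, min_sites=1)
        assert d.matrix[0, 1] == 0.0

    def test_matches_independent_closed_form(self):
        # build two pseudo-sequences via homozygous dosages and compare with
        # an oracle evaluated directly on the spelled-out sequences
        rng = np.random.default_rng(7)
        n_loci = 120
        bases = ["A", "C", "G", "T"]
        loci = []
        for j in range(n_loci):
            ref, alt = rng.choice(4, size=2, replace=False)
            loci.append(Locus(f"L{j}", f"g{j}", j + 1, bases[ref], bases[alt]))
        dosage = rng.choice([0, 2], size=(2, n_loci), p=[0.9, 0.1]).astype(np.int8)
        m = _matrix(dosage, loci=loci)
        d = tamura_nei_distance(m, min_sites=1)
        seqs = []
        for i in range(2):
            seqs.append(
                "".join(
                    l.ref if dosage[i, j] == 0 else l.alt for j, l in enumerate(loci)
                )
            )
        assert d.matrix[0, 1] == pytest.approx(tn93_oracle(*seqs), abs=1e-9)

    def test_reduces_to_jukes_cantor_limit(self):
        # equal base composition, substitutions spread evenly over the six
        # unordered pairs -> TN93 equals -(3/4) ln(1 - 4D/3)
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        D = 0.12
        d = _tn93_from_counts(pi, D / 6, D / 6, 4 * D / 6)
        assert d == pytest.approx(-0.75 * np.log(1 - 4 * D / 3), abs=1e-9)

    def test_correction_never_below_raw_difference(self):
        pi = np.array([0.25, 0.25, 0.25, 0.25])
        for D in (0.05, 0.2, 0.4):
            d = _tn93_from_counts(pi, 0.0, 0.0, D)
            assert d >= D

    def test_few_sites_flagged_unreliable(self):
        m = _matrix([[0, MISSING], [0, 0]])
        d = tamura_nei_distance(m, min_sites=10)
        assert d.unreliable[0, 1]


class TestPcoa:
    def test_collinear_points_single_axis(self):
        d = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.warns(UserWarning):
            res = pcoa(DistanceMatrix(list("ABC"), d, "nei_unbiased"), n_axes=2)
        assert res.percent_variance[0] == pytest.approx(100.0)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(11)
        points = rng.normal(size=(15, 2))
        d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix([f"E{i}" for i in range(15)], d, "fst"), n_axes=2)
        # Procrustes: align up to rotation/reflection/translation
        from scipy.linalg import orthogonal_procrustes

        a = points - points.mean(axis=0)
        b = res.coordinates - res.coordinates.mean(axis=0)
        rot, _ = orthogonal_procrustes(b, a)
        residual = float(((b @ rot - a) ** 2).sum())
        assert residual < 1e-8

    def test_zero_matrix_gives_no_axes(self):
        d = np.zeros((4, 4))
        with pytest.warns(UserWarning):
            res = pcoa(DistanceMatrix(list("ABCD"), d, "fst"), n_axes=2)
        assert res.coordinates.shape[1] == 0

    def test_agrees_with_skbio(self):
        import skbio

        rng = np.random.default_rng(13)
        points = rng.normal(size=(10, 3))
        d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
        ours = pcoa(DistanceMatrix([str(i) for i in range(10)], d, "fst"), n_axes=3)
        theirs = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(d))
        np.testing.assert_allclose(
            ours.eigenvalues[:3], theirs.eigvals.values[:3], atol=1e-8
        )
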