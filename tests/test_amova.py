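import numpy as np
import pytest

from cloverpop.amova import amova, individual_distance_matrix, _fit_components
from cloverpop.io_formats import MISSING, GenotypeMatrix, Locus, PopulationMap
from cloverpop.simulate import SimulationConfig, make_population_map, simulate_populations

from oracles import amova_oracle


def _matrix(dosage):
    dosage = np.asarray(dosage, dtype=np.int8)
    loci = [Locus(f"L{j}", f"g{j}", j + 1, "A", "C") for j in range(dosage.shape[1])]
    return GenotypeMatrix([f"I{i}" for i in range(dosage.shape[0])], loci, dosage)


def _map(pop_of_ind, origin_of_pop=None):
    accs = sorted(set(pop_of_ind))
    return PopulationMap(
        {f"I{i}": f"P{p}" for i, p in enumerate(pop_of_ind)},
        {f"P{p}": (origin_of_pop or {}).get(p, f"O{p}") for p in accs},
        {f"P{p}": "W" for p in accs},
        {f"P{p}": "diploid" for p in accs},
    )


class TestHaplotypeDistances:
    def test_identical_homozygotes_have_zero_distance(self):
        hd = individual_distance_matrix(_matrix([[0, 2], [0, 2]]))
        assert hd.d2.max() == 0.0

    def test_opposite_homozygotes_distance_equals_locus_count(self):
        hd = individual_distance_matrix(_matrix([[0, 0, 0], [2, 2, 2]]))
        assert hd.d2[0, 2] == 3.0  # first hap of I0 vs first hap of I1

    def test_symmetric_zero_diagonal(self, small_sim):
        _, m, _, _ = small_sim
        hd = individual_distance_matrix(m)
        np.testing.assert_allclose(hd.d2, hd.d2.T)
        assert np.diag(hd.d2).max() == 0.0

    def test_missing_handled_pairwise(self):
        hd = individual_distance_matrix(_matrix([[0, MISSING], [2, 2]]))
        assert hd.d2[0, 2] == 1.0  # only the called locus counts

    def test_phase_invariance_of_components(self):
        # heterozygote phase is arbitrary; components must not depend on it
        rng = np.random.default_rng(2)
        dosage = rng.integers(0, 3, size=(12, 15))
        m = _matrix(dosage)
        pm = _map([0] * 6 + [1] * 6)
        res = amova(m, pm, n_permutations=5, seed=0)
        # flip phase by reversing locus order (phase fixed by locus order)
        m_flipped = _matrix(dosage[:, ::-1])
        res_flipped = amova(m_flipped, pm, n_permutations=5, seed=0)
        for key in res.indices:
            assert res.indices[key] == pytest.approx(res_flipped.indices[key], abs=1e-12)


class TestComponents:
    def test_identical_population_multisets_give_nonpositive_va(self):
        rng = np.random.default_rng(4)
        block = rng.integers(0, 3, size=(6, 8))
        m = _matrix(np.vstack([block, block]))
        pm = _map([0] * 6 + [1] * 6)
        res = amova(m, pm, n_permutations=99, seed=1)
        assert res.table["variance_component"].iloc[0] <= 1e-9
        assert res.percentage("Among accessions") <= 1e-7
        assert res.p_values["F_ST"] > 0.5

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_expected_mean_square_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dosage = rng.integers(0, 3, size=(12, 5))
        m = _matrix(dosage)
        pop_of_ind = [0] * 4 + [1] * 4 + [2] * 4
        pm = _map(pop_of_ind, origin_of_pop={0: "X", 1: "X", 2: "Y"})
        # oracle works on explicit haplotype coordinates
        hap = np.empty((24, 5))
        hap[0::2] = (dosage == 2).astype(float)
        hap[1::2] = (dosage >= 1).astype(float)

        # ungrouped design: groups=accessions, populations=individuals
        res = amova(m, pm, n_permutations=5, seed=0)
        oracle = amova_oracle(
            hap,
            pop_of_unit=list(np.repeat(np.arange(12), 2)),
            group_of_pop={i: pop_of_ind[i] for i in range(12)},
        )
        np.testing.assert_allclose(
            res.table["variance_component"].iloc[:3], oracle["components"], atol=1e-10
        )
        np.testing.assert_allclose(
            list(res.indices.values()), oracle["phi"], atol=1e-10
        )

        # grouped design: groups from the origin labels
        res_g = amova(m, pm, grouping="origin", n_permutations=5, seed=0)
        oracle_g = amova_oracle(
            hap,
            pop_of_unit=list(np.repeat(pop_of_ind, 2)),
            group_of_pop={0: 0, 1: 0, 2: 1},
        )
        np.testing.assert_allclose(
            res_g.table["variance_component"].iloc[:3], oracle_g["components"], atol=1e-10
        )

    def test_total_ss_identity_and_df(self, small_sim):
        _, m, _, pm = small_sim
        res = amova(m, pm, n_permutations=5, seed=0)
        hd = individual_distance_matrix(m)
        n_units = hd.d2.shape[0]
        assert res.table["df"].iloc[:3].sum() == n_units - 1
        assert res.table["sum_of_squares"].iloc[3] == pytest.approx(
            hd.d2.sum() / (2 * n_units)
        )
        assert res.table["percent_variation"].iloc[:3].sum() == pytest.approx(100.0)

    def test_negative_components_are_preserved(self):
        # excess heterozygosity forces a negative among-individual component
        dosage = np.ones((8, 10), dtype=np.int8)  # everyone heterozygous
        res = amova(_matrix(dosage), _map([0] * 4 + [1] * 4), n_permutations=5, seed=0)
        v_b = res.table.set_index("source").loc[
            "Among individuals within accessions", "variance_component"
        ]
        assert v_b < 0

    def test_strong_differentiation_is_significant(self):
        cfg = SimulationConfig(
            n_pops=4, n_individuals_per_pop=10, n_target_loci=80, n_denovo_loci=0,
            n_tetraploid_pops=0, monomorphic_fraction=0.0, error_rate=0.0,
            low_coverage_locus_fraction=0.0, target_differentiation=0.3, seed=21,
        )
        m, _ = simulate_populations(cfg)
        res = amova(m, make_population_map(cfg), n_permutations=999, seed=5)
        assert res.p_values["F_ST"] == pytest.approx(1 / 1000)

    def test_rejects_bad_inputs(self, small_sim):
        _, m, _, pm = small_sim
        with pytest.raises(ValueError):
            amova(m, pm, n_permutations=0, seed=0)
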