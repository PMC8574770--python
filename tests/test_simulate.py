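import numpy as np
import pytest

from cloverpop.calling import call_genotypes, classify_and_filter
from cloverpop.io_formats import MISSING
from cloverpop.simulate import (
    SimulationConfig,
    generate_cds_fixtures,
    simulate_populations,
    simulate_read_counts,
)
from cloverpop.diversity import diversity_summary
from cloverpop.simulate import make_population_map


def _cfg(**kw):
    base = dict(
        n_pops=3,
        n_individuals_per_pop=10,
        n_target_loci=50,
        n_denovo_loci=0,
        n_tetraploid_pops=0,
        monomorphic_fraction=0.0,
        low_coverage_locus_fraction=0.0,
        seed=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulatePopulations:
    def test_zero_differentiation_collapses_to_shared_frequencies(self):
        m, truth = simulate_populations(_cfg(target_differentiation=0.0))
        assert np.allclose(truth.pop_freqs, truth.pop_freqs[0])

    def test_deterministic_given_seed(self):
        a = simulate_populations(_cfg(seed=9))
        b = simulate_populations(_cfg(seed=9))
        np.testing.assert_array_equal(a[0].dosage, b[0].dosage)
        np.testing.assert_array_equal(a[1].pop_freqs, b[1].pop_freqs)

    def test_tetraploid_collapse_rule(self):
        cfg = _cfg(n_pops=2, n_tetraploid_pops=1)
        m, truth = simulate_populations(cfg)
        tetra = truth.ploidy_per_individual == 4
        collapsed = m.dosage[tetra]
        raw = truth.alt_counts[tetra]
        assert np.all(collapsed[raw == 0] == 0)
        assert np.all(collapsed[raw == 4] == 2)
        assert np.all(collapsed[(raw > 0) & (raw < 4)] == 1)

    def test_mixed_tetraploid_genotype_exceeds_diploid_het_probability(self):
        # enumeration over a frequency grid: the collapse rule must force
        # heterozygote excess, hence negative F_IS, for tetraploids
        p = np.linspace(0.02, 0.98, 49)
        p_mixed = 1 - p**4 - (1 - p) ** 4
        assert np.all(p_mixed > 2 * p * (1 - p))

    def test_tetraploid_population_negative_fis(self):
        cfg = _cfg(n_pops=4, n_individuals_per_pop=30, n_target_loci=200,
                   n_tetraploid_pops=4, seed=3)
        m, _ = simulate_populations(cfg)
        ds = diversity_summary(m, make_population_map(cfg))
        assert ds.overall["F_IS"] < -0.1

    def test_observed_heterozygosity_matches_closed_form(self):
        # diploid random mating at F=0: E[H_O] = mean over loci of 2p(1-p)
        cfg = _cfg(n_pops=1, n_individuals_per_pop=400, n_target_loci=300,
                   target_differentiation=0.0, seed=4)
        m, truth = simulate_populations(cfg)
        p = truth.pop_freqs[0]
        expected = float(np.mean(2 * p * (1 - p)))
        observed = float((m.dosage == 1).mean())
        assert observed == pytest.approx(expected, abs=0.01)


class TestSimulateReadCounts:
    def test_error_free_deep_coverage_reproduces_truth(self):
        cfg = _cfg(seed=5)
        m, truth = simulate_populations(cfg)
        counts = simulate_read_counts(m, truth, mean_coverage=500, error_rate=0.0,
                                      low_coverage_locus_fraction=0.0, seed=6)
        called, _ = classify_and_filter(call_genotypes(counts))
        sub = {l.locus_id: k for k, l in enumerate(m.loci)}
        cols = [sub[l.locus_id] for l in called.loci]
        got = called.dosage
        truth_d = m.dosage[:, cols]
        mask = got != MISSING
        assert mask.mean() > 0.99
        np.testing.assert_array_equal(got[mask], truth_d[mask])

    def test_spurious_allele_fraction_increases_with_error_rate(self):
        cfg = _cfg(n_target_loci=150, seed=7)
        m, truth = simulate_populations(cfg)
        fractions = []
        for err in (0.0, 0.005, 0.02):
            counts = simulate_read_counts(m, truth, mean_coverage=500, error_rate=err,
                                          low_coverage_locus_fraction=0.0, seed=8)
            _, summary = classify_and_filter(call_genotypes(counts))
            multi = summary.class_counts["triallelic"] + summary.class_counts["tetraallelic"]
            fractions.append(multi / summary.n_loci)
        assert fractions[0] == 0.0
        assert fractions[0] <= fractions[1] <= fractions[2]
        assert fractions[2] > 0

    def test_coverage_below_threshold_gives_all_missing(self):
        cfg = _cfg(seed=9)
        m, truth = simulate_populations(cfg)
        counts = simulate_read_counts(m, truth, mean_coverage=2.0, error_rate=0.0,
                                      low_coverage_locus_fraction=0.0, seed=10)
        raw = call_genotypes(counts, min_allele_count=8)
        assert (raw.allele_pair[:, :, 0] == -1).mean() > 0.99

    def test_byte_identical_given_seed(self):
        cfg = _cfg(seed=12)
        m, truth = simulate_populations(cfg)
        a = simulate_read_counts(m, truth, seed=13)
        b = simulate_read_counts(m, truth, seed=13)
        np.testing.assert_array_equal(a.counts, b.counts)


class TestCdsFixtures:
    def test_forced_labels(self):
        seqs, table = generate_cds_fixtures(60, seed=2)
        from cloverpop.effects import classify_variants

        res = classify_variants(seqs, table.drop(columns=["effect"]))
        assert (res["effect"] == table["effect"]).all()

    def test_class_counts_respected(self):
        _, table = generate_cds_fixtures(
            20, seed=3, class_counts={"missense": 12, "nonsense": 3, "same_sense": 5}
        )
        assert table["effect"].value_counts().to_dict() == {
            "missense": 12, "same_sense": 5, "nonsense": 3
        }

    def test_ref_matches_sequence(self):
        seqs, table = generate_cds_fixtures(25, seed=4)
        for row in table.itertuples(index=False):
            assert seqs[row.seq_id][row.pos] == row.ref
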