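import numpy as np
import pytest

from cloverpop.selection import (
    _island_replicates,
    calibrate_migration,
    fdist_scan,
    hwe_exact_test,
    hwe_scan,
    selection_report,
    simulate_neutral_island_dataset,
)

from oracles import hwe_enumeration_oracle


class TestHweExact:
    def test_two_homozygotes_worked_example(self):
        # conditional law over h in {0, 2}: P(2) = 2/3, P(0) = 1/3 -> p = 1/3
        res = hwe_exact_test(1, 0, 1)
        assert res.p_value == pytest.approx(1 / 3)
        assert res.direction == "deficit"

    def test_expectation_matched_counts_give_p_one(self):
        res = hwe_exact_test(1, 2, 1)  # h = 2 = 2*2/3 is the modal/expected value
        assert res.p_value == 1.0
        assert res.direction == "none"

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            hwe_exact_test(5, 0, 0)

    def test_direction_tracks_sign_of_het_excess(self):
        assert hwe_exact_test(0, 10, 0).direction == "excess"
        assert hwe_exact_test(5, 0, 5).direction == "deficit"

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(50):
            # at least one heterozygote and two individuals, both alleles present
            counts = [int(rng.integers(0, 5)), int(rng.integers(1, 5)), int(rng.integers(0, 5))]
            if sum(counts) < 2:
                counts[1] += 1
            exact = hwe_exact_test(*counts).p_value
            mc = hwe_exact_test(
                *counts, mode="monte_carlo", chain_steps=50_000,
                dememorization=5_000, seed=int(rng.integers(2**31)),
            ).p_value
            worst = max(worst, abs(mc - exact))
        # three Monte-Carlo standard errors for a short random walk over a
        # support of <= ~10 states (autocorrelation-inflated)
        assert worst < 0.03

    def test_scan_reports_monomorphic_as_undefined(self, small_sim):
        _, m, _, _ = small_sim
        m.dosage[:, 0] = 0
        table = hwe_scan(m)
        assert table["direction"].iloc[0] == "undefined"
        assert np.isnan(table["hwe_p"].iloc[0])


class TestIslandSampler:
    def test_matches_msprime_island_model(self):
        import msprime

        from cloverpop.selection import _pooled_locus_stats

        sizes, n_demes, big_m, n_loci = [4] * 4, 10, 10.0, 500
        ours = _island_replicates(sizes, n_demes, big_m, n_loci, seed=1)

        dem = msprime.Demography.island_model(
            [1.0] * n_demes, migration_rate=big_m / (4 * (n_demes - 1))
        )
        reps = msprime.sim_ancestry(
            samples={f"pop_{k}": n for k, n in enumerate(sizes)},
            demography=dem, ploidy=2, num_replicates=n_loci, random_seed=7,
        )
        rng = np.random.default_rng(7)
        pop_of_ind = np.repeat(np.arange(len(sizes)), sizes)
        ref = np.empty((n_loci, 2))
        for r, ts in enumerate(reps):
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lengths = np.array([tree.branch_length(u) for u in nodes])
            pick = nodes[int(rng.choice(len(nodes), p=lengths / lengths.sum()))]
            below = set(tree.samples(pick))
            alleles = np.fromiter(
                (1 if x in below else 0 for x in ts.samples()), dtype=np.int8
            )
            ref[r] = _pooled_locus_stats(
                alleles[0::2] + alleles[1::2], pop_of_ind, len(sizes)
            )
        # means agree within combined Monte-Carlo error
        for col, tol in ((0, 0.02), (1, 0.025)):
            se = np.hypot(ref[:, col].std(), ours[:, col].std()) / np.sqrt(n_loci)
            assert abs(ref[:, col].mean() - ours[:, col].mean()) < max(3 * se, tol)

    def test_migration_monotonically_reduces_differentiation(self):
        means = [
            np.nanmean(_island_replicates([8] * 6, 30, M, 300, seed=3)[:, 1])
            for M in (2.0, 20.0, 200.0)
        ]
        assert means[0] > means[1] > means[2]

    def test_calibration_hits_target(self):
        target = 0.08
        m = calibrate_migration(target, [8] * 6, 20, seed=5, n_calibration_loci=400)
        realized = np.nanmean(_island_replicates([8] * 6, 20, m, 1500, seed=6)[:, 1])
        assert realized == pytest.approx(target, abs=0.015)


@pytest.fixture(scope="module")
def neutral_scan():
    m, pm = simulate_neutral_island_dataset(
        [10] * 8, n_loci=150, n_demes=30, migration_rate=18.0, seed=9
    )
    return fdist_scan(
        m, pm, n_simulations=1500, n_demes=30, seed=10,
        bin_size=300, n_calibration_loci=300,
    )


class TestFdistScan:
    def test_upper_and_lower_tails_cover(self, neutral_scan):
        p_up = neutral_scan["fdist_p"].dropna()
        p_lo = neutral_scan["fdist_p_lower"].dropna()
        assert ((p_up + p_lo) >= 1.0 - 1e-9).all()

    def test_monotone_in_fst_at_fixed_heterozygosity(self, neutral_scan):
        df = neutral_scan.dropna(subset=["fdist_p"]).sort_values("H_S")
        rows = df.to_dict("records")
        for a, b in zip(rows, rows[1:]):
            if abs(a["H_S"] - b["H_S"]) < 0.005:
                lo, hi = (a, b) if a["F_ST"] <= b["F_ST"] else (b, a)
                assert hi["fdist_p"] <= lo["fdist_p"] + 0.02

    def test_spiked_locus_flagged_extreme(self):
        m, pm = simulate_neutral_island_dataset(
            [10] * 8, n_loci=120, n_demes=30, migration_rate=18.0, seed=11
        )
        # plant a locus fixed for alternative alleles in half the demes
        spike = np.zeros(m.n_individuals, dtype=np.int8)
        spike[: m.n_individuals // 2] = 2
        m.dosage[:, 0] = spike
        res = fdist_scan(
            m, pm, n_simulations=2500, n_demes=30, seed=12,
            bin_size=1000, n_calibration_loci=300,
        )
        assert res["fdist_p"].iloc[0] <= 0.001

    def test_too_few_loci_rejected(self):
        m, pm = simulate_neutral_island_dataset(
            [6] * 4, n_loci=10, n_demes=20, migration_rate=10.0, seed=13
        )
        with pytest.raises(ValueError, match=">= 20"):
            fdist_scan(m, pm, n_simulations=100, n_demes=20, seed=14)


class TestSelectionReport:
    def _tables(self):
        import pandas as pd

        hwe = pd.DataFrame(
            {
                "locus_id": ["L1", "L2", "L3"],
                "hwe_p": [0.001, 0.5, 0.02],
                "direction": ["deficit", "none", "excess"],
                "observed_het": [1, 5, 9],
                "expected_het": [4.0, 5.0, 5.0],
            }
        )
        fdist = pd.DataFrame(
            {
                "locus_id": ["L1", "L2", "L3"],
                "H_S": [0.2, 0.3, 0.4],
                "F_ST": [0.3, 0.05, 0.01],
                "fdist_p": [0.01, 0.2, 0.9],
                "fdist_p_lower": [0.99, 0.8, 0.2],
            }
        )
        return hwe, fdist

    def test_flag_counts_are_set_identities(self):
        hwe, fdist = self._tables()
        rep = selection_report(hwe, fdist, alpha_hwe=0.01, alpha_fdist=0.05)
        counts = rep.attrs["counts"]
        assert counts["hwe_deviant"] == 1
        assert counts["under_selection"] == 1
        assert counts["both"] == 1
        assert counts["hwe_excess"] + counts["hwe_deficit"] == counts["hwe_deviant"]

    def test_permissive_thresholds_flag_everything(self):
        hwe, fdist = self._tables()
        rep = selection_report(hwe, fdist, alpha_hwe=1.1, alpha_fdist=1.1)
        assert rep["hwe_deviant"].all() and rep["under_selection"].all()

    def test_strict_thresholds_flag_nothing(self):
        hwe, fdist = self._tables()
        rep = selection_report(hwe, fdist, alpha_hwe=1e-9, alpha_fdist=1e-9)
        assert not rep["hwe_deviant"].any() and not rep["under_selection"].any()
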