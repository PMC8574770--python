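import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cloverpop.io_formats import NUCLEOTIDES, AlleleCountTable, PopulationMap
from cloverpop.simulate import SimulationConfig, make_population_map, simulate_populations


@pytest.fixture
def small_sim():
    """4 diploid populations, modest differentiation, error-free setting."""
    cfg = SimulationConfig(
        n_pops=4,
        n_individuals_per_pop=8,
        n_target_loci=60,
        n_denovo_loci=20,
        n_tetraploid_pops=0,
        monomorphic_fraction=0.0,
        error_rate=0.0,
        low_coverage_locus_fraction=0.0,
        seed=11,
    )
    m, truth = simulate_populations(cfg)
    return cfg, m, truth, make_population_map(cfg)


def build_printed_counts_table(
    n_ind: int = 20,
    n_mono: int = 15,
    n_bi: int = 352,
    n_tri: int = 30,
    n_tetra: int = 3,
    n_bi_missing: int = 25,
    n_denovo: int = 296,
) -> AlleleCountTable:
    """Depth table engineered to reproduce given locus-class counts.

    Biallelic loci carry clean deep calls; ``n_bi_missing`` of them have
    exactly one uncalled individual (5% of 20), which puts them right on the
    missingness boundary. De-novo loci are clean biallelic rows flagged
    target=False.
    """
    n_target = n_mono + n_bi + n_tri + n_tetra
    n_loci = n_target + n_denovo
    counts = np.zeros((n_ind, n_loci, 4), dtype=np.int64)
    alleles: list[tuple[str, ...]] = []
    target = np.array([True] * n_target + [False] * n_denovo)
    locus_ids = [f"T{j:04d}" for j in range(n_target)] + [
        f"D{j:04d}" for j in range(n_denovo)
    ]

    def fill_biallelic(j: int, ref_ix: int, alt_ix: int, missing_ind: int | None):
        for i in range(n_ind):
            if i == missing_ind:
                continue  # zero depth -> missing call
            if i % 3 == 0:
                counts[i, j, ref_ix] = 250
            elif i % 3 == 1:
                counts[i, j, ref_ix] = 120
                counts[i, j, alt_ix] = 130
            else:
                counts[i, j, alt_ix] = 250
        alleles.append((NUCLEOTIDES[ref_ix], NUCLEOTIDES[alt_ix]))

    j = 0
    for _ in range(n_mono):
        counts[:, j, 0] = 400
        alleles.append(("A",))
        j += 1
    for k in range(n_bi):
        fill_biallelic(j, 0, 1, missing_ind=0 if k < n_bi_missing else None)
        j += 1
    for _ in range(n_tri):
        fill_biallelic(j, 0, 1, None)
        counts[1, j, 2] = 40  # third allele passes threshold in one individual
        alleles[-1] = ("A", "C", "G")
        j += 1
    for _ in range(n_tetra):
        fill_biallelic(j, 0, 1, None)
        counts[1, j, 2] = 40
        counts[2, j, 3] = 40
        alleles[-1] = ("A", "C", "G", "T")
        j += 1
    for _ in range(n_denovo):
        fill_biallelic(j, 2, 3, None)
        j += 1

    return AlleleCountTable(
        individual_ids=[f"I{i:02d}" for i in range(n_ind)],
        locus_ids=locus_ids,
        alleles_per_locus=alleles,
        counts=counts,
        target_flag=target,
    )


@pytest.fixture(scope="session")
def printed_counts_table() -> AlleleCountTable:
    return build_printed_counts_table()
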