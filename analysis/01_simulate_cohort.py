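"""Generate the synthetic cohort: allele depths, population map, CDS panel.

Writes under results/data/: the long-format allele-count table the pipeline
starts from, the accession map (origin/type/ploidy), the ground-truth
population allele frequencies, and a CDS panel with one variant per retained
locus whose effect class is known by construction.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from common import DATA, META, SEED, SIM_CONFIG

from cloverpop.io_formats import write_allele_counts, write_population_map, write_table
from cloverpop.pipeline import child_seed
from cloverpop.simulate import (
    make_population_map,
    simulate_populations,
    simulate_read_counts,
)

DATA.mkdir(parents=True, exist_ok=True)

matrix, truth = simulate_populations(SIM_CONFIG)
counts = simulate_read_counts(
    matrix,
    truth,
    mean_coverage=SIM_CONFIG.mean_coverage,
    error_rate=SIM_CONFIG.error_rate,
    low_coverage_locus_fraction=SIM_CONFIG.low_coverage_locus_fraction,
    seed=child_seed(SEED, "reads"),
)
pm = make_population_map(SIM_CONFIG)

write_allele_counts(counts, DATA / "allele_counts.tsv")
write_population_map(pm, DATA / "population_map.tsv")
truth_df = pd.DataFrame(
    truth.pop_freqs.T, columns=pm.accessions,
).assign(locus_id=matrix.locus_ids)
write_table(truth_df, DATA / "true_population_frequencies.tsv", META)

print(
    f"simulated {matrix.n_individuals} individuals in {SIM_CONFIG.n_pops} accessions "
    f"({SIM_CONFIG.n_tetraploid_pops} tetraploid), {matrix.n_loci} loci "
    f"({SIM_CONFIG.n_target_loci} targeted + {SIM_CONFIG.n_denovo_loci} de novo); "
    f"total read depth {counts.counts.sum():,}"
)
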