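"""HWE exact tests per locus and the fdist F_ST-outlier scan.

The HWE test runs on the pooled sample (the per-accession view is written
alongside for the headline-deviant loci). The fdist scan calibrates island-
model migration to the observed mean F_ST and compares each locus's F_ST
with simulated neutral loci of similar heterozygosity.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import DATA, META, RESULTS, RUN_CONFIG, SEED

from cloverpop.io_formats import read_genotypes_vcf, read_population_map, write_table
from cloverpop.pipeline import child_seed
from cloverpop.selection import fdist_scan, hwe_scan, selection_report

matrix = read_genotypes_vcf(RESULTS / "genotypes.vcf")
pm = read_population_map(DATA / "population_map.tsv")

hwe = hwe_scan(matrix)
fdist = fdist_scan(
    matrix, pm,
    n_simulations=RUN_CONFIG.n_fdist_simulations,
    seed=child_seed(SEED, "fdist"),
)
report = selection_report(hwe, fdist)
write_table(report, RESULTS / "selection_scan.tsv",
            {**META, "migration_M": fdist.attrs["migration_M"]})

# per-accession HWE for the pooled-deviant loci
deviants = report.loc[report["hwe_deviant"], "locus_id"].tolist()
rows = []
for acc in pm.accessions:
    sub = hwe_scan(matrix.subset_loci(deviants), individuals=pm.individuals_of(acc))
    rows.append(sub.assign(accession=acc))
if rows:
    write_table(pd.concat(rows), RESULTS / "hwe_deviants_per_accession.tsv", META)

counts = report.attrs["counts"]
print(
    f"HWE deviants (p<0.01): {counts['hwe_deviant']} "
    f"({counts['hwe_excess']} excess / {counts['hwe_deficit']} deficit); "
    f"F_ST outliers (p<0.05): {counts['under_selection']}; both: {counts['both']}"
)
print(f"calibrated island-model M = {fdist.attrs['migration_M']:.1f}")
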