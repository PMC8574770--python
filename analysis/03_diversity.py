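"""Per-accession and overall diversity, grouped summaries, zygosity table.

Produces the per-accession table (%PL, H_S, H_O, F_IS), the overall
F-statistics, box-plot-style group summaries by origin/type/ploidy, and a
zygosity table for the ten most heterozygous loci.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import DATA, META, RESULTS

from cloverpop.diversity import diversity_summary, group_summary, zygosity_table
from cloverpop.io_formats import read_genotypes_vcf, read_population_map, write_table

matrix = read_genotypes_vcf(RESULTS / "genotypes.vcf")
pm = read_population_map(DATA / "population_map.tsv")

ds = diversity_summary(matrix, pm)
write_table(ds.per_accession, RESULTS / "diversity_per_accession.tsv", META)
write_table(pd.DataFrame([ds.overall]), RESULTS / "diversity_overall.tsv", META)
for grouping in ("origin", "type", "ploidy"):
    write_table(group_summary(matrix, pm, grouping),
                RESULTS / f"diversity_by_{grouping}.tsv", META)

top_het = ds.per_locus["H_O"].nlargest(10).index.tolist()
write_table(zygosity_table(matrix, pm, top_het), RESULTS / "zygosity_top_loci.tsv", META)

o = ds.overall
print(
    f"overall H_O={o['H_O']:.2f} H_S={o['H_S']:.2f} H_T={o['H_T']:.2f} "
    f"F_ST={o['F_ST']:.3f} F_IS={o['F_IS']:.3f}"
)
by_ploidy = ds.per_accession.assign(
    ploidy=[pm.accession_ploidy[a] for a in ds.per_accession["accession"]]
).groupby("ploidy")["F_IS"].mean()
print("mean F_IS by ploidy:", by_ploidy.round(3).to_dict())
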