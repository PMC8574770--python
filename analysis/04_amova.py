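"""Hierarchical AMOVA: ungrouped, and grouped by origin, type and ploidy.

Each design partitions squared haplotype distances across its strata and
attaches permutation p-values (1000 permutations).
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, META, RESULTS, RUN_CONFIG, SEED

from cloverpop.amova import amova
from cloverpop.io_formats import read_genotypes_vcf, read_population_map, write_table
from cloverpop.pipeline import child_seed

matrix = read_genotypes_vcf(RESULTS / "genotypes.vcf")
pm = read_population_map(DATA / "population_map.tsv")

for name, grouping in [("ungrouped", None), ("origin", "origin"),
                       ("type", "type"), ("ploidy", "ploidy")]:
    res = amova(
        matrix, pm, grouping=grouping,
        n_permutations=RUN_CONFIG.n_permutations,
        seed=child_seed(SEED, f"amova:{name}"),
    )
    meta = {**META, "indices": res.indices, "p_values": res.p_values}
    write_table(res.table, RESULTS / f"amova_{name}.tsv", meta)
    first = res.table.iloc[0]
    index_name = next(iter(res.indices))
    print(
        f"{name:>9}: {first['source']} = {first['percent_variation']:.2f}% "
        f"({index_name}={res.indices[index_name]:.3f}, "
        f"p={res.p_values[index_name]:.4f})"
    )
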