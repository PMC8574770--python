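"""Distances, pairwise F_ST, neighbor-joining trees and PCoA.

Accession-level: Nei standard/unbiased distances, pairwise F_ST with
permutation significance, NJ tree on the unbiased matrix, PCoA. Individual
level: TN93 distances on SNP pseudo-sequences and the corresponding NJ tree.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import numpy as np
import pandas as pd
from common import DATA, META, RESULTS, RUN_CONFIG, SEED

from cloverpop.diversity import allele_frequencies
from cloverpop.io_formats import read_genotypes_vcf, read_population_map, write_table
from cloverpop.pipeline import child_seed
from cloverpop.structure import (
    mean_pairwise_fst,
    nei_distance,
    neighbor_joining,
    pairwise_fst,
    pcoa,
    tamura_nei_distance,
)

matrix = read_genotypes_vcf(RESULTS / "genotypes.vcf")
pm = read_population_map(DATA / "population_map.tsv")
ft = allele_frequencies(matrix, pm)

nei_std = nei_distance(ft, "standard")
nei_unb = nei_distance(ft, "unbiased")
for name, dm in [("nei_standard", nei_std), ("nei_unbiased", nei_unb)]:
    write_table(dm.to_frame().reset_index(names="population"),
                RESULTS / f"distance_{name}.tsv", META)
off = nei_std.matrix[~np.eye(len(nei_std.ids), dtype=bool)]
print(f"Nei standard distance range {off.min():.3f}..{off.max():.3f}")

fst = pairwise_fst(matrix, pm, n_permutations=RUN_CONFIG.n_pairwise_permutations,
                   seed=child_seed(SEED, "pairwise_fst"))
write_table(fst.to_frame().reset_index(names="population"),
            RESULTS / "distance_fst.tsv", META)
write_table(pd.DataFrame(fst.p_values, index=fst.ids, columns=fst.ids)
            .reset_index(names="population"), RESULTS / "pairwise_fst_pvalues.tsv", META)
write_table(mean_pairwise_fst(fst), RESULTS / "mean_pairwise_fst.tsv", META)

tree = neighbor_joining(nei_unb)
(RESULTS / "tree_accessions_nei_unbiased.nwk").write_text(tree.to_newick() + "\n")
tn = tamura_nei_distance(matrix)
if np.isfinite(tn.matrix).all():
    (RESULTS / "tree_individuals_tn93.nwk").write_text(
        neighbor_joining(tn).to_newick() + "\n"
    )
    print(f"TN93 individual tree over {len(tn.ids)} individuals written")
else:
    print("TN93 matrix has saturated pairs; individual tree skipped")

res = pcoa(nei_unb, n_axes=2)
coords = pd.DataFrame(res.coordinates, columns=["axis1", "axis2"])
coords.insert(0, "accession", res.ids)
write_table(coords, RESULTS / "pcoa_coordinates.tsv", META)
print(
    f"PCoA: axis1 {res.percent_variance[0]:.1f}%, axis2 {res.percent_variance[1]:.1f}% "
    "of positive variance"
)
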