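"""Call genotypes from allele depths, classify loci, filter to the final set.

Applies the >= 8-read allele threshold, drops mono/tri/tetra-allelic loci and
biallelic loci with >= 5% missing calls, and writes the analysis-ready VCF
plus the locus-class summary.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import DATA, META, RESULTS, RUN_CONFIG

from cloverpop.calling import call_genotypes, classify_and_filter
from cloverpop.io_formats import read_allele_counts, write_genotypes_vcf, write_table

counts = read_allele_counts(DATA / "allele_counts.tsv")
raw = call_genotypes(counts, RUN_CONFIG.min_allele_count)
matrix, summary = classify_and_filter(raw, RUN_CONFIG.max_missing_fraction)

write_genotypes_vcf(matrix, RESULTS / "genotypes.vcf")
write_table(summary.to_frame(), RESULTS / "locus_class_summary.tsv", META)

pct = summary.class_percentages
print(
    f"classes: mono {summary.class_counts['monomorphic']} ({pct['monomorphic']}%), "
    f"bi {summary.class_counts['biallelic']} ({pct['biallelic']}%), "
    f"tri {summary.class_counts['triallelic']} ({pct['triallelic']}%), "
    f"tetra {summary.class_counts['tetraallelic']} ({pct['tetraallelic']}%)"
)
print(
    f"removed {summary.n_removed_missing} biallelic loci with >= 5% missing; "
    f"final set {matrix.n_loci} = {summary.n_retained_target} target "
    f"+ {summary.n_retained_denovo} de novo"
)
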