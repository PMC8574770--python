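"""Genotype calling from allele read depths, locus classification and filtering.

The calling rule is depth-thresholded diploid calling: at each (individual,
locus) cell, alleles with read depth below the threshold (default 8) are
treated as absent — a guard against alleles produced by sequencing error.
Exactly one retained allele makes a homozygote, exactly two a heterozygote,
none a missing call, and three or more an ambiguous cell that is set missing
and counted. Loci are then classified by the number of distinct alleles
retained anywhere in the sample (monomorphic / bi- / tri- / tetra-allelic);
only biallelic loci with a missing fraction strictly below 5% survive into
the analysis-ready dosage matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import (
    MISSING,
    NUCLEOTIDES,
    AlleleCountTable,
    FormatError,
    GenotypeMatrix,
    Locus,
)

CLASS_NAMES = ("monomorphic", "biallelic", "triallelic", "tetraallelic")


@dataclass
class RawCalls:
    """Per-cell diploid calls before locus classification.

    ``allele_pair`` holds nucleotide indices (0..3 into A/C/G/T) of the two
    called allele copies, or (-1, -1) for a missing/ambiguous cell.
    ``retained`` marks which alleles passed the depth threshold per cell.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    allele_pair: np.ndarray  # (n_ind, n_loci, 2) int8
    retained: np.ndarray  # (n_ind, n_loci, 4) bool
    declared_ref: list[str]  # first listed allele per locus
    target_flag: np.ndarray
    n_ambiguous_cells: int

    def observed_alleles(self, j: int) -> list[int]:
        """Distinct allele indices retained at locus ``j`` across individuals."""
        return sorted(np.nonzero(self.retained[:, j].any(axis=0))[0])


def call_genotypes(counts: AlleleCountTable, min_allele_count: int = 8) -> RawCalls:
    """Apply the depth threshold and produce per-cell diploid calls."""
    if min_allele_count < 1:
        raise ValueError("min_allele_count must be >= 1")
    if counts.n_loci == 0 or counts.n_individuals == 0:
        raise FormatError("empty allele-count table")

    retained = counts.counts >= min_allele_count
    n_ind, n_loci = counts.n_individuals, counts.n_loci
    n_retained = retained.sum(axis=2)

    allele_pair = np.full((n_ind, n_loci, 2), -1, dtype=np.int8)
    # homozygote: the single retained allele twice
    hom = n_retained == 1
    if hom.any():
        single = np.argmax(retained, axis=2)
        allele_pair[hom, 0] = single[hom]
        allele_pair[hom, 1] = single[hom]
    # heterozygote: the two retained alleles in nucleotide order
    het = n_retained == 2
    if het.any():
        order = np.argsort(~retained, axis=2, kind="stable")  # retained first
        allele_pair[het, 0] = order[het][:, 0]
        allele_pair[het, 1] = order[het][:, 1]
    n_ambiguous = int((n_retained >= 3).sum())

    return RawCalls(
        individual_ids=list(counts.individual_ids),
        locus_ids=list(counts.locus_ids),
        allele_pair=allele_pair,
        retained=retained,
        declared_ref=[alleles[0] for alleles in counts.alleles_per_locus],
        target_flag=counts.target_flag.copy(),
        n_ambiguous_cells=n_ambiguous,
    )


def _round_pct(x: float) -> float:
    """One-decimal rounding, the convention of printed class percentages."""
    return round(x, 1)


@dataclass
class LocusClassSummary:
    """Counts of loci by allele-number class and the effect of filtering."""

    class_counts: dict[str, int]
    n_removed_missing: int
    n_retained_target: int
    n_retained_denovo: int
    n_ambiguous_cells: int = 0

    @property
    def n_loci(self) -> int:
        return sum(self.class_counts.values())

    @property
    def class_percentages(self) -> dict[str, float]:
        """Percent of loci per class, rounded as printed (one decimal)."""
        total = self.n_loci
        if total == 0:
            return {name: 0.0 for name in CLASS_NAMES}
        return {
            name: _round_pct(100.0 * self.class_counts[name] / total)
            for name in CLASS_NAMES
        }

    @property
    def n_retained(self) -> int:
        return self.n_retained_target + self.n_retained_denovo

    def to_frame(self) -> pd.DataFrame:
        pct = self.class_percentages
        return pd.DataFrame(
            {
                "class": list(CLASS_NAMES),
                "count": [self.class_counts[c] for c in CLASS_NAMES],
                "percent": [pct[c] for c in CLASS_NAMES],
            }
        )


def classify_and_filter(
    raw: RawCalls,
    max_missing_fraction: float = 0.05,
    locus_meta: Mapping[str, tuple[str, int]] | None = None,
) -> tuple[GenotypeMatrix, LocusClassSummary]:
    """Classify loci by allele number, keep clean biallelic loci, code dosage.

    Loci with three or more alleles observed across individuals are excluded
    (sequencing-error artefacts at a biallelic assay), as are monomorphic loci
    and biallelic loci whose missing fraction is >= ``max_missing_fraction``
    (a locus at exactly the threshold is removed: "strictly less" is retained).
    The declared reference allele keeps the ref role when it is one of the two
    observed alleles; otherwise the observed pair is taken in nucleotide order.
    """
    n_ind = len(raw.individual_ids)
    class_counts = {name: 0 for name in CLASS_NAMES}
    kept_loci: list[Locus] = []
    kept_cols: list[int] = []
    kept_alt_ix: list[int] = []
    kept_ref_ix: list[int] = []
    n_removed_missing = 0

    for j, lid in enumerate(raw.locus_ids):
        observed = raw.observed_alleles(j)
        n_alleles = len(observed)
        cls = CLASS_NAMES[min(max(n_alleles, 1), 4) - 1]
        class_counts[cls] += 1
        if n_alleles != 2:
            continue
        missing = (raw.allele_pair[:, j, 0] == -1).sum()
        if missing / n_ind >= max_missing_fraction:
            n_removed_missing += 1
            continue
        declared = NUCLEOTIDES.index(raw.declared_ref[j])
        if declared in observed:
            ref_ix = declared
            alt_ix = observed[0] if observed[1] == declared else observed[1]
        else:
            ref_ix, alt_ix = observed
        gene_id, position = (locus_meta or {}).get(lid, (lid, 1))
        kept_loci.append(
            Locus(
                locus_id=lid,
                gene_id=gene_id,
                position=position,
                ref=NUCLEOTIDES[ref_ix],
                alt=NUCLEOTIDES[alt_ix],
                target=bool(raw.target_flag[j]),
            )
        )
        kept_cols.append(j)
        kept_ref_ix.append(ref_ix)
        kept_alt_ix.append(alt_ix)

    if kept_cols:
        pair = raw.allele_pair[:, kept_cols, :]  # (n_ind, n_kept, 2)
        alt = np.asarray(kept_alt_ix, dtype=np.int8)
        dosage = (pair == alt[None, :, None]).sum(axis=2).astype(np.int8)
        dosage[pair[:, :, 0] == -1] = MISSING
    else:
        dosage = np.zeros((n_ind, 0), dtype=np.int8)

    matrix = GenotypeMatrix(list(raw.individual_ids), kept_loci, dosage)
    summary = LocusClassSummary(
        class_counts=class_counts,
        n_removed_missing=n_removed_missing,
        n_retained_target=sum(1 for l in kept_loci if l.target),
        n_retained_denovo=sum(1 for l in kept_loci if not l.target),
        n_ambiguous_cells=raw.n_ambiguous_cells,
    )
    return matrix, summary


def matrix_to_raw_calls(m: GenotypeMatrix) -> RawCalls:
    """Re-express a dosage matrix as raw calls (for re-filtering checks)."""
    n_ind, n_loci = m.n_individuals, m.n_loci
    allele_pair = np.full((n_ind, n_loci, 2), -1, dtype=np.int8)
    retained = np.zeros((n_ind, n_loci, 4), dtype=bool)
    ref_ix = np.array([NUCLEOTIDES.index(l.ref) for l in m.loci], dtype=np.int8)
    alt_ix = np.array([NUCLEOTIDES.index(l.alt) for l in m.loci], dtype=np.int8)
    for value, pair in ((0, (ref_ix, ref_ix)), (1, (ref_ix, alt_ix)), (2, (alt_ix, alt_ix))):
        mask = m.dosage == value
        allele_pair[mask, 0] = np.broadcast_to(pair[0], mask.shape)[mask]
        allele_pair[mask, 1] = np.broadcast_to(pair[1], mask.shape)[mask]
        ii, jj = np.nonzero(mask)
        retained[ii, jj, np.broadcast_to(pair[0], mask.shape)[mask]] = True
        retained[ii, jj, np.broadcast_to(pair[1], mask.shape)[mask]] = True
    return RawCalls(
        individual_ids=list(m.individual_ids),
        locus_ids=m.locus_ids,
        allele_pair=allele_pair,
        retained=retained,
        declared_ref=[l.ref for l in m.loci],
        target_flag=np.array([l.target for l in m.loci], dtype=bool),
        n_ambiguous_cells=0,
    )
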