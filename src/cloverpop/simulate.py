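"""Synthetic study generator.

Emulates the statistical structure of a targeted SNP survey of an outcrossing
forage legume: 29 accessions of ~10 plants each, ~400 targeted biallelic loci
plus nearby de-novo loci, island-model differentiation around F_ST = 0.05,
random-mating diploids (F_IS ~ 0) alongside a few autotetraploid accessions
that are genotype-called as diploids (which forces strongly negative F_IS),
deep targeted coverage (~500x) with per-read sequencing error that produces
spurious tri-/tetra-allelic loci, and CDS contexts with variants of known
missense/nonsense/same-sense effect.

Population allele frequencies follow the Balding–Nichols model: for ancestral
frequency p and differentiation F, each population's frequency is drawn from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p(1-p). F is
therefore an explicit, recoverable simulation parameter.

All randomness flows from a single seed through ``numpy.random.SeedSequence``
children, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import (
    MISSING,
    NUCLEOTIDES,
    AlleleCountTable,
    GenotypeMatrix,
    Locus,
    PopulationMap,
)

_STOPS = ("TAA", "TAG", "TGA")
_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in _STOPS:
    _CODON_TO_AA[_stop] = "*"


@dataclass
class SimulationConfig:
    """Design of the synthetic study; defaults mirror the emulated survey."""

    n_pops: int = 29
    n_individuals_per_pop: int = 10
    n_target_loci: int = 400
    n_denovo_loci: int = 296
    #: island-model differentiation parameter (Balding–Nichols F), in [0, 1)
    target_differentiation: float = 0.05
    #: ancestral alt-allele frequency law: uniform on this interval
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    #: fraction of *target* loci fixed for the reference allele in the sample
    monomorphic_fraction: float = 0.0375
    #: number of tetraploid populations (placed last), genotyped as diploid
    n_tetraploid_pops: int = 4
    mean_coverage: float = 500.0
    #: per-read probability of substitution to a uniformly random other base
    error_rate: float = 0.009
    #: fraction of loci with severely reduced capture efficiency (coverage
    #: multiplier drawn uniform on [0, 0.04]), yielding missing-data-heavy loci
    low_coverage_locus_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.target_differentiation < 1:
            raise ValueError("target_differentiation must be in [0, 1)")
        if self.mean_coverage <= 0:
            raise ValueError("mean_coverage must be positive")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.n_tetraploid_pops > self.n_pops:
            raise ValueError("more tetraploid populations than populations")

    @property
    def n_loci(self) -> int:
        return self.n_target_loci + self.n_denovo_loci

    @property
    def n_individuals(self) -> int:
        return self.n_pops * self.n_individuals_per_pop

    def ploidy_per_pop(self) -> np.ndarray:
        ploidy = np.full(self.n_pops, 2, dtype=int)
        if self.n_tetraploid_pops:
            ploidy[-self.n_tetraploid_pops:] = 4
        return ploidy


@dataclass
class TruthRecord:
    """Ground truth retained next to the simulated data for validation."""

    pop_freqs: np.ndarray  # (n_pops, n_loci) true alt frequency per population
    alt_counts: np.ndarray  # (n_ind, n_loci) true alt copies, 0..ploidy
    ploidy_per_individual: np.ndarray  # (n_ind,)
    pop_of_individual: np.ndarray  # (n_ind,) population index
    monomorphic: np.ndarray  # (n_loci,) loci fixed for ref by design

    def alt_fraction(self) -> np.ndarray:
        return self.alt_counts / self.ploidy_per_individual[:, None]


def _rng_children(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def make_population_map(cfg: SimulationConfig) -> PopulationMap:
    """Accession metadata for the synthetic design.

    Accessions cycle through five origins; tetraploid accessions are labelled
    as synthetic breeding populations from a single breeder origin, mirroring
    the composition of the emulated panel.
    """
    origins = ("Denmark", "Finland", "Norway", "Sweden", "Russia")
    ploidy = cfg.ploidy_per_pop()
    ind_to_acc: dict[str, str] = {}
    acc_origin: dict[str, str] = {}
    acc_type: dict[str, str] = {}
    acc_ploidy: dict[str, str] = {}
    for p in range(cfg.n_pops):
        acc = f"ACC{p + 1:02d}"
        if ploidy[p] == 4:
            acc_origin[acc] = "Breeder"
            acc_type[acc] = "S"
            acc_ploidy[acc] = "tetraploid"
        else:
            acc_origin[acc] = origins[p % len(origins)]
            acc_type[acc] = ("C_N", "L", "W")[p % 3]
            acc_ploidy[acc] = "diploid"
        for i in range(cfg.n_individuals_per_pop):
            ind_to_acc[f"{acc}_I{i + 1:02d}"] = acc
    return PopulationMap(ind_to_acc, acc_origin, acc_type, acc_ploidy)


def simulate_populations(cfg: SimulationConfig) -> tuple[GenotypeMatrix, TruthRecord]:
    """Draw true genotypes under the Balding–Nichols island model.

    Diploid dosages are Binomial(2, p_pop) under random mating. Tetraploid
    genotypes are Binomial(4, p_pop) allele counts collapsed to diploid coding:
    4 ref copies -> 0, 4 alt copies -> 2, any mixed genotype -> 1. The collapse
    is the single point emulating diploid genotype calling of tetraploids and
    is what drives their negative F_IS.
    """
    rng_freq, rng_geno, rng_meta = _rng_children(cfg.seed, 3)
    F = cfg.target_differentiation
    lo, hi = cfg.ancestral_freq_range
    n_loci, n_pops = cfg.n_loci, cfg.n_pops

    n_mono = int(round(cfg.monomorphic_fraction * cfg.n_target_loci))
    monomorphic = np.zeros(n_loci, dtype=bool)
    if n_mono:
        monomorphic[rng_freq.choice(cfg.n_target_loci, size=n_mono, replace=False)] = True

    p_anc = rng_freq.uniform(lo, hi, size=n_loci)
    if F > 0:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        pop_freqs = rng_freq.beta(a[None, :], b[None, :], size=(n_pops, n_loci))
        # numerically degenerate draws are redrawn (logged via the mask count)
        bad = (pop_freqs <= 0) | (pop_freqs >= 1)
        while bad.any():
            pop_freqs[bad] = rng_freq.beta(
                np.broadcast_to(a, (n_pops, n_loci))[bad],
                np.broadcast_to(b, (n_pops, n_loci))[bad],
            )
            bad = (pop_freqs <= 0) | (pop_freqs >= 1)
    else:
        pop_freqs = np.broadcast_to(p_anc, (n_pops, n_loci)).copy()
    pop_freqs[:, monomorphic] = 0.0

    ploidy_pop = cfg.ploidy_per_pop()
    pop_of_ind = np.repeat(np.arange(n_pops), cfg.n_individuals_per_pop)
    ploidy_ind = ploidy_pop[pop_of_ind]
    p_ind = pop_freqs[pop_of_ind]  # (n_ind, n_loci)
    alt_counts = rng_geno.binomial(ploidy_ind[:, None], p_ind)

    dosage = np.where(
        ploidy_ind[:, None] == 2,
        alt_counts,
        np.select(
            [alt_counts == 0, alt_counts == ploidy_ind[:, None]], [0, 2], default=1
        ),
    ).astype(np.int8)

    loci = _make_loci(cfg, rng_meta)
    pm = make_population_map(cfg)
    individuals = list(pm.individual_to_accession)
    matrix = GenotypeMatrix(individuals, loci, dosage)
    truth = TruthRecord(pop_freqs, alt_counts, ploidy_ind, pop_of_ind, monomorphic)
    return matrix, truth


def _make_loci(cfg: SimulationConfig, rng: np.random.Generator) -> list[Locus]:
    """Locus metadata: de-novo loci sit within 75 bp of a target locus."""
    loci: list[Locus] = []
    base_pos = rng.integers(100, 400, size=cfg.n_target_loci)
    for j in range(cfg.n_target_loci):
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            Locus(
                locus_id=f"T{j + 1:04d}",
                gene_id=f"gene{j % max(cfg.n_target_loci // 2, 1)}",
                position=int(base_pos[j]),
                ref=NUCLEOTIDES[ref],
                alt=NUCLEOTIDES[alt],
                target=True,
            )
        )
    for k in range(cfg.n_denovo_loci):
        anchor = int(rng.integers(0, cfg.n_target_loci))
        offset = int(rng.integers(1, 76)) * (1 if rng.random() < 0.5 else -1)
        ref, alt = rng.choice(4, size=2, replace=False)
        loci.append(
            Locus(
                locus_id=f"D{k + 1:04d}",
                gene_id=loci[anchor].gene_id,
                position=max(1, loci[anchor].position + offset),
                ref=NUCLEOTIDES[ref],
                alt=NUCLEOTIDES[alt],
                target=False,
            )
        )
    # locus ids are unique by construction; positions may collide (harmless)
    return loci


def simulate_read_counts(
    matrix: GenotypeMatrix,
    truth: TruthRecord,
    mean_coverage: float = 500.0,
    error_rate: float = 0.01,
    low_coverage_locus_fraction: float = 0.05,
    seed: int = 0,
) -> AlleleCountTable:
    """Sample per-allele read depths from the true genotypes.

    Total depth per (individual, locus) is Poisson with a per-locus coverage
    multiplier (a small fraction of loci get a near-zero multiplier, emulating
    uneven capture efficiency). Each read is drawn from the individual's true
    allele proportions, then with probability ``error_rate`` substituted by a
    uniformly random *other* nucleotide — which is what creates spurious
    third/fourth alleles at deep coverage.
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    rng = np.random.default_rng(seed)
    n_ind, n_loci = matrix.n_individuals, matrix.n_loci

    multiplier = np.ones(n_loci)
    n_low = int(round(low_coverage_locus_fraction * n_loci))
    if n_low:
        low = rng.choice(n_loci, size=n_low, replace=False)
        multiplier[low] = rng.uniform(0.0, 0.04, size=n_low)

    depth = rng.poisson(mean_coverage * multiplier[None, :], size=(n_ind, n_loci))
    alt_frac = truth.alt_fraction()
    alt_reads = rng.binomial(depth, alt_frac)
    ref_reads = depth - alt_reads

    counts = np.zeros((n_ind, n_loci, 4), dtype=np.int64)
    nuc_ix = {n: k for k, n in enumerate(NUCLEOTIDES)}
    ref_col = np.array([nuc_ix[l.ref] for l in matrix.loci])
    alt_col = np.array([nuc_ix[l.alt] for l in matrix.loci])

    for source_reads, source_col in ((ref_reads, ref_col), (alt_reads, alt_col)):
        errors = rng.binomial(source_reads, error_rate)
        correct = source_reads - errors
        # scatter correct reads onto the source nucleotide column
        idx = np.broadcast_to(source_col, (n_ind, n_loci))
        np.add.at(counts, (np.arange(n_ind)[:, None], np.arange(n_loci)[None, :], idx), correct)
        # split errors uniformly over the three other nucleotides
        e1 = rng.binomial(errors, 1.0 / 3.0)
        e2 = rng.binomial(errors - e1, 0.5)
        e3 = errors - e1 - e2
        others = np.array([[k for k in range(4) if k != c] for c in range(4)])
        for slot, e in enumerate((e1, e2, e3)):
            target_col = others[source_col, slot]
            idx = np.broadcast_to(target_col, (n_ind, n_loci))
            np.add.at(
                counts, (np.arange(n_ind)[:, None], np.arange(n_loci)[None, :], idx), e
            )

    alleles_per_locus: list[tuple[str, ...]] = []
    for j, locus in enumerate(matrix.loci):
        observed = {NUCLEOTIDES[k] for k in np.nonzero(counts[:, j].sum(axis=0))[0]}
        ordered = [locus.ref, locus.alt] + sorted(observed - {locus.ref, locus.alt})
        alleles_per_locus.append(tuple(ordered))

    return AlleleCountTable(
        individual_ids=list(matrix.individual_ids),
        locus_ids=matrix.locus_ids,
        alleles_per_locus=alleles_per_locus,
        counts=counts,
        target_flag=np.array([l.target for l in matrix.loci], dtype=bool),
    )


# ---------------------------------------------------------------------------
# CDS fixtures with known variant effects
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + stop."""
    codons = [c for c in _CODON_TO_AA if c not in _STOPS and c != "ATG"]
    body = "".join(rng.choice(codons) for _ in range(n_codons))
    return "ATG" + body + str(rng.choice(_STOPS))


def _classify_substitution(codon: str, pos_in_codon: int, alt: str) -> str:
    new = codon[:pos_in_codon] + alt + codon[pos_in_codon + 1:]
    aa_ref, aa_new = _CODON_TO_AA[codon], _CODON_TO_AA[new]
    if aa_new == aa_ref:
        return "same_sense"
    if aa_new == "*":
        return "nonsense"
    if aa_ref == "*":
        return "missense"  # stop-loss; not generated by design
    return "missense"


def generate_cds_fixtures(
    n_variants: int,
    seed: int = 0,
    class_counts: Mapping[str, int] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Build CDS sequences with one variant each and a known effect label.

    Returns ``(sequences, table)`` where ``sequences`` maps sequence id to the
    nucleotide string and ``table`` has columns seq_id, pos (0-based offset of
    the SNP in the sequence), ref, alt, effect. Effects are assigned from the
    standard genetic code and are recoverable by the effect classifier.

    ``class_counts`` fixes how many variants of each effect class to produce;
    by default classes are drawn uniformly.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    if class_counts is not None and sum(class_counts.values()) != n_variants:
        raise ValueError("class_counts must sum to n_variants")
    rng = np.random.default_rng(seed)
    labels: list[str] = []
    if class_counts is None:
        classes = ("missense", "nonsense", "same_sense")
        labels = [classes[int(rng.integers(3))] for _ in range(n_variants)]
    else:
        for cls, k in class_counts.items():
            labels.extend([cls] * k)

    from .effects import longest_orf  # local import to avoid cycle at import time

    sequences: dict[str, str] = {}
    rows = []
    for v, wanted in enumerate(labels):
        while True:
            n_codons = int(rng.integers(20, 60))
            cds = _random_cds(rng, n_codons)
            # pyrimidine-only padding cannot introduce a competing start codon
            pad5 = "".join(rng.choice(["C", "T"], size=int(rng.integers(0, 13))))
            pad3 = "".join(rng.choice(["C", "T"], size=int(rng.integers(0, 13))))
            seq = pad5 + cds + pad3
            orf = longest_orf(seq)
            if orf is None or orf.start != len(pad5) or orf.end != len(pad5) + len(cds):
                continue  # padding interacted with the ORF scan; redraw
            placement = _place_variant(rng, cds, wanted)
            if placement is None:
                continue
            codon_ix, pos_in_codon, alt = placement
            pos = len(pad5) + 3 * codon_ix + pos_in_codon
            sequences[f"cds{v + 1:04d}"] = seq
            rows.append((f"cds{v + 1:04d}", pos, seq[pos], alt, wanted))
            break
    table = pd.DataFrame(rows, columns=["seq_id", "pos", "ref", "alt", "effect"])
    return sequences, table


def _place_variant(
    rng: np.random.Generator, cds: str, wanted: str
) -> tuple[int, int, str] | None:
    """Find a single-nucleotide substitution of the wanted effect class."""
    n_codons = len(cds) // 3
    for codon_ix in rng.permutation(np.arange(1, n_codons - 1)):
        codon = cds[3 * codon_ix: 3 * codon_ix + 3]
        options = []
        for pos_in_codon in range(3):
            for alt in NUCLEOTIDES:
                if alt == codon[pos_in_codon]:
                    continue
                if _classify_substitution(codon, pos_in_codon, alt) == wanted:
                    options.append((int(codon_ix), pos_in_codon, alt))
        if options:
            return options[int(rng.integers(len(options)))]
    return None


def write_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
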