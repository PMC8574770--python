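"""Domain containers and file I/O for the SNP analysis pipeline.

All other modules exchange data exclusively through the types defined here:

* :class:`AlleleCountTable` — per-individual, per-locus, per-allele read depths
  (the entry point of the pipeline; targeted assays report depths per declared
  allele rather than raw reads).
* :class:`GenotypeMatrix` — individuals x biallelic loci coded as alt-allele
  dosage {0, 1, 2} with a missing sentinel, plus per-locus metadata.
* :class:`PopulationMap` — individual -> accession and accession ->
  (origin, type, ploidy) hierarchy used by every grouped analysis.
* :class:`RunConfig` — thresholds, simulation/permutation sizes and the master
  seed, serialisable to YAML/JSON with a stable content hash.

External formats are deliberately boring: tab-separated text (UTF-8, lines
starting with ``#`` ignored) and standard VCF 4.2 via :mod:`pysam`.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

NUCLEOTIDES = ("A", "C", "G", "T")
#: sentinel for an uncalled genotype in dosage matrices
MISSING = -1
#: the six accession type codes admitted by the population map
ACCESSION_TYPES = frozenset({"B", "C_L", "C_N", "L", "S", "W"})
PLOIDY_CODES = frozenset({"diploid", "tetraploid", "unknown"})


class FormatError(ValueError):
    """Raised when an input file violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Read depth per (individual, locus, allele).

    ``counts`` is dense over the four nucleotides (columns ordered A, C, G, T);
    only alleles listed in ``alleles_per_locus`` may carry non-zero depth.
    The first listed allele of each locus is the reference allele.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    alleles_per_locus: list[tuple[str, ...]]
    counts: np.ndarray  # (n_individuals, n_loci, 4) int64
    target_flag: np.ndarray  # (n_loci,) bool

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.target_flag = np.asarray(self.target_flag, dtype=bool)
        n_ind, n_loc = len(self.individual_ids), len(self.locus_ids)
        if self.counts.shape != (n_ind, n_loc, 4):
            raise FormatError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{n_ind} individuals x {n_loc} loci x 4 nucleotides"
            )
        if len(self.alleles_per_locus) != n_loc or self.target_flag.shape != (n_loc,):
            raise FormatError("per-locus metadata length mismatch")
        if len(set(self.locus_ids)) != n_loc:
            raise FormatError("duplicate locus ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise FormatError("read counts must be integral")
        if (self.counts < 0).any():
            raise FormatError("negative read count")
        for lid, alleles in zip(self.locus_ids, self.alleles_per_locus):
            if len(alleles) < 1:
                raise FormatError(f"locus {lid} lists no alleles")
            if len(set(alleles)) != len(alleles):
                raise FormatError(f"locus {lid} lists a duplicate allele")
            if any(a not in NUCLEOTIDES for a in alleles):
                raise FormatError(f"locus {lid} has a non-ACGT allele")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)


@dataclass(frozen=True)
class Locus:
    """Metadata for one retained biallelic locus (VCF-style 1-based position)."""

    locus_id: str
    gene_id: str
    position: int
    ref: str
    alt: str
    target: bool = True


@dataclass
class GenotypeMatrix:
    """Alt-allele dosage in {0, 1, 2, MISSING} per (individual, locus)."""

    individual_ids: list[str]
    loci: list[Locus]
    dosage: np.ndarray  # (n_individuals, n_loci) int8

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individual_ids), len(self.loci)):
            raise FormatError("dosage shape inconsistent with ids/loci")
        valid = np.isin(self.dosage, (0, 1, 2, MISSING))
        if not valid.all():
            raise FormatError("dosage outside {0,1,2,MISSING}")
        ids = [l.locus_id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate locus ids")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.locus_id for l in self.loci]

    def called_mask(self) -> np.ndarray:
        return self.dosage != MISSING

    def subset_loci(self, locus_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {l.locus_id: j for j, l in enumerate(self.loci)}
        missing = [lid for lid in locus_ids if lid not in index]
        if missing:
            raise KeyError(f"unknown locus ids: {missing[:5]}")
        cols = [index[lid] for lid in locus_ids]
        return GenotypeMatrix(
            list(self.individual_ids),
            [self.loci[j] for j in cols],
            self.dosage[:, cols].copy(),
        )

    def subset_individuals(self, individual_ids: Sequence[str]) -> "GenotypeMatrix":
        index = {iid: i for i, iid in enumerate(self.individual_ids)}
        rows = [index[iid] for iid in individual_ids]
        return GenotypeMatrix(list(individual_ids), list(self.loci), self.dosage[rows].copy())


@dataclass
class PopulationMap:
    """Hierarchy individual -> accession -> (origin, type, ploidy)."""

    individual_to_accession: dict[str, str]
    accession_origin: dict[str, str]
    accession_type: dict[str, str]
    accession_ploidy: dict[str, str]

    def __post_init__(self) -> None:
        for acc, t in self.accession_type.items():
            if t not in ACCESSION_TYPES:
                raise FormatError(
                    f"accession {acc}: type {t!r} not in {sorted(ACCESSION_TYPES)}"
                )
        for acc, p in self.accession_ploidy.items():
            if p not in PLOIDY_CODES:
                raise FormatError(f"accession {acc}: ploidy {p!r} unknown")

    @property
    def accessions(self) -> list[str]:
        seen: dict[str, None] = {}
        for acc in self.individual_to_accession.values():
            seen.setdefault(acc, None)
        return list(seen)

    def accession_of(self, individual: str) -> str:
        return self.individual_to_accession[individual]

    def individuals_of(self, accession: str) -> list[str]:
        return [i for i, a in self.individual_to_accession.items() if a == accession]

    def check_covers(self, m: GenotypeMatrix) -> None:
        unmapped = [i for i in m.individual_ids if i not in self.individual_to_accession]
        if unmapped:
            raise FormatError(f"individuals not in population map: {unmapped[:5]}")

    def group_of(self, accession: str, grouping: str) -> str:
        if grouping == "origin":
            return self.accession_origin[accession]
        if grouping == "type":
            return self.accession_type[accession]
        if grouping == "ploidy":
            return self.accession_ploidy[accession]
        raise KeyError(f"unknown grouping {grouping!r}")


@dataclass
class RunConfig:
    """Run-level knobs shared by the analysis drivers.

    ``seed`` is the master seed; stages derive child seeds from it (see
    :func:`cloverpop.pipeline.child_seed`) so that any stage can be re-run in
    isolation and reproduce its part of a full run.
    """

    input_counts: str | None = None
    input_population_map: str | None = None
    min_allele_count: int = 8
    max_missing_fraction: float = 0.05
    n_permutations: int = 1000
    n_pairwise_permutations: int = 200
    n_fdist_simulations: int = 20_000
    hwe_chain_steps: int = 1_000_000
    hwe_dememorization: int = 100_000
    seed: int = 0
    groupings: tuple[str, ...] = ("origin", "type", "ploidy")

    def __post_init__(self) -> None:
        if self.min_allele_count < 1:
            raise FormatError("min_allele_count must be >= 1")
        if not 0 < self.max_missing_fraction <= 1:
            raise FormatError("max_missing_fraction must be in (0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "groupings" in raw:
            raw["groupings"] = tuple(raw["groupings"])
        return cls(**raw)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file without header") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    return df


def read_allele_counts(path: str | Path) -> AlleleCountTable:
    """Parse a long-format depth table (columns: individual, locus, allele,
    count, optional target) into an :class:`AlleleCountTable`.

    Row order is immaterial; duplicated (individual, locus, allele) rows and
    negative or non-integral counts are rejected with the offending line
    number (counting the header as line 1, comments included).
    """
    df = _read_tsv(path, ("individual", "locus", "allele", "count"))
    # recover 1-based file line numbers for error messages
    with open(path) as fh:
        data_lines = [
            i + 1
            for i, line in enumerate(fh)
            if line.strip() and not line.startswith("#")
        ]
    line_of_row = dict(enumerate(data_lines[1:]))  # skip header

    individuals: list[str] = list(dict.fromkeys(df["individual"]))
    loci: list[str] = list(dict.fromkeys(df["locus"]))
    ind_ix = {v: i for i, v in enumerate(individuals)}
    loc_ix = {v: j for j, v in enumerate(loci)}
    nuc_ix = {n: k for k, n in enumerate(NUCLEOTIDES)}

    counts = np.zeros((len(individuals), len(loci), 4), dtype=np.int64)
    seen: set[tuple[str, str, str]] = set()
    alleles: dict[str, list[str]] = {lid: [] for lid in loci}
    target: dict[str, bool] = {}
    has_target = "target" in df.columns

    for row_i, row in enumerate(df.itertuples(index=False)):
        line = line_of_row.get(row_i, "?")
        allele = row.allele
        if allele not in nuc_ix:
            raise FormatError(f"{path}:{line}: allele {allele!r} is not A/C/G/T")
        key = (row.individual, row.locus, allele)
        if key in seen:
            raise FormatError(f"{path}:{line}: duplicated row for {key}")
        seen.add(key)
        try:
            depth = int(row.count)
        except ValueError:
            raise FormatError(f"{path}:{line}: count {row.count!r} is not an integer") from None
        if depth < 0:
            raise FormatError(f"{path}:{line}: negative count {depth}")
        counts[ind_ix[row.individual], loc_ix[row.locus], nuc_ix[allele]] += depth
        if allele not in alleles[row.locus]:
            alleles[row.locus].append(allele)
        if has_target:
            flag = str(row.target).strip().lower() in ("1", "true", "yes")
            if row.locus in target and target[row.locus] != flag:
                raise FormatError(f"{path}:{line}: conflicting target flag for {row.locus}")
            target[row.locus] = flag

    return AlleleCountTable(
        individual_ids=individuals,
        locus_ids=loci,
        alleles_per_locus=[tuple(alleles[lid]) for lid in loci],
        counts=counts,
        target_flag=np.array([target.get(lid, True) for lid in loci], dtype=bool),
    )


def write_allele_counts(table: AlleleCountTable, path: str | Path) -> None:
    """Write the long-format depth table (only listed alleles are emitted)."""
    nuc_ix = {n: k for k, n in enumerate(NUCLEOTIDES)}
    rows = []
    for j, lid in enumerate(table.locus_ids):
        flag = int(table.target_flag[j])
        for allele in table.alleles_per_locus[j]:
            k = nuc_ix[allele]
            for i, iid in enumerate(table.individual_ids):
                rows.append((iid, lid, allele, int(table.counts[i, j, k]), flag))
    pd.DataFrame(rows, columns=["individual", "locus", "allele", "count", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_population_map(path: str | Path) -> PopulationMap:
    """Parse a TSV with columns individual, accession, origin, type, ploidy.

    A blank ploidy field is recorded as ``unknown`` (gene-bank passport data
    often omit it); a type code outside the six admitted codes is an error.
    """
    df = _read_tsv(path, ("individual", "accession", "origin", "type"))
    ind_to_acc: dict[str, str] = {}
    origin: dict[str, str] = {}
    typ: dict[str, str] = {}
    ploidy: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.individual in ind_to_acc:
            raise FormatError(f"{path}:{i}: individual {row.individual!r} listed twice")
        ind_to_acc[row.individual] = row.accession
        if row.type not in ACCESSION_TYPES:
            raise FormatError(
                f"{path}:{i}: type {row.type!r} not one of {sorted(ACCESSION_TYPES)}"
            )
        p = getattr(row, "ploidy", "").strip() if hasattr(row, "ploidy") else ""
        p = p or "unknown"
        if p not in PLOIDY_CODES:
            raise FormatError(f"{path}:{i}: ploidy {p!r} unknown")
        for store, value in ((origin, row.origin), (typ, row.type), (ploidy, p)):
            if row.accession in store and store[row.accession] != value:
                raise FormatError(
                    f"{path}:{i}: accession {row.accession!r} has conflicting metadata"
                )
            store[row.accession] = value
    return PopulationMap(ind_to_acc, origin, typ, ploidy)


def write_population_map(pm: PopulationMap, path: str | Path) -> None:
    rows = [
        (
            ind,
            acc,
            pm.accession_origin[acc],
            pm.accession_type[acc],
            pm.accession_ploidy[acc],
        )
        for ind, acc in pm.individual_to_accession.items()
    ]
    pd.DataFrame(
        rows, columns=["individual", "accession", "origin", "type", "ploidy"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF round trip
# ---------------------------------------------------------------------------

_GT_OF_DOSAGE = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}


def write_genotypes_vcf(m: GenotypeMatrix, path: str | Path) -> None:
    """Serialise a :class:`GenotypeMatrix` as uncompressed VCF 4.2.

    GT encodes dosage: 0/0, 0/1, 1/1 and ./. for missing. The gene id is used
    as the contig and the locus position is the 1-based position within it.
    """
    header = pysam.VariantHeader()
    header.add_line("##source=cloverpop")
    contigs: dict[str, int] = {}
    for locus in m.loci:
        contigs[locus.gene_id] = max(contigs.get(locus.gene_id, 0), locus.position)
    for name, length in contigs.items():
        header.contigs.add(name, length=length + 1000)
    header.formats.add("GT", 1, "String", "Genotype")
    header.info.add("TARGET", 0, "Flag", "Originally targeted locus (not de novo)")
    for iid in m.individual_ids:
        header.add_sample(iid)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, locus in enumerate(m.loci):
            rec = vcf.new_record(
                contig=locus.gene_id,
                start=locus.position - 1,
                alleles=(locus.ref, locus.alt),
                id=locus.locus_id,
            )
            if locus.target:
                rec.info["TARGET"] = True
            for i, iid in enumerate(m.individual_ids):
                rec.samples[iid]["GT"] = _GT_OF_DOSAGE[int(m.dosage[i, j])]
            vcf.write(rec)


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic VCF back into a :class:`GenotypeMatrix`.

    Records with zero or more than one ALT allele, or GT codes other than
    combinations of 0, 1 and missing, are rejected.
    """
    with pysam.VariantFile(str(path)) as vcf:
        individuals = list(vcf.header.samples)
        loci: list[Locus] = []
        rows: list[list[int]] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise FormatError(
                    f"{path}: record {rec.id or rec.pos} is not biallelic"
                )
            loci.append(
                Locus(
                    locus_id=rec.id or f"{rec.contig}_{rec.pos}",
                    gene_id=rec.contig,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    target=bool(rec.info.get("TARGET", False)),
                )
            )
            col = []
            for iid in individuals:
                gt = rec.samples[iid]["GT"]
                if gt is None or all(a is None for a in gt):
                    col.append(MISSING)
                    continue
                if any(a is None for a in gt) or any(a not in (0, 1) for a in gt):
                    raise FormatError(f"{path}: unsupported GT {gt} at {rec.id}")
                col.append(sum(gt))
            rows.append(col)
    dosage = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(individuals, loci, dosage)


def write_table(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, object] | None = None) -> None:
    """Write a result table as TSV with ``# key: value`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=False)
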