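"""Longest-ORF detection and missense/nonsense/same-sense classification.

Input sequences are CDS-oriented gene fragments, so only the three forward
reading frames are scanned (a six-frame search can be enabled where strand
orientation is unknown). Translation uses the standard genetic code (table
1, plant nuclear genes).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO

_STOP_CODONS = {"TAA", "TAG", "TGA"}
EFFECTS = ("missense", "nonsense", "same_sense", "noncoding")


@dataclass(frozen=True)
class Orf:
    """0-based, half-open ORF coordinates; length is a multiple of 3."""

    start: int
    end: int
    frame: int

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class CdsVariant:
    seq_id: str
    sequence: str
    pos: int  # 0-based offset within the sequence
    ref: str
    alt: str

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.sequence[self.pos] != self.ref:
            raise ValueError(
                f"{self.seq_id}: reference allele {self.ref!r} does not match "
                f"sequence base {self.sequence[self.pos]!r} at offset {self.pos}"
            )


def _frame_orfs(seq: str, frame: int) -> list[Orf]:
    orfs: list[Orf] = []
    start: int | None = None
    last_complete = frame + 3 * ((len(seq) - frame) // 3)
    for i in range(frame, last_complete, 3):
        codon = seq[i: i + 3]
        if start is None and codon == "ATG":
            start = i
        elif start is not None and codon in _STOP_CODONS:
            orfs.append(Orf(start, i + 3, frame))
            start = None
    if start is not None:
        # open ORF: runs to the last complete codon of the frame
        orfs.append(Orf(start, last_complete, frame))
    return orfs


def longest_orf(sequence: str, search_reverse: bool = False) -> Orf | None:
    """Longest ATG-initiated open reading frame (stop codon included).

    Ties are broken by smaller start position, then smaller frame index.
    Returns None when no frame contains an ATG (the variant is noncoding).
    ``search_reverse`` extends the scan to the reverse strand (coordinates
    still refer to the forward strand) for inputs of unknown orientation.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    candidates = [o for f in range(3) for o in _frame_orfs(seq, f)]
    if search_reverse:
        rc = str(Seq(seq).reverse_complement())
        n = len(seq)
        for f in range(3):
            for o in _frame_orfs(rc, f):
                candidates.append(Orf(n - o.end, n - o.start, f + 3))
    if not candidates:
        return None
    return min(candidates, key=lambda o: (-len(o), o.start, o.frame))


def _translate(seq: str) -> str:
    return str(Seq(seq).translate())


def classify_effect(v: CdsVariant) -> str:
    """Effect of the alternative allele on the longest-ORF protein.

    Translates the ORF with the reference and the alternative allele:
    identical proteins are same-sense, a stop introduced before the
    reference stop is nonsense, any other amino-acid change is missense,
    and a variant outside the longest ORF is noncoding.
    """
    orf = longest_orf(v.sequence)
    if orf is None or not (orf.start <= v.pos < orf.end):
        return "noncoding"
    region = v.sequence[orf.start: orf.end]
    offset = v.pos - orf.start
    alt_region = region[:offset] + v.alt + region[offset + 1:]
    p_ref = _translate(region)
    p_alt = _translate(alt_region)
    if p_alt == p_ref:
        return "same_sense"
    stop_ref = p_ref.find("*") if "*" in p_ref else len(p_ref)
    stop_alt = p_alt.find("*") if "*" in p_alt else len(p_alt)
    if stop_alt < stop_ref:
        return "nonsense"
    return "missense"


def classify_variants(
    sequences: Mapping[str, str], variants: pd.DataFrame
) -> pd.DataFrame:
    """Classify a variant table (columns seq_id, pos, ref, alt).

    Returns the table with an ``effect`` column appended; the percentage of
    each class is stored in ``attrs['percentages']`` (integer-rounded).
    """
    effects = []
    for row in variants.itertuples(index=False):
        v = CdsVariant(row.seq_id, sequences[row.seq_id], int(row.pos), row.ref, row.alt)
        effects.append(classify_effect(v))
    out = variants.copy()
    out["effect"] = effects
    n = len(out)
    out.attrs["percentages"] = {
        cls: int(round(100.0 * (out["effect"] == cls).sum() / n)) for cls in EFFECTS
    }
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
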