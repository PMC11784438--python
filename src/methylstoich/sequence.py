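"""Protein sequences, in-silico tryptic digestion, and peptide-to-protein mapping.

Coordinates are 1-based inclusive throughout, matching the residue-numbering
convention used for modification sites (e.g. "Lys616" is position 616).

The digestion rule is the classical trypsin rule: cleave C-terminal to K or R
unless the next residue is P.  Digestion is modification-blind: it operates on
the bare sequence, because site quantification happens downstream of the
identification search and never re-digests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ValidationError

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Letters accepted in a ProteinRecord; 'X' (unknown residue) is allowed in
#: sequences but never matched by peptide mapping.
ALLOWED_LETTERS = frozenset(AMINO_ACIDS + "X")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus amino-acid sequence.

    This is the coordinate frame for everything downstream: digest peptides,
    modification positions and stoichiometry rows are all reported against
    this sequence, 1-based inclusive.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("protein id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"protein {self.id!r}: sequence must be non-empty")
        seq = self.sequence.upper()
        bad = set(seq) - ALLOWED_LETTERS
        if bad:
            raise ValidationError(
                f"protein {self.id!r}: disallowed letters {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue letter at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise ValidationError(
                f"position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]

    def lysine_positions(self) -> list[int]:
        """All 1-based positions of K residues, ascending."""
        return [i + 1 for i, a in enumerate(self.sequence) if a == "K"]


@dataclass(frozen=True)
class DigestPeptide:
    """One peptide produced by in-silico digestion.

    ``start``/``end`` are 1-based inclusive positions in the parent protein;
    ``missed_cleavages`` counts internal uncut sites.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read all records from a FASTA file (description line preserved)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA."""
    seqrecords = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    SeqIO.write(seqrecords, str(path), "fasta")


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cleaves between sequence[i] and
    sequence[i+1]: sequence[i] in {K, R} and sequence[i+1] != 'P'.

    The C-terminus is not a cleavage *site* (it is a terminus); sites are
    strictly internal.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def _digest_between_boundaries(
    sequence: str, sites: Sequence[int], max_missed: int
) -> list[DigestPeptide]:
    # Boundaries are cut points in 0-based inter-residue coordinates:
    # 0 (before residue 1), each site i cuts after residue i+1, and len(seq).
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    peptides = []
    for j in range(len(bounds) - 1):
        for k in range(j + 1, len(bounds)):
            missed = k - j - 1
            if missed > max_missed:
                break
            lo, hi = bounds[j], bounds[k]
            peptides.append(
                DigestPeptide(
                    sequence=sequence[lo:hi],
                    start=lo + 1,
                    end=hi,
                    missed_cleavages=missed,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def tryptic_digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    *,
    min_length: int | None = None,
    max_length: int | None = None,
) -> list[DigestPeptide]:
    """Enumerate tryptic peptides with at most ``max_missed`` missed cleavages.

    Returns every peptide bounded by cleavage sites (after K/R except before P)
    or the sequence termini, sorted by (start, end).  Length filters default
    to off.
    """
    if max_missed < 0:
        raise ValidationError("max_missed must be >= 0")
    sites = cleavage_sites(protein.sequence)
    peptides = _digest_between_boundaries(protein.sequence, sites, max_missed)
    if min_length is not None:
        peptides = [p for p in peptides if len(p.sequence) >= min_length]
    if max_length is not None:
        peptides = [p for p in peptides if len(p.sequence) <= max_length]
    return peptides


def map_peptide_occurrences(peptide_seq: str, protein: ProteinRecord) -> list[int]:
    """All 1-based start positions where ``peptide_seq`` occurs exactly in the
    protein, ascending; overlapping occurrences are all reported.

    Protein positions holding 'X' never match anything (including a literal
    'X' in the query).  An empty result is a valid outcome, not an error.
    """
    if not peptide_seq:
        raise ValidationError("peptide_seq must be non-empty")
    seq = protein.sequence
    n, m = len(seq), len(peptide_seq)
    hits = []
    if "X" not in seq:
        start = 0
        while True:
            i = seq.find(peptide_seq, start)
            if i < 0:
                break
            hits.append(i + 1)
            start = i + 1
    else:
        for i in range(n - m + 1):
            window = seq[i : i + m]
            if "X" in window:
                continue
            if window == peptide_seq:
                hits.append(i + 1)
    return hits


def as_table_rows(peptides: Iterable[DigestPeptide]) -> list[dict]:
    """Digest peptides as plain dicts (for TSV emission)."""
    return [dataclasses.asdict(p) for p in peptides]
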