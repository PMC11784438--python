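"""Flanking-sequence motif analysis around methylated lysines.

Windows of ±``flank`` residues are extracted around each methylated K,
stacked into a position frequency matrix, and each column is scored by its
information content, IC = log2(20) − H(column), with H the Shannon entropy
of the observed letter frequencies (pad characters at sequence termini are
excluded from the denominator).  A column is "informative" when its IC
reaches a threshold (1 bit by default); the center column, which is K by
construction, is never counted as evidence of a consensus.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .sequence import AMINO_ACIDS, ProteinRecord
from .stoichiometry import ResidueStoichiometry

PAD = "-"
LOG2_20 = math.log2(20.0)


@dataclass(frozen=True)
class MotifWindow:
    """A fixed-width window centered on one residue (1-based position)."""

    center_position: int
    window: str

    @property
    def flank(self) -> int:
        return (len(self.window) - 1) // 2

    @property
    def center_letter(self) -> str:
        return self.window[self.flank]


def extract_windows(
    protein: ProteinRecord, positions: Sequence[int], flank: int = 10
) -> list[MotifWindow]:
    """One window of length 2·flank+1 per position; out-of-range flanks are
    padded with '-'."""
    if flank < 0:
        raise ValidationError("flank must be >= 0")
    n = len(protein.sequence)
    windows = []
    for pos in positions:
        if not 1 <= pos <= n:
            raise ValidationError(f"position {pos} outside 1..{n}")
        chars = []
        for p in range(pos - flank, pos + flank + 1):
            chars.append(protein.sequence[p - 1] if 1 <= p <= n else PAD)
        windows.append(MotifWindow(center_position=pos, window="".join(chars)))
    return windows


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-column letter counts over a stack of equal-length windows."""

    counts: tuple[dict[str, int], ...]
    n_windows: int
    flank: int

    def column_frequencies(self, col: int) -> dict[str, float]:
        column = self.counts[col]
        total = sum(column.values())
        if total == 0:
            return {}
        return {letter: c / total for letter, c in column.items()}

    def information_content(self) -> np.ndarray:
        """Per-column IC in bits: log2(20) minus the column's Shannon
        entropy.  Columns with no (non-pad) observations score 0."""
        ic = np.zeros(len(self.counts))
        for j in range(len(self.counts)):
            freqs = self.column_frequencies(j)
            if not freqs:
                continue
            entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
            ic[j] = LOG2_20 - entropy
        return ic

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame: rows = letters, columns = offsets
        −flank..+flank."""
        offsets = list(range(-self.flank, self.flank + 1))
        data = {
            off: [self.counts[j].get(a, 0) for a in AMINO_ACIDS]
            for j, off in enumerate(offsets)
        }
        return pd.DataFrame(data, index=list(AMINO_ACIDS))


def build_pfm(windows: Sequence[MotifWindow]) -> PositionFrequencyMatrix:
    """Stack windows into a position frequency matrix (pads ignored)."""
    if not windows:
        raise ValidationError("cannot build a PFM from zero windows")
    widths = {len(w.window) for w in windows}
    if len(widths) != 1:
        raise ValidationError(f"windows have mixed lengths {sorted(widths)}")
    width = widths.pop()
    counts: list[dict[str, int]] = []
    for j in range(width):
        col = Counter(w.window[j] for w in windows)
        col.pop(PAD, None)
        counts.append(dict(col))
    return PositionFrequencyMatrix(
        counts=tuple(counts), n_windows=len(windows), flank=(width - 1) // 2
    )


@dataclass(frozen=True)
class ConsensusVerdict:
    """Per-column informativeness flags and the overall consensus call."""

    ic: tuple[float, ...]
    column_flags: tuple[bool, ...]
    ic_threshold: float
    consensus: bool

    def to_dict(self) -> dict:
        return {
            "ic_bits": list(self.ic),
            "column_flags": list(self.column_flags),
            "ic_threshold": self.ic_threshold,
            "consensus": self.consensus,
        }


def consensus_verdict(
    pfm: PositionFrequencyMatrix, ic_threshold: float = 1.0
) -> ConsensusVerdict:
    """Flag columns with IC ≥ threshold; call a consensus when any non-center
    column is flagged.  The center column (conditioned to be K) is excluded
    from the overall call but still reported in the per-column flags."""
    ic = pfm.information_content()
    flags = ic >= ic_threshold
    center = pfm.flank
    non_center = [flags[j] for j in range(len(flags)) if j != center]
    return ConsensusVerdict(
        ic=tuple(float(x) for x in ic),
        column_flags=tuple(bool(f) for f in flags),
        ic_threshold=ic_threshold,
        consensus=any(non_center),
    )


def methylated_positions(
    table: Sequence[ResidueStoichiometry], min_percent: float = 0.0
) -> list[int]:
    """Positions whose methylated fraction qualifies for window extraction.

    Default selects any detected residue with positive methyl-state abundance
    (``min_percent=0``); raise ``min_percent`` to restrict to residues whose
    methylated percentage is at least that value.
    """
    out = []
    for r in table:
        if not r.detected or not r.methylated:
            continue
        pm = r.percent_methylated
        if pm is not None and pm >= min_percent and (pm > 0 or min_percent == 0):
            out.append(r.position)
    return out


def write_windows_fasta_like(windows: Sequence[MotifWindow], path) -> None:
    """Aligned windows as FASTA-like text, one record per center position."""
    with open(path, "w") as handle:
        for w in windows:
            handle.write(f">pos{w.center_position}\n{w.window}\n")


def write_pfm_tsv(pfm: PositionFrequencyMatrix, path) -> None:
    pfm.to_frame().to_csv(path, sep="\t", index_label="letter")
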