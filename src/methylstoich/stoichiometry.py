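"""Per-lysine methylation stoichiometry with repeat-aware apportionment.

The quantification rule, applied residue by residue:

1. Peptide species (sequence + modifications) with the same identity are
   aggregated by summing their peak-area abundances.
2. Modified species whose localization was not confident are excluded.
3. Each species is mapped to *every* exact occurrence of its sequence in the
   target protein; its abundance is divided equally among those occurrences
   (repetitive proteins make this multi-mapping routine, not exceptional).
4. For each lysine, the abundance of each methylation state
   (un/mono/di/tri) is the sum of the apportioned shares of all occurrences
   covering it whose modification implies that state; percentages divide by
   the residue's total abundance and multiply by 100.

A residue is "detected" when its total abundance is strictly positive (an
optional minimum-abundance threshold is available and defaults to 0);
percentages of undetected residues are undefined (``None``), never silently
zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .psm import PeptideObservation, filter_ambiguous
from .sequence import ProteinRecord, map_peptide_occurrences

#: The four mutually exclusive per-residue methylation states.
STATES = ("un", "mono", "di", "tri")


@dataclass(frozen=True)
class ResidueStoichiometry:
    """Abundance and percentage of one lysine over the four methyl states."""

    protein_id: str
    position: int
    residue_letter: str
    abundance_by_state: Mapping[str, float]
    detected: bool

    @property
    def total_abundance(self) -> float:
        return sum(self.abundance_by_state[s] for s in STATES)

    @property
    def percent_by_state(self) -> dict[str, float] | None:
        """State percentages summing to 100, or ``None`` if undetected."""
        total = self.total_abundance
        if not self.detected or total <= 0:
            return None
        return {s: 100.0 * self.abundance_by_state[s] / total for s in STATES}

    @property
    def methylated(self) -> bool:
        """Any methyl-state abundance strictly positive."""
        return any(self.abundance_by_state[s] > 0 for s in ("mono", "di", "tri"))

    @property
    def percent_methylated(self) -> float | None:
        pct = self.percent_by_state
        if pct is None:
            return None
        return 100.0 - pct["un"]


@dataclass(frozen=True)
class MethylationSummary:
    """Protein-level counts and the unweighted mean methylation percentage."""

    protein_id: str
    n_lysines_total: int
    n_detected: int
    n_methylated: int
    n_monomethylated: int
    n_dimethylated: int
    n_trimethylated: int
    mean_methylation_percent: float | None

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "n_lysines_total": self.n_lysines_total,
            "n_detected": self.n_detected,
            "n_methylated": self.n_methylated,
            "n_monomethylated": self.n_monomethylated,
            "n_dimethylated": self.n_dimethylated,
            "n_trimethylated": self.n_trimethylated,
            "mean_methylation_percent": self.mean_methylation_percent,
        }


@dataclass
class QuantifyDiagnostics:
    """Bookkeeping for peptides excluded or shared during quantification."""

    n_input_rows: int = 0
    n_species: int = 0
    n_ambiguous_excluded: int = 0
    n_unmapped: int = 0
    n_multi_mapping: int = 0
    unmapped_peptides: list[str] = field(default_factory=list)
    excluded_peptides: list[str] = field(default_factory=list)
    multi_mapping_peptides: list[str] = field(default_factory=list)

    def to_lines(self) -> list[str]:
        lines = [
            f"input rows: {self.n_input_rows}",
            f"aggregated peptide species: {self.n_species}",
            f"excluded (ambiguous localization): {self.n_ambiguous_excluded}",
            f"unmapped in target protein: {self.n_unmapped}",
            f"multi-mapping species: {self.n_multi_mapping}",
        ]
        lines += [f"excluded ambiguous: {p}" for p in self.excluded_peptides]
        lines += [f"unmapped: {p}" for p in self.unmapped_peptides]
        lines += [f"multi-mapping: {p}" for p in self.multi_mapping_peptides]
        return lines


def assign_state_at_position(
    obs: PeptideObservation, occurrence_start: int, position: int
) -> str | None:
    """Methylation state implied by ``obs`` (placed at ``occurrence_start``)
    for the protein position ``position``; ``None`` when the occurrence does
    not cover the position.  Non-methyl modifications imply state 'un'."""
    offset = position - occurrence_start + 1
    if offset < 1 or offset > len(obs.peptide_seq):
        return None
    return obs.methyl_state_at(offset)


def apportion_abundance(abundance: float, occurrences: Sequence[int]) -> list[float]:
    """Split an abundance equally among occurrence start positions.

    Shares sum exactly to the input (each is abundance / n).
    """
    if not occurrences:
        raise ValidationError("cannot apportion over zero occurrences")
    share = abundance / len(occurrences)
    return [share] * len(occurrences)


def aggregate_species(
    observations: Iterable[PeptideObservation],
) -> list[PeptideObservation]:
    """Merge rows with identical sequence+modifications by summing abundance.

    A species is confident only if every contributing row was confident.
    Output is sorted by (sequence, modification string) for determinism.
    """
    merged: dict[tuple, list] = {}
    for obs in observations:
        key = (obs.peptide_seq, obs.modifications)
        if key not in merged:
            merged[key] = [0.0, True]
        merged[key][0] += obs.abundance
        merged[key][1] = merged[key][1] and obs.localization_confident
    out = [
        PeptideObservation(
            peptide_seq=seq,
            modifications=mods,
            abundance=total,
            localization_confident=confident,
        )
        for (seq, mods), (total, confident) in merged.items()
    ]
    out.sort(key=lambda o: (o.peptide_seq, o.modification_string()))
    return out


def residue_stoichiometry(
    observations: Sequence[PeptideObservation],
    protein: ProteinRecord,
    *,
    min_abundance: float = 0.0,
    diagnostics: QuantifyDiagnostics | None = None,
) -> list[ResidueStoichiometry]:
    """Quantify every lysine of ``protein`` from peptide observations.

    Returns one row per K position (ascending).  ``observations`` are
    defensively re-filtered for ambiguous localization, aggregated into
    species, mapped, apportioned and accumulated as described in the module
    docstring.  Pass a :class:`QuantifyDiagnostics` to collect exclusion and
    multi-mapping counts.
    """
    diag = diagnostics if diagnostics is not None else QuantifyDiagnostics()
    diag.n_input_rows = len(observations)

    kept = filter_ambiguous(observations)
    for obs in observations:
        if obs.is_modified and not obs.localization_confident:
            diag.n_ambiguous_excluded += 1
            diag.excluded_peptides.append(
                f"{obs.peptide_seq} [{obs.modification_string()}]"
            )

    species = aggregate_species(kept)
    diag.n_species = len(species)

    k_positions = protein.lysine_positions()
    acc: dict[int, dict[str, float]] = {
        pos: {s: 0.0 for s in STATES} for pos in k_positions
    }
    k_set = set(k_positions)

    # occurrences depend on the sequence only; cache across species
    occurrence_cache: dict[str, list[int]] = {}
    for obs in species:
        occurrences = occurrence_cache.get(obs.peptide_seq)
        if occurrences is None:
            occurrences = map_peptide_occurrences(obs.peptide_seq, protein)
            occurrence_cache[obs.peptide_seq] = occurrences
            if len(occurrences) > 1:
                diag.n_multi_mapping += 1
                diag.multi_mapping_peptides.append(
                    f"{obs.peptide_seq} x{len(occurrences)}"
                )
        if not occurrences:
            diag.n_unmapped += 1
            diag.unmapped_peptides.append(obs.peptide_seq)
            continue
        shares = apportion_abundance(obs.abundance, occurrences)
        for start, share in zip(occurrences, shares):
            for offset in range(len(obs.peptide_seq)):
                pos = start + offset
                if pos in k_set:
                    state = obs.methyl_state_at(offset + 1)
                    acc[pos][state] += share

    table = [
        ResidueStoichiometry(
            protein_id=protein.id,
            position=pos,
            residue_letter="K",
            abundance_by_state=dict(acc[pos]),
            detected=sum(acc[pos].values()) > min_abundance,
        )
        for pos in k_positions
    ]
    return table


def methylation_summary(table: Sequence[ResidueStoichiometry]) -> MethylationSummary:
    """Protein-level counts and the unweighted mean methylation percentage.

    The mean is taken over detected residues of (100 − percent unmethylated);
    with zero detected residues it is undefined and reported as ``None``.
    """
    protein_ids = {r.protein_id for r in table}
    if len(protein_ids) > 1:
        raise ValidationError(f"table mixes proteins: {sorted(protein_ids)}")
    protein_id = protein_ids.pop() if protein_ids else ""
    detected = [r for r in table if r.detected]
    methyl_pcts = [r.percent_methylated for r in detected]
    mean = (
        sum(methyl_pcts) / len(methyl_pcts) if methyl_pcts else None
    )
    return MethylationSummary(
        protein_id=protein_id,
        n_lysines_total=len(table),
        n_detected=len(detected),
        n_methylated=sum(1 for r in detected if r.methylated),
        n_monomethylated=sum(
            1 for r in detected if r.abundance_by_state["mono"] > 0
        ),
        n_dimethylated=sum(1 for r in detected if r.abundance_by_state["di"] > 0),
        n_trimethylated=sum(1 for r in detected if r.abundance_by_state["tri"] > 0),
        mean_methylation_percent=mean,
    )


def stoichiometry_frame(table: Sequence[ResidueStoichiometry]) -> pd.DataFrame:
    """Wide per-lysine table (one row per K) as a DataFrame."""
    rows = []
    for r in table:
        pct = r.percent_by_state
        rows.append(
            {
                "protein_id": r.protein_id,
                "position": r.position,
                "residue": r.residue_letter,
                **{f"abundance_{s}": r.abundance_by_state[s] for s in STATES},
                **{
                    f"pct_{s}": (pct[s] if pct is not None else math.nan)
                    for s in STATES
                },
                "detected": r.detected,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "position",
            "residue",
            *[f"abundance_{s}" for s in STATES],
            *[f"pct_{s}" for s in STATES],
            "detected",
        ],
    )


def write_stoichiometry_tsv(
    table: Sequence[ResidueStoichiometry], path: str | Path
) -> None:
    frame = stoichiometry_frame(table)
    frame.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_stoichiometry_tsv(path: str | Path) -> list[ResidueStoichiometry]:
    frame = pd.read_csv(path, sep="\t", na_values=["NA"])
    table = []
    for _, row in frame.iterrows():
        table.append(
            ResidueStoichiometry(
                protein_id=str(row["protein_id"]),
                position=int(row["position"]),
                residue_letter=str(row["residue"]),
                abundance_by_state={s: float(row[f"abundance_{s}"]) for s in STATES},
                detected=bool(row["detected"]),
            )
        )
    return table


def write_summary_json(summary: MethylationSummary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
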