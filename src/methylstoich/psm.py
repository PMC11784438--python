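"""Peptide-level identification/quantification tables.

A row of such a table is one *peptide species*: a sequence, its modification
annotation, a label-free abundance (sum of chromatographic peak areas, in
arbitrary units) and a flag saying whether the modification localization was
confident.  Search engines export this in proprietary dialects, so reading is
driven by a declarative column mapping (:class:`TableDialect`); the package's
native dialect is tab-separated with a fixed header.

Modification annotations use the token form ``X<pos>(<Name>)`` separated by
semicolons, e.g. ``"K3(Monomethyl); K7(Dimethyl)"``; ``N-Term(Acetyl)`` maps
to within-peptide position 0.  Unknown modification names are carried with
kind ``other`` and treated as "no methylation" by the stoichiometry stage.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import TableFormatError, ValidationError


class ModKind(str, Enum):
    MONOMETHYL = "monomethyl"
    DIMETHYL = "dimethyl"
    TRIMETHYL = "trimethyl"
    ACETYL_NTERM = "acetyl-nterm"
    OXIDATION = "oxidation"
    OTHER = "other"


#: The three mutually exclusive methyl states a residue copy can carry.
METHYL_KINDS = frozenset(
    {ModKind.MONOMETHYL, ModKind.DIMETHYL, ModKind.TRIMETHYL}
)

_MOD_NAMES = {
    "monomethyl": ModKind.MONOMETHYL,
    "methyl": ModKind.MONOMETHYL,
    "dimethyl": ModKind.DIMETHYL,
    "trimethyl": ModKind.TRIMETHYL,
    "oxidation": ModKind.OXIDATION,
}

_CANONICAL_NAME = {
    ModKind.MONOMETHYL: "Monomethyl",
    ModKind.DIMETHYL: "Dimethyl",
    ModKind.TRIMETHYL: "Trimethyl",
    ModKind.ACETYL_NTERM: "Acetyl",
    ModKind.OXIDATION: "Oxidation",
    ModKind.OTHER: "Other",
}

_TOKEN_RE = re.compile(r"^([A-Z])(\d+)\(([^()]+)\)$")
_NTERM_RE = re.compile(r"^N-?Term\(([^()]+)\)$", re.IGNORECASE)


@dataclass(frozen=True)
class ModificationSite:
    """One modification within a peptide.

    ``within_peptide_position`` is 1-based; 0 denotes the peptide N-terminus.
    """

    within_peptide_position: int
    residue_letter: str
    kind: ModKind

    def __post_init__(self) -> None:
        if self.within_peptide_position < 0:
            raise ValidationError("modification position must be >= 0")
        if self.within_peptide_position == 0 and self.kind in METHYL_KINDS:
            raise ValidationError("methylation cannot sit on the peptide N-terminus")

    def token(self) -> str:
        """Canonical annotation token for this site."""
        if self.within_peptide_position == 0:
            return f"N-Term({_CANONICAL_NAME[self.kind]})"
        return (
            f"{self.residue_letter}{self.within_peptide_position}"
            f"({_CANONICAL_NAME[self.kind]})"
        )


@dataclass(frozen=True)
class PeptideObservation:
    """One identified peptide species with its label-free abundance."""

    peptide_seq: str
    modifications: tuple[ModificationSite, ...] = ()
    abundance: float = 0.0
    localization_confident: bool = True

    def __post_init__(self) -> None:
        if not self.peptide_seq:
            raise ValidationError("peptide_seq must be non-empty")
        if self.abundance < 0:
            raise ValidationError(
                f"peptide {self.peptide_seq}: abundance must be >= 0"
            )
        mods = tuple(
            sorted(self.modifications, key=lambda m: m.within_peptide_position)
        )
        positions = [m.within_peptide_position for m in mods]
        if len(positions) != len(set(positions)):
            raise ValidationError(
                f"peptide {self.peptide_seq}: more than one modification at "
                "the same within-peptide position"
            )
        for m in mods:
            if m.within_peptide_position > len(self.peptide_seq):
                raise ValidationError(
                    f"peptide {self.peptide_seq}: modification position "
                    f"{m.within_peptide_position} exceeds peptide length"
                )
            if m.within_peptide_position >= 1:
                actual = self.peptide_seq[m.within_peptide_position - 1]
                if m.residue_letter != actual:
                    raise ValidationError(
                        f"peptide {self.peptide_seq}: annotation names "
                        f"{m.residue_letter}{m.within_peptide_position} but the "
                        f"residue there is {actual}"
                    )
                if m.kind in METHYL_KINDS and actual not in "KR":
                    raise ValidationError(
                        f"peptide {self.peptide_seq}: methylation on "
                        f"{actual}{m.within_peptide_position}; only K/R allowed"
                    )
        object.__setattr__(self, "modifications", mods)

    @property
    def is_modified(self) -> bool:
        return len(self.modifications) > 0

    def modification_string(self) -> str:
        return "; ".join(m.token() for m in self.modifications)

    def methyl_state_at(self, within_peptide_position: int) -> str:
        """Methylation state of the residue at a 1-based within-peptide
        position: 'un', 'mono', 'di' or 'tri'.  Non-methyl modifications
        (oxidation, acetylation, unknown) count as 'un'."""
        for m in self.modifications:
            if m.within_peptide_position == within_peptide_position:
                if m.kind is ModKind.MONOMETHYL:
                    return "mono"
                if m.kind is ModKind.DIMETHYL:
                    return "di"
                if m.kind is ModKind.TRIMETHYL:
                    return "tri"
                return "un"
        return "un"


def parse_modification_string(text: str) -> list[ModificationSite]:
    """Parse a semicolon-separated modification annotation.

    Empty/blank text yields no sites.  Residue/position consistency against
    the peptide is checked when the sites are attached to an observation,
    not here.
    """
    sites: list[ModificationSite] = []
    if not text or not text.strip():
        return sites
    for raw in text.split(";"):
        token = raw.strip()
        if not token:
            continue
        nterm = _NTERM_RE.match(token)
        if nterm:
            name = nterm.group(1).strip().lower()
            kind = ModKind.ACETYL_NTERM if name == "acetyl" else ModKind.OTHER
            sites.append(ModificationSite(0, "-", kind))
            continue
        m = _TOKEN_RE.match(token)
        if not m:
            raise ValidationError(f"unparseable modification token {token!r}")
        letter, pos, name = m.group(1), int(m.group(2)), m.group(3).strip().lower()
        kind = _MOD_NAMES.get(name, ModKind.OTHER)
        sites.append(ModificationSite(pos, letter, kind))
    return sites


@dataclass(frozen=True)
class TableDialect:
    """Declarative column mapping for a peptide-table dialect."""

    peptide_column: str = "peptide"
    modifications_column: str = "modifications"
    abundance_column: str = "abundance"
    confidence_column: str = "localization_confident"
    separator: str = "\t"
    true_values: frozenset[str] = frozenset({"true", "1", "yes", "high"})
    false_values: frozenset[str] = frozenset({"false", "0", "no", "low", ""})

    def parse_bool(self, text: str) -> bool:
        t = text.strip().lower()
        if t in self.true_values:
            return True
        if t in self.false_values:
            return False
        raise ValidationError(f"unrecognized confidence value {text!r}")


NATIVE_DIALECT = TableDialect()


def read_psm_table(
    path: str | Path, dialect: TableDialect = NATIVE_DIALECT
) -> list[PeptideObservation]:
    """Read a peptide table under a dialect.

    Rows with zero abundance are retained.  Malformed rows are collected with
    their line numbers and surfaced together in a single
    :class:`TableFormatError`; a missing required column fails immediately,
    naming the column.
    """
    path = Path(path)
    observations: list[PeptideObservation] = []
    row_errors: list[str] = []
    with path.open(newline="") as handle:
        reader = csv.DictReader(handle, delimiter=dialect.separator)
        header = reader.fieldnames or []
        for col in (
            dialect.peptide_column,
            dialect.modifications_column,
            dialect.abundance_column,
            dialect.confidence_column,
        ):
            if col not in header:
                raise TableFormatError(
                    f"{path}: required column {col!r} missing from header {header}"
                )
        for lineno, row in enumerate(reader, start=2):
            try:
                mods = parse_modification_string(
                    row[dialect.modifications_column] or ""
                )
                abundance_text = (row[dialect.abundance_column] or "").strip()
                try:
                    abundance = float(abundance_text)
                except ValueError:
                    raise ValidationError(
                        f"unparseable abundance {abundance_text!r}"
                    ) from None
                observations.append(
                    PeptideObservation(
                        peptide_seq=(row[dialect.peptide_column] or "").strip(),
                        modifications=tuple(mods),
                        abundance=abundance,
                        localization_confident=dialect.parse_bool(
                            row[dialect.confidence_column] or ""
                        ),
                    )
                )
            except ValidationError as exc:
                row_errors.append(f"{path}:{lineno}: {exc}")
    if row_errors:
        raise TableFormatError(
            f"{path}: {len(row_errors)} malformed row(s)", row_errors
        )
    return observations


def write_psm_table(
    observations: Iterable[PeptideObservation],
    path: str | Path,
    dialect: TableDialect = NATIVE_DIALECT,
) -> None:
    """Write observations in a dialect (native by default); round-trips with
    :func:`read_psm_table`."""
    path = Path(path)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter=dialect.separator, lineterminator="\n")
        writer.writerow(
            [
                dialect.peptide_column,
                dialect.modifications_column,
                dialect.abundance_column,
                dialect.confidence_column,
            ]
        )
        for obs in observations:
            writer.writerow(
                [
                    obs.peptide_seq,
                    obs.modification_string(),
                    repr(obs.abundance),
                    "true" if obs.localization_confident else "false",
                ]
            )


def filter_ambiguous(
    observations: Sequence[PeptideObservation],
) -> list[PeptideObservation]:
    """Drop modified observations whose localization was not confident.

    Unmodified observations are always retained (there is nothing to
    localize), order is preserved, and the operation is idempotent.
    """
    return [
        obs
        for obs in observations
        if obs.localization_confident or not obs.is_modified
    ]
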