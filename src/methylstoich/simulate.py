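"""Synthetic repetitive proteins with known methyl-lysine occupancy, and
simulated label-free peptide tables.

The generator emulates the data-generating process the quantification
assumes: a protein built as head + n tandem copies of a repeat unit (each
copy independently point-mutated) + tail; a ground-truth occupancy vector
(f_un, f_mono, f_di, f_tri) for every lysine; tryptic peptide species whose
expected peak area is ``abundance_base`` times the product of the occupancy
of the state carried at each of its lysines; log-normal multiplicative
intensity noise; Bernoulli detection; and a fraction of modified species
flagged as ambiguously localized.

Identical peptide+modification species arising from different repeat copies
are merged by summing their expected abundances *before* noise — a label-free
table reports one peak area per peptide species and carries no positional
information.  This merging is what makes the repeat-apportionment problem
real in the synthetic data.

All randomness flows from ``config.seed`` through a single generator when
:func:`simulate_dataset` is used; each stage is also callable on its own.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .psm import ModificationSite, ModKind, PeptideObservation
from .sequence import (
    AMINO_ACIDS,
    ProteinRecord,
    cleavage_sites,
    _digest_between_boundaries,
)
from .stoichiometry import STATES, ResidueStoichiometry

# Residue sampling weights loosely shaped like a small-residue-rich fiber
# protein (A/G/S/T/V-heavy, C/W rare), with K and R frequent enough that
# tryptic peptides are short but non-trivial.
_AA_WEIGHTS = {
    "A": 0.12, "G": 0.10, "S": 0.09, "T": 0.09, "V": 0.08,
    "N": 0.07, "D": 0.07, "L": 0.06, "I": 0.05, "K": 0.05,
    "Q": 0.04, "E": 0.04, "R": 0.03, "F": 0.03, "Y": 0.02,
    "P": 0.02, "H": 0.015, "M": 0.015, "W": 0.01, "C": 0.01,
}

_STATE_KINDS = {
    "mono": ModKind.MONOMETHYL,
    "di": ModKind.DIMETHYL,
    "tri": ModKind.TRIMETHYL,
}

#: Dirichlet concentration for the default occupancy scheme: unmethylated
#: dominant, monomethyl the predominant modification, dimethyl rare,
#: trimethyl near-absent (mean occupancy ≈ 0.73/0.24/0.018/0.006).
DEFAULT_DIRICHLET_ALPHA = (6.0, 2.0, 0.15, 0.05)

_MAX_STATE_COMBOS = 4 ** 10


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the assumed search conditions (two missed cleavages,
    modification-independent digestion) and a moderately repetitive adhesin
    architecture.
    """

    n_repeats: int = 5
    repeat_unit_length: int = 30
    inter_repeat_mutation_rate: float = 0.2
    head_length: int = 12
    tail_length: int = 12
    max_missed: int = 2
    p_block_cleavage_if_methylated: float = 0.0
    abundance_base: float = 1e6
    noise_sigma: float = 0.0
    detection_probability: float = 1.0
    ambiguous_fraction: float = 0.0
    occupancy_scheme: str = "dirichlet"
    fixed_occupancy: tuple[float, float, float, float] | None = None
    dirichlet_alpha: tuple[float, float, float, float] = DEFAULT_DIRICHLET_ALPHA
    repeat_unit: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1 or self.repeat_unit_length < 1:
            raise ValidationError("n_repeats and repeat_unit_length must be >= 1")
        if self.head_length < 0 or self.tail_length < 0:
            raise ValidationError("head/tail lengths must be >= 0")
        if not 0.0 <= self.inter_repeat_mutation_rate <= 1.0:
            raise ValidationError("inter_repeat_mutation_rate must be in [0,1]")
        if self.max_missed < 0:
            raise ValidationError("max_missed must be >= 0")
        if not 0.0 <= self.p_block_cleavage_if_methylated <= 1.0:
            raise ValidationError("p_block_cleavage_if_methylated must be in [0,1]")
        if self.abundance_base <= 0:
            raise ValidationError("abundance_base must be > 0")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if not 0.0 < self.detection_probability <= 1.0:
            raise ValidationError("detection_probability must be in (0,1]")
        if not 0.0 <= self.ambiguous_fraction < 1.0:
            raise ValidationError("ambiguous_fraction must be in [0,1)")
        if self.occupancy_scheme not in {"dirichlet", "fixed", "all-unmethylated"}:
            raise ValidationError(
                f"unknown occupancy scheme {self.occupancy_scheme!r}"
            )
        if self.occupancy_scheme == "fixed":
            v = self.fixed_occupancy
            if v is None or len(v) != 4 or any(x < 0 for x in v):
                raise ValidationError("fixed scheme needs a non-negative 4-vector")
            if abs(sum(v) - 1.0) > 1e-9:
                raise ValidationError("fixed_occupancy must sum to 1")
        if self.repeat_unit is not None:
            if len(self.repeat_unit) != self.repeat_unit_length:
                raise ValidationError(
                    "repeat_unit length must equal repeat_unit_length"
                )
            if "K" not in self.repeat_unit:
                raise ValidationError("repeat_unit must contain at least one K")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fixed_occupancy"] = (
            list(self.fixed_occupancy) if self.fixed_occupancy else None
        )
        d["dirichlet_alpha"] = list(self.dirichlet_alpha)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if d.get("fixed_occupancy") is not None:
            d["fixed_occupancy"] = tuple(d["fixed_occupancy"])
        if d.get("dirichlet_alpha") is not None:
            d["dirichlet_alpha"] = tuple(d["dirichlet_alpha"])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth per-lysine occupancy for a synthetic protein."""

    protein: ProteinRecord
    occupancy: Mapping[int, tuple[float, float, float, float]]

    def __post_init__(self) -> None:
        k_positions = set(self.protein.lysine_positions())
        if set(self.occupancy) != k_positions:
            raise ValidationError(
                "occupancy keys must be exactly the protein's K positions"
            )
        for pos, vec in self.occupancy.items():
            if len(vec) != 4 or any(f < 0 for f in vec):
                raise ValidationError(f"K{pos}: occupancy must be a non-negative 4-vector")
            if abs(sum(vec) - 1.0) > 1e-12:
                raise ValidationError(f"K{pos}: occupancy must sum to 1")

    def to_json_dict(self) -> dict:
        return {
            "protein": {
                "id": self.protein.id,
                "sequence": self.protein.sequence,
                "description": self.protein.description,
            },
            "occupancy": {str(p): list(v) for p, v in self.occupancy.items()},
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "SyntheticTruth":
        return cls(
            protein=ProteinRecord(**d["protein"]),
            occupancy={int(p): tuple(v) for p, v in d["occupancy"].items()},
        )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    letters = np.array(list(_AA_WEIGHTS))
    weights = np.array(list(_AA_WEIGHTS.values()))
    weights = weights / weights.sum()
    return "".join(rng.choice(letters, size=length, p=weights)) if length else ""


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    chars = list(seq)
    for i, a in enumerate(chars):
        if rng.random() < rate:
            others = [b for b in AMINO_ACIDS if b != a]
            chars[i] = others[rng.integers(len(others))]
    return "".join(chars)


def generate_repeat_protein(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> ProteinRecord:
    """Head + n point-mutated copies of one repeat unit + tail.

    The unit is random by default (guaranteed to contain at least one K);
    a designed unit can be supplied via ``config.repeat_unit``, which is
    useful for constructions where every tryptic peptide must sit at the
    same offset in every copy.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    head = _random_sequence(rng, config.head_length)
    if config.repeat_unit is not None:
        unit = config.repeat_unit
    else:
        unit = _random_sequence(rng, config.repeat_unit_length)
        if "K" not in unit:
            pos = int(rng.integers(len(unit)))
            unit = unit[:pos] + "K" + unit[pos + 1 :]
    copies = [
        _mutate(rng, unit, config.inter_repeat_mutation_rate)
        for _ in range(config.n_repeats)
    ]
    tail = _random_sequence(rng, config.tail_length)
    sequence = head + "".join(copies) + tail
    return ProteinRecord(
        id=f"synthetic_r{config.n_repeats}_seed{config.seed}",
        sequence=sequence,
        description=(
            f"synthetic repeat protein: head={config.head_length} "
            f"unit={config.repeat_unit_length}x{config.n_repeats} "
            f"mut={config.inter_repeat_mutation_rate} tail={config.tail_length}"
        ),
    )


def repeat_positions(config: SimulationConfig, unit_offset: int) -> list[int]:
    """1-based protein positions of a given 1-based within-unit offset in
    each repeat copy (copies have equal length even when mutated)."""
    return [
        config.head_length + j * config.repeat_unit_length + unit_offset
        for j in range(config.n_repeats)
    ]


def assign_truth(
    protein: ProteinRecord,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Draw a ground-truth occupancy vector for every K in the protein.

    Schemes: ``all-unmethylated`` → (1,0,0,0) everywhere; ``fixed`` → the
    configured vector everywhere; ``dirichlet`` → an independent draw per
    residue from the configured concentration (heterogeneous truth).
    """
    k_positions = protein.lysine_positions()
    if not k_positions:
        raise ValidationError("protein has no lysines to assign occupancy to")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    occupancy: dict[int, tuple[float, float, float, float]] = {}
    for pos in k_positions:
        if config.occupancy_scheme == "all-unmethylated":
            vec = np.array([1.0, 0.0, 0.0, 0.0])
        elif config.occupancy_scheme == "fixed":
            vec = np.array(config.fixed_occupancy, dtype=float)
        else:
            vec = rng.dirichlet(np.array(config.dirichlet_alpha))
        vec = vec / vec.sum()
        occupancy[pos] = tuple(float(x) for x in vec)
    return SyntheticTruth(protein=protein, occupancy=occupancy)


def generate_motif_protein(
    n_sites: int,
    flank: int = 10,
    planted: Mapping[int, str] | None = None,
    seed: int = 0,
) -> tuple[ProteinRecord, list[int]]:
    """A protein of ``n_sites`` concatenated blocks, each a K flanked by
    ``flank`` residues on either side, plus the K positions (1-based).

    Flanking residues are uniform over the 20 amino acids except at the
    offsets of ``planted`` (a map offset → letter, offsets in −flank..+flank
    excluding 0), which carry the given letter in every block — a planted
    motif that a flanking-window analysis should detect.  With ``planted``
    empty the flanks carry no signal.
    """
    if n_sites < 1 or flank < 0:
        raise ValidationError("need n_sites >= 1 and flank >= 0")
    planted = dict(planted or {})
    for off, letter in planted.items():
        if off == 0 or abs(off) > flank:
            raise ValidationError(f"planted offset {off} outside ±{flank}\\{{0}}")
        if letter not in AMINO_ACIDS:
            raise ValidationError(f"planted letter {letter!r} not an amino acid")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    width = 2 * flank + 1
    blocks = []
    positions = []
    for i in range(n_sites):
        block = list(rng.choice(letters, size=width))
        block[flank] = "K"
        for off, letter in planted.items():
            block[flank + off] = letter
        blocks.append("".join(block))
        positions.append(i * width + flank + 1)
    protein = ProteinRecord(
        id=f"motif_n{n_sites}_seed{seed}",
        sequence="".join(blocks),
        description=f"synthetic motif protein, planted={sorted(planted.items())}",
    )
    return protein, positions


def simulate_psm_table(
    truth: SyntheticTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[PeptideObservation], dict]:
    """Simulate a label-free peptide table from a ground truth.

    For every digest peptide occurrence and every combination of methylation
    states over its lysines (states with zero occupancy are skipped), the
    expected abundance is ``abundance_base × Π f``; species identical in
    sequence+modifications are merged by summation; the merged expectation
    is multiplied by log-normal noise, emitted with the detection
    probability, and (if modified) flagged ambiguous with the configured
    fraction.  When ``p_block_cleavage_if_methylated > 0``, each cleavage
    site at a lysine is suppressed, before enumeration, with probability
    p_block × (that lysine's methylated occupancy mass).

    Returns the observation list and a provenance record (config + counts).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    seq = truth.protein.sequence

    sites = cleavage_sites(seq)
    if config.p_block_cleavage_if_methylated > 0:
        kept_sites = []
        for i in sites:
            pos = i + 1
            if seq[i] == "K" and pos in truth.occupancy:
                methyl_mass = 1.0 - truth.occupancy[pos][0]
                p_suppress = config.p_block_cleavage_if_methylated * methyl_mass
                if rng.random() < p_suppress:
                    continue
            kept_sites.append(i)
        sites = kept_sites

    peptides = _digest_between_boundaries(seq, sites, config.max_missed)

    expected: dict[tuple[str, tuple], float] = {}
    for pep in peptides:
        k_offsets = [j for j, a in enumerate(pep.sequence) if a == "K"]
        choices = []
        n_combos = 1
        for j in k_offsets:
            occ = truth.occupancy[pep.start + j]
            opts = [(s, f) for s, f in zip(STATES, occ) if f > 0]
            choices.append(opts)
            n_combos *= len(opts)
        if n_combos > _MAX_STATE_COMBOS:
            raise ValidationError(
                f"peptide {pep.sequence} spans {len(k_offsets)} lysines; "
                f"{n_combos} state combinations exceed the supported limit"
            )
        for combo in itertools.product(*choices):
            abundance = config.abundance_base
            mods = []
            for j, (state, f) in zip(k_offsets, combo):
                abundance *= f
                if state != "un":
                    mods.append((j + 1, state))
            key = (pep.sequence, tuple(mods))
            expected[key] = expected.get(key, 0.0) + abundance

    observations: list[PeptideObservation] = []
    n_dropped = 0
    for (pep_seq, mods) in sorted(expected):
        value = expected[(pep_seq, mods)]
        if config.noise_sigma > 0:
            value *= math.exp(rng.normal(0.0, config.noise_sigma))
        if config.detection_probability < 1.0 and rng.random() >= config.detection_probability:
            n_dropped += 1
            continue
        confident = True
        if mods and config.ambiguous_fraction > 0:
            confident = rng.random() >= config.ambiguous_fraction
        observations.append(
            PeptideObservation(
                peptide_seq=pep_seq,
                modifications=tuple(
                    ModificationSite(offset, "K", _STATE_KINDS[state])
                    for offset, state in mods
                ),
                abundance=value,
                localization_confident=confident,
            )
        )

    provenance = {
        "config": config.to_dict(),
        "n_digest_peptides": len(peptides),
        "n_species_expected": len(expected),
        "n_species_emitted": len(observations),
        "n_species_dropped": n_dropped,
    }
    return observations, provenance


@dataclass(frozen=True)
class SimulatedDataset:
    protein: ProteinRecord
    truth: SyntheticTruth
    observations: tuple[PeptideObservation, ...]
    provenance: dict


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run all three stages from a single seeded generator."""
    rng = np.random.default_rng(config.seed)
    protein = generate_repeat_protein(config, rng)
    truth = assign_truth(protein, config, rng)
    observations, provenance = simulate_psm_table(truth, config, rng)
    return SimulatedDataset(
        protein=protein,
        truth=truth,
        observations=tuple(observations),
        provenance=provenance,
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Absolute errors (percentage points) between estimated and true
    occupancy, over detected residues."""

    per_residue_error: Mapping[int, dict[str, float]]
    max_abs_error: float
    mean_abs_error: float
    coverage: float
    n_detected: int
    n_lysines: int

    def to_dict(self) -> dict:
        return {
            "max_abs_error": self.max_abs_error,
            "mean_abs_error": self.mean_abs_error,
            "coverage": self.coverage,
            "n_detected": self.n_detected,
            "n_lysines": self.n_lysines,
        }


def evaluate_recovery(
    estimate: Sequence[ResidueStoichiometry], truth: SyntheticTruth
) -> RecoveryReport:
    """Compare an estimated stoichiometry table with the planted truth.

    Errors are |estimated% − 100·f_true| per state, over detected residues;
    undetected residues are excluded from the error and reported via
    coverage (fraction of K's detected).
    """
    ids = {r.protein_id for r in estimate}
    if ids and ids != {truth.protein.id}:
        raise ValidationError(
            f"stoichiometry table is for {sorted(ids)}, truth for "
            f"{truth.protein.id!r}"
        )
    per_residue: dict[int, dict[str, float]] = {}
    errors: list[float] = []
    n_detected = 0
    for r in estimate:
        if not r.detected:
            continue
        n_detected += 1
        pct = r.percent_by_state
        true_vec = truth.occupancy[r.position]
        errs = {
            s: abs(pct[s] - 100.0 * f) for s, f in zip(STATES, true_vec)
        }
        per_residue[r.position] = errs
        errors.extend(errs.values())
    n_lysines = len(estimate)
    return RecoveryReport(
        per_residue_error=per_residue,
        max_abs_error=max(errors) if errors else 0.0,
        mean_abs_error=(sum(errors) / len(errors)) if errors else 0.0,
        coverage=(n_detected / n_lysines) if n_lysines else 0.0,
        n_detected=n_detected,
        n_lysines=n_lysines,
    )


def write_truth_json(
    truth: SyntheticTruth, config: SimulationConfig, path: str | Path
) -> None:
    payload = truth.to_json_dict()
    payload["config"] = config.to_dict()
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_truth_json(path: str | Path) -> tuple[SyntheticTruth, SimulationConfig]:
    payload = json.loads(Path(path).read_text())
    truth = SyntheticTruth.from_json_dict(payload)
    config = SimulationConfig.from_dict(payload["config"])
    return truth, config
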