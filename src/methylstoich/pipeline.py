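"""End-to-end quantification pipeline and tabular reporting.

``run_quantify_pipeline`` wires FASTA + peptide table → per-lysine
stoichiometry TSV + protein-level summary JSON + plain-text diagnostics log,
deterministically: identical inputs and config give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .psm import TableDialect, NATIVE_DIALECT, read_psm_table
from .sequence import ProteinRecord, read_fasta
from .stoichiometry import (
    STATES,
    MethylationSummary,
    QuantifyDiagnostics,
    ResidueStoichiometry,
    methylation_summary,
    residue_stoichiometry,
    stoichiometry_frame,
    write_stoichiometry_tsv,
    write_summary_json,
)


@dataclass
class RunConfig:
    """Paths and parameters of one quantification run."""

    fasta_path: str | Path
    psm_path: str | Path
    protein_id: str
    out_prefix: str | Path
    dialect: TableDialect = field(default_factory=lambda: NATIVE_DIALECT)
    min_abundance: float = 0.0


@dataclass(frozen=True)
class PipelineResult:
    protein: ProteinRecord
    table: tuple[ResidueStoichiometry, ...]
    summary: MethylationSummary
    diagnostics: QuantifyDiagnostics
    stoichiometry_path: Path
    summary_path: Path
    log_path: Path


def select_protein(records: Sequence[ProteinRecord], protein_id: str) -> ProteinRecord:
    for rec in records:
        if rec.id == protein_id:
            return rec
    available = ", ".join(r.id for r in records)
    raise ValidationError(
        f"protein id {protein_id!r} not in FASTA (available: {available})"
    )


def run_quantify_pipeline(config: RunConfig) -> PipelineResult:
    """Quantify one protein's lysine methylation stoichiometry end to end."""
    records = read_fasta(config.fasta_path)
    protein = select_protein(records, config.protein_id)
    observations = read_psm_table(config.psm_path, config.dialect)

    diagnostics = QuantifyDiagnostics()
    table = residue_stoichiometry(
        observations,
        protein,
        min_abundance=config.min_abundance,
        diagnostics=diagnostics,
    )
    summary = methylation_summary(table)

    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    stoich_path = prefix.with_name(prefix.name + ".stoichiometry.tsv")
    summary_path = prefix.with_name(prefix.name + ".summary.json")
    log_path = prefix.with_name(prefix.name + ".log.txt")

    write_stoichiometry_tsv(table, stoich_path)
    write_summary_json(summary, summary_path)
    log_path.write_text("\n".join(diagnostics.to_lines()) + "\n")

    return PipelineResult(
        protein=protein,
        table=tuple(table),
        summary=summary,
        diagnostics=diagnostics,
        stoichiometry_path=stoich_path,
        summary_path=summary_path,
        log_path=log_path,
    )


def render_state_profile(table: Sequence[ResidueStoichiometry]) -> pd.DataFrame:
    """Long-format per-residue state percentages for stacked-bar plotting.

    Detected residues contribute one row per state (percent summing to 100);
    undetected residues contribute a single row with state 'NA' and a
    missing percent, so absence is visible rather than silently zero.
    """
    rows = []
    for r in table:
        pct = r.percent_by_state
        if pct is None:
            rows.append(
                {"position": r.position, "state": "NA", "percent": math.nan}
            )
        else:
            for s in STATES:
                rows.append(
                    {"position": r.position, "state": s, "percent": pct[s]}
                )
    return pd.DataFrame(rows, columns=["position", "state", "percent"])


def plot_state_profile(
    table: Sequence[ResidueStoichiometry], path: str | Path
) -> None:
    """Stacked per-residue state percentages as a bar figure (optional;
    requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = stoichiometry_frame(table)
    detected = frame[frame["detected"]]
    fig, ax = plt.subplots(figsize=(max(6, len(frame) * 0.15), 3.5))
    bottom = None
    colors = {"un": "#bbbbbb", "mono": "#1f77b4", "di": "#ff7f0e", "tri": "#d62728"}
    for s in STATES:
        values = detected[f"pct_{s}"].to_numpy()
        ax.bar(
            detected["position"], values, bottom=bottom, label=s,
            color=colors[s], width=0.8,
        )
        bottom = values if bottom is None else bottom + values
    ax.set_xlabel("lysine position")
    ax.set_ylabel("% of residue abundance")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
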