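"""Per-lysine methylation stoichiometry from a small peptide table.

Builds observations for one protein by hand — an unmodified and a
monomethylated form of the same peptide — and quantifies the lysine's
state percentages: percent = state abundance / residue total x 100.
"""

from methylstoich import PeptideObservation, ProteinRecord, residue_stoichiometry
from methylstoich.psm import ModificationSite, ModKind

protein = ProteinRecord("demo", "MKAAAR")
observations = [
    PeptideObservation("MKAAAR", (), abundance=80.0),
    PeptideObservation(
        "MKAAAR",
        (ModificationSite(2, "K", ModKind.MONOMETHYL),),
        abundance=20.0,
    ),
]

for r in residue_stoichiometry(observations, protein):
    pct = r.percent_by_state
    print(f"K{r.position}: " + "  ".join(f"{s}={pct[s]:.1f}%" for s in pct))
print("-> 20% of this lysine's population carries one methyl group;")
print("   percentages always sum to 100 over the four states.")
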