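"""End-to-end parameter recovery on synthetic data.

Simulates a repetitive protein with known per-lysine occupancy, runs the
full quantification chain on the simulated peptide table, and compares the
estimates with the planted truth.  With no noise, full detection and
diverged repeats the recovery is exact.
"""

from methylstoich import (
    SimulationConfig,
    evaluate_recovery,
    methylation_summary,
    residue_stoichiometry,
    simulate_dataset,
)

config = SimulationConfig(
    n_repeats=5,
    inter_repeat_mutation_rate=0.2,
    noise_sigma=0.0,
    detection_probability=1.0,
    ambiguous_fraction=0.0,
    seed=42,
)
data = simulate_dataset(config)
print(f"protein: {len(data.protein)} aa, "
      f"{len(data.protein.lysine_positions())} lysines, "
      f"{len(data.observations)} peptide species")

table = residue_stoichiometry(list(data.observations), data.protein)
summary = methylation_summary(table)
report = evaluate_recovery(table, data.truth)
print(f"detected {summary.n_detected}/{summary.n_lysines_total} lysines, "
      f"{summary.n_methylated} methylated")
print(f"mean methylation {summary.mean_methylation_percent:.2f}%")
print(f"max |estimate - truth| = {report.max_abs_error:.2e} percentage points")
print("-> exact (within float precision): the apportionment rule loses no")
print("   information when every peptide maps to a unique position.")
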