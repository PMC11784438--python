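"""Flanking-sequence consensus test around methylated lysines.

Compares a protein with a planted 3-letter motif around its methylated K's
against one with uniform flanks.  Column information content (bits) flags
planted positions; uniform flanks stay below the 1-bit threshold.
"""

from methylstoich import (
    build_pfm,
    consensus_verdict,
    extract_windows,
    generate_motif_protein,
)

for label, planted in [("planted A@-2 G@+1 S@+5", {-2: "A", 1: "G", 5: "S"}),
                       ("uniform flanks", {})]:
    protein, positions = generate_motif_protein(
        n_sites=100, flank=10, planted=planted, seed=5
    )
    windows = extract_windows(protein, positions, flank=10)
    verdict = consensus_verdict(build_pfm(windows), ic_threshold=1.0)
    flagged = [i - 10 for i, f in enumerate(verdict.column_flags)
               if f and i != 10]
    print(f"{label}: consensus={verdict.consensus}, "
          f"informative offsets={flagged}")
print("-> a real consensus shows up as specific flanking offsets with high")
print("   information content; featureless flanks give none.")
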