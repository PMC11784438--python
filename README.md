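# methylstoich

Per-residue lysine-methylation stoichiometry from label-free peptide-level
mass-spectrometry results — built for repetitive proteins, where the same
peptide sequence occurs at many positions and naive site quantification
breaks down.

Large bacterial surface adhesins (trimeric autotransporter adhesins and
similar fiber proteins) carry hundreds of lysines, many of them methylated
by dedicated outer-membrane-protein lysine methyltransferases. Because
these proteins are built from homologous repeats, a tryptic peptide often
cannot be assigned to a single position. This package implements the
peptide-to-residue quantification that handles this, plus everything needed
to test it end to end without any external data.

## The computation

For a target protein and a table of identified peptide species (sequence,
modifications, summed peak-area abundance, localization-confidence flag):

1. rows with identical sequence + modifications are aggregated by summing
   abundances;
2. modified species whose localization is ambiguous are excluded;
3. each species is mapped to **every** exact occurrence of its sequence in
   the protein, and its abundance *A* is apportioned equally: each of the
   *k* occurrences receives *A*/*k*;
4. for each lysine *i* and methylation state
   *s* ∈ {un, mono, di, tri}, the abundance is

   ```
   a_i(s) = Σ over (species, occurrence) covering i with state s of  A/k
   ```

   and the stoichiometry is `p_i(s) = 100 · a_i(s) / Σ_s' a_i(s')`.

A residue is *detected* when its total abundance is positive; percentages
of undetected residues are reported as missing, never as zeros. Protein-
level summaries count detected/methylated residues and the unweighted mean
of (100 − p_i(un)) over detected residues.

Also included: in-silico tryptic digestion (cleave after K/R, not before P,
bounded missed cleavages), a ±10-residue flanking-window motif analysis
(position frequency matrix + per-column information content, with a 1-bit
consensus threshold), a synthetic-data simulator with planted per-lysine
occupancy for parameter-recovery testing, and the autoagglutination-ratio
formula for OD660 phenotype readings.

## Worked example

`examples/03_simulate_and_recover.py` simulates a repetitive protein
(5 imperfect repeat copies, known occupancy per lysine, no intensity noise),
runs the full quantification chain on the simulated peptide table, and
compares estimates with the planted truth:

```
protein: 174 aa, 8 lysines, 570 peptide species
detected 8/8 lysines, 8 methylated
mean methylation 31.84%
max |estimate - truth| = 1.42e-14 percentage points
```

Every lysine is detected, and each estimated occupancy vector matches the
planted one to floating-point precision: when every peptide species maps to
a unique position, the apportionment rule loses no information. The other
examples cover digestion/mapping, direct stoichiometry on a hand-built
table, motif discrimination, and the autoagglutination ratio.

The same pipeline runs from the shell:

```sh
methylstoich simulate --seed 42 --out-prefix run
methylstoich quantify --fasta run.fasta --psms run.psms.tsv \
    --protein-id synthetic_r5_seed42 --out-prefix run
methylstoich recover --truth run.truth.json --stoich run.stoichiometry.tsv
```

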