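# Methods

## Quantification model

The observable is a label-free peptide table: one row per peptide *species*
(sequence + modification annotation) with a summed chromatographic
peak-area abundance. The model behind the per-residue computation is that a
residue copy of a lysine is in exactly one of four states — unmethylated,
mono-, di- or trimethylated — and that, other things being equal, the peak
area of a peptide form is proportional to the fraction of protein
molecules carrying that form. Under that proportionality, dividing the
summed abundance carrying state *s* at residue *i* by the residue's total
abundance estimates the state's occupancy f_i(s).

Assumptions worth stating explicitly:

- **Equal ionization/detection efficiency across methyl forms of the same
  peptide.** Methylation shifts mass and slightly shifts retention and
  charge behavior; the ratio estimator ignores this, as does any label-free
  site-stoichiometry calculation of this form.
- **Ambiguous localization is exclusion, not re-weighting.** A modified
  species whose site assignment is not confident is dropped entirely
  (unmodified species carry no localization question and are always kept).
  Ambiguity is a per-observation boolean, not per-site probabilities.
- **Equal apportionment across repeat occurrences.** When a peptide's
  sequence occurs at *k* positions, each receives abundance/*k*. This is
  the only assignment available without positional information, and its
  systematic consequence is quantified below.
- Non-methyl modifications (oxidation, N-terminal acetylation, anything
  unrecognized) are parsed and carried but count as "unmethylated" at any
  lysine they sit on; arginine methylation is carried but only lysines are
  quantified.

A residue is *detected* when its accumulated abundance exceeds a threshold
(default 0, i.e. strictly positive). Undetected residues have undefined
percentages, reported as missing — zero-filling would fabricate an
unmethylated call. The protein-level mean methylation percentage is the
**unweighted** mean over detected residues of (100 − percent unmethylated);
an abundance-weighted mean would let a few well-ionizing peptides dominate
a protein-level number meant to describe residues.

## Digestion

Trypsin rule: cleave C-terminal to K or R except when the next residue is
P; peptides are all runs between boundaries containing at most
`max_missed` internal sites (default 2). Digestion is modification-blind:
quantification is downstream of the identification search and never
re-digests. Interplay between methylation and cleavage exists only in the
simulator (`p_block_cleavage_if_methylated`), defaulting to off. Length
filters exist but default to off. Coordinates are 1-based inclusive
everywhere. Peptide mapping is exact substring matching; an `X` in the
protein never matches anything.

## The repeat-apportionment bias, exactly

Let a peptide species cover a lysine offset that exists in *k* repeat
copies with true occupancies f_1 … f_k. The species' merged abundance is
proportional to Σ_c f_c(s) for each state *s*, and equal apportionment
assigns each copy 1/k of it. If **every** species covering a position
occurs at the same offset in all *k* copies, the estimate at every copy is
exactly the across-copy mean (1/k) Σ_c f_c — the apportionment rule
averages, it does not invent. This is exact, and it is the strongest
statement available: positional information about differences between
copies is destroyed by species merging before the data ever reach the
pipeline.

The condition matters. A peptide spanning the junction between adjacent
copies of a tandem repeat occurs only k−1 times, so border positions mix a
junction average with the all-copy average and the clean law above picks up
edge terms. The test construction for the averaging law therefore uses a
pure tandem repeat whose unit ends at a cleavage site, digested without
missed cleavages, where every species provably sits at the same offset in
every copy. With diverged repeats (the default simulator setting), most
species map uniquely and recovery is exact residue by residue; short
peptides that still multi-map pull their positions toward the mean of the
matching sites.

## Motif analysis

Windows of ±`flank` residues (default 10) are taken around each methylated
lysine (default selector: any detected residue with positive methyl-state
abundance; a minimum-percentage selector exists). Out-of-range flanks are
padded with `-`; pads are excluded from column denominators, so terminal
columns rest on fewer observations. Column information content is
IC = log2 20 − H(column) in bits; a column is informative at ≥ 1 bit
(configurable), and a consensus is called when any non-center column is
informative — the center is conditioned to be K and is never evidence. No
small-sample IC correction is applied by default; with uniform flanks the
sampling bias is ≈ 19/(2·n·ln 2) bits (≈ 0.14 at n = 100), far below the
1-bit threshold, so the default verdict is well separated on both sides.

## Synthetic data generator

The generator emulates the statistical structure the quantification
assumes, with one seeded generator driving everything:

- **Protein**: head + n copies of a repeat unit + tail. Residues are drawn
  from a small-residue-rich composition (A/G/S/T/V-heavy, ~5% K, ~3% R)
  typical of fibrous adhesins; each copy is independently point-mutated at
  `inter_repeat_mutation_rate` (default 0.2 — repeats homologous, not
  identical, which is also what makes most peptides map uniquely). A
  designed unit can be supplied verbatim for constructions with controlled
  cleavage structure. Defaults: 5 repeats of 30 residues, head/tail 12.
- **Truth**: per-lysine occupancy vectors. Schemes: all-unmethylated; a
  fixed vector shared by all residues; or independent Dirichlet draws with
  concentration (6, 2, 0.15, 0.05) — unmethylated dominant, monomethyl the
  predominant modification (mean ≈ 0.24), dimethyl rare, trimethyl
  near-absent, giving a mean methylated fraction around 27%.
- **Table**: for each digest peptide occurrence (2 missed cleavages by
  default) and each state combination over its lysines, expected abundance
  = `abundance_base` × Π f; identical sequence+modification species are
  merged by summation **before** noise — one peak area exists per species,
  and this merging is precisely what erases positional information. The
  merged expectation is multiplied by exp(N(0, σ)) (log-normal is the
  standard peak-area error model; σ on the natural-log scale, default 0),
  emitted with probability `detection_probability` (default 1), and modified
  species are flagged ambiguous with probability `ambiguous_fraction`
  (default 0). Cleavage blocking at methylated K, when enabled, suppresses
  a site with probability p_block × (methylated occupancy mass) — a
  per-sequence approximation of a per-molecule phenomenon, default off so
  the noiseless identifiability results stay exact.

What the simulator does **not** model: spectra (m/z, charge, retention),
identification error and FDR, intensity-dependent detection, ionization
differences between methyl forms, and co-eluting interference. Passing
recovery tests therefore validate the quantification arithmetic and its
repeat handling — not robustness to search-engine artifacts in real data.

## Numerical choices

- Percentages in double precision; test comparisons at 1e-9 absolute.
- State-combination enumeration skips zero-occupancy states and refuses
  more than 4^10 combinations per peptide (a peptide spanning > 10 lysines
  with fully mixed occupancy is outside the intended regime).
- Species iteration is sorted, making simulated tables byte-reproducible
  and the pipeline deterministic (re-runs hash identically).
- The autoagglutination ratio is computed as 100·((initial−after)/initial)
  so a fully settled suspension gives exactly 100.
- Problem sizes in the test suite and acceptance script (proteins of a few
  hundred residues, 20-seed noise grids) were chosen as the smallest
  instances where every property is informative; all properties are
  size-free and hold unchanged at larger scales.

## Known limitations

- Stoichiometry is per target protein; peptides shared across *different*
  proteins are counted in diagnostics, not resolved (protein inference is
  out of scope).
- The equal-apportionment estimator is biased toward the across-repeat mean
  whenever copies genuinely differ and peptides multi-map; the bias is
  exactly characterized above but not corrected — no unbiased correction
  exists without positional evidence.
- Localization ambiguity as a boolean discards partially localized signal
  that probabilistic site-localization scores could retain.
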