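# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `helminthamp`, and what the synthetic-data tests do and
do not demonstrate.

## Pipeline model and assumptions

The package assumes the classical secretory prepropeptide architecture:
an N-terminal signal peptide, one or more propeptide regions separated by
prohormone-convertase cleavage sites (dibasic K/R pairs, cleavage after the
second basic residue), and one or more mature peptides.  Candidate mature
peptides are therefore defined purely positionally, from the boundary set
B = {signal end} ∪ {propeptide sites} ∪ {C-terminus}.  Because convertase
processing is often partial and site prediction is noisy, the default
`all_pairs` excision keeps **every** ordered boundary pair (m(m−1)/2
candidates), not just consecutive segments; `segments` mode is provided for
sensitivity analysis.  This deliberately over-generates: downstream
consensus prediction and curation are the selective steps.

The C-terminal glycine rule (`synthesis_form`): a peptide ending in G is
produced amidated with the glycine removed, the amide-donor convention of
peptidylglycine α-amidating monooxygenase.  This matches the synthesised
forms of amidated candidates, whose sequences lack the donor glycine.

## Thresholds (defaults, units, rationale)

| parameter | default | rationale |
|---|---|---|
| precursor length cap | 150 aa | the vast majority of known AMP precursors are shorter |
| peptide gate | 10–99 aa | working range of batch AMP prediction tools (<10 and ≥100 removed) |
| consensus fraction | > 0.5 strict | "more than half the tools"; an exact tie on an even ensemble is negative |
| overall % rounding | nearest integer, half-up | makes the 11-tool lattice {0, 9, …, 55, 64, …, 100}; 6/11 → 55, 7/11 → 64 |
| grouping threshold | ≥ 100 bits | sequelog definition; with λ = 0.267, K = 0.041 this needs raw ≥ 248 |
| exclusion threshold | ≥ 50 bits | conservative similarity to a known AMP; no published value exists, so it is configurable |
| group length cutoff | > 60 aa for a strict majority of members | most AMPs are < 60 aa |
| TPM cutoff | > 2, any sample | standard expressed/not-expressed convention; absent genes are *unknown*, not false |
| PSM tiers | ≥ 47.4 / ≥ 20 / ≥ 13 (−10lgP) | 1 % FDR, P < 0.01, P < 0.05 search-engine mappings; boundary values take the higher tier |
| MIC activity | < 100 μg/ml | the APD activity convention |
| match tolerances | 15 ppm parent, 0.1 Da fragment | typical high-resolution CID settings |

## Alignment and grouping

`smith_waterman` is an affine-gap Gotoh DP (numba-compiled, linear space)
under the BLAST gap convention: a gap of length L costs 11 + L.  Bit
conversion uses the standard gapped BLOSUM62/11/1 Karlin–Altschul constants
λ = 0.267, K = 0.041, since sequelog thresholds are quoted in bits without
constants.  "Overall bit score" is read as the best single local alignment
per pair; HSP chaining and E-values (which need database-size corrections)
are out of scope.

Grouping defaults to aligning the **full precursor** (≤ 150 aa) rather than
the mature peptide.  This is a deliberate design choice: under the default
constants a pair cannot reach 100 bits below raw score 248, which typical
mature peptides (10–45 aa) cannot attain even as perfect self-matches, yet
short peptides demonstrably do form sequelog groups.  The ≥100-bit
criterion is therefore only meaningful on the longer precursor sequences;
a mature-peptide mode with a user-set threshold remains available
(`grouping_on: peptide`).

Group consensus uses a center-star multiple alignment (center = member with
maximal summed pairwise bit score; pairwise global alignments merged with
the once-a-gap-always-a-gap rule).  The consensus is the modal residue per
column with alphabetical tie-break; columns that are majority-gap are
dropped.  The representative is the member with the highest percent
identity to that consensus (ties: longer member, then smallest id).
Identity is computed as matches over the longer sequence length, which
penalises truncation.

Curation predicates (GO, group length) are pure functions of a group, so
the surviving set is order-independent; the GO filter removes a group when
**any** member carries a blocklisted Biological Process / Molecular
Function term (the conservative reading; an all-annotated-members mode is
available), and fully unannotated groups are always retained.  GO ancestor
propagation over the ontology graph is not performed; the blocklist must
list the concrete accessions to act on.

## Masses, charge, conversions

Monoisotopic and average masses come from standard residue tables
(pyteomics backend) plus fixed deltas: pyro-Glu −17.026549, oxidation
+15.994915, sulfation +79.956815, amide −0.984016 (−0.985 average) Da.
Masses are reported to 4 decimals and compared to printed values at
|Δ| ≤ 0.001 Da (published tables show occasional last-digit rounding
differences).  μM conversions round half-up to integers.  One published
detected-peptide mass (ADIPSAPIL, 911.4963) sits exactly +15.995 Da above
its computed unmodified mass — consistent with an unannotated oxidation —
and is excluded from the verification set.

Net charge defaults to the simple counting model (+1 K/R, −1 D/E, +0.5 H,
+1 free N-terminus, −1 free C-terminus, termini silenced by
pyro-Glu/amide); a Henderson–Hasselbalch model at pH 7 is selectable.  A
published group-level charge of +27.5 for one arginine-rich family was
computed on an unprinted gap-stripped consensus of 11 peptides and is not
reproducible from the synthesised sequence under common models; it is not
used as an oracle (the corresponding test asserts only a strongly cationic
value, > +25, from the synthesised form).

Fragment ladders are singly/multiply protonated b/y series only (CID of
2–4+ parents); a/c/z ions are out of scope.  b_i = N-terminal residue sum
+ proton; y_j = C-terminal residue sum + water + proton; residue
modifications land in whichever fragment contains them.  The
complementarity identity b_i + y_{n−i} = M + 2·proton is asserted for every
generated ladder.  Sequence coverage is the interval union of PSM spans at
or above a tier over the **full prepropeptide** length (signal included).

## Signal/propeptide heuristics

The built-in signal-peptide locator is a Kyte–Doolittle window rule: the
first 8-residue window starting at positions 3–30 with mean hydropathy
≥ 1.6 marks the h-region; the cleavage site is placed 5 residues after the
window end, capped at position 35.  The propeptide scanner reports every
dibasic K/R pair (overlaps included).  Both are deliberately simple,
deterministic stand-ins so the pipeline runs without external predictors;
supplied annotations (SignalP 4.1 short, ProP 1.0, or the generic TSV)
always take precedence.  They are not neural-network predictors and no
claim of equivalence is made.

## Ensemble stand-ins

Three deterministic physicochemical rules (net charge ≥ +2; hydrophobic
fraction 30–60 %; mean Eisenberg helical moment ≥ 0.2 at 100°/residue)
serve as built-in "tools" when real per-tool call tables are absent.  They
capture the cationic-amphipathic archetype only — they will miss anionic
and many cysteine-rich AMPs — and exist so fixtures and smoke runs are
self-contained, not as reproductions of any published predictor.

## Synthetic data: what it emulates and what it does not

The generator plants, per family, an ancestor prepropeptide
(15-residue signal with a protected hydrophobic h-region; 12–16-residue
acidic spacer; KR; 26–40-residue cationic-amphipathic core; KR; short polar
tail) and replicates it across pseudo-genomes with i.i.d. substitutions
(default 5 %).  Substitutions never touch the initial Met, the h-region or
any K/R residue, and never introduce K/R or C, so cleavage truth, charge
and cysteine class are preserved by construction.  Decoys are
secreted-but-neutral or non-secreted polar proteins; known-AMP plants embed
exact copies of a small generated library; GO-blocklisted families are
AMP-like but carry blocklisted terms.  Tool-call tables derive from the
reference rules with seeded symmetric label noise (8 %).

Consequences for interpretation: passing tests show the pipeline's
*mechanics* are correct (counts, boundaries, recovery of planted structure
under mutation) — they do not show that real helminth AMPs would be found,
because the fixtures contain no indels, no alternative cleavage chemistry
(mono-basic or non-canonical sites), no compositional drift between
genomes, and tool calls far better behaved than real web predictors.
Genome-scale published counts additionally depend on external resources
(WormBase ParaSite proteomes, SignalP/ProP, 11 web predictors) and are out
of desk-scale scope.

Default problem sizes (8 families × 4 genomes, ~70–90 proteins, ~300
candidate peptides) were chosen as the smallest scale at which every stage
has non-trivial work — multiple families per genome, multiple peptides per
precursor, non-empty removal at every filter — while keeping the whole
suite interactive.

## Numerical conventions

Coordinates are 1-based inclusive everywhere in files and reports.
Rounding is half-up for all integer percentages and μM values.  Tie-breaks
are deterministic and documented at each site (first-in-input for dedup;
alphabetical for consensus residues; size-then-smallest-member for group
ids).  All randomness flows through a single integer seed; identical seeds
give byte-identical fixture bundles and pipeline outputs.
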