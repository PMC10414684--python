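# helminthamp

Computational discovery of antimicrobial-peptide-like peptides (AMP-LPs)
from parasitic-worm (nematode and flatworm) predicted proteomes.

Parasitic helminths live in intensely microbial niches and secrete short
innate-immune effector peptides, but their AMPs are sequence-divergent and
largely invisible to homology searches.  `helminthamp` implements a
peptide-centric discovery funnel that works from predicted proteomes
instead: it filters precursor proteins, excises candidate mature peptides
at signal-peptide and propeptide (dibasic K/R) cleavage sites, designates
AMP-LPs by ensemble consensus over AMP prediction tools, clusters them into
sequelog groups by local-alignment bit score, curates the groups (known-AMP
exclusion, GO blocklist, group length, cysteine class, expression), and
characterises the survivors.  It also supports LC-MS/MS validation of
candidates detected in worm biofluid (PSM confidence tiers, theoretical b/y
fragment ladders, sequence coverage), and ships a seeded synthetic-proteome
generator with full ground truth so every stage is testable offline.

It is aimed at researchers prioritising candidate AMPs from helminth (or
other invertebrate) genome resources, and at anyone who needs a
reproducible, scriptable version of this class of discovery pipeline.

## The method in brief

1. **Precursor filtering.** Per-genome exact deduplication; removal of
   sequences containing unknown residues (X) or stop codons (\*); removal of
   proteins > 150 aa (AMP precursors are almost always shorter).
2. **Excision.** For each secreted precursor with signal-peptide end *s*
   and propeptide cleavage sites *p₁ < p₂ < …*, the boundary set is
   B = {s, p₁, …, pₖ, L}.  Every ordered boundary pair (bᵢ, bⱼ) yields a
   candidate peptide spanning residues bᵢ+1…bⱼ — m(m−1)/2 candidates for
   m boundaries — then a 10–99 aa length gate is applied.  Deterministic
   hydropathy/dibasic-motif heuristics stand in when external
   signal-peptide/convertase annotations are not supplied.
3. **Ensemble consensus.** A peptide is an AMP-LP iff strictly more than
   50 % of the contributing prediction tools call it antimicrobial.  With
   an 11-tool ensemble the overall score lattice is {0, 9, …, 91, 100} %
   and the weakest AMP-LP scores 55 % (6/11).
4. **Sequelog grouping.**  All-vs-all Smith–Waterman (BLOSUM62, gap
   open 11, extend 1) raw scores S convert to bits via
   B = (λS − ln K)/ln 2 with λ = 0.267, K = 0.041; pairs with B ≥ 100 are
   sequelogs and groups are the connected components.  Singleton groups and
   groups confined to one genome assembly are discarded.  Candidates
   scoring ≥ 50 bits against a known-AMP library are excluded first.
5. **Curation.**  Groups carrying non-antimicrobial GO terms (blocklist,
   e.g. `GO:0010951` negative regulation of endopeptidase activity) are
   removed; unannotated groups are retained.  Groups where a strict
   majority of members exceed 60 aa are removed.  Peptides are triaged by
   cysteine count (≤1 linear, 2 two-cysteine, >2 cysteine-rich) and flagged
   as expressed when any RNA-seq sample shows TPM > 2.
6. **Characterisation.**  Monoisotopic/average mass with PTMs (pyro-Glu
   −17.0265, Met oxidation +15.9949, sulfation +79.9568, C-terminal amide
   −0.9840 Da), net charge, hydrophobic %, and MIC μg/ml → μM conversion
   (μM = 1000·MIC/average mass, half-up; active iff MIC < 100 μg/ml).
7. **Peptidomics validation.**  −10lgP tiers (≥47.4 high / ≥20 medium /
   ≥13 low), the ≥3-consecutive-b/y-ion acceptance rule, and interval-union
   sequence coverage of the prepropeptide.

## Worked example

Generate a ground-truthed synthetic dataset (8 planted AMP families
replicated across 4 pseudo-genomes at 5 % per-residue mutation, 2
GO-blocklisted decoy families, 20 decoys, 12 planted copies of known AMPs,
plus duplicate/invalid/over-length proteins) and run the full funnel:

```
helminthamp fixtures --seed 17 --out demo/fix
helminthamp run --input-dir demo/fix --out-dir demo/out
```

which prints the per-stage funnel and summary:

```
[
 {"stage": "deduplicate",         "n_in": 85,  "n_out": 80},
 {"stage": "remove_invalid",      "n_in": 80,  "n_out": 76},
 {"stage": "length_filter",       "n_in": 76,  "n_out": 72},
 {"stage": "signal_peptide",      "n_in": 72,  "n_out": 62},
 {"stage": "excision_length_gate","n_in": 322, "n_out": 270},
 {"stage": "ensemble_consensus",  "n_in": 270, "n_out": 208},
 {"stage": "known_amp_exclusion", "n_in": 208, "n_out": 160},
 {"stage": "sequelog_grouping",   "n_in": 160, "n_out": 160},
 {"stage": "go_filter",           "n_in": 10,  "n_out": 8},
 {"stage": "group_length_filter", "n_in": 8,   "n_out": 8}
]
8 prioritised group(s) → demo/out
```

Reading the funnel: 5 duplicate, 4 invalid and 4 over-length proteins are
removed; 62 of 72 survivors carry a signal peptide; all-pairs excision
yields 322 candidates of which 270 pass the 10–99 aa gate; 208 are flagged
AMP-LP by >50 % tool consensus; 48 peptides matching the known-AMP library
are excluded; grouping plus curation leaves exactly the 8 planted AMP
families (both GO-blocklisted decoy families are removed at `go_filter`).
`demo/out/prioritised_groups.tsv` lists one representative per group, e.g.

```
sequence                length  monoisotopic_mass  net_charge  hydrophobic_pct  cysteine_class  expressed
GEDSQGQGEDAQEIKRVKGLWK… 60      6563.5549          8.0         28               linear          True
```

— a cationic, linear, expressed candidate ready for synthesis triage.

## Input files

The pipeline reads a directory containing per-genome
`proteins_<genome>.fasta` files plus optional tables (the fixture generator
writes all of them): `cleavage.tsv` (generic dialect: `protein_id`,
`signal_end`, `propeptide_sites` ;-separated, 1-based inclusive —
SignalP 4.1 short and ProP 1.0 text outputs are also parsed by
`io_formats.read_cleavage_tables`), `tool_calls/*.tsv` (`peptide_id`,
`tool_name`, `call` as booleans or probabilities), `go.tsv`, `tpm.tsv`,
and `known_amps.fasta`.  All coordinates in all files are 1-based
inclusive.  Individual stages are available as subcommands
(`filter`, `excise`, `predict`, `group`, `characterize`, `psm`) and as
library functions.

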