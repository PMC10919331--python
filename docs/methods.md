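# Methods

## Provirus model

The package models integrase-mediated integration of a circular viral genome
at a short attachment sequence. Integration duplicates the att core: the
chromosome afterwards reads

```
... host | att | provirus core | att | host ...
           attL                  attR
```

so an integrated provirus is detectable purely from sequence as a pair of
exact direct repeats separated by an element-sized interval. Excision is the
inverse reaction and leaves one att copy at each junction: one in the
chromosome, one on the circle (attV). Two consequences are used throughout:

- the excised circle length equals `attR.start − attL.start` (one att copy
  retained), and the circle is reported rotated so attV starts at position 0;
- excision followed by re-integration must reproduce the chromosome
  byte-identically, which the tests assert on every fixture.

The repeat-inclusive element span (`attR.end − attL.start`) is also reported,
since published element sizes do not always state which convention they use.

## Repeat finding

`find_direct_repeats` seeds on an exact k-mer index with k equal to
`min_repeat_len` (default 15 nt), pairs seed positions whose separation lies
in `[min_element_len, max_element_len]` (defaults 5–50 kb), extends each pair
to maximality on both sides, and deduplicates. For exact repeats this is
provably equivalent to a full all-pairs maximal-repeat scan — every repeat of
length ≥ k shares a k-mer at the same offset — and the test suite checks
exact agreement against an independent per-diagonal run-scanning oracle.
With `max_mismatches > 0` extension tolerates a shared Hamming budget
(right side first, trimmed back so both repeat ends match exactly, trimmed
budget refunded); mismatch mode is a convenience extension, not covered by
the maximality guarantee. The scan operates on the linear sequence
representation; repeat pairs spanning a circular chromosome's origin are not
sought, since an integrated element lies within the chromosome body.

Evidence scoring is an explicit, documented heuristic:
`score = repeat_length + 50·[tRNA overlap] + 50·[integrase within
max_integrase_distance]` (default 2,000 bp, end-to-nearest-end). The bonuses
are large relative to realistic repeat lengths so that an element with
integration-biology evidence always outranks chance repeat pairs. Calls with
overlapping spans are resolved by score, then repeat length, then leftmost
position, making output deterministic.

## In-silico PCR

Primer sites are exact string matches (configurable mismatch count). A
product is reported for every forward-site/reverse-site pair in which the
reverse-complement site begins at or after the forward site start; the
length runs from the forward primer's 5′ start to the reverse primer's 5′
start on the opposite strand, inclusive of both primers. Circular templates
are searched on a doubled sequence with forward sites restricted to the
first copy and product length capped at the template length, which yields
junction-spanning amplicons exactly when the topology permits them. Both
primer orientations are tried; products above `max_product` (default 10 kb)
are suppressed, mirroring what a PCR would plausibly amplify.

## ORF calling

Both strands, three frames, genetic code 11, start codons {ATG, GTG, TTG}
(alternative starts translate as Met), minimum product length 30 aa. Within
each stop-anchored frame segment the ORF runs from the most upstream
permitted start to the stop, which collapses nested same-frame ORFs to the
longest — the standard deterministic convention. Circular genomes are
scanned on a doubled sequence; ORFs starting in the first copy are kept, so
origin-spanning ORFs are called once, with `end` allowed to exceed the
genome length to mark the wrap. ORFs lacking a terminal stop on a linear
sequence are not called. The defaults are configurable because published ORF
counts are sensitive to them; the real-data check runs a small documented
parameter sweep.

## Pairwise identity and synteny

Global alignment with BLOSUM62 and affine gaps (a gap of length L costs
11 + (L−1)·1), via Biopython's PairwiseAligner. Identity is matches divided
by aligned columns after trimming terminal-gap columns, ×100; coverage is
the fraction of the shorter sequence in residue-to-residue columns. Because
optimal alignments can tie and the aligner's first traceback depends on
operand order, the operand pair is canonically ordered before alignment,
which makes identity exactly symmetric. The test suite verifies the optimal
score against an independent Gotoh dynamic program and recomputes identity
from the returned alignment strings.

The synteny map compares consecutive genomes in the user-given display
order, all ORFs against all ORFs, and keeps reciprocal best hits above
identity/coverage thresholds (defaults 20% / 0.5), so each ORF joins at most
one link per genome pair. The SVG ribbon plot shades links darker with
higher identity.

## Structure signatures

- **Sequons**: every overlapping window matching N-X-S/T with X ≠ P is
  counted, regardless of structural context; no C-terminal or transmembrane
  exclusion is applied. A user-supplied 1-based residue range can trim
  terminal transmembrane spans before counting (trimming is never
  predicted).
- **Salt bridges**: any ASP OD1/OD2 or GLU OE1/OE2 atom within 4.0 Å of any
  ARG NH1/NH2/NE, LYS NZ or HIS ND1/NE2 atom; one bridge per residue pair
  with the minimum distance reported. HIS donates contacts but contributes 0
  to the net-charge sum (pH 7 convention: D/E −1, R/K +1, H 0).
- **Hydrophobic clusters**: residues in {A, V, L, I, M, F, W, Y} are in
  contact when any side-chain heavy-atom pair is within 4.5 Å; clusters are
  connected components of at least 3 residues. Enlarging either cutoff can
  only merge, never split, which the tests assert.
- **Surface charge**: a residue is "exposed" when its CA has at most 18
  other CA atoms within 10 Å — a neighbor-count burial proxy chosen for
  determinism and zero extra dependencies; a solvent-accessibility backend
  is an extension point. `exposed_negative_fraction` is exposed acidic over
  all exposed charged (D/E/R/K) residues, reported as 0 with a `defined`
  flag when no charged residue is exposed; structures under 10 residues are
  rejected because the proxy is meaningless there.

All cutoffs are keyword arguments with these documented defaults, since
published structure comparisons rarely state their criteria precisely.

## Group comparison

Student's unpaired two-sided t-test with pooled variance, implemented from
the closed form with the p-value from the t distribution. Degenerate inputs:
zero pooled variance with equal means gives t = 0, p = 1; with unequal means
p = 0 with a warning. Calibration is checked empirically: 10,000
same-distribution replicates at n = 10/group must reject at 4–6% for
α = 0.05.

## Synthetic data: what it emulates, and what it does not

The genome generator plants one provirus (defaults: 100-kb chromosome,
17.9-kb element, 27-nt att, tRNA on attL, integrase 200 bp inside attR, two
shorter decoy repeat pairs) in an i.i.d. uniform background (GC configurable,
e.g. 0.48 to mimic an *Archaeoglobus* host). The bases immediately flanking
each planted att copy are forced to differ so the maximal repeat equals the
planted att exactly, keeping "exact boundary recovery" well defined. Random
100-kb backgrounds still contain chance ~15-nt repeat pairs, so recovery is
asserted as "the planted pair is found with exact boundaries and is the
top-scoring call", not as the only candidate. The protein generator draws
per-group Poisson sequon counts and builds backgrounds without asparagine,
so counted = planted exactly. The structure generator places CA atoms on a
3.8-Å self-avoiding walk with idealized side-chain pseudo-atoms and then
relocates specific atoms to create bridges (3.0 Å) and packed clusters
(pairwise ≲ 2 Å); side-chain geometry is deliberately not stereochemically
realistic. None of the generators emulate real genome composition, codon
structure, repeat families, or real protein packing — passing tests
demonstrate algorithmic correctness on the stated model, not performance on
real annotation quality or real structural models. Each generator draws from
its own named stream of a single integer seed, so outputs are byte-identical
under a fixed seed and adding a generator never perturbs existing fixtures.

## Problem sizes and numerical choices

The recovery sweep uses 100 seeds at the default 100-kb/17.9-kb
configuration. Oracle-equivalence checks use 20 genomes of 12–30 kb with a
narrowed element window (the per-diagonal oracle scales with window width ×
genome length), 50 toy structures of 45 residues, and 1,000 random 300-aa
proteins. Statistical calibration uses 10,000 null replicates and 200 power
replicates, matching the group sizes the comparison is designed for. Ties in
sorting are fully ordered everywhere (documented in each function) so every
output is deterministic.

## Pipeline

`run_pipeline` composes find → excise → annotate → synteny → signatures from
one YAML config, validated with all errors reported at once. Outputs are
stage-named TSV/GFF3/FASTA/SVG files, each table with a JSON sidecar naming
its column schema, plus a manifest recording the package version, a config
hash, and SHA-256 checksums of every output; identical configs reproduce
identical checksums. Note that circles excised from decoy-level calls feed
the downstream stages too; tightening `finder.min_repeat_len` restricts the
run to high-confidence elements.

## Known limitations

- Only exact direct repeats are guaranteed maximal; the mismatch mode is
  greedy and may report suboptimal extensions.
- Origin-spanning repeats on circular chromosomes are not detected.
- tRNA and integrase features must be supplied (GenBank/GFF3); the package
  does not predict them, and integrase recognition from annotations is
  keyword-based (`integrase`, `recombinase`, `XerC/XerD`; configurable).
- Identity shading uses one global-alignment parameterization; it is not a
  homology search and will miss remote homologs a profile method would find.
- The exposure proxy correlates with, but does not equal, solvent
  accessibility; absolute exposed-fraction values should be compared only
  within this package.
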