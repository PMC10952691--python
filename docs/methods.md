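# Methods

This note documents the models, conventions and design choices behind
`thiotraits`, in the order the pipeline uses them.

## The trait expression language

A functional trait is called Present in a genome iff a boolean expression
over gene symbols is satisfied by the genome's annotated gene set.  The
grammar is

    expr := alt
    alt  := conj (',' conj)*          # comma = OR, binds lowest
    conj := term+                     # juxtaposition = AND
    term := ('+' | '-')? atom
    atom := SYMBOL | '(' expr ')'

with three semantic rules that matter:

* **Unsigned atoms are required.**  This is forced by pure-OR cells such
  as `apeE,fhaC,yadA` (a type V secretion system is present if any of the
  three autotransporter genes is) — an unsigned atom inside an OR must
  still demand its gene.
* **`-` means "not required", never negation.**  A `-`-signed gene is
  recorded (it appears in `ignored_optional` of the evaluation result) but
  has no effect on the call.  The language is therefore *positive*:
  enlarging a gene set can only turn Absent into Present, never the
  reverse.  A strict mode asserting the *absence* of `-`-signed genes is
  deliberately not implemented; the catalogue's wording supports the
  ignore reading, and a negative-constraint semantics would break
  monotonicity and the witness-construction used by the simulator.
* **Comma binds lower than juxtaposition.**  Verified consistent with
  every catalogue cell: commas occur only inside brackets or in pure-OR
  cells.

Failing calls are explained by `missing_required`: for a conjunction, the
union of missing genes over its failing required terms; for an
alternation, the branch with the fewest missing genes (ties: first in
printed order).  This is a minimal *explanation*, not a minimal repair
set.

Text normalization strips all whitespace and maps the Unicode hyphen
variants U+2010–U+2013 and U+2212 to ASCII `-`; typeset tables routinely
use U+2010, so this step is mandatory before tokenization.

Macros are expanded only through an explicit macro table; the packaged
table has a single entry, `ndhA_to_ndhN` → the fourteen NADH-dehydrogenase
subunit genes `ndhA`…`ndhN`.  No generic `_to_` pattern inference is
attempted (too error-prone for arbitrary symbols).

## The packaged catalogue

`thiotraits/data/trait_catalog.tsv` holds the 46 trait definitions
(5 columns: Id, TraitGroup, TraitName, ShortTraitName,
GeneTraitComposition) transcribed character-for-character, including the
spelling `shdA` in the cytochrome-bd row; a checksum test pins the
transcription.  `published_calls.tsv` carries the two published
Present/Absent columns (31 Present for the ectosymbiont, 39 for the
free-living strain, 24 shared).

**Aliases.**  Gene symbol matching is exact and case-sensitive.  An alias
table (symbol → canonical symbol) is applied to *both* the genome's gene
set and the expression atoms at evaluation time, so that an annotator's
`sdhA` satisfies the catalogue's `shdA`.  Canonicalizing only the gene set
could never repair a typo that lives in the catalogue itself, which is why
both sides are mapped.  The packaged table contains exactly the
`shdA → sdhA` entry and can be disabled (`use_aliases=False`,
`--no-aliases`).

One catalogue row is intentionally ambiguous in its source: the
polyphosphate trait is *named* "PHK and PHX" but its expression is
`PHK, PHX`.  We follow the expression (comma = interchangeability = OR);
the row is flagged here rather than silently edited.

## Trait calling and counting

`call_traits` evaluates all 46 expressions per genome; a genome with an
empty gene set yields all-Absent calls (warning-level event, not an
error).  Because the language is positive, a genome whose gene set is a
superset of another's has a superset of Present traits — this subset
property is the formal core of the "the symbiont's capabilities are a
subset of its relative's" style of analysis, and is property-tested.
Shared counts are plain set intersections of Present sets;
`shared(A, A) = count(A)` by construction.

## Assembly statistics

* **N50**: sort contig lengths descending, return the length at which the
  cumulative sum first reaches ≥ half the total.  This is the most common
  convention; where a published table used another convention the third
  significant digit could differ.
* **GC content**: (G+C)/(A+C+G+T), case-folded, with N and all other
  ambiguity codes excluded from numerator *and* denominator.  Reported
  percentages are rounded half-up to one decimal for TSV output; JSON
  keeps full precision.
* **GC skew**: (G−C)/(G+C) per window, default 1000 bp non-overlapping
  (step = window), windows with no G or C marked NaN.  Defined values lie
  in [−1, 1] and negate under reverse complement (windows re-anchored from
  the other end) — both property-tested.
* **Percent reduction**: (1 − a/b)·100, reported raw and rounded half-up
  to the nearest integer.  On the study's printed assembly sizes
  (2,381,364 vs 3,528,654 bp) this gives 32.51 → 33%, and on the CDS
  counts (2486 vs 3452) 27.98 → 28%.

## Alignment, RBH and AAI

* Protein pairs: Smith–Waterman local alignment, BLOSUM62, gap open 11,
  extend 1 (BLAST-like defaults).  `X` is scored 0 against everything.
  Identity = identical columns / aligned columns, **gap columns included
  in the denominator** (the BLAST `pident` convention).  A pair with no
  positive-scoring local alignment is returned as an explicit
  no-alignment result, not an exception.
* RBH: each query's best hit is chosen by score, then identity, then
  lexicographically smallest id (fully deterministic); a pair is kept iff
  mutual-best and identity ≥ 30% and coverage of the shorter sequence
  ≥ 70% (CompareM-like defaults, configurable).  A shared-5-mer prescreen
  (≥ 1 shared 5-mer) restricts the all-vs-all alignment to plausible
  pairs; at 50% identity and ~300-residue proteins the chance that a true
  pair shares no 5-mer is ~10⁻⁴, while unrelated pairs almost never pass,
  so the screen changes essentially nothing but the runtime.  Disable
  with `prescreen_k=0`.
* AAI = arithmetic mean identity over RBH pairs.  Alignments are computed
  once per candidate pair and reused for both best-hit directions (the
  score matrix is symmetric), which makes `aai(A, B) = aai(B, A)` exact.
* Nucleotide identity: Needleman–Wunsch global alignment, match +5,
  mismatch −4, gap open 10, extend 0.5 (EDNAFULL-like), identity over all
  aligned columns; the aligned-column count is reported so "x% identical
  over N aligned positions" statements are reproducible.  Note that a
  published 16S identity computed after multiple alignment and trimming
  is a *different* procedure; direct global pairwise identity is a
  consistency check against such numbers, not an exact reproduction.
* Greedy identity clustering: sequences visited longest-first (ties:
  smallest id); each joins the first cluster whose representative it
  matches at ≥ the threshold (default 98.65%, the standard 16S species
  cutoff), else founds a new cluster.  Every member therefore matches its
  representative at ≥ threshold, which is re-asserted by alignment in the
  tests.

## Comparison reports

Euler counts and subset fractions are plain set arithmetic; granularities
not supplied are marked absent (`null` in JSON), never zero.  Mobilome
counting matches product descriptions case-insensitively against two
keyword vocabularies (phage: phage, prophage, capsid, tail protein,
terminase, portal; other MGE: transposase, insertion sequence, integrase,
recombinase, mobile element, plasmid).  A product matching both
vocabularies — "phage integrase" is the canonical offender — counts as
phage only, so every matched gene is counted exactly once.  The lists are
data, not code, in spirit: both are overridable per call.  COG counting
tallies a gene once per category letter; untagged genes go to
`unassigned`.

## Simulators

All generators draw from numpy's seeded PCG64 stream; identical
configurations give byte-identical outputs, and every generator returns a
truth object verifiable from its own output (closed loop).

* **Assemblies**: i.i.d. bases with P(G)=P(C)=gc/2; lognormal contig
  lengths (default 46 contigs, mean 52 kb, σ=0.8 — the shape of a
  mid-sized reduced bacterial draft genome).  With ≥ 100 kb the realized
  GC is within ~0.5 points of target.
* **Diverged pairs** (proteomes and nucleotide): per-site substitution
  with probability (100 − target)/100, substitutions uniform over the
  other letters, *no indels* — so the expected identity equals the target
  exactly and the truth map's realized identities are exact column
  recounts.  An indel-free model is what makes the AAI parameter-recovery
  test analytically clean; real proteome divergence also involves indels,
  domain shuffling and paralogy, so passing it shows estimator
  correctness under the model, not annotator-grade robustness.
* **Presence tables**: for a prescribed Present/Absent trait vector, each
  Present trait contributes a witness gene set (cheapest OR-branch first);
  the union is checked against every Absent trait and OR-branches are
  re-chosen by seeded random restarts on conflict (cap 200).  The output
  is verified by `call_traits` before being returned, so a successful
  generation is a proof of feasibility.  Decoy symbols outside the
  catalogue universe are added for realism.  A full SAT encoding was
  considered and rejected as unnecessary at this catalogue size — in
  practice both published columns succeed on the first, deterministic
  attempt, and random vectors essentially always converge because gene
  sharing between traits is limited to a handful of TCA/glyoxylate/
  succinate-dehydrogenase genes.
* **Annotation tables**: exactly the requested numbers of phage and
  other-MGE products are planted (drawn from the two vocabularies), the
  rest are neutral products that match neither list; COG letters are
  sampled from a configurable distribution (default: uniform over 20
  letters with a 15% unassigned fraction, ~5% dual-letter genes).

## Problem sizes used in the test suite

The statistical tests run at sizes where the expected behaviour is sharp
but cheap: AAI parameter recovery uses 100 proteins of mean length 300
over targets {50, 70, 90}% × seeds 1–10 (mean absolute error ≤ 2 points);
the exhaustive expression-oracle check enumerates all subsets for every
catalogue expression with ≤ 12 mentioned genes (41 of 46) and samples the
rest; the presence round trip covers both published columns plus 100
random vectors; simulated assemblies for the statistics checks use the
published contig counts and GC values (46 contigs / 49.4%,
25 / 61.9%).

## Known limitations

* Trait calling consumes annotator output; nothing is inferred from raw
  sequence, and disagreements between annotators' naming conventions must
  be handled through the alias table.
* AAI defaults are CompareM-*like*; published AAI values computed with
  other aligners/thresholds will differ by a few points.
* Accession-based checks (recomputing published N50/GC from deposited
  assemblies) require downloading those assemblies and are therefore not
  part of the test suite; the same code paths are exercised on simulated
  assemblies with matched shape instead.
* The greedy clustering is O(n·k) alignments (k clusters) and is meant
  for marker-gene scale, not metagenome scale.
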