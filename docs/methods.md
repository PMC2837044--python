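# Methods

## The motif and its coordinates

A C2H2 zinc finger is modelled purely at sequence level as four anchors
C1 < C2 < H1 < H2 with bounded spacings; a CWCH2 finger additionally has
tryptophan at C1+2. A tandem CWCH2 (tCWCH2) is an adjacent CWCH2 pair
whose **linker** — the residues strictly between ZF1's last histidine and
ZF2's first cysteine — falls within bounds. Derived features per tandem:

* **ϕ1/ϕ2** — the single residue at H1+1 of each finger. The worked
  64-aa consensus carries V and I exactly there, matching the top of the
  published ϕ-frequency tables, which fixes this definition.
* **extra sequence** — intra-cysteine residue count minus 4 (the typical
  x-W-x-x content), floored at 0.
* **TGE(K/R)P** — regex `TGE[KR]P` on the linker.

Internally all coordinates are 0-based half-open; every rendered report
(TSV/JSON/CLI) is 1-based inclusive.

## Spacing presets

Bounds are stored as counts of residues strictly between anchors. The
`strict` preset transcribes the survey pattern
`xCxWx(2,35)Cx(5,15)Hx(2,5)Hx(5,25)CxWx(1,3)Cx(5,17)Hx(2,5)Hx`:
ZF1 C→C 4–37, C→H 5–15, H→H 2–5; linker 5–25; ZF2 C→C 3–5, C→H 5–17,
H→H 2–5. The `loose` preset widens to linker 5–42, ZF2 C→C 3–8 and
C→H 5–31 (ZF1 C→C 3–37). Single-finger detection uses the union of the
two roles' bounds; pairing then enforces the role-specific bounds.

Detection is a left-to-right greedy scan: at each candidate cysteine the
lexicographically smallest feasible (C2, H1, H2) triple is taken and the
scan resumes after the finger. Pairing is likewise left-to-right and each
finger joins at most one tandem — consistent with proteins that carry two
disjoint tandems (ZF1-2 and ZF3-4 arrays). Greedy smallest-anchor choice
makes annotation deterministic and coincides with the `nonoverlapping`
reduction of the pattern engine (see below); on sequences where the
pattern admits several overlapping placements, `match_pattern(...,
mode="all")` is the exhaustive reference.

An unknown residue `X` in a subject sequence matches any pattern literal
(database sequences contain X and wildcard positions are arbitrary).

## Pattern engine

Patterns are token lists of literals (single residues or classes, both
`[KR]` and `(K/R)` notations accepted) and bounded gaps (`x`, `x(m)`,
`x(m,n)`). Matching enumerates **all distinct literal-anchor tuples** by
backtracking with memoisation on (element, position); this is a defined
semantics rather than an attempt to mimic any particular search engine's
internal greediness, which is unspecified. For a given anchor tuple the
reported span takes minimal lengths for gaps outside the outermost
literals. `nonoverlapping` mode greedily selects span-disjoint matches
left to right, preferring the smallest anchor tuple at each start; it is
provably a subset of `all`. Correctness is checked against a naive
enumerate-every-placement oracle: exhaustively for all sequences over
{A,C,H,W} up to length 7 plus seeded random sequences up to length 60 and
random patterns (the full 4^15 enumeration is out of reach on a desk
budget; the memoised matcher has no length-dependent branching that the
covered lengths would miss).

## Segment-header linker arithmetic

For `NAME/start-end` aligned-segment headers, consecutive segments of one
protein give a linker length. The default convention is strictly-between
(`next.start − prev.end − 1`), consistent with the His→Cys linker
definition; the literal subtract convention (`next.start − prev.end`) is
available via `convention="subtract"`. Lengths > 41 aa are excluded
(taken to separate independent finger arrays); negative lengths (from
overlapping segments) are discarded with a warning.

## Statistics

* SDs are sample SDs (n−1) throughout.
* Mann-Whitney U is two-sided; the null distribution is exact for
  tie-free samples with n_a+n_b ≤ 12, otherwise normal approximation with
  tie and continuity corrections (scipy). U is reported for the first
  sample. An independent rank-enumeration oracle cross-checks the exact
  branch in the tests.
* The F test reports F = var(a)/var(b) with a two-sided p from the
  F(n_a−1, n_b−1) distribution.
* The ϕ-enrichment chi-square is a 2-category (df = 1) goodness-of-fit on
  counts inside vs outside the hydrophobic set — {V,L,I} at ϕ1,
  {V,L,I,M} at ϕ2, the residues whose published frequencies are summed —
  with expected counts from the background table scaled to the observed
  total. The 20-category per-residue statistic is exposed as a secondary
  value in `extras`. A p-value below float range is reported as the string
  `"< 1e-300"` alongside the 0.0 float.
* Tryptophan conservation locates each family member's finger pair with
  the W requirement relaxed, then scores W at both C1+2 positions;
  members with no locatable pair count against conservation, with a
  warning. No multiple-testing correction is applied anywhere.

## Consensus procedure

Alignments are inputs (aligned FASTA or Clustal; building the alignment
is out of scope so results do not depend on a bundled aligner). Columns
with gap fraction **strictly** above the threshold (default 0.5) are
removed; each remaining column contributes its most frequent non-gap
residue, ties breaking to the lexicographically smallest for determinism.
Gaps are never consensus candidates but do appear in the reported
per-column frequencies.

## Synthetic-data generator

The generator emulates the survey's summary statistics, not real protein
families; it makes no attempt at homology structure, domain context
outside the motif, or realistic global composition.

* **Record layout**: flank + ZF1 + linker + ZF2 + flank, with
  C x W x(2+extra) C spacer H ϕ x x H per finger. Spacers are 5–15 aa with
  a central phenylalanine (the conserved hydrophobic of the classical
  C2H2 consensus); ZF2's intra-cysteine count is 3–5. Filler residues are
  uniform over the 18 letters excluding C and H, so random filler cannot
  create unintended fingers.
* **Linkers**: a normal draw rounded to integer and rejection-truncated
  to the model bounds — tcwch2 preset 11.8 ± 4.4 on [5, 37], background
  preset 8.1 ± 5.0 on [1, 41]. Truncation shifts the realised mean above
  the nominal centre (analytic means 12.27 and 8.77); the analytic mean
  of the declared model, available as
  `LinkerModel.expected_mean(lo, hi)`, is therefore the reference value
  for recovery tests, not the nominal centre.
* **ϕ residues** are drawn from the published tables with the unprinted
  remainder spread uniformly over the other residues (a declared
  emulation choice; only the printed V/L/I/M shares are data).
* **TGE(K/R)P**: in full records the pentamer (K or R with equal odds)
  replaces the first five linker residues of background records at the
  configured rate where the linker is long enough — length-neutral, so
  the linker-length distribution is untouched, at the cost of a realised
  carrier share slightly below nominal. The linker-collection sampler
  `sample_background_linkers` instead makes the rate exact by resampling
  carrier lengths to ≥ 5 aa, emulating an alignment-derived linker set
  with a stated carrier share. Use the former to study lengths, the
  latter to study carrier rates.
* **Decoys**: `w_to_g` (ZF1 tryptophan → glycine: fingers remain, tandem
  lost), `spacing_violation` (linker forced to 40 aa: invisible to
  strict, visible to loose), `single_finger` (truncation after ZF1).
* **Self-check**: every record is rescanned with the preset's promised
  spacing configuration (strict for the tcwch2 preset; strict with linker
  bounds 1–41 for the background preset) and resampled on any mismatch
  (bounded retries). Planted motifs are therefore recoverable by
  construction, and the tcwch2 linker distribution is effectively further
  truncated at 25 aa — removing ~0.09% of mass and shifting the analytic
  mean by ~0.01 aa. All sampling comes from one `numpy` generator seeded
  by the config, so output is byte-identical across runs for a given
  seed.
* **Perturbed alignments** (`perturbed_alignment`) wrap a template with
  per-cell substitutions (default 10%), template-column gaps placed with
  exact counts ≤ 40% of rows, and interleaved majority-gap decoy columns
  (> 50% by exact count), so the gap filter's keep/drop decisions are
  deterministic while the modal residue remains the template's with
  overwhelming probability at 200 rows.

## Problem sizes

The validation suite uses the sizes at which the checked properties are
statistically meaningful on a desk budget: exhaustive pattern-oracle
equivalence to length 7 plus sampled longer sequences; 1000 records for
exact recall/precision; 10 000 records for ϕ-frequency recovery and 5000
per arm for linker means and the location test (3-SE bands); 200
alignment rows for consensus recovery. The acceptance script mirrors
these sizes.

## Known limitations

* The annotator is sequence-only; it cannot confirm the hydrophobic core
  structurally, and non-C2H2 zinc-finger classes are out of scope.
* Greedy smallest-anchor assignment is a convention; in C/H-dense regions
  a different feasible anchor assignment may exist (the pattern engine's
  `all` mode enumerates them).
* Passing tests on generator output shows the pipeline recovers the
  declared statistical structure; real proteomes add compositional bias,
  degenerate fingers and multi-tandem arrays that the generator only
  partially represents (decoys and two-finger records).
* The strict preset transcribes one survey pattern; families whose
  spacing falls outside it (e.g. tandems interrupted by intervening
  fingers) require the loose preset or custom bounds and may still be
  missed.
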