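# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `adaseed`, module by module.

## Seed patterns and matching semantics

A seed pattern is a string over `{0, T, 1}`. Against a gapless
alignment column, `1` accepts only a base match, `T` accepts a match or
a transition (A↔G, C↔T), and `0` accepts anything. The weight
(#`1` + ½·#`T`) is stored as twice-weight in integer form so that
design never compares half-integers through floating point. A seed
*set* hits an alignment if any pattern matches at any allowed start
offset; with seeding sparsity c only offsets ≡ 0 (mod c) are allowed.

Patterns may legally begin or end with `0` (trimming produces such
patterns); parsing warns but does not reject. Note that trimming a
pattern to its shortest cyclically-regenerating prefix is **not**
idempotent: `1011` trims to `101` (because `10` extends to `1010`, not
`1011`), and `101` itself trims to `10`. The fixed points of trimming
are the primitive patterns; round-trip properties hold for those.

## Exact sensitivity

The alignment model is i.i.d. over the three letters (transversion,
transition, match); the probability triple is always ordered
(p_v, p_s, p_m) to avoid silent permutation bugs. Sensitivity for
length l is P(the seed set hits a random length-l string).

It is computed exactly by building a deterministic automaton whose
states are (position mod c, set of live pattern-prefix items), where a
live item (pattern, j) means the last j letters match the pattern's
first j symbols starting from an allowed offset. New items are seeded
only at offsets ≡ 0 (mod c); completing any pattern enters a single
absorbing accepting state. A forward probability vector is then pushed
through the transition table l times. State counts stay small (tens to
a few thousand) for the spans (≤ ~24) and set sizes (≤ ~16) this
package targets; probabilities stay in double precision, which is ample
for l up to a few hundred.

The independent oracle (`sensitivity_bruteforce`) re-derives matching
from the pattern symbols and sums the probability of every hit string,
pruning the search tree at the first position where a hit completes
(all extensions of a hit prefix are hits, with total probability equal
to the prefix probability). It is exact and guarded to l ≤ 14.

Monotonicity facts used by the tests: sensitivity is non-decreasing in
l (the accepting state is absorbing), non-decreasing under adding a
pattern, and sparsity c > 1 never beats c = 1.

## Seed design

Design is random-restart greedy hill climbing over fixed-weight
patterns with spans in [span_min, span_max]:

- initialization: uniformly random feasible symbol counts
  (k1 ones, kT T's with k1 + kT/2 = weight), shuffled; the first and
  last symbols are forced non-`0` when at least two non-`0` symbols
  exist (with a single one, only the first position is forced);
- neighborhood (weight-preserving, span-preserving): swap two unequal
  symbols; replace a `1` by two `T`s (at the `1` and at a `0`);
  replace two `T`s by a `1` and a `0`;
- multiple patterns are climbed coordinate-wise against the *joint*
  sensitivity, sweeping until no single-pattern move improves; ties are
  broken toward the lexicographically smaller pattern text so runs are
  reproducible.

The climb never worsens its start, so the reported sensitivity is ≥
that of every initialization; the best-so-far history is returned.
Restarts default to 200 — a desk-scale default chosen so that design
runs complete in seconds to minutes; the search is heuristic either
way, with no optimality guarantee (exhaustive design over
transition-constrained multi-seed spaces is infeasible). The objective
is plain length-l Bernoulli sensitivity; defaults l = 64, and the
bundled examples use the foreground models (0.12, 0.18, 0.70)
(a 3:2 transition:transversion ratio at 70% identity, typical of
diverged mammal genomes) and (0.15, 0.15, 0.70). The designed 3:2 sets
come out with many `T` positions — more transition positions than
fixed-low-T designs, which is exactly why they help on mammalian
divergence.

## Subset suffix arrays and adaptive seeds

Lowercase letters (repeat masking) and every non-ACGT character are
replaced by N before indexing or alignment, so repeats neither seed nor
score as matches.

One index is built per seed pattern (memory is linear in the number of
patterns). Sampled positions (every w-th) are sorted by their suffix
*transformed* under the cyclically extended pattern: at a `1` position
the four bases are distinct classes, at a `T` position the classes are
{A,G} and {C,T}, at a `0` position all bases are one class, and N is a
terminator that ends comparison (and sorts first). Realizing the `T`
classes as a per-position alphabet remap keeps every narrowing step a
single contiguous suffix-array interval — which is also why `0`
positions are one class rather than a 4-way union. Positions whose
first transformed letter is N are excluded. Sorting materializes
(positions × depth) class keys and argsorts them as fixed-width byte
strings; the comparison depth is capped (default 512, configurable) and
match lengths are capped at the same depth, so search never relies on
unsorted depths. The benchmark uses depth 64: at the genome sizes and
rareness thresholds it runs, adaptive seeds terminate at far shallower
depths.

Adaptive seeds: from every k-th query start, the suffix-array interval
is narrowed one pattern position at a time (two binary searches per
step) until at most m indexed positions remain; all of them are emitted
at that minimal length. If the count never drops to m before the query
ends, an N is hit, or the depth cap is reached, the start emits
nothing — the stricter of the two possible conventions. Because
sparser indexing (larger w) lowers occurrence counts, seeds stop at
*shorter* prefixes; the containment that holds is that every w = 1
match at an indexed-under-w position is also found under the sparser
index, not the converse.

The quadratic reference matcher (`adaptive_seeds_bruteforce`) re-derives
all of this by scanning every reference position and is used to verify
the suffix-array path on small inputs.

## Extension and alignment

Scoring schemes carry a symmetric 4×4 substitution table, affine gap
costs (a gap of length g costs gap_exist + gap_extend·g, so 7/1 prices
a single-base gap at 8), a minimum reported score, an N-score applied
to N against anything (including N), and optionally the score-matrix
scale factor t. The two stock schemes are +1/−1, gaps 7/1, minimum 35,
N = −1 (default gapless drop y = 10, a package choice) and HoxD70
(Chiaromonte, Yap & Miller 2002), gaps 400/30, minimum 4000, N = −100,
t = 96.1735, y = 962, gapped drop 3999.

**Gapless extension** proceeds left and right of the seed span, each
direction stopping when the running score falls more than y below its
maximum; the extended span is then trimmed to its maximal-score
contiguous subsegment (leftmost on ties). Only segments scoring at
least the gapless threshold d go on to gapped extension. The default
d = round(t·ln(m·r/(10·n))) — with m the rareness threshold, n the
number of patterns, r the unmasked reference size — is a reconstruction
of the standard rule from its two published endpoints (2466 at
m = 1000, n = 1 and 1823 at m = 10, n = 8, with r = 1 363 595 724 and
t = 96.1735); it keeps the gapped phase's workload roughly proportional
to the gapless phase's, and is always overridable.

**Gapped extension** is affine-gap X-drop DP run forward and backward
from a single anchor column, with back-to-back insertions and
deletions permitted and per-row contiguous live windows (cells more
than ydrop below the running maximum are pruned; the window grows on
overflow). The best is tracked over match states only, since with
positive gap costs an optimal extension never ends in a gap. Traceback
bytes reconstruct the column path, and every reported record's score is
re-derivable from that path (tested).

**Anchor choice.** The standalone `gapped_extend` anchors by default at
the gapless segment's maximum-score column (leftmost on ties). The
pipeline, however, anchors each gapped extension at the *originating
seed's own cell*, deduplicating on (segment, anchor): the segment peak
need not lie on the optimal gapped path, and anchoring at seeds makes
the pipeline provably recover the full local-alignment optimum in the
exhaustive configuration (pattern `1`, unbounded m/y/ydrop), because
every match column of an optimal path is then itself an anchor. The
cost is one extension per distinct seed cell on a qualifying segment
rather than one per segment; X-drop pruning keeps this cheap at
realistic drops.

The pipeline per strand (the reverse-complemented query is a second
pass): adaptive seeds → batch gapless extension → keep segments ≥ d →
gapped extension per (segment, seed anchor) → keep records ≥ the
scheme's minimum → merge records with identical coordinates keeping the
best score → sort by score. Overlap handling beyond exact-coordinate
merging (chaining, netting, paralog removal) is out of scope.

A note on the gapless gate: with d equal to the reporting minimum, an
alignment whose optimal path contains no gapless stretch scoring ≥ d
cannot be found by *any* gapless-gated seed-and-extend procedure; the
equivalence tests therefore generate pairs diverged gently enough
(6–8% substitutions over 120–200 bp, at most one short indel) that the
homology retains a qualifying gapless core.

## Synthetic genome pairs and the benchmark

The simulator draws an i.i.d. uniform ACGT ancestor, optionally
overwrites a configurable fraction with copies of other segments
(lowercased, so repeats are self-similar and masked like real
repeat-annotated genomes), then derives a copy: per-column
substitutions with P(transition) : P(transversion) in the configured
ratio (identity + p_s + p_v = 1), and indel events at a per-base rate,
insertion or deletion with equal probability, geometric lengths
(default mean 3). The column-level truth alignment is recorded during
simulation, so substitution-rate counting is independent of any
re-alignment. Defaults (identity 0.70, ts:tv 3:2 → 70/18/12,
indel rate 0.02, repeat fraction 5%) emulate diverged mammal genome
pairs. What the simulator does *not* emulate: composition bias and CpG
context effects, rate heterogeneity along the genome, large-scale
rearrangements and duplications, and realistic repeat families —
so benchmark results here validate machinery and qualitative parameter
response, not absolute sensitivity on real genomes.

`count_substitutions` classifies aligned ACGT column pairs (gaps, N and
other letters excluded from the denominator) into identities,
transitions (A↔G, C↔T) and transversions; among all 12 ordered
mismatching base pairs the unbiased split is 4:8, i.e. 1:2
transitions:transversions, which the counting reproduces exactly.

The chunk benchmark samples random chunks (default 1 kb) with start
positions drawn without replacement, rejecting chunks containing any
non-ACGT uppercase letter (lowercase is allowed — masking happens at
alignment time). Each config aligns every chunk; a config's error
count is the number of chunks where its best score is below the
per-chunk maximum over all configs. Wall time is recorded but never
asserted. The acceptance-scale run uses 500 chunks of 1 kb against a
1 Mb pair at the default divergence, seed sets nested as
{p1} ⊂ {p1, p2}, m ∈ {10, 100, 1000}, query step k = 8, y = 10, d = 25,
ydrop = 40 under the +1/−1 scheme — sizes chosen so the whole suite
runs on a laptop-class single core in a few minutes; error counts are
non-increasing in m and in n, the qualitative shape expected of
rarer-seed thresholds and added codesigned patterns.

## Numerical and degenerate-input choices

- Sensitivity DP uses plain double precision; brute-force agreement is
  asserted to 1e−12.
- Empty alignments (l = 0) have sensitivity 0; an empty query or empty
  index yields no seeds; an all-N query aligns to nothing.
- Ties in design are broken lexicographically; ties in gapless trimming
  leftmost; ties in the gapped best-cell toward the earlier row/column.
- The X-drop window starts at 2·(ydrop/gap_extend) + 8 columns and
  doubles on overflow, so unbounded-ydrop runs degrade gracefully to
  full DP.
- Indexing every w-th position with w > 1 plus query step k > 1
  composes; strand handling is by aligning the reverse-complemented
  query, never by touching the index.

## Known limitations

- Gapless-gated search cannot report alignments with no gapless core ≥
  d (inherent to the method family, see above).
- The hit automaton's subset construction can blow up for many long
  patterns at large sparsity; it is intended for design-scale inputs.
- No E-values: scores only, with the minimum-score cutoffs of the two
  stock schemes; the scale factor t is taken as given, never estimated.
- No chaining/netting, no interpolation between alignments, no
  compressed indexes; single reference sequence per index.
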