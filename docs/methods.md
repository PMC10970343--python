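# Methods

## The model

`catseq` compares DNA sequences without aligning them.  Each sequence is
summarised once by a constant-size **CAT profile** — three `(D, H)`
coordinate pairs, one per reference benchmark — and any two sequences are
then compared in constant time from their profiles alone.  The intended use
is as a pre-filter in large sequence stores: profiles are computed at upload
time and stored as metadata, so look-ups never touch sequence text; hits can
then be confirmed with an exact aligner.

### Benchmarks and per-position scoring

Three constant periodic reference sequences replace the data-dependent
"favorite sequence" of earlier database heuristics:

| key | period | infinite repeat |
|-----|--------|-----------------|
| A | `ACGT` | `ACGTACGT…` |
| T | `GTAC` | `GTACGTAC…` |
| C | `AGTC` | `AGTCAGTC…` |

The periods are chosen so the A- and T-benchmarks never agree at any
position, while the C-benchmark agrees with each at exactly one position in
four.  A query base at position *i* is scored against a benchmark by the
circular offset *d* of the base's position within the period from
*i* mod 4: offset 0 is an exact match (score 1, no near score), offsets 1
and 3 are the adjacent neighbours (near score 0.6), offset 2 is the far
neighbour (0.4).  The near-score table `base_distance = [0, 0.6, 0.4, 0.6]`
is configurable; the wrap-around (circular) neighbour rule is used because
the benchmarks are infinite periodic repeats, so "left of position 0" is
well defined.

### Match accumulation with a previous-match bonus

One left-to-right pass per benchmark accumulates match mass with a
positional weighting: a match that follows other matches is worth more,
which sharpens profile uniqueness.  With all accumulators starting at 0:

```
nearMatches        += nearMatch  + prevMatches * nearMatch
exactMatches       += exactMatch + prevMatches * exactMatch
prevMatches         = sequencePrevLength/(i+1) + exactMatch + nearMatch − minPoint
bonusTotal         += (i == n−1) ? 0 : prevMatches
sequencePrevLength += prevMatches
```

and the normalised match measure is

```
dnaDistance = (nearMatches + exactMatches) / (bonusTotal + n)
```

`minPoint` defaults to 0.4, the smallest nonzero match score, so a bare far
match is bonus-neutral; it is recorded in profile provenance and
configurable.  The recurrence is applied literally, including the exclusion
of the last position from `bonusTotal`; `prevMatches` can go negative early
in a poorly matching sequence, which is permitted but flagged
(`MatchAccumulators.went_negative`) so pathological inputs are visible.

### Trilateration

The three benchmarks are treated as reference points a unit distance apart.
For each benchmark key X (cyclic successor order C→A→T→C) the triangle with
sides `d_near = dnaDistance(X)` and `d_far = dnaDistance(successor(X))`
over the unit base is solved with the law of cosines:

```
cos α = (d_near² + 1 − d_far²) / (2·d_near)
D     = d_near · cos α
H     = sqrt(d_near² − D²)
```

`(D, H)` — foot of the altitude and altitude — are the stored leg for X.
The three side lengths are not guaranteed to satisfy the triangle
inequality, so `cos α` is clamped to [−1, 1] and the radicand floored at 0;
profiles record when clamping occurred.  When `cos α` is not clamped the
Pythagorean identity `D² + H² = d_near²` holds to 1e−9 and is tested.  A
zero side yields the degenerate leg (cos 1, D 0, H 0), flagged.

Which two of the three distances form each leg's triangle is a genuine
design choice; the cyclic C→A→T→C pairing is tagged `"cyclic-CAT"` in every
profile's provenance, and the comparison layer refuses profiles whose
provenance (periods, scoring constants, pairing) differs, so incompatible
profiles are never silently compared.

### Comparison

For profiles *p*, *q*:

```
result_X  = sqrt((p.X.D − q.X.D)² + (p.X.H − q.X.H)²),  X ∈ {C, A, T}
raw       = 1 − (result_C + result_A + result_T) / 3
percent   = 100 · clamp(raw, 0, 1)
```

Identical profiles give exactly 100%. The raw value can go negative for very
distant profiles; it is exposed for diagnostics while the percent is clamped
to [0, 100].  Two profiles count as a *full match* when every per-benchmark
distance is strictly below 1e−12, a floating-point stand-in for exact
profile equality.

## Collision analysis

A collision is a pair of distinct equal-length sequences whose profiles
compare as a full match.  `collision_experiment(n, sample_size, seed)`
enumerates all 4ⁿ sequences, profiles them with a vectorised batch path
(bit-identical to the scalar path — tested), draws `sample_size` query
indices without replacement, and counts full matches per query.  Candidate
matches are narrowed with a binary-search window on the sorted C-leg `D`
column — sound, since a full match bounds every coordinate difference by
the tolerance — then confirmed with the exact three-distance criterion.
Batches (default 2²⁰ sequences) keep memory bounded for large *n*; lengths
up to 13 fit comfortably, length 15 is reachable but takes on the order of
an hour and is not exercised by the test suite.  The per-query counts are
reported raw; an average of 1 means every query matched only itself.

Problem sizes used in the test suite: exhaustive length-5 distinctness
(1,024 profiles), length-8 with 200 queries, and the full length-10 space
(1,048,576 sequences) with 1,000 seeded queries — the latter reproduces the
collision-free result at the first row of the published experiment and runs
in a few seconds thanks to the vectorised path.

## Baselines

Needleman–Wunsch global alignment (full dynamic programming, linear gap;
defaults match=1, mismatch=−1, gap=−1 since no published scheme is attached
to the method; traceback ties broken diagonal → up → left for determinism)
and Knuth–Morris–Pratt substring search are included as the exact baselines.
Both are validated against independent oracles: exhaustive recursion over
all gapped alignments for NW on small pairs, naive sliding-window search for
KMP.  The performance claim — profile comparison cost flat in sequence
length while alignment cost grows — is asserted only as a qualitative trend
(ratios with generous slack), never as absolute wall-clock times, which are
hardware-dependent.

## Synthetic data

`generate_fixtures(n, length, seed)` draws uniform i.i.d. bases — the same
regime as the published speed experiment (100 sequences of lengths 100 to
50,000) and the natural null model for collision analysis, since exhaustive
enumeration weights every sequence equally.  Real genomic sequence is not
i.i.d. (GC bias, repeats, low-complexity tracts), so passing tests establish
the method's arithmetic and its collision behaviour over uniform spaces, not
retrieval quality on real genomes.  All generators take explicit seeds and
are fully reproducible.

## Numerical choices

- All accumulation in double precision; profiles serialise through Python's
  shortest round-tripping float repr, so a sidecar round trip is bit-exact
  and stored profiles yield bit-identical comparison results to in-memory
  ones (tested).
- Full-match tolerance 1e−12; cos clamp to [−1, 1]; altitude radicand
  floored at 0.
- Empty sequences, non-ACGT bases (rejected by default; an opt-in
  `allow_unknown` scores them 0), negative positions, and non-positive
  `dnaDistance` denominators all raise typed errors; the denominator error
  carries the accumulator state.

## Known limitations

- Similarity percent is a heuristic screen, not an alignment identity; it
  can rank near-identical sequences below a coarser match in principle, and
  negative raw similarities are truncated at 0.
- The bonus recurrence is asymmetric in position, so profile similarity is
  not invariant under reverse-complementation; strand handling is the
  caller's responsibility.
- DNA alphabet only; no protein support.
- The polygon-overlap refinement of the comparison stage (triangle-area
  intersection) is out of scope.
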