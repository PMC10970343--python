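# catseq

Alignment-free DNA sequence comparison via trilateration against constant
periodic benchmark sequences (the CAT method).

Searching a large sequence store with an exact aligner means re-running an
O(mn) dynamic program per candidate.  `catseq` instead summarises every
sequence **once**, at upload time, by a constant-size **CAT profile**, and
compares any two sequences in O(1) from their profiles alone — a fast
pre-filter whose hits can be confirmed afterwards with an exact aligner.
It is aimed at people building sequence databases or screening pipelines
who need a cheap, stable, data-independent similarity key.

## The method in brief

Three constant periodic benchmarks — A: `ACGTACGT…`, T: `GTACGTAC…`,
C: `AGTCAGTC…` — serve as fixed reference points a unit distance apart.
For each benchmark, a single pass accumulates exact (1) and near
(0.6 adjacent / 0.4 far, by circular offset within the period) match
scores, weighted by a running previous-match bonus, giving a normalised
match measure

```
dnaDistance = (nearMatches + exactMatches) / (bonusTotal + n).
```

Treating the three `dnaDistance` values as distances to the benchmarks,
the law of cosines over the unit benchmark-to-benchmark base gives, per
benchmark, the foot of the altitude and the altitude

```
cos α = (d₁² + 1 − d₂²)/(2d₁),   D = d₁·cos α,   H = √(d₁² − D²),
```

and the six numbers `{C:(D,H), A:(D,H), T:(D,H)}` are the profile.  Two
profiles compare through per-benchmark Euclidean distances:

```
result_X = √((D_X−D'_X)² + (H_X−H'_X)²),   similarity = 100·(1 − Σ result_X / 3).
```

Identical sequences score exactly 100%.  Exhaustive enumeration shows the
profiles are collision-free at the tested lengths (every query over the
full 4¹⁰ space matches only itself).  See `docs/methods.md` for the full
model, parameter defaults and limitations.

## Worked example

```
$ printf ">s1\nACGTACGTACGTACGTACGT\n" > s1.fasta
$ printf ">s2\nACGTACGTAAGTACGTACGT\n" > s2.fasta   # one substitution
$ catseq compare s1.fasta s2.fasta --raw
result_C: 0.028947
result_A: 0.025483
result_T: 0.037553
similarity: 96.933900%
raw: 0.969339
```

The three `result_*` lines are the Euclidean distances between the two
profiles' per-benchmark `(D, H)` points — zero would mean identical legs —
and the similarity is 100·(1 − their mean): a single substitution in 20
bases moves the profile slightly, giving 96.93%.

A profile store is just a JSON-lines sidecar, built once and searched
without touching sequence text:

```
$ catseq fixtures --n 100 --length 100 --seed 42 -o db.fasta
$ catseq profile db.fasta -o db.jsonl
$ catseq search s1.fasta db.jsonl --min-similarity 95
```

The collision harness enumerates an exhaustive 4^n space and counts
100%-similarity matches per random query (an average of 1 means every
query matched only itself):

```
$ catseq collide --length 8 --sample 200 --seed 123
length 8: 65536 permutations, 200 queries, average full matches 1.0
```

Needleman–Wunsch global alignment (`catseq.needleman_wunsch`) and
Knuth–Morris–Pratt substring search (`catseq.kmp_search`) are included as
exact baselines, and `catseq bench` prints informal timing comparisons.

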