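"""CAT profile construction: match accumulation and trilateration geometry.

A sequence's CAT profile is six numbers — a ``(D, H)`` coordinate pair per
benchmark — computed in two steps:

1. **Match accumulation.**  A single left-to-right pass over the sequence
   accumulates exact- and near-match mass against each benchmark.  A running
   *previous-match bonus* ``prevMatches`` inflates the contribution of a
   match that follows other matches (a positional weighting that increases
   profile uniqueness), and every bonus handed out is tracked in
   ``bonusTotal`` so the final ratio stays normalised::

       nearMatches        += nearMatch + prevMatches * nearMatch
       exactMatches       += exactMatch + prevMatches * exactMatch
       prevMatches         = sequencePrevLength/(i+1) + exactMatch + nearMatch - minPoint
       bonusTotal         += (i == n-1) ? 0 : prevMatches
       sequencePrevLength += prevMatches

   The normalised match measure is then
   ``dnaDistance = (nearMatches + exactMatches) / (bonusTotal + n)``.

2. **Trilateration.**  The three benchmarks are treated as reference points
   a unit distance apart.  For each benchmark the triangle with sides
   (distance to that benchmark, distance to the next benchmark in the cyclic
   order C→A→T→C) over the unit base is solved with the law of cosines:

       cos α = (d_near² + 1 − d_far²) / (2 · d_near)
       D     = d_near · cos α          (foot of the altitude)
       H     = sqrt(d_near² − D²)      (altitude)

   ``cos α`` is clamped to [−1, 1] and the radicand floored at 0 when the
   three lengths cannot form a triangle; profiles record whether clamping
   occurred.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .benchmarks import (
    BENCHMARKS,
    DEFAULT_SCORING,
    DNA_ALPHABET,
    BenchmarkSpec,
    ScoringConstants,
    exact_match,
    near_match,
)
from .errors import ProfileComputationError

#: Pairing convention tag recorded in provenance: leg X is the triangle over
#: (distance-to-X, distance-to-successor(X)) with successor order C→A→T→C.
PAIRING_CONVENTION = "cyclic-CAT"

_SUCCESSOR = {"C": "A", "A": "T", "T": "C"}


@dataclass
class MatchAccumulators:
    """Running sums of the accumulation pass (one benchmark)."""

    near_matches: float = 0.0
    exact_matches: float = 0.0
    prev_matches: float = 0.0
    bonus_total: float = 0.0
    sequence_prev_length: float = 0.0
    #: True if the near/exact sums ever dipped below zero (can happen when a
    #: sequence opens with a long run of far mismatches and the bonus goes
    #: negative); the literal recurrence is kept, this only flags it.
    went_negative: bool = False


@dataclass(frozen=True)
class BenchmarkLeg:
    """Solved triangle for one benchmark: side length, angle and altitude."""

    dna_distance: float
    cos_alpha: float
    D: float
    H: float
    clamped: bool = False
    degenerate: bool = False


@dataclass(frozen=True)
class Provenance:
    """Everything that determines a profile's numbers besides the sequence.

    Profiles with different provenance are never comparable; the comparison
    layer enforces equality of this record.
    """

    periods: Mapping[str, str] = field(
        default_factory=lambda: {k: b.period for k, b in BENCHMARKS.items()}
    )
    base_distance: tuple[float, ...] = DEFAULT_SCORING.base_distance
    min_point: float = DEFAULT_SCORING.min_point
    pairing: str = PAIRING_CONVENTION

    def __post_init__(self):
        object.__setattr__(self, "periods", dict(self.periods))
        object.__setattr__(self, "base_distance", tuple(self.base_distance))


@dataclass
class CatProfile:
    """Constant-size metadata for one DNA sequence.

    ``legs`` maps benchmark key → ``(D, H)``; together with ``provenance``
    this is all that downstream comparison ever reads.
    """

    sequence_id: str
    length: int
    legs: dict[str, tuple[float, float]]
    provenance: Provenance
    #: Non-semantic diagnostics (clamp/degenerate/negative flags); excluded
    #: from equality so round-tripped profiles compare equal.
    diagnostics: dict = field(default_factory=dict, compare=False)


def accumulate(
    seq: str,
    spec: BenchmarkSpec,
    constants: ScoringConstants = DEFAULT_SCORING,
) -> MatchAccumulators:
    """Run the accumulation pass of ``seq`` against one benchmark.

    The sequence is uppercased on entry; an empty sequence or a base outside
    the alphabet raises.  All accumulators start at zero.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    seq = seq.upper()
    acc = MatchAccumulators()
    n = len(seq)
    for i in range(n):
        nm = near_match(spec, i, seq[i], constants)
        em = exact_match(spec, i, seq[i], constants)
        acc.near_matches += nm + acc.prev_matches * nm
        acc.exact_matches += em + acc.prev_matches * em
        acc.prev_matches = (
            acc.sequence_prev_length / (i + 1) + em + nm - constants.min_point
        )
        if i != n - 1:
            acc.bonus_total += acc.prev_matches
        acc.sequence_prev_length += acc.prev_matches
        if acc.near_matches < 0 or acc.exact_matches < 0:
            acc.went_negative = True
    return acc


def dna_distance(acc: MatchAccumulators, n: int) -> float:
    """Normalised match measure ``(near + exact) / (bonusTotal + n)``."""
    if n < 1:
        raise ValueError(f"sequence length must be >= 1, got {n}")
    denom = acc.bonus_total + n
    if denom <= 0:
        raise ProfileComputationError(
            f"dnaDistance denominator {denom} is not positive "
            f"(bonus_total={acc.bonus_total}, n={n})",
            accumulators=acc,
        )
    return (acc.near_matches + acc.exact_matches) / denom


def triangle_legs(d_near: float, d_far: float) -> BenchmarkLeg:
    """Solve the benchmark triangle with sides ``d_near``, ``d_far`` over a
    unit base.

    Returns the leg for the ``d_near`` vertex: ``cos α``, the foot of the
    altitude ``D = d_near·cos α`` and the altitude
    ``H = sqrt(d_near² − D²)``.  When the three lengths violate the triangle
    inequality ``cos α`` is clamped to [−1, 1] (flagged); a zero ``d_near``
    yields the degenerate leg (cos 1, D 0, H 0).
    """
    if d_near < 0:
        raise ValueError(f"triangle side must be non-negative, got {d_near}")
    if d_near == 0:
        return BenchmarkLeg(0.0, 1.0, 0.0, 0.0, clamped=False, degenerate=True)
    raw = (d_near * d_near + 1.0 - d_far * d_far) / (2.0 * d_near)
    cos_a = min(1.0, max(-1.0, raw))
    clamped = cos_a != raw
    D = d_near * cos_a
    H = math.sqrt(max(d_near * d_near - D * D, 0.0))
    return BenchmarkLeg(d_near, cos_a, D, H, clamped=clamped, degenerate=False)


def benchmark_distances(
    seq: str, constants: ScoringConstants = DEFAULT_SCORING
) -> dict[str, float]:
    """``dnaDistance`` of ``seq`` to each of the three benchmarks."""
    seq = seq.upper()
    return {
        key: dna_distance(accumulate(seq, spec, constants), len(seq))
        for key, spec in BENCHMARKS.items()
    }


def compute_profile(
    seq: str,
    constants: ScoringConstants = DEFAULT_SCORING,
    sequence_id: str = "",
) -> CatProfile:
    """Compute the CAT profile of ``seq``.

    Deterministic: the same sequence and constants always give a
    bit-identical profile.
    """
    if not seq:
        raise ValueError("sequence must be non-empty")
    seq = seq.upper()
    dists = benchmark_distances(seq, constants)
    legs: dict[str, tuple[float, float]] = {}
    diagnostics: dict = {}
    for key in ("C", "A", "T"):
        leg = triangle_legs(dists[key], dists[_SUCCESSOR[key]])
        legs[key] = (leg.D, leg.H)
        if leg.clamped or leg.degenerate:
            diagnostics[key] = {
                "clamped": leg.clamped,
                "degenerate": leg.degenerate,
            }
    prov = Provenance(
        periods={k: b.period for k, b in BENCHMARKS.items()},
        base_distance=constants.base_distance,
        min_point=constants.min_point,
        pairing=PAIRING_CONVENTION,
    )
    return CatProfile(
        sequence_id=sequence_id,
        length=len(seq),
        legs=legs,
        provenance=prov,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Vectorised batch path (used by the collision harness).  Operates on base
# codes 0..3 in A<C<G<T order and mirrors the scalar recurrence exactly, so
# scalar and batch profiles are bit-identical.
# ---------------------------------------------------------------------------

def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes 0..3 (A<C<G<T order)."""
    codes = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    table = np.full(256, 255, dtype=np.uint8)
    for c, b in enumerate(DNA_ALPHABET):
        table[ord(b)] = c
    out = table[codes]
    if (out == 255).any():
        bad = int(np.argmax(out == 255))
        raise ValueError(f"invalid base {seq[bad]!r} at position {bad}")
    return out


def _accumulate_batch(
    codes: np.ndarray, spec: BenchmarkSpec, constants: ScoringConstants
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised accumulation over rows of ``codes`` (shape ``(m, n)``).

    Returns ``(near_matches, exact_matches, bonus_total)`` arrays.
    """
    m, n = codes.shape
    # canonical period index of each base code under this benchmark
    canon = np.array(
        [spec.period.index(b) for b in DNA_ALPHABET], dtype=np.int64
    )
    bd = np.asarray(constants.base_distance, dtype=np.float64)
    near = np.zeros(m)
    exact = np.zeros(m)
    prev = np.zeros(m)
    bonus = np.zeros(m)
    seq_prev = np.zeros(m)
    for i in range(n):
        d = (canon[codes[:, i]] - (i % 4)) % 4
        nm = bd[d]
        em = (d == 0).astype(np.float64)
        near += nm + prev * nm
        exact += em + prev * em
        prev = seq_prev / (i + 1) + em + nm - constants.min_point
        if i != n - 1:
            bonus += prev
        seq_prev += prev
    return near, exact, bonus


def profile_matrix(
    codes: np.ndarray, constants: ScoringConstants = DEFAULT_SCORING
) -> np.ndarray:
    """CAT profiles for a batch of equal-length sequences.

    ``codes`` has shape ``(m, n)`` with base codes 0..3.  Returns an
    ``(m, 6)`` float64 array with columns
    ``[C_D, C_H, A_D, A_H, T_D, T_H]``.
    """
    codes = np.atleast_2d(np.asarray(codes, dtype=np.uint8))
    m, n = codes.shape
    if n == 0:
        raise ValueError("sequences must be non-empty")
    dists = {}
    for key, spec in BENCHMARKS.items():
        near, exact, bonus = _accumulate_batch(codes, spec, constants)
        denom = bonus + n
        if (denom <= 0).any():
            raise ProfileComputationError(
                "dnaDistance denominator not positive in batch"
            )
        dists[key] = (near + exact) / denom
    out = np.empty((m, 6), dtype=np.float64)
    for j, key in enumerate(("C", "A", "T")):
        d_near = dists[key]
        d_far = dists[_SUCCESSOR[key]]
        with np.errstate(divide="ignore", invalid="ignore"):
            raw = (d_near * d_near + 1.0 - d_far * d_far) / (2.0 * d_near)
        cos_a = np.clip(raw, -1.0, 1.0)
        D = d_near * cos_a
        H = np.sqrt(np.maximum(d_near * d_near - D * D, 0.0))
        zero = d_near == 0
        if zero.any():
            D[zero] = 0.0
            H[zero] = 0.0
        out[:, 2 * j] = D
        out[:, 2 * j + 1] = H
    return out
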