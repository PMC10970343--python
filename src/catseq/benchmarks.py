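"""Constant benchmark sequences and per-position match scoring.

The CAT method replaces the data-dependent "favorite sequence" of earlier
database heuristics with three *constant* periodic reference sequences, the
A-, T- and C-benchmarks.  Each is an infinite repeat of a 4-base period:

    A-benchmark  ACGTACGTACGT...
    T-benchmark  GTACGTACGTAC...
    C-benchmark  AGTCAGTCAGTC...

The periods are chosen so that the A- and T-benchmarks never agree at any
position, while the C-benchmark agrees with each of them at exactly one
position in four (25%).  A query base is scored against a benchmark position
either as an *exact* match (the benchmark base itself, score 1) or as a
*near* match: the circular offset of the base within the benchmark period
determines the score, taken from the ``base_distance`` table
``[0, 0.6, 0.4, 0.6]`` — adjacent neighbours score 0.6, the opposite (far)
neighbour 0.4, and offset 0 (the exact case) carries no near score.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import SequenceAlphabetError

DNA_ALPHABET = "ACGT"


@dataclass(frozen=True)
class BenchmarkSpec:
    """One of the periodic benchmark sequences.

    Parameters
    ----------
    key
        Benchmark name, conventionally one of ``"C"``, ``"A"``, ``"T"``.
    period
        The 4-character repeat unit; must use each DNA base exactly once.
    """

    key: str
    period: str

    def __post_init__(self) -> None:
        if len(self.period) != 4 or sorted(self.period) != sorted(DNA_ALPHABET):
            raise ValueError(
                f"benchmark period must be a permutation of {DNA_ALPHABET!r}, "
                f"got {self.period!r}"
            )

    def char(self, i: int) -> str:
        """Benchmark base at zero-based position ``i`` of the infinite repeat."""
        if i < 0:
            raise ValueError(f"position must be non-negative, got {i}")
        return self.period[i % 4]

    def canonical_index(self, base: str) -> int:
        """Position of ``base`` within the period (0..3)."""
        idx = self.period.find(base)
        if idx < 0:
            raise SequenceAlphabetError(
                f"base {base!r} is outside the DNA alphabet {DNA_ALPHABET!r}"
            )
        return idx


@dataclass(frozen=True)
class ScoringConstants:
    """Tunable scoring parameters shared by all three benchmarks.

    ``base_distance[d]`` is the near-match score for a base whose canonical
    period position lies at circular offset ``d`` from the aligned position;
    entry 0 is the exact-match slot and is 0 because the exact case is scored
    separately.  ``min_point`` is the per-step deduction in the
    previous-match bonus recurrence (the smallest nonzero match score by
    default).  ``allow_unknown`` opts in to scoring non-ACGT characters as 0
    instead of rejecting them.
    """

    base_distance: tuple[float, float, float, float] = (0.0, 0.6, 0.4, 0.6)
    min_point: float = 0.4
    allow_unknown: bool = False


DEFAULT_SCORING = ScoringConstants()

A_BENCHMARK = BenchmarkSpec("A", "ACGT")
T_BENCHMARK = BenchmarkSpec("T", "GTAC")
C_BENCHMARK = BenchmarkSpec("C", "AGTC")

#: The three shipped benchmarks in the canonical C, A, T order.
BENCHMARKS: dict[str, BenchmarkSpec] = {
    "C": C_BENCHMARK,
    "A": A_BENCHMARK,
    "T": T_BENCHMARK,
}


def benchmark_char(spec: BenchmarkSpec, i: int) -> str:
    """Base of the (infinite) benchmark at zero-based position ``i``."""
    return spec.char(i)


def exact_match(
    spec: BenchmarkSpec,
    i: int,
    base: str,
    constants: ScoringConstants = DEFAULT_SCORING,
) -> float:
    """1.0 if ``base`` equals the benchmark base at position ``i``, else 0.0."""
    if base not in DNA_ALPHABET:
        if constants.allow_unknown:
            return 0.0
        raise SequenceAlphabetError(
            f"base {base!r} is outside the DNA alphabet {DNA_ALPHABET!r}"
        )
    return 1.0 if spec.char(i) == base else 0.0


def near_match(
    spec: BenchmarkSpec,
    i: int,
    base: str,
    constants: ScoringConstants = DEFAULT_SCORING,
) -> float:
    """Near-match score of ``base`` against benchmark position ``i``.

    The score is ``base_distance[d]`` where ``d`` is the circular offset of
    the base's canonical period position from ``i mod 4``.  Offset 0 (an
    exact match) returns 0 — the exact case carries no near score.
    """
    if i < 0:
        raise ValueError(f"position must be non-negative, got {i}")
    if base not in DNA_ALPHABET:
        if constants.allow_unknown:
            return 0.0
        raise SequenceAlphabetError(
            f"base {base!r} is outside the DNA alphabet {DNA_ALPHABET!r}"
        )
    d = (spec.canonical_index(base) - (i % 4)) % 4
    return constants.base_distance[d]
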