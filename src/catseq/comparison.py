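"""Constant-time similarity of two sequences from their CAT profiles.

Comparison never touches sequence text: it reads the six stored numbers of
each profile, takes the Euclidean distance between the per-benchmark
``(D, H)`` points,

    result_X = sqrt((D_X − D'_X)² + (H_X − H'_X)²),   X ∈ {C, A, T}

and converts the mean distance to a similarity::

    similarity_raw     = 1 − (result_C + result_A + result_T) / 3
    similarity_percent = 100 · clamp(similarity_raw, 0, 1)

Identical profiles give exactly 100%.  The raw value can go negative for
very distant profiles; it is exposed for diagnostics while the percent is
clamped to [0, 100].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .benchmarks import DEFAULT_SCORING, ScoringConstants
from .errors import ProvenanceMismatchError
from .profiling import CatProfile, compute_profile

#: Two profiles count as a full (100%) match when every per-benchmark
#: distance is strictly below this tolerance.
FULL_MATCH_TOLERANCE = 1e-12


@dataclass(frozen=True)
class SimilarityResult:
    """Per-benchmark profile distances and the derived similarity."""

    result_c: float
    result_a: float
    result_t: float
    similarity_raw: float
    similarity_percent: float

    @property
    def is_full_match(self) -> bool:
        return (
            self.result_c < FULL_MATCH_TOLERANCE
            and self.result_a < FULL_MATCH_TOLERANCE
            and self.result_t < FULL_MATCH_TOLERANCE
        )


def _leg_distance(p: CatProfile, q: CatProfile, key: str) -> float:
    dp, hp = p.legs[key]
    dq, hq = q.legs[key]
    dx = dp - dq
    dy = hp - hq
    return math.sqrt(dx * dx + dy * dy)


def compare_profiles(p: CatProfile, q: CatProfile) -> SimilarityResult:
    """Similarity of two profiles; O(1) in sequence length.

    Raises :class:`ProvenanceMismatchError` if the profiles were built under
    different benchmark periods, scoring constants or pairing conventions.
    """
    if p.provenance != q.provenance:
        raise ProvenanceMismatchError(
            "profiles are not comparable: they were computed under different "
            f"provenance ({p.provenance} vs {q.provenance})"
        )
    rc = _leg_distance(p, q, "C")
    ra = _leg_distance(p, q, "A")
    rt = _leg_distance(p, q, "T")
    raw = 1.0 - (rc + ra + rt) / 3.0
    percent = 100.0 * min(1.0, max(0.0, raw))
    return SimilarityResult(rc, ra, rt, raw, percent)


def compare_sequences(
    s1: str, s2: str, constants: ScoringConstants = DEFAULT_SCORING
) -> SimilarityResult:
    """Convenience composition: profile both sequences, then compare."""
    return compare_profiles(
        compute_profile(s1, constants), compute_profile(s2, constants)
    )
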