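"""Collision analysis, threshold profile search, and reference baselines.

The collision harness answers the reliability question for CAT profiles:
over the exhaustive space of all 4^n sequences of length *n*, how many set
members does a random query's profile match at 100%?  A count of 1 for every
query (the query itself) means the profiles are collision-free at that
length.  Profile computation over the space is vectorised and batched so the
experiment scales to large *n* with bounded memory.

Needleman–Wunsch global alignment and Knuth–Morris–Pratt substring search
are included as the exact baselines the heuristic is measured against; they
are textbook implementations with configurable scoring.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np

from .benchmarks import DEFAULT_SCORING, DNA_ALPHABET, ScoringConstants
from .comparison import FULL_MATCH_TOLERANCE, compare_profiles
from .errors import ProvenanceMismatchError
from .profiling import CatProfile, profile_matrix

#: Largest length for which the full 4^n space may be enumerated eagerly.
MAX_EAGER_LENGTH = 13


@dataclass
class CollisionReport:
    """Result of one collision experiment."""

    length: int
    total_permutations: int
    sample_size: int
    seed: int
    average_full_matches: float
    per_query_counts: list[int]


@dataclass(frozen=True)
class SearchHit:
    sequence_id: str
    similarity_percent: float


@dataclass(frozen=True)
class AlignmentResult:
    """Global alignment of two sequences under a linear gap scheme."""

    score: float
    aligned_a: str
    aligned_b: str
    identity_percent: float


def enumerate_space(n: int, streaming: bool = False) -> Iterator[str]:
    """Yield every DNA sequence of length ``n`` once, in lexicographic
    order (A < C < G < T).

    Lengths above ``MAX_EAGER_LENGTH`` require ``streaming=True`` as an
    explicit acknowledgement that the 4^n space will not fit in memory if
    collected.
    """
    if n < 1:
        raise ValueError(f"length must be >= 1, got {n}")
    if n > MAX_EAGER_LENGTH and not streaming:
        raise ValueError(
            f"length {n} exceeds the eager limit {MAX_EAGER_LENGTH} "
            f"(4^{n} sequences); pass streaming=True to iterate anyway"
        )
    for tup in itertools.product(DNA_ALPHABET, repeat=n):
        yield "".join(tup)


def _codes_from_indices(indices: np.ndarray, n: int) -> np.ndarray:
    """Base-code matrix for the sequences at the given lexicographic ranks."""
    idx = np.asarray(indices, dtype=np.int64)
    out = np.empty((idx.size, n), dtype=np.uint8)
    for j in range(n - 1, -1, -1):
        out[:, j] = idx & 3
        idx = idx >> 2
    return out


def sequence_at(index: int, n: int) -> str:
    """The ``index``-th length-``n`` sequence in lexicographic order."""
    return "".join(DNA_ALPHABET[c] for c in _codes_from_indices([index], n)[0])


def _sample_indices(total: int, k: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if total <= 4**12:
        return rng.choice(total, size=k, replace=False)
    chosen: list[int] = []
    seen: set[int] = set()
    while len(chosen) < k:
        c = int(rng.integers(0, total))
        if c not in seen:
            seen.add(c)
            chosen.append(c)
    return np.asarray(chosen, dtype=np.int64)


def collision_experiment(
    n: int,
    sample_size: int,
    seed: int,
    constants: ScoringConstants = DEFAULT_SCORING,
    batch_size: int = 1 << 20,
    tolerance: float = FULL_MATCH_TOLERANCE,
) -> CollisionReport:
    """Count 100%-similarity set members for random queries over all 4^n
    sequences.

    Profiles for the whole space are computed in batches of ``batch_size``.
    Within a batch, candidate matches for each query are narrowed by a
    binary-search window on the C-leg ``D`` coordinate (a full match forces
    every coordinate difference below ``tolerance``), then confirmed with
    the same three-distance criterion the comparison layer uses.
    """
    total = 4**n
    if sample_size > total:
        raise ValueError(
            f"sample_size {sample_size} exceeds the space size 4^{n}={total}"
        )
    qidx = _sample_indices(total, sample_size, seed)
    qprof = profile_matrix(_codes_from_indices(qidx, n), constants)
    counts = np.zeros(sample_size, dtype=np.int64)
    for start in range(0, total, batch_size):
        stop = min(start + batch_size, total)
        prof = profile_matrix(
            _codes_from_indices(np.arange(start, stop), n), constants
        )
        order = np.argsort(prof[:, 0], kind="stable")
        c_sorted = prof[order, 0]
        for k in range(sample_size):
            q = qprof[k]
            lo = np.searchsorted(c_sorted, q[0] - tolerance, side="left")
            hi = np.searchsorted(c_sorted, q[0] + tolerance, side="right")
            if hi <= lo:
                continue
            cand = prof[order[lo:hi]]
            full = np.ones(hi - lo, dtype=bool)
            for j in range(3):
                dx = cand[:, 2 * j] - q[2 * j]
                dy = cand[:, 2 * j + 1] - q[2 * j + 1]
                full &= np.sqrt(dx * dx + dy * dy) < tolerance
            counts[k] += int(np.count_nonzero(full))
    return CollisionReport(
        length=n,
        total_permutations=total,
        sample_size=sample_size,
        seed=seed,
        average_full_matches=float(counts.mean()),
        per_query_counts=[int(c) for c in counts],
    )


def search(
    query: CatProfile,
    store: Iterable[CatProfile],
    min_similarity: float,
) -> list[SearchHit]:
    """All store profiles with similarity ≥ ``min_similarity`` percent,
    sorted by descending similarity, ties broken by sequence id."""
    hits: list[SearchHit] = []
    for prof in store:
        if prof.provenance != query.provenance:
            raise ProvenanceMismatchError(
                f"store profile {prof.sequence_id!r} has provenance "
                "incompatible with the query"
            )
        res = compare_profiles(query, prof)
        if res.similarity_percent >= min_similarity:
            hits.append(SearchHit(prof.sequence_id, res.similarity_percent))
    hits.sort(key=lambda h: (-h.similarity_percent, h.sequence_id))
    return hits


def needleman_wunsch(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> AlignmentResult:
    """Optimal global alignment by full dynamic programming.

    Linear gap penalty; traceback ties resolved diagonal, then up (gap in
    ``b``), then left (gap in ``a``), making the alignment deterministic.
    """
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    m, n = len(a), len(b)
    score = np.empty((m + 1, n + 1), dtype=np.float64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[0, :] = gap * np.arange(n + 1)
    score[:, 0] = gap * np.arange(m + 1)
    ptr[0, 1:] = 2
    ptr[1:, 0] = 1
    for i in range(1, m + 1):
        ai = a[i - 1]
        row = score[i]
        prev = score[i - 1]
        for j in range(1, n + 1):
            diag = prev[j - 1] + (match if ai == b[j - 1] else mismatch)
            up = prev[j] + gap
            left = row[j - 1] + gap
            if diag >= up and diag >= left:
                row[j] = diag
            elif up >= left:
                row[j] = up
                ptr[i, j] = 1
            else:
                row[j] = left
                ptr[i, j] = 2
    # traceback
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        move = ptr[i, j]
        if move == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif move == 1:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    aligned_a = "".join(reversed(out_a))
    aligned_b = "".join(reversed(out_b))
    matches = sum(x == y for x, y in zip(aligned_a, aligned_b))
    identity = 100.0 * matches / len(aligned_a)
    return AlignmentResult(float(score[m, n]), aligned_a, aligned_b, identity)


def kmp_search(pattern: str, text: str) -> list[int]:
    """All zero-based occurrence positions of ``pattern`` in ``text``
    (overlaps included), via the classic failure-function automaton."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    p = len(pattern)
    fail = [0] * p
    k = 0
    for i in range(1, p):
        while k > 0 and pattern[i] != pattern[k]:
            k = fail[k - 1]
        if pattern[i] == pattern[k]:
            k += 1
        fail[i] = k
    hits: list[int] = []
    k = 0
    for i, ch in enumerate(text):
        while k > 0 and ch != pattern[k]:
            k = fail[k - 1]
        if ch == pattern[k]:
            k += 1
        if k == p:
            hits.append(i - p + 1)
            k = fail[k - 1]
    return hits
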