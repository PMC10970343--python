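"""Collision analysis, threshold search, and the NW / KMP baselines."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from catseq import (
    collision_experiment,
    compute_profile,
    enumerate_space,
    kmp_search,
    needleman_wunsch,
    search,
    sequence_at,
)

from .conftest import random_dna


class TestEnumerateSpace:
    def test_length_one(self):
        assert list(enumerate_space(1)) == ["A", "C", "G", "T"]

    def test_lexicographic_bounds(self):
        seqs = list(enumerate_space(2))
        assert seqs[0] == "AA" and seqs[-1] == "TT"
        assert len(seqs) == 16
        assert seqs == sorted(seqs)

    def test_space_size_matches_four_to_the_n(self):
        assert sum(1 for _ in enumerate_space(6)) == 4**6

    def test_large_length_needs_streaming(self):
        with pytest.raises(ValueError, match="streaming"):
            next(enumerate_space(14))
        first = next(enumerate_space(14, streaming=True))
        assert first == "A" * 14

    def test_sequence_at_agrees_with_enumeration(self):
        seqs = list(enumerate_space(3))
        for k in (0, 1, 17, 63):
            assert sequence_at(k, 3) == seqs[k]


class TestCollisionExperiment:
    def test_length_one_each_query_matches_itself_only(self):
        report = collision_experiment(1, 4, seed=0)
        assert report.per_query_counts == [1, 1, 1, 1]
        assert report.average_full_matches == 1.0
        assert report.total_permutations == 4

    def test_length_five_no_collisions(self):
        report = collision_experiment(5, 100, seed=11)
        assert report.average_full_matches == 1.0
        assert all(c == 1 for c in report.per_query_counts)
        assert report.total_permutations == 1024

    def test_every_query_matches_at_least_itself(self):
        report = collision_experiment(4, 50, seed=3)
        assert all(c >= 1 for c in report.per_query_counts)

    def test_seeded_determinism(self):
        r1 = collision_experiment(4, 20, seed=9)
        r2 = collision_experiment(4, 20, seed=9)
        assert r1 == r2

    def test_batching_does_not_change_counts(self):
        whole = collision_experiment(5, 30, seed=2)
        batched = collision_experiment(5, 30, seed=2, batch_size=100)
        assert whole == batched

    def test_oversized_sample_rejected(self):
        with pytest.raises(ValueError):
            collision_experiment(2, 17, seed=0)

    def test_length_five_profiles_pairwise_distinct(self):
        """Exhaustive check: 1,024 length-5 sequences give 1,024 distinct
        profiles (no silent absorption of collisions)."""
        from catseq import profile_matrix
        from catseq.searchbench import _codes_from_indices

        mat = profile_matrix(_codes_from_indices(np.arange(4**5), 5))
        assert len(np.unique(mat, axis=0)) == 4**5


class TestSearch:
    def _store(self, seqs):
        return [compute_profile(s, sequence_id=s) for s in seqs]

    def test_query_finds_itself_at_100(self):
        store = self._store(["ACGTA", "TTTTT", "GATTA"])
        hits = search(compute_profile("TTTTT"), store, 100.0)
        assert [h.sequence_id for h in hits] == ["TTTTT"]
        assert hits[0].similarity_percent == 100.0

    def test_threshold_zero_returns_everything_sorted(self):
        seqs = ["ACGTA", "TTTTT", "GATTA", "ACGTC"]
        hits = search(compute_profile("ACGTA"), self._store(seqs), 0.0)
        assert len(hits) == len(seqs)
        sims = [h.similarity_percent for h in hits]
        assert sims == sorted(sims, reverse=True)

    def test_exhaustive_length4_store_exact_match_unique(self):
        seqs = ["".join(t) for t in itertools.product("ACGT", repeat=4)]
        store = self._store(seqs)
        hits = search(compute_profile("GATC"), store, 100.0)
        assert [h.sequence_id for h in hits] == ["GATC"]

    def test_tie_break_on_sequence_id(self):
        p = compute_profile("ACGT", sequence_id="q")
        twin_b = compute_profile("ACGT", sequence_id="b")
        twin_a = compute_profile("ACGT", sequence_id="a")
        hits = search(p, [twin_b, twin_a], 100.0)
        assert [h.sequence_id for h in hits] == ["a", "b"]


def brute_force_global_score(a, b, match=1.0, mismatch=-1.0, gap=-1.0):
    """Independent oracle: exhaustive recursion over all gapped alignments."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    sub = match if a[0] == b[0] else mismatch
    return max(
        brute_force_global_score(a[1:], b[1:], match, mismatch, gap) + sub,
        brute_force_global_score(a[1:], b, match, mismatch, gap) + gap,
        brute_force_global_score(a, b[1:], match, mismatch, gap) + gap,
    )


class TestNeedlemanWunsch:
    def test_self_alignment(self):
        s = "ACGTACGT"
        res = needleman_wunsch(s, s)
        assert res.score == len(s)
        assert res.identity_percent == 100.0
        assert res.aligned_a == res.aligned_b == s

    def test_single_base_mismatch(self):
        assert needleman_wunsch("A", "T").score == -1.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            needleman_wunsch("", "ACGT")

    def test_gap_recovery_invariant(self):
        res = needleman_wunsch("ACGTT", "AGT")
        assert res.aligned_a.replace("-", "") == "ACGTT"
        assert res.aligned_b.replace("-", "") == "AGT"
        assert len(res.aligned_a) == len(res.aligned_b)

    def test_score_symmetry(self, rng):
        for _ in range(20):
            a = random_dna(rng, int(rng.integers(1, 12)))
            b = random_dna(rng, int(rng.integers(1, 12)))
            assert needleman_wunsch(a, b).score == needleman_wunsch(b, a).score

    def test_matches_brute_force_on_small_pairs(self, rng):
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 6)))
            b = random_dna(rng, int(rng.integers(1, 6)))
            assert needleman_wunsch(a, b).score == brute_force_global_score(a, b)

    def test_custom_scoring_scheme(self):
        res = needleman_wunsch("AC", "AG", match=2.0, mismatch=-3.0, gap=-1.0)
        # A matched (2), then C/G either mismatched (-3) or double-gapped (-2)
        assert res.score == 0.0


def naive_find_all(pattern, text):
    return [
        i
        for i in range(len(text) - len(pattern) + 1)
        if text[i : i + len(pattern)] == pattern
    ]


class TestKmpSearch:
    def test_overlapping_occurrences(self):
        assert kmp_search("A", "AAA") == [0, 1, 2]

    def test_no_occurrence(self):
        assert kmp_search("ACG", "TTTT") == []

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            kmp_search("", "ACGT")

    def test_self_overlapping_pattern(self):
        assert kmp_search("ACAC", "ACACACAC") == [0, 2, 4]

    @given(
        pattern=st.text(alphabet="ACGT", min_size=1, max_size=5),
        text=st.text(alphabet="ACGT", max_size=40),
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_naive_search(self, pattern, text):
        assert kmp_search(pattern, text) == naive_find_all(pattern, text)
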