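from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliswarm.io import Amplicon
from ampliswarm.segment_filter import (
    bidirectional_check,
    build_indices,
    candidates,
    partition_positions,
    select_substrings,
)

from oracles import full_edit_distance


def mutate(rng: random.Random, seq: str, n_edits: int) -> str:
    s = list(seq)
    for _ in range(n_edits):
        op = rng.choice("sid")
        pos = rng.randrange(len(s)) if s else 0
        if op == "s" and s:
            s[pos] = rng.choice("ACGT")
        elif op == "i":
            s.insert(pos, rng.choice("ACGT"))
        elif len(s) > 1:
            del s[pos]
    return "".join(s)


class TestPartitionPositions:
    @pytest.mark.parametrize(
        "l,n,expected",
        [
            (10, 3, ((0, 3), (3, 3), (6, 4))),
            (9, 3, ((0, 3), (3, 3), (6, 3))),
            (6, 2, ((0, 3), (3, 3))),
            (7, 1, ((0, 7),)),
        ],
    )
    def test_examples(self, l, n, expected):
        assert partition_positions(l, n).segments == expected

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            partition_positions(2, 3)

    @given(st.integers(min_value=1, max_value=300), st.integers(min_value=1, max_value=10))
    @settings(deadline=None)
    def test_tiles_sequence_with_near_equal_longer_last(self, l, n):
        if l < n:
            return
        segs = partition_positions(l, n).segments
        assert len(segs) == n
        pos = 0
        for start, length in segs:
            assert start == pos
            pos += length
        assert pos == l
        lengths = [ln for _, ln in segs]
        assert max(lengths) - min(lengths) <= 1
        assert lengths == sorted(lengths)  # longer segments last


class TestSelectSubstrings:
    @pytest.mark.parametrize(
        "s_len,l,i,p,l_i,tau,expected",
        [
            (10, 10, 2, 3, 3, 2, {2, 3, 4}),
            (10, 10, 1, 0, 3, 2, {0}),
            (10, 10, 3, 6, 4, 2, {6}),
        ],
    )
    def test_tight_windows(self, s_len, l, i, p, l_i, tau, expected):
        assert set(select_substrings(s_len, l, i, p, l_i, tau)) == expected

    def test_window_complete_over_all_two_edit_neighbours(self):
        """Every <=2-edit neighbour S of R has a preserved segment inside
        its tight window, for the segment left untouched by the edits."""
        rng = random.Random(5)
        tau = 2
        for _ in range(300):
            r = "".join(rng.choice("ACGT") for _ in range(rng.randint(12, 20)))
            s = mutate(rng, r, rng.randint(0, tau))
            if abs(len(s) - len(r)) > tau:
                continue
            segs = partition_positions(len(r), tau + 1).segments
            found = False
            for i, (p, l_i) in enumerate(segs, start=1):
                seg = r[p : p + l_i]
                for w in select_substrings(len(s), len(r), i, p, l_i, tau):
                    if s[w : w + l_i] == seg:
                        found = True
                        break
                if found:
                    break
            assert found, (r, s)


def index_of(seqs: list[str], tau: int, k: int):
    amps = [Amplicon(f"r{i}", s, 1, i) for i, s in enumerate(seqs)]
    return amps, build_indices(amps, tau, k)


class TestCandidates:
    def test_shared_segment_is_found(self):
        amps, idx = index_of(["AAAACCCC"], 1, 1)
        q = Amplicon("q", "AAAACCCG", 1, 9)
        assert candidates(q, idx) == {"r0"}

    def test_disjoint_sequences_yield_nothing(self):
        amps, idx = index_of(["AAAACCCC"], 1, 1)
        assert candidates(Amplicon("q", "TTTTGGGG", 1, 9), idx) == set()

    def test_self_match_excluded(self):
        amps, idx = index_of(["AAAACCCC"], 1, 1)
        assert candidates(amps[0], idx) == set()

    def test_short_amplicons_reachable_via_side_list(self):
        amps, idx = index_of(["AC"], 2, 2)  # length 2 < tau + k = 4
        q = Amplicon("q", "ACG", 1, 9)
        assert candidates(q, idx, tau=1) == {"r0"}

    @pytest.mark.parametrize("tau", [1, 2, 3])
    @pytest.mark.parametrize("k", [1, 2])
    def test_complete_on_random_mutated_pairs(self, tau, k):
        rng = random.Random(100 * tau + k)
        for _ in range(400):
            r = "".join(rng.choice("ACGT") for _ in range(60))
            s = mutate(rng, r, rng.randint(0, tau))
            if full_edit_distance(r, s) > tau:
                continue
            amps, idx = index_of([r], tau, k)
            q = Amplicon("q", s, 1, 9)
            assert "r0" in candidates(q, idx), (r, s, tau, k)
            assert bidirectional_check(q, amps[0], tau, k)

    def test_raising_tau_never_loses_true_pairs(self):
        """The filters at tau and tau+1 use different partitions, so the
        spurious candidates need not nest — but every candidate within
        true distance tau must appear in both sets (completeness nests)."""
        rng = random.Random(17)
        seqs = ["".join(rng.choice("ACGT") for _ in range(30))]
        for _ in range(40):
            seqs.append(mutate(rng, seqs[0], rng.randint(0, 4)))
        by_id = {f"r{i}": s for i, s in enumerate(seqs)}
        q = Amplicon("q", mutate(rng, seqs[0], 2), 1, 99)
        for tau in (1, 2, 3):
            for k in (1, 2):
                _, idx_lo = index_of(seqs, tau, k)
                _, idx_hi = index_of(seqs, tau + 1, k)
                dropped = candidates(q, idx_lo) - candidates(q, idx_hi)
                for ident in dropped:
                    assert full_edit_distance(q.sequence, by_id[ident]) > tau

    def test_extra_k2_candidates_are_never_true_pairs(self):
        """k=1 is complete, so any candidate admitted at k=2 but rejected
        at k=1 must truly lie beyond tau (an over-selection of the
        conservative k>1 windows, not a missed pair)."""
        rng = random.Random(17)
        seqs = ["".join(rng.choice("ACGT") for _ in range(30))]
        for _ in range(40):
            seqs.append(mutate(rng, seqs[0], rng.randint(0, 4)))
        by_id = {f"r{i}": s for i, s in enumerate(seqs)}
        q = Amplicon("q", mutate(rng, seqs[0], 2), 1, 99)
        for tau in (1, 2, 3):
            _, idx_k1 = index_of(seqs, tau, 1)
            _, idx_k2 = index_of(seqs, tau, 2)
            extra = candidates(q, idx_k2) - candidates(q, idx_k1)
            for ident in extra:
                assert full_edit_distance(q.sequence, by_id[ident]) > tau


class TestBidirectionalCheck:
    def test_rejects_disjoint_pair(self):
        a = Amplicon("a", "AAAAAAAA", 1, 0)
        b = Amplicon("b", "TTTTTTTT", 1, 1)
        assert not bidirectional_check(a, b, 1, 1)

    def test_never_rejects_true_pairs(self):
        rng = random.Random(23)
        for _ in range(500):
            r = "".join(rng.choice("ACGT") for _ in range(40))
            s = mutate(rng, r, rng.randint(0, 3))
            d = full_edit_distance(r, s)
            for tau in (1, 2, 3, 4):
                if d > tau:
                    continue
                for k in (1, 2):
                    a = Amplicon("a", r, 1, 0)
                    b = Amplicon("b", s, 1, 1)
                    assert bidirectional_check(a, b, tau, k)
                    assert bidirectional_check(b, a, tau, k)
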