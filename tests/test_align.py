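"""Anchoring, chaining, closing, variant calling and gap mapping."""

from collections import defaultdict
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpair import (
    AlignmentBlock,
    AlignmentBlockSet,
    Anchor,
    UndefinedResultError,
    align_genomes,
    align_sequences,
    aligned_identity,
    call_variants,
    chain_anchors,
    close_alignment,
    find_anchors,
    map_large_gaps,
)
from clonalpair.align import _align_segment
from clonalpair.genome import revcomp


def _random_seq(n, rng):
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(seq, n_snps, rng):
    s = list(seq)
    pos = rng.choice(len(s), size=n_snps, replace=False)
    for p in pos:
        s[p] = rng.choice([b for b in "ACGT" if b != s[p]])
    return "".join(s), sorted(int(p) for p in pos)


class TestFindAnchors:
    def test_identity_anchors_are_diagonal(self):
        rng = np.random.default_rng(0)
        seq = _random_seq(2_000, rng)
        anchors = find_anchors(seq, seq, k=21)
        assert anchors and all(a.a == a.b for a in anchors)

    def test_reverse_complement_gives_no_forward_anchors(self):
        rng = np.random.default_rng(1)
        seq = _random_seq(5_000, rng)
        assert find_anchors(seq, revcomp(seq), k=21) == []

    def test_matches_exhaustive_kmer_table_oracle(self):
        """Anchor set equals brute-force unique k-mer table intersection on a
        10 kb pair at 99% identity."""
        rng = np.random.default_rng(2)
        a = _random_seq(10_000, rng)
        b, _ = _mutate(a, 100, rng)
        k = 21
        expected = set()
        tables = []
        for s in (a, b):
            t = defaultdict(list)
            for i in range(len(s) - k + 1):
                t[s[i : i + k]].append(i)
            tables.append(t)
        for km, pa in tables[0].items():
            pb = tables[1].get(km, [])
            if len(pa) == 1 and len(pb) == 1:
                expected.add((pa[0], pb[0]))
        got = {(x.a, x.b) for x in find_anchors(a, b, k=k)}
        assert got == expected


class TestChainAnchors:
    def test_collinear_anchors_all_retained(self):
        anchors = [Anchor(100 * i, 100 * i + 7, 21) for i in range(30)]
        assert chain_anchors(anchors) == anchors

    def test_transposed_anchor_dropped(self):
        anchors = [Anchor(100 * i, 100 * i, 21) for i in range(50)]
        anchors.append(Anchor(2510, 10_000, 21))
        chain = chain_anchors(anchors)
        assert Anchor(2510, 10_000, 21) not in chain
        assert len(chain) == 50

    def test_matches_exhaustive_subset_oracle(self):
        """Chain score equals the best over all co-increasing subsets of
        <= 15 anchors (exhaustive enumeration)."""
        rng = np.random.default_rng(3)
        anchors = sorted(
            (Anchor(int(a), int(b), int(l))
             for a, b, l in zip(rng.integers(0, 2_000, 15) * 3,
                                rng.integers(0, 2_000, 15) * 3,
                                rng.integers(15, 40, 15))),
            key=lambda x: (x.a, x.b),
        )

        def chain_score(c):
            """Sequential trimmed score; None when the chain is invalid
            (starts not strictly co-increasing, or a link adds nothing)."""
            score = c[0].length
            for x, y in zip(c, c[1:]):
                if not (x.a < y.a and x.b < y.b):
                    return None
                gain = y.length - max(0, x.a_end - y.a, x.b_end - y.b)
                if gain <= 0:
                    return None
                score += gain
            return score

        best = 0
        for r in range(1, len(anchors) + 1):
            for combo in combinations(anchors, r):
                s = chain_score(list(combo))
                if s is not None:
                    best = max(best, s)
        chain = chain_anchors(anchors)
        assert sum(x.length for x in chain) == best
        assert all(x.a_end <= y.a and x.b_end <= y.b for x, y in zip(chain, chain[1:]))

    def test_equal_score_ties_prefer_leftmost(self):
        # two crossing anchors of equal weight: only one can be kept
        a1, a2 = Anchor(0, 500, 21), Anchor(30, 0, 21)
        assert chain_anchors([a1, a2]) == [a1]
        assert chain_anchors([a2, a1]) == [a1]


class TestCloseAlignment:
    def test_identical_sequences_one_block(self):
        rng = np.random.default_rng(4)
        seq = _random_seq(5_000, rng)
        bs = align_sequences(seq, seq)
        assert len(bs.blocks) == 1
        assert bs.identity_aligned == 1.0
        assert not bs.gaps_a and not bs.gaps_b and not bs.tails_a

    def test_500b_deletion_becomes_gap_in_a(self):
        rng = np.random.default_rng(5)
        a = _random_seq(8_000, rng)
        b = a[:4_000] + a[4_500:]
        bs = align_sequences(a, b)
        assert bs.gaps_a and not bs.gaps_b
        total = sum(e - s for s, e in bs.gaps_a)
        assert total == 500
        assert bs.identity_aligned == 1.0

    def test_segment_alignment_matches_quadratic_dp(self):
        """Closed-segment alignments carry the same edit cost as a full
        quadratic DP on segments up to 2 kb."""
        rng = np.random.default_rng(6)
        for _ in range(40):
            n = int(rng.integers(10, 2_000))
            a = _random_seq(n, rng)
            b = list(a)
            for _ in range(int(rng.integers(0, 8))):
                p = int(rng.integers(len(b)))
                r = rng.random()
                if r < 0.6:
                    b[p] = rng.choice([x for x in "ACGT" if x != b[p]])
                elif r < 0.8:
                    b.insert(p, rng.choice(list("ACGT")))
                else:
                    del b[p]
            b = "".join(b)
            ops = _align_segment(a, b)
            cost = sum(num for op, num in ops if op != "=")
            assert cost == _edit_distance(a, b)

    def test_base_accounting(self, pair_200k):
        anc, div, _ = pair_200k
        pa = align_genomes(anc, div)
        for bs in pa.pairs.values():
            assert bs.accounted_bases("a") == bs.length_a
            assert bs.accounted_bases("b") == bs.length_b


def _edit_distance(a, b):
    prev = np.arange(len(b) + 1)
    for i, ca in enumerate(a, 1):
        cur = np.empty(len(b) + 1, dtype=int)
        cur[0] = i
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return int(prev[-1])


class TestCallVariants:
    def test_identity_alignment_empty_variant_set(self):
        rng = np.random.default_rng(7)
        seq = _random_seq(3_000, rng)
        bs = align_sequences(seq, seq)
        assert len(call_variants(bs, seq, seq)) == 0

    def test_exact_snp_positions_recovered(self):
        """200 planted SNPs with spacing > k are each called at the planted
        coordinate with the planted alleles."""
        rng = np.random.default_rng(8)
        a = _random_seq(30_000, rng)
        b = list(a)
        positions = sorted(rng.choice(np.arange(100, 29_900, 30), 200, replace=False))
        truth = {}
        for p in positions:
            alt = rng.choice([x for x in "ACGT" if x != b[p]])
            truth[int(p)] = (b[p], alt)
            b[p] = alt
        b = "".join(b)
        vs = call_variants(align_sequences(a, b), a, b)
        called = {r.a_position: (r.ref, r.alt) for r in vs.snps()}
        assert called == truth
        assert not vs.indels()

    def test_homopolymer_insertion_left_aligned(self):
        vs = call_variants(align_sequences("AAAA", "AAAAA"), "AAAA", "AAAAA")
        assert len(vs) == 1
        r = vs.records[0]
        assert r.kind == "insertion"
        assert r.a_position == 0 and r.b_position == 0
        assert r.alt == "A"
        assert r.homopolymer_run_length == 4

    def test_symmetry_mirrors_records(self, pair_100k):
        anc, div, _ = pair_100k
        sa, sb = anc.sequences["chromosome"], div.sequences["chromosome"]
        fwd = align_sequences(sa, sb)
        rev = align_sequences(sb, sa)
        v_fwd = call_variants(fwd, sa, sb)
        v_rev = call_variants(rev, sb, sa)
        mirrored = {(r.b_position, r.a_position, r.alt, r.ref) for r in v_rev.snps()}
        assert {(r.a_position, r.b_position, r.ref, r.alt) for r in v_fwd.snps()} == mirrored
        assert [(s, e) for s, e in fwd.gaps_a] == rev.gaps_b
        assert [(s, e) for s, e in fwd.gaps_b] == rev.gaps_a


class TestMapLargeGaps:
    def _bs_with_gaps(self, gap_lengths):
        bs = AlignmentBlockSet("a", "b", 100_000, 100_000)
        bs.blocks = [AlignmentBlock(0, 10, 0, 10, [("=", 10)])]
        pos = 1_000
        for gl in gap_lengths:
            bs.gaps_a.append((pos, pos + gl))
            pos += gl + 1_000
        return bs

    def test_strictly_greater_than_threshold(self):
        rep = map_large_gaps(self._bs_with_gaps([99, 100, 150]), min_len=100)
        lengths = [e - s for s, e in rep.intervals_a["a"]]
        assert lengths == [150]

    def test_no_gaps_fraction_zero(self):
        rep = map_large_gaps(self._bs_with_gaps([]))
        assert rep.fraction_a == 0.0 and not rep.intervals_a

    def test_gap_fraction_arithmetic(self):
        bs = AlignmentBlockSet("a", "b", 50_000, 48_000)
        bs.blocks = [AlignmentBlock(0, 10, 0, 10, [("=", 10)])]
        bs.gaps_a = [(1_000, 1_700), (10_000, 10_800), (30_000, 30_500)]
        rep = map_large_gaps(bs, min_len=100)
        assert rep.gap_bases("a") == 2_000
        assert rep.fraction_a == pytest.approx(0.04)


class TestAlignedIdentity:
    def test_arithmetic(self):
        bs = AlignmentBlockSet("a", "b", 1_000, 1_000)
        bs.blocks = [AlignmentBlock(0, 1_000, 0, 1_000, [("=", 995), ("X", 5)])]
        assert aligned_identity(bs) == pytest.approx(0.995)

    def test_no_aligned_columns_raises(self):
        bs = AlignmentBlockSet("a", "b", 10, 10)
        with pytest.raises(UndefinedResultError):
            aligned_identity(bs)

    def test_identity_from_truth_snps(self, pair_100k):
        anc, div, truth = pair_100k
        pa = align_genomes(anc, div)
        cols = sum(
            sum(n for op, n in blk.ops if op in "=X")
            for bs in pa.pairs.values()
            for blk in bs.blocks
        )
        assert aligned_identity(pa) == pytest.approx(1 - len(truth.snps) / cols)


class TestSelfComparison:
    def test_self_alignment_invariants(self, ancestor_100k):
        pa = align_genomes(ancestor_100k, ancestor_100k)
        assert not pa.only_a and not pa.only_b
        for bs in pa.pairs.values():
            assert len(bs.blocks) == 1
            assert bs.identity_aligned == 1.0
            assert not bs.gaps_a and not bs.gaps_b
        vs = call_variants(pa, ancestor_100k.sequences, ancestor_100k.sequences)
        assert len(vs) == 0


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    a=st.text(alphabet="ACGT", min_size=1, max_size=300),
    b=st.text(alphabet="ACGT", min_size=1, max_size=300),
)
def test_base_accounting_property(a, b):
    """For arbitrary sequence pairs, aligned + gap + tail bases account for
    every base of each genome exactly once."""
    bs = align_sequences(a, b)
    assert bs.accounted_bases("a") == len(a)
    assert bs.accounted_bases("b") == len(b)
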