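import numpy as np
import pytest

from mitorecomb.genome import AnnotatedGenome, reverse_complement
from mitorecomb.repeats import (
    RepeatPair,
    find_repeat_pairs,
    select_assayable_repeats,
)

from conftest import random_seq
from oracles import make_repeat_genome, oracle_repeats, sw_best_local


def _genome(seq, gid="g"):
    return AnnotatedGenome(id=gid, sequence=seq)


def _loci(p):
    return frozenset(
        {(p.copy1.start, p.copy1.end), (p.copy2.start, p.copy2.end)}
    )


def test_exact_direct_repeat_recovered():
    rng = np.random.default_rng(7)
    seq, loci, cols, matches = make_repeat_genome(rng, 3000, 120, "direct", 0)
    pairs = find_repeat_pairs(_genome(seq))
    assert len(pairs) == 1
    p = pairs[0]
    assert p.direction == "direct"
    assert _loci(p) == loci
    assert p.aligned_length == 120 and p.identity_pct == 100.0
    assert p.copy1.start < p.copy2.start


def test_diverged_inverted_repeat_recovered():
    rng = np.random.default_rng(8)
    seq, loci, cols, matches = make_repeat_genome(rng, 3000, 120, "inverted", 3)
    pairs = find_repeat_pairs(_genome(seq))
    assert len(pairs) == 1
    p = pairs[0]
    assert p.direction == "inverted"
    assert _loci(p) == loci
    assert p.aligned_length == 120 and p.matches == 117
    assert p.identity_pct == round(100 * 117 / 120, 2)


def test_alignment_rows_match_genome_sequence():
    rng = np.random.default_rng(9)
    seq, loci, *_ = make_repeat_genome(rng, 3000, 90, "inverted", 2)
    g = _genome(seq)
    (p,) = find_repeat_pairs(g)
    row1, row2 = p.alignment
    assert row1.replace("-", "") == seq[p.copy1.start : p.copy1.end]
    assert row2.replace("-", "") == reverse_complement(
        seq[p.copy2.start : p.copy2.end]
    )
    assert p.recompute_identity() == pytest.approx(p.identity_pct, abs=0.01)


def test_length_threshold_boundaries():
    rng = np.random.default_rng(10)
    # 49 bp exact repeat: below min_len, not reported
    seq, *_ = make_repeat_genome(rng, 3000, 49, "direct", 0)
    assert find_repeat_pairs(_genome(seq)) == []
    # 50 bp exact repeat: inclusive bound, reported
    seq, loci, *_ = make_repeat_genome(rng, 3000, 50, "direct", 0)
    (p,) = find_repeat_pairs(_genome(seq))
    assert p.aligned_length == 50 and _loci(p) == loci


def test_identity_threshold():
    rng = np.random.default_rng(11)
    # 200 bp repeat with 35 substitutions clustered in the middle 70 bp:
    # 82.5% overall identity, so no reported pair may span both halves
    seq_l = list(random_seq(rng, 4000))
    rep = random_seq(rng, 200)
    copy2 = list(rep)
    for k in range(35):
        p = 65 + 2 * k
        copy2[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy2[p]]
    seq_l[500:700] = list(rep)
    seq_l[2500:2700] = copy2
    got = find_repeat_pairs(_genome("".join(seq_l)))
    for p in got:
        assert p.identity_pct >= 85.0
        assert p.aligned_length < 150  # only one clean half qualifies
    assert got, "the exact 65 bp flank should still be reported"


def test_no_repeats_in_random_sequence():
    rng = np.random.default_rng(12)
    seq = random_seq(rng, 3000)
    assert find_repeat_pairs(_genome(seq)) == []
    # the oracle agrees no qualifying alignment can exist (score bound)
    assert sw_best_local(seq, seq, mask_lower=True)[0] < 28


def test_rotation_invariance():
    rng = np.random.default_rng(13)
    seq, loci, *_ = make_repeat_genome(rng, 2500, 100, "direct", 2)
    (p0,) = find_repeat_pairs(_genome(seq))
    for shift in (700, 1900):
        rot = seq[shift:] + seq[:shift]
        (p,) = find_repeat_pairs(_genome(rot))
        expected = {
            ((a - shift) % 2500, b) for (a, b) in _loci(p0) for b in [None]
        }
        got_starts = {(iv.start) for iv in (p.copy1, p.copy2)}
        assert got_starts == {(a - shift) % 2500 for (a, _) in _loci(p0)}
        assert p.aligned_length == p0.aligned_length
        assert p.matches == p0.matches
        assert p.direction == "direct"


def test_repeat_spanning_origin_found():
    rng = np.random.default_rng(14)
    L = 2500
    seq, loci, *_ = make_repeat_genome(rng, L, 100, "direct", 0)
    # rotate so copy1 straddles the origin
    (a, _), _ = sorted(loci)
    shift = a + 50
    rot = seq[shift:] + seq[:shift]
    (p,) = find_repeat_pairs(_genome(rot))
    starts = {p.copy1.start, p.copy2.start}
    assert {(x - shift) % L for (x, _) in loci} == starts
    assert any(iv.wraps for iv in (p.copy1, p.copy2))
    assert p.aligned_length == 100 and p.identity_pct == 100.0


def test_strand_symmetry():
    rng = np.random.default_rng(15)
    L = 2500
    seq, loci, *_ = make_repeat_genome(rng, L, 80, "inverted", 2)
    (p,) = find_repeat_pairs(_genome(seq))
    (q,) = find_repeat_pairs(_genome(reverse_complement(seq)))
    assert q.direction == "inverted"
    mirrored = frozenset({(L - e, L - s) for (s, e) in _loci(p)})
    assert _loci(q) == mirrored
    assert (q.aligned_length, q.matches) == (p.aligned_length, p.matches)


def test_oracle_equivalence_small_sample():
    # a quick version of the exhaustive-DP comparison (the full 50-genome
    # sweep runs in the acceptance tests)
    rng = np.random.default_rng(16)
    for k in range(6):
        direction = "direct" if k % 2 == 0 else "inverted"
        n_mut = [0, 2, 4][k // 2]
        seq, loci, cols, matches = make_repeat_genome(rng, 1500, 150, direction, n_mut)
        got = find_repeat_pairs(_genome(seq))
        expected = oracle_repeats(seq)
        assert len(got) == len(expected) == 1
        g, e = got[0], expected[0]
        assert _loci(g) == e["loci"] == loci
        assert g.direction == e["direction"] == direction
        assert g.aligned_length == e["cols"]
        assert g.matches == e["matches"]


def test_indel_repeat_agrees_with_oracle():
    rng = np.random.default_rng(17)
    seq_l = list(random_seq(rng, 2000))
    rep = random_seq(rng, 120)
    copy2 = rep[:50] + rep[51:]  # one interior deletion
    seq_l[300:420] = list(rep)
    seq_l[1200 : 1200 + len(copy2)] = list(copy2)
    # force mismatching borders
    for t in range(1, 5):
        for i, j in (
            (300 - t, 1200 - t),
            (420 + t - 1, 1200 + len(copy2) + t - 1),
        ):
            if seq_l[j] == seq_l[i]:
                seq_l[j] = "A" if seq_l[i] != "A" else "C"
    seq = "".join(seq_l)
    got = find_repeat_pairs(_genome(seq))
    expected = oracle_repeats(seq)
    assert len(got) == 1 and len(expected) == 1
    assert _loci(got[0]) == expected[0]["loci"]
    assert got[0].aligned_length == expected[0]["cols"] == 120  # gap column counted
    assert got[0].matches == expected[0]["matches"] == 119


def test_select_assayable_bounds_and_overlap():
    def mk(len_, s1, s2, L=10_000):
        from mitorecomb.intervals import CircularInterval

        return RepeatPair(
            id="x",
            copy1=CircularInterval(s1, s1 + len_, L),
            copy2=CircularInterval(s2, s2 + len_, L),
            direction="direct",
            identity_pct=100.0,
            aligned_length=len_,
            alignment=("A" * len_, "A" * len_),
        )

    pairs = [mk(49, 100, 5000), mk(50, 100, 5000), mk(250, 1000, 5000), mk(251, 1000, 5000)]
    kept = select_assayable_repeats(pairs)
    assert [p.aligned_length for p in kept] == [50, 250]
    # overlapping copies rejected
    assert select_assayable_repeats([mk(100, 100, 150)]) == []
    # copy-gap filter
    assert select_assayable_repeats([mk(100, 100, 300)], min_copy_gap=150) == []
    assert len(select_assayable_repeats([mk(100, 100, 300)], min_copy_gap=50)) == 1
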