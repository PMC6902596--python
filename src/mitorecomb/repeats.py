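"""Dispersed repeat discovery on circular genomes.

Detection is seed-and-extend: exact 20-mer matches between the doubled
sequence and itself (direct orientation) or its reverse complement
(inverted orientation) are chained along (anti)diagonals, and each chain is
extended by affine-gap local alignment. A pair is reported when the local
alignment reaches the field's working definition of a repeat: identity of
at least 85% over at least 50 aligned bases. Identity is computed over all
alignment columns, gaps included.

Scoring: match +1, mismatch -2, gap of length g costs 5 + 2g.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass

from Bio import Align

from .genome import AnnotatedGenome, GenomeError, reverse_complement
from .intervals import CircularInterval, interval_overlap

SEED_K = 20
_CHAIN_GAP = 60  # max bp between chained seeds on one diagonal
_DIAG_BAND = 15  # diagonals merged into one candidate if this close
_MARGIN = 60  # extension margin around a seed chain

MATCH = 1
MISMATCH = -2
GAP_OPEN = -7  # Biopython convention: first gap base costs open, rest extend
GAP_EXTEND = -2


@dataclass
class RepeatPair:
    """Two aligned copies of a dispersed repeat on one circular genome.

    ``alignment`` holds the two gapped alignment strings (copy1 row,
    copy2 row; for inverted pairs the copy2 row is the reverse complement
    of the genomic copy2 locus).
    """

    id: str
    copy1: CircularInterval
    copy2: CircularInterval
    direction: str  # direct | inverted
    identity_pct: float
    aligned_length: int
    alignment: tuple[str, str]
    score: float = 0.0

    def recompute_identity(self) -> float:
        a, b = self.alignment
        matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
        return 100.0 * matches / len(a)

    @property
    def matches(self) -> int:
        a, b = self.alignment
        return sum(1 for x, y in zip(a, b) if x == y and x != "-")


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _alignment_stats(aln) -> tuple[int, int, str, str]:
    s1, s2 = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(s1, s2) if x == y and x != "-")
    return matches, len(s1), s1, s2


def _best_alignment(aligner, w1: str, w2: str):
    """Deterministically pick among co-optimal local alignments.

    Preference: most matches, then fewest columns, then smallest start
    coordinates. Only the first few co-optimal paths are inspected; ties
    beyond that are degenerate low-complexity cases.
    """
    alns = aligner.align(w1, w2)
    if len(alns) == 0 or alns.score <= 0:
        return None
    best = None
    best_key = None
    for idx, aln in enumerate(alns):
        if idx >= 16:
            break
        matches, cols, _, _ = _alignment_stats(aln)
        key = (-matches, cols, aln.aligned[0][0][0], aln.aligned[1][0][0])
        if best_key is None or key < best_key:
            best, best_key = aln, key
    return best


def _circle_interval(start: int, span: int, L: int) -> CircularInterval:
    s = start % L
    e = (s + span) % L
    if e == 0:
        e = L
    return CircularInterval(s, e, L)


def _kmer_positions(doubled: str, L: int, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(doubled[i : i + k], []).append(i)
    return index


def _chain_seeds(
    seeds_by_diag: dict[int, list[int]], L: int
) -> list[tuple[int, int, int, int]]:
    """Chain seeds into candidate blocks.

    Returns (i_min, i_max, d_min, d_max) per block, where i is the seed
    start in copy1 coordinates and d the (anti)diagonal key. Seed runs
    crossing the circle origin are chained by also considering each start
    shifted by one full turn; chains living entirely in the shifted copy
    are dropped as duplicates.
    """
    runs = []
    for d, starts in seeds_by_diag.items():
        uniq = sorted(set(starts))
        ext = uniq + [i + L for i in uniq]
        chains: list[list[int]] = []
        lo = prev = ext[0]
        for i in ext[1:]:
            if i - prev > _CHAIN_GAP:
                chains.append([lo, prev])
                lo = i
            prev = i
        chains.append([lo, prev])
        for lo, hi in chains:
            if lo >= L:
                continue  # duplicate of an unshifted chain
            runs.append([lo, min(hi, lo + L - 1), d, d])
    # merge runs on nearby diagonals with overlapping i ranges
    runs.sort(key=lambda r: (r[2], r[0]))
    merged: list[list[int]] = []
    for r in runs:
        hit = None
        for m in merged:
            if (
                min(r[3], m[3]) + _DIAG_BAND >= max(r[2], m[2])
                and r[0] <= m[1] + _CHAIN_GAP
                and m[0] <= r[1] + _CHAIN_GAP
            ):
                hit = m
                break
        if hit is None:
            merged.append(list(r))
        else:
            hit[0] = min(hit[0], r[0])
            hit[1] = max(hit[1], r[1])
            hit[2] = min(hit[2], r[2])
            hit[3] = max(hit[3], r[3])
    return [tuple(m) for m in merged]


def find_repeat_pairs(
    genome: AnnotatedGenome,
    min_len: int = 50,
    min_identity: float = 85.0,
    directions: set[str] = frozenset({"direct", "inverted"}),
) -> list[RepeatPair]:
    """Find dispersed direct/inverted repeat pairs meeting the thresholds.

    Mirror duplicates are removed (copy1 is always the copy with the
    smaller start), and pairs whose two copies both lie inside another
    pair's copies are collapsed onto the higher-scoring pair.
    """
    S = genome.sequence
    L = genome.length
    if L < 2 * min_len:
        raise GenomeError(f"genome {genome.id} shorter than 2*min_len")
    if "N" in S:
        # seeds never cross N, and identity arithmetic treats N as mismatch
        pass
    bad = set(S) - set("ACGTN")
    if bad:
        raise GenomeError(f"non-ACGTN symbols {sorted(bad)} in genome {genome.id}")

    D = S + S
    aligner = _make_aligner()
    candidates: list[RepeatPair] = []
    counter = 0

    if "direct" in directions:
        index = _kmer_positions(D, L, SEED_K)
        seeds_by_diag: dict[int, list[int]] = {}
        for positions in index.values():
            if len(positions) < 2:
                continue
            for a in positions:
                for b in positions:
                    if a == b:
                        continue
                    d = (b - a) % L
                    if d == 0:
                        continue
                    seeds_by_diag.setdefault(d, []).append(a)
        for i_min, i_max, d_min, d_max in _chain_seeds(seeds_by_diag, L):
            a0 = i_min - _MARGIN
            width = (i_max + SEED_K + _MARGIN) - a0
            width = min(width, L)
            b0 = a0 + d_min - _DIAG_BAND
            bwidth = width + (d_max - d_min) + 2 * _DIAG_BAND
            bwidth = min(bwidth, L)
            w1 = D[a0 % L : a0 % L + width]
            w2 = D[b0 % L : b0 % L + bwidth]
            aln = _best_alignment(aligner, w1, w2)
            if aln is None:
                continue
            matches, cols, s1, s2 = _alignment_stats(aln)
            identity = 100.0 * matches / cols
            if cols < min_len or identity < min_identity:
                continue
            r1 = aln.aligned[0]
            r2 = aln.aligned[1]
            start1 = a0 % L + r1[0][0]
            span1 = r1[-1][1] - r1[0][0]
            start2 = b0 % L + r2[0][0]
            span2 = r2[-1][1] - r2[0][0]
            c1 = _circle_interval(start1, span1, L)
            c2 = _circle_interval(start2, span2, L)
            if (c1.start, c1.end) == (c2.start, c2.end):
                continue
            if c1.start > c2.start:
                continue  # mirror candidate covers this pair
            counter += 1
            candidates.append(
                RepeatPair(
                    id=f"rep{counter}",
                    copy1=c1,
                    copy2=c2,
                    direction="direct",
                    identity_pct=round(identity, 2),
                    aligned_length=cols,
                    alignment=(s1, s2),
                    score=float(aln.score),
                )
            )

    if "inverted" in directions:
        R = reverse_complement(S)
        RR = R + R
        index = _kmer_positions(D, L, SEED_K)
        rindex = _kmer_positions(RR, L, SEED_K)
        seeds_by_diag: dict[int, list[int]] = {}
        for kmer, positions in index.items():
            rpos = rindex.get(kmer)
            if not rpos:
                continue
            for i in positions:
                for p in rpos:
                    # partner copy in genome coords starts at (L - p - k) % L
                    j = (L - p - SEED_K) % L
                    if j == i:
                        # a perfect palindrome aligned onto itself
                        continue
                    # copy1 vs reverse-complement is collinear, so one
                    # repeat keeps p - i constant across its seeds
                    d = (p - i) % L
                    seeds_by_diag.setdefault(d, []).append(i)
        for i_min, i_max, d_min, d_max in _chain_seeds(seeds_by_diag, L):
            a0 = i_min - _MARGIN
            width = (i_max + SEED_K + _MARGIN) - a0
            width = min(width, L)
            # a seed at copy1 position i on diagonal d sits at
            # reverse-strand coordinate p = i + d
            p0 = a0 + d_min - _DIAG_BAND
            pwidth = width + (d_max - d_min) + 2 * _DIAG_BAND
            pwidth = min(pwidth, L)
            w1 = D[a0 % L : a0 % L + width]
            w2 = RR[p0 % L : p0 % L + pwidth]
            aln = _best_alignment(aligner, w1, w2)
            if aln is None:
                continue
            matches, cols, s1, s2 = _alignment_stats(aln)
            identity = 100.0 * matches / cols
            if cols < min_len or identity < min_identity:
                continue
            r1 = aln.aligned[0]
            r2 = aln.aligned[1]
            start1 = a0 % L + r1[0][0]
            span1 = r1[-1][1] - r1[0][0]
            pa = p0 % L + r2[0][0]
            span2 = r2[-1][1] - r2[0][0]
            start2 = (L - (pa + span2)) % L
            c1 = _circle_interval(start1, span1, L)
            c2 = _circle_interval(start2, span2, L)
            if (c1.start, c1.end) == (c2.start, c2.end):
                continue
            if c1.start > c2.start:
                continue
            counter += 1
            candidates.append(
                RepeatPair(
                    id=f"rep{counter}",
                    copy1=c1,
                    copy2=c2,
                    direction="inverted",
                    identity_pct=round(identity, 2),
                    aligned_length=cols,
                    alignment=(s1, s2),
                    score=float(aln.score),
                )
            )

    return _deduplicate(candidates)


def _contains(outer: CircularInterval, inner: CircularInterval) -> bool:
    return interval_overlap(outer, inner) == inner.span()


def _deduplicate(pairs: list[RepeatPair]) -> list[RepeatPair]:
    # exact duplicates (same loci, same direction): keep best score
    by_key: dict[tuple, RepeatPair] = {}
    for p in pairs:
        key = (
            p.direction,
            p.copy1.start,
            p.copy1.end,
            p.copy2.start,
            p.copy2.end,
        )
        q = by_key.get(key)
        if q is None or p.score > q.score:
            by_key[key] = p
    unique = list(by_key.values())
    # collapse contained pairs onto the maximal-scoring pair
    unique.sort(key=lambda p: (-p.score, p.copy1.start, p.copy2.start))
    kept: list[RepeatPair] = []
    for p in unique:
        contained = any(
            q.direction == p.direction
            and _contains(q.copy1, p.copy1)
            and _contains(q.copy2, p.copy2)
            for q in kept
        )
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p.copy1.start, p.copy2.start))
    for n, p in enumerate(kept, 1):
        p.id = f"rep{n}"
    return kept


def select_assayable_repeats(
    pairs: list[RepeatPair],
    min_len: int = 50,
    max_len: int = 250,
    min_copy_gap: int = 1,
) -> list[RepeatPair]:
    """Repeats whose recombination is assayable by ~350 bp inserts.

    Keeps pairs with ``min_len <= aligned_length <= max_len`` (bounds
    inclusive) and non-overlapping copies; ordering is stable by copy1
    start. ``min_copy_gap`` requires at least that many bases between the
    copies on at least one arc (1 = merely non-overlapping).
    """
    kept = []
    for p in sorted(pairs, key=lambda p: (p.copy1.start, p.copy2.start)):
        if not (min_len <= p.aligned_length <= max_len):
            continue
        if interval_overlap(p.copy1, p.copy2) > 0:
            continue
        if min_copy_gap > 1:
            gap = _copy_gap(p)
            if gap < min_copy_gap:
                continue
        kept.append(p)
    return kept


def _copy_gap(p: RepeatPair) -> int:
    """Smaller of the two inter-copy arc lengths."""
    L = p.copy1.genome_length
    g1 = (p.copy2.start - p.copy1.end) % L
    g2 = (p.copy1.start - p.copy2.end) % L
    return min(g1, g2)


def _open_out(dest):
    if hasattr(dest, "write"):
        return contextlib.nullcontext(dest)
    return open(dest, "w")


def write_repeats_tsv(path, pairs: list[RepeatPair]) -> None:
    """One row per pair; coordinates 1-based inclusive on output."""
    with _open_out(path) as fh:
        fh.write(
            "id\tcopy1_start\tcopy1_end\tcopy2_start\tcopy2_end\t"
            "direction\tidentity_pct\taligned_length\n"
        )
        for p in pairs:
            fh.write(
                f"{p.id}\t{p.copy1.start + 1}\t{p.copy1.end}\t"
                f"{p.copy2.start + 1}\t{p.copy2.end}\t{p.direction}\t"
                f"{p.identity_pct:.2f}\t{p.aligned_length}\n"
            )
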