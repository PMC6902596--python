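"""Independent reference implementations used only by the test suite.

The repeat-finder oracle is a full-matrix affine-gap Smith-Waterman
(exhaustive dynamic programming, no seeding heuristics) written directly
from the recurrences, sharing no code with the package. Scoring matches
the package contract: match +1, mismatch -2, gap of length g costs 5+2g.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -(10**9)

_ENC = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[c] for c in reversed(s))


def _encode(s: str) -> np.ndarray:
    a = _ENC[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (a < 0).any():
        raise ValueError("non-ACGT base")
    return a


@njit(cache=True)
def _sw_matrices(s1, s2, mask_lower):
    n1, n2 = len(s1), len(s2)
    H = np.zeros((n1 + 1, n2 + 1), np.int32)
    E = np.full((n1 + 1, n2 + 1), NEG, np.int32)
    F = np.full((n1 + 1, n2 + 1), NEG, np.int32)
    best = 0
    bi = bj = 0
    for i in range(1, n1 + 1):
        for j in range(1, n2 + 1):
            if mask_lower and j <= i:
                continue
            e = H[i, j - 1] - 7
            if E[i, j - 1] - 2 > e:
                e = E[i, j - 1] - 2
            E[i, j] = e
            f = H[i - 1, j] - 7
            if F[i - 1, j] - 2 > f:
                f = F[i - 1, j] - 2
            F[i, j] = f
            sub = 1 if s1[i - 1] == s2[j - 1] else -2
            h = H[i - 1, j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi, bj = i, j
    return H, E, F, best, bi, bj


def sw_best_local(s1: str, s2: str, mask_lower: bool = False):
    """Best local alignment (score, start1, end1, start2, end2, cols,
    matches) with half-open coordinate ranges, or None when score is 0.

    With ``mask_lower`` alignments are restricted to cells j > i (used
    for self-comparison so a sequence cannot align onto itself and the
    first copy always precedes the second)."""
    a1, a2 = _encode(s1), _encode(s2)
    H, E, F, best, bi, bj = _sw_matrices(a1, a2, mask_lower)
    if best <= 0:
        return None
    # traceback from (bi, bj); diagonal preferred, then E (gap in s1), F
    i, j = bi, bj
    cols = matches = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            sub = 1 if a1[i - 1] == a2[j - 1] else -2
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + sub:
                cols += 1
                if sub == 1:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == E[i, j]:
                state = "E"
            elif H[i, j] == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                raise AssertionError("traceback failed")
        elif state == "E":
            cols += 1
            if E[i, j] == H[i, j - 1] - 7:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:
            cols += 1
            if F[i, j] == H[i - 1, j] - 7:
                i -= 1
                state = "H"
            else:
                i -= 1
    return best, i, bi, j, bj, cols, matches


def oracle_repeats(seq: str, min_len: int = 50, min_identity: float = 85.0):
    """Best qualifying direct and inverted repeat pair of a sequence.

    Returns a list of dicts with keys loci (frozenset of (start, end)),
    direction, cols, matches. Intended for test genomes carrying at most
    one planted pair per direction, away from the origin.
    """
    out = []
    hit = sw_best_local(seq, seq, mask_lower=True)
    if hit is not None:
        score, s1, e1, s2, e2, cols, matches = hit
        if cols >= min_len and 100.0 * matches / cols >= min_identity:
            out.append(
                {
                    "loci": frozenset({(s1, e1), (s2, e2)}),
                    "direction": "direct",
                    "cols": cols,
                    "matches": matches,
                    "score": score,
                }
            )
    L = len(seq)
    hit = sw_best_local(seq, revcomp(seq))
    if hit is not None:
        score, s1, e1, s2, e2, cols, matches = hit
        if cols >= min_len and 100.0 * matches / cols >= min_identity:
            locus2 = (L - e2, L - s2)
            out.append(
                {
                    "loci": frozenset({(s1, e1), locus2}),
                    "direction": "inverted",
                    "cols": cols,
                    "matches": matches,
                    "score": score,
                }
            )
    return out


def best_local_score(seq: str) -> int:
    """Max local-alignment score over both orientations (for null genomes)."""
    best = 0
    for hit in (
        sw_best_local(seq, seq, mask_lower=True),
        sw_best_local(seq, revcomp(seq)),
    ):
        if hit is not None:
            best = max(best, hit[0])
    return best


# ---------------------------------------------------------------------------
# Planted-repeat genome construction for oracle comparisons

_BASES = "ACGT"


def _other_base(rng, not_these) -> str:
    choices = [b for b in _BASES if b not in not_these]
    return choices[int(rng.integers(len(choices)))]


def make_repeat_genome(rng, L: int, length: int, direction: str, n_mut: int):
    """Random sequence with one planted repeat pair and unambiguous borders.

    Substitution positions are interior (>= 5 bp from either end) and
    pairwise >= 30 bp apart — every inter-mutation stretch then carries an
    exact 20-mer, keeping the pair inside the detector's documented
    sensitivity — and the 4 bases flanking each copy are forced to
    mismatch their aligned counterparts, so the optimal local alignment is
    unique and covers exactly the planted loci.

    Returns (seq, loci frozenset, cols, matches).
    """
    seq = list("".join(rng.choice(list(_BASES), size=L)))
    pos1 = int(rng.integers(100, L // 2 - length - 200))
    pos2 = int(rng.integers(L // 2 + 100, L - length - 100))
    rep = [seq[pos1 + k] for k in range(length)]
    copy2 = list(rep)
    chosen: list[int] = []
    if n_mut:
        step = (length - 10) // n_mut
        assert step >= 30, "repeat too short for requested mutations"
        for k in range(n_mut):
            chosen.append(5 + k * step + int(rng.integers(0, step - 29)))
    for p in chosen:
        copy2[p] = _other_base(rng, {copy2[p]})
    if direction == "direct":
        seq[pos2 : pos2 + length] = copy2
        for t in range(1, 5):
            if seq[pos2 - t] == seq[pos1 - t]:
                seq[pos2 - t] = _other_base(rng, {seq[pos1 - t]})
            i, j = pos1 + length + t - 1, pos2 + length + t - 1
            if seq[j] == seq[i]:
                seq[j] = _other_base(rng, {seq[i]})
    else:
        seq[pos2 : pos2 + length] = list(revcomp("".join(copy2)))
        for t in range(0, 4):
            # right extension of copy1 pairs with the base before copy2
            i, j = pos1 + length + t, pos2 - 1 - t
            if seq[j] == _COMP[seq[i]]:
                seq[j] = _other_base(rng, {_COMP[seq[i]]})
            # left extension of copy1 pairs with the base after copy2
            i, j = pos1 - 1 - t, pos2 + length + t
            if seq[j] == _COMP[seq[i]]:
                seq[j] = _other_base(rng, {_COMP[seq[i]]})
    loci = frozenset({(pos1, pos1 + length), (pos2, pos2 + length)})
    return "".join(seq), loci, length, length - n_mut


# ---------------------------------------------------------------------------
# Brute-force circular-interval oracle

def circle_positions(start: int, end: int, L: int) -> set[int]:
    """Positions of the arc [start, end) walked forward on a circle,
    treating start >= end (with end != L) as wrapping."""
    if end != L and start >= end:
        return set(range(start, L)) | set(range(0, end))
    return set(range(start, end))
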