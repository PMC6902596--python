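"""Circular-coordinate arithmetic.

Plant mitochondrial assemblies are circular molecules with an arbitrary
origin, so features (and especially dispersed repeats) may span the
sequence start. All internal coordinates are 0-based half-open on the
circle; an interval *wraps* when ``start >= end``, in which case it covers
``[start, genome_length) + [0, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass


class CoordinateError(ValueError):
    """An interval is inconsistent with its genome."""


@dataclass(frozen=True)
class CircularInterval:
    """A non-empty arc of a circular genome.

    Parameters
    ----------
    start:
        0-based inclusive start, in ``[0, genome_length)``.
    end:
        0-based exclusive end, in ``[0, genome_length]``. ``end <= start``
        denotes an arc wrapping through the origin.
    genome_length:
        Length of the circle in bp.
    """

    start: int
    end: int
    genome_length: int

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise CoordinateError(f"genome_length must be positive, got {self.genome_length}")
        if not (0 <= self.start < self.genome_length):
            raise CoordinateError(
                f"start {self.start} outside [0, {self.genome_length})"
            )
        if not (0 <= self.end <= self.genome_length):
            raise CoordinateError(f"end {self.end} outside [0, {self.genome_length}]")
        if self.span() == 0:
            raise CoordinateError("zero-span interval is not allowed")

    @property
    def wraps(self) -> bool:
        """True iff the arc runs through the origin."""
        # end == genome_length is a plain suffix interval, not a wrap
        return self.end != self.genome_length and self.start >= self.end

    def span(self) -> int:
        """Number of bases covered, in [1, genome_length]."""
        if self.end == self.genome_length and self.start == 0:
            return self.genome_length
        d = (self.end - self.start) % self.genome_length
        return d if d > 0 else self.genome_length

    def segments(self) -> list[tuple[int, int]]:
        """Linear half-open segments covering the arc (1 or 2 of them)."""
        if self.wraps:
            segs = [(self.start, self.genome_length)]
            if self.end > 0:
                segs.append((0, self.end))
            return segs
        return [(self.start, self.end)]

    def contains(self, pos: int) -> bool:
        pos %= self.genome_length
        return any(a <= pos < b for a, b in self.segments())

    def positions(self) -> list[int]:
        """All covered positions in arc order (small spans only)."""
        return [(self.start + k) % self.genome_length for k in range(self.span())]

    def shifted(self, offset: int) -> "CircularInterval":
        """The same arc after rotating the origin by ``offset`` bases."""
        L = self.genome_length
        s = (self.start + offset) % L
        e = (s + self.span()) % L
        if e == 0:
            e = L
        return CircularInterval(s, e, L)


def interval_overlap(a: CircularInterval, b: CircularInterval) -> int:
    """Number of bases shared by two arcs of the same circle (symmetric)."""
    if a.genome_length != b.genome_length:
        raise CoordinateError(
            f"intervals on different circles ({a.genome_length} vs {b.genome_length})"
        )
    total = 0
    for a0, a1 in a.segments():
        for b0, b1 in b.segments():
            total += max(0, min(a1, b1) - max(a0, b0))
    return total


def from_one_based(start1: int, end1: int, genome_length: int) -> CircularInterval:
    """Convert a 1-based inclusive (GFF3/GenBank style) range.

    ``start1 > end1`` is rejected; origin-spanning features arrive as joins
    and are merged by the readers, not here.
    """
    if start1 < 1 or end1 > genome_length or start1 > end1:
        raise CoordinateError(
            f"1-based range {start1}..{end1} invalid on genome of length {genome_length}"
        )
    return CircularInterval(start1 - 1, end1, genome_length)


def to_one_based(iv: CircularInterval) -> list[tuple[int, int]]:
    """1-based inclusive segment(s); two segments for a wrapping arc."""
    return [(a + 1, b) for a, b in iv.segments()]
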