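"""Gene-order consequences of recombination and rearrangement distances.

Gene orders are signed circular permutations (sign = strand). Two orders
are compared after canonicalizing under rotation and reflection (a
reflection reverses the list and flips every sign — reading the circle
from the other strand). "Gene order changed" after a recombination event
means the canonical set of signed gene adjacencies over all product
circles differs from the master's: direct-repeat excisions that pop out a
gene-free subcircle preserve every adjacency and leave the order
unchanged, whereas inverting a gene-bearing segment rewires the two
boundary adjacencies.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

from .genome import AnnotatedGenome, Feature
from .intervals import interval_overlap
from .repeats import RepeatPair

SignedGene = tuple[str, int]  # (label, +1/-1)


@dataclass
class GeneOrder:
    """A signed circular permutation of gene labels."""

    genome_id: str
    order: tuple[SignedGene, ...]

    def __post_init__(self) -> None:
        labels = [g for g, _ in self.order]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.genome_id}: duplicate gene labels in order")

    def canonical(self) -> tuple[SignedGene, ...]:
        return canonical_form(self.order)

    def adjacencies(self) -> frozenset:
        return adjacency_set(self.order)


@dataclass
class RecombinationOutcome:
    event_id: str
    products: list[GeneOrder]
    gene_order_state: str  # changed | unchanged
    genes_affected: list[str] = field(default_factory=list)
    high_impact: list[str] = field(default_factory=list)  # genes inside a repeat copy


# ---------------------------------------------------------------------------
# Canonical forms and adjacencies

def _reflect(order: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
    return tuple((g, -s) for g, s in reversed(order))


def canonical_form(order: tuple[SignedGene, ...]) -> tuple[SignedGene, ...]:
    """Lexicographically smallest rotation over both reading directions."""
    if not order:
        return order
    variants = []
    for seq in (order, _reflect(order)):
        for i in range(len(seq)):
            variants.append(seq[i:] + seq[:i])
    return min(variants)


def _canon_adj(a: SignedGene, b: SignedGene) -> tuple:
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(order: tuple[SignedGene, ...]) -> frozenset:
    """Reflection-invariant signed adjacencies of a circular order."""
    n = len(order)
    if n == 0:
        return frozenset()
    return frozenset(_canon_adj(order[i], order[(i + 1) % n]) for i in range(n))


# ---------------------------------------------------------------------------
# Extraction and recombination application

def extract_gene_order(
    genome: AnnotatedGenome,
    include_kinds: set[str] | frozenset[str] = frozenset({"gene", "tRNA", "rRNA"}),
) -> GeneOrder:
    """Gene order by start position on the circle; sign from strand.

    Duplicate gene labels are suffixed _1, _2, ... in positional order.
    """
    if not include_kinds:
        raise ValueError("include_kinds must be non-empty")
    feats = sorted(
        (f for f in genome.features if f.kind in include_kinds),
        key=lambda f: (f.interval.start, f.id),
    )
    if not feats:
        raise ValueError(f"genome {genome.id}: no features of kinds {sorted(include_kinds)}")
    seen: dict[str, int] = {}
    order: list[SignedGene] = []
    for f in feats:
        label = f.gene_name or f.id
        seen[label] = seen.get(label, 0) + 1
        order.append((label, 1 if f.strand == "+" else -1))
    dup = {k for k, v in seen.items() if v > 1}
    if dup:
        counters = {k: 0 for k in dup}
        renamed = []
        for g, s in order:
            if g in dup:
                counters[g] += 1
                renamed.append((f"{g}_{counters[g]}", s))
            else:
                renamed.append((g, s))
        order = renamed
    return GeneOrder(genome_id=genome.id, order=tuple(order))


def _split_by_arc(
    genome: AnnotatedGenome, pair: RepeatPair, feats: list[Feature]
) -> tuple[list[Feature], list[Feature]]:
    """Partition genes into (between-copies arc B, remainder A).

    The inter-copy arc runs from copy1-end to copy2-start in ascending
    coordinate direction; genes are assigned by their start position. Both
    lists preserve circular order starting at copy1-end.
    """
    L = genome.length
    origin = pair.copy1.end % L
    d = (pair.copy2.start - origin) % L
    keyed = sorted(feats, key=lambda f: ((f.interval.start - origin) % L, f.id))
    B = [f for f in keyed if (f.interval.start - origin) % L < d]
    A = [f for f in keyed if (f.interval.start - origin) % L >= d]
    return B, A


def _feats_to_order(genome_id: str, feats: list[Feature], labels: dict[str, str]) -> GeneOrder:
    return GeneOrder(
        genome_id=genome_id,
        order=tuple((labels[f.id], 1 if f.strand == "+" else -1) for f in feats),
    )


def invert_block(order: tuple[SignedGene, ...], n_block: int) -> tuple[SignedGene, ...]:
    """Reverse and sign-flip the first ``n_block`` entries (one inversion)."""
    block = tuple((g, -s) for g, s in reversed(order[:n_block]))
    return block + order[n_block:]


def apply_recombination(
    genome: AnnotatedGenome,
    pair: RepeatPair,
    include_kinds: set[str] | frozenset[str] = frozenset({"gene", "tRNA", "rRNA"}),
) -> RecombinationOutcome:
    """Predict the structural outcome of recombination across a repeat pair.

    Inverted pair: the segment between the copies is inverted in place,
    one product circle. Direct pair: that segment (plus one repeat copy)
    is excised as a second circle, two products. Genes affected are those
    overlapping either repeat copy.
    """
    if interval_overlap(pair.copy1, pair.copy2) > 0:
        raise ValueError(f"pair {pair.id}: copies overlap; not assayable")
    master = extract_gene_order(genome, include_kinds)
    feats = sorted(
        (f for f in genome.features if f.kind in include_kinds),
        key=lambda f: (f.interval.start, f.id),
    )
    # reuse extract_gene_order's dedup labels, keyed by feature id
    labels = {f.id: g for f, (g, _) in zip(feats, _order_in_start_order(master, feats))}

    affected = []
    high_impact = []
    for f in feats:
        ov = max(
            interval_overlap(f.interval, pair.copy1),
            interval_overlap(f.interval, pair.copy2),
        )
        if ov > 0:
            affected.append(labels[f.id])
            if ov == f.interval.span():
                high_impact.append(labels[f.id])

    B, A = _split_by_arc(genome, pair, feats)
    if pair.direction == "inverted":
        rotated = B + A  # circular order starting at copy1-end
        order = _feats_to_order(genome.id, rotated, labels).order
        product = GeneOrder(genome_id=f"{genome.id}|inv", order=invert_block(order, len(B)))
        products = [product]
    else:
        main = GeneOrder(
            genome_id=f"{genome.id}|main",
            order=_feats_to_order(genome.id, A, labels).order,
        )
        sub = GeneOrder(
            genome_id=f"{genome.id}|sub",
            order=_feats_to_order(genome.id, B, labels).order,
        )
        products = [main, sub]

    union_adj = frozenset().union(*(p.adjacencies() for p in products))
    state = "unchanged" if union_adj == master.adjacencies() else "changed"
    return RecombinationOutcome(
        event_id=pair.id,
        products=products,
        gene_order_state=state,
        genes_affected=affected,
        high_impact=high_impact,
    )


def _order_in_start_order(master: GeneOrder, feats: list[Feature]) -> list[SignedGene]:
    """master.order is already in start order and aligned with feats."""
    assert len(master.order) == len(feats)
    return list(master.order)


# ---------------------------------------------------------------------------
# Rearrangement distances

def _intersect(o1: GeneOrder, o2: GeneOrder) -> tuple[tuple, tuple, int]:
    l1 = {g for g, _ in o1.order}
    l2 = {g for g, _ in o2.order}
    common = l1 & l2
    dropped = len(l1 - common) + len(l2 - common)
    a = tuple((g, s) for g, s in o1.order if g in common)
    b = tuple((g, s) for g, s in o2.order if g in common)
    if not common:
        raise ValueError("gene orders share no labels")
    return a, b, dropped


def breakpoint_distance(o1: GeneOrder, o2: GeneOrder) -> int:
    """Adjacencies of order1 absent from order2 (circular, reflection-aware)."""
    a, b, _ = _intersect(o1, o2)
    return len(adjacency_set(a) - adjacency_set(b))


def _neighbors(order: tuple[SignedGene, ...]):
    n = len(order)
    seen = set()
    for i in range(n):
        rot = order[i:] + order[:i]
        for l in range(1, n):
            cand = canonical_form(invert_block(rot, l))
            if cand not in seen:
                seen.add(cand)
                yield cand


def inversion_distance(o1: GeneOrder, o2: GeneOrder, max_genes: int = 12, max_depth: int = 10) -> int:
    """Minimum number of signed inversions, exact by bidirectional BFS.

    Exact search is limited to ``max_genes`` genes; larger instances
    should use :func:`inversion_distance_bounds`.
    """
    a, b, _ = _intersect(o1, o2)
    if len(a) > max_genes:
        lo, hi = inversion_distance_bounds(o1, o2)
        if lo == hi:
            return lo
        raise ValueError(
            f"exact inversion distance limited to {max_genes} genes; "
            f"bounds are [{lo}, {hi}]"
        )
    start, goal = canonical_form(a), canonical_form(b)
    if start == goal:
        return 0
    front = {start: 0}
    back = {goal: 0}
    fq, bq = deque([start]), deque([goal])
    depth_f = depth_b = 0
    while fq or bq:
        if depth_f + depth_b >= max_depth:
            raise ValueError(f"inversion distance exceeds search depth {max_depth}")
        # expand the smaller frontier
        if len(fq) <= len(bq):
            frontier, other, q = front, back, fq
            depth_f += 1
            depth = depth_f
        else:
            frontier, other, q = back, front, bq
            depth_b += 1
            depth = depth_b
        nxt = deque()
        for _ in range(len(q)):
            state = q.popleft()
            for nb in _neighbors(state):
                if nb in other:
                    return depth + other[nb]
                if nb not in frontier:
                    frontier[nb] = depth
                    nxt.append(nb)
        q.extend(nxt)
    raise ValueError("orders are not connected under inversions")  # pragma: no cover


def inversion_distance_bounds(o1: GeneOrder, o2: GeneOrder) -> tuple[int, int]:
    """(lower, upper) bounds on the inversion distance.

    Lower: ceil(breakpoints / 2) — one inversion repairs at most two
    adjacencies. Upper: a constructive sort placing each gene in turn with
    at most two inversions (one to position, one to fix sign).
    """
    a, b, _ = _intersect(o1, o2)
    bp = len(adjacency_set(a) - adjacency_set(b))
    lo = (bp + 1) // 2
    # constructive upper bound
    cur = list(a)
    target = list(b)
    moves = 0
    # rotate target so its first gene matches by label
    for k in range(len(target)):
        if target[k][0] == cur[0][0]:
            target = target[k:] + target[:k]
            break
    for i in range(len(target)):
        g, s = target[i]
        j = next(k for k in range(i, len(cur)) if cur[k][0] == g)
        if j != i:
            cur[i : j + 1] = [(x, -y) for x, y in reversed(cur[i : j + 1])]
            moves += 1
        if cur[i][1] != s:
            cur[i] = (cur[i][0], -cur[i][1])
            moves += 1
    hi = max(moves, lo)
    return lo, hi


def rearrangement_distance(o1: GeneOrder, o2: GeneOrder, metric: str = "breakpoint") -> int:
    """Pairwise gene-order distance; symmetric, zero iff canonically equal."""
    if metric == "breakpoint":
        return breakpoint_distance(o1, o2)
    if metric == "inversion":
        return inversion_distance(o1, o2)
    raise ValueError(f"unknown metric {metric!r}")
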