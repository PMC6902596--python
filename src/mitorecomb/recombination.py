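"""Read-pair detection of repeat-mediated recombination.

For every assayable repeat pair a *reference panel* is built: the two
original junction sequences (each repeat copy with up to 200 bp of genomic
flank on both sides) plus the recombinant junctions that homologous
exchange across the two copies would create. With identical copies there
are two distinct recombinants (4 panel members); with diverged copies,
six — the four crossover products (both flank swaps, carrying either
copy's repeat sequence) and the two conversion products (each original
flank context carrying the other copy's repeat sequence) — for 8 members.

A read pair supports a member when both mates align end-to-end to it,
inward-facing, each at >= 98% identity, with the united footprint covering
at least 50 bp of the upstream AND downstream flank, and an implied insert
no larger than 1 kb. A pair is assigned to its best-scoring member; equal
best support for an original and a recombinant member makes it ambiguous
and it is discarded. The per-repeat recombination rate is the percentage
of unambiguous junction-informative pairs supporting any recombinant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import edlib

from .genome import AnnotatedGenome, ReadPair, reverse_complement, subsequence
from .intervals import CircularInterval, interval_overlap
from .repeats import RepeatPair

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


class UndefinedRateError(ValueError):
    """No informative read pairs: the rate has an empty denominator."""


@dataclass
class PanelMember:
    label: str
    sequence: str
    flank_up: int
    flank_down: int
    truncated: bool = False

    @property
    def conformation(self) -> str:
        return "original" if self.label.startswith("original") else "recombinant"


@dataclass
class ReferencePanel:
    pair_id: str
    members: list[PanelMember]

    def __post_init__(self) -> None:
        labels = [m.label for m in self.members]
        if len(set(labels)) != len(labels):
            raise ValueError(f"panel {self.pair_id}: duplicate member labels")
        n_orig = sum(1 for m in self.members if m.conformation == "original")
        if n_orig != 2:
            raise ValueError(f"panel {self.pair_id}: expected 2 originals, got {n_orig}")


@dataclass
class SupportCounts:
    pair_id: str
    master_pairs: int = 0
    alternative_pairs: int = 0
    ambiguous_pairs: int = 0
    unmatched_pairs: int = 0
    per_member: dict[str, int] = field(default_factory=dict)


@dataclass
class RecombinationEvent:
    """One detected (or transcribed) recombination observation."""

    species: str
    length_bp: int
    identity_pct: float
    direction: str
    copy1_pos: str
    copy2_pos: str
    master_count: int
    alt_count: int
    rate_pct: float
    gene_order_state: str  # changed | unchanged
    genes_affected: list[str] = field(default_factory=list)
    master_pct: float | None = None  # as printed/derived; counts stay authoritative
    alt_pct: float | None = None
    event_id: str = ""
    # printed master/alt percentages fail to sum to 100 (transcription quirk)
    percent_discrepancy: bool = False


@dataclass
class RecombinationSummary:
    n_events: int
    n_species: int
    rate_median_pct: float
    rate_min_pct: float
    rate_max_pct: float
    mean_repeat_length: int
    n_repeats_gt100: int
    pct_repeats_gt100: float
    n_small: int
    rate_median_small_pct: float | None
    n_order_changed: int
    # 2x2 tables: {(direction, outcome): count}
    contingency_direction_by_order_change: dict[tuple[str, str], int]
    contingency_direction_by_genes_affected: dict[tuple[str, str], int]


# ---------------------------------------------------------------------------
# Reference panel

def _arc_gap(from_end: int, to_start: int, L: int) -> int:
    """Bases strictly between two circle coordinates, walking forward."""
    return (to_start - from_end) % L


def _flank_interval(start: int, length: int, L: int) -> CircularInterval | None:
    if length <= 0:
        return None
    s = start % L
    e = (s + length) % L
    return CircularInterval(s, e if e != 0 else L, L)


def build_reference_panel(
    genome: AnnotatedGenome, pair: RepeatPair, flank: int = 200
) -> ReferencePanel:
    """Build the master/alternative junction reference panel for one pair.

    Flanks that would run into the partner copy are truncated at the copy
    boundary and the member is flagged ``truncated``. For inverted pairs
    copy2 and its flanks are reverse-complemented so every member reads on
    one strand.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    if interval_overlap(pair.copy1, pair.copy2) > 0:
        raise ValueError(f"pair {pair.id}: copies overlap; not assayable")
    L = genome.length
    c1, c2 = pair.copy1, pair.copy2
    r1 = subsequence(genome, c1)

    # available flank room before hitting the partner copy
    up1_len = min(flank, _arc_gap(c2.end, c1.start, L))
    down1_len = min(flank, _arc_gap(c1.end, c2.start, L))
    up1 = _extract_flank(genome, (c1.start - up1_len) % L, up1_len)
    down1 = _extract_flank(genome, c1.end % L, down1_len)

    if pair.direction == "direct":
        r2 = subsequence(genome, c2)
        up2_len = min(flank, _arc_gap(c1.end, c2.start, L))
        down2_len = min(flank, _arc_gap(c2.end, c1.start, L))
        up2 = _extract_flank(genome, (c2.start - up2_len) % L, up2_len)
        down2 = _extract_flank(genome, c2.end % L, down2_len)
    else:
        # read copy2 on the minus strand: upstream of the reading direction
        # is the genomic segment after copy2, reverse-complemented
        r2 = reverse_complement(subsequence(genome, c2))
        up2_len = min(flank, _arc_gap(c2.end, c1.start, L))
        down2_len = min(flank, _arc_gap(c1.end, c2.start, L))
        up2 = reverse_complement(_extract_flank(genome, c2.end % L, up2_len))
        down2 = reverse_complement(
            _extract_flank(genome, (c2.start - down2_len) % L, down2_len)
        )

    trunc1 = up1_len < flank or down1_len < flank
    trunc2 = up2_len < flank or down2_len < flank
    identical = r1 == r2

    members = [
        PanelMember("original_1", up1 + r1 + down1, up1_len, down1_len, trunc1),
        PanelMember("original_2", up2 + r2 + down2, up2_len, down2_len, trunc2),
    ]
    if identical:
        members += [
            PanelMember("recomb_u1_d2", up1 + r1 + down2, up1_len, down2_len, trunc1 or trunc2),
            PanelMember("recomb_u2_d1", up2 + r2 + down1, up2_len, down1_len, trunc1 or trunc2),
        ]
    else:
        members += [
            # crossover products: flank swap x either repeat-copy sequence
            PanelMember("recomb_u1_r1_d2", up1 + r1 + down2, up1_len, down2_len, trunc1 or trunc2),
            PanelMember("recomb_u1_r2_d2", up1 + r2 + down2, up1_len, down2_len, trunc1 or trunc2),
            PanelMember("recomb_u2_r1_d1", up2 + r1 + down1, up2_len, down1_len, trunc1 or trunc2),
            PanelMember("recomb_u2_r2_d1", up2 + r2 + down1, up2_len, down1_len, trunc1 or trunc2),
            # conversion products: original flank context, partner repeat copy
            PanelMember("recomb_u1_r2_d1", up1 + r2 + down1, up1_len, down1_len, trunc1),
            PanelMember("recomb_u2_r1_d2", up2 + r1 + down2, up2_len, down2_len, trunc2),
        ]
    return ReferencePanel(pair_id=pair.id, members=members)


def _extract_flank(genome: AnnotatedGenome, start: int, length: int) -> str:
    if length <= 0:
        return ""
    iv = _flank_interval(start, length, genome.length)
    return subsequence(genome, iv)


# ---------------------------------------------------------------------------
# Read-pair classification

def _cigar_stats(cigar: str) -> tuple[int, int]:
    """(alignment columns, matches) from an extended cigar string."""
    cols = matches = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
        elif op == "M":  # plain M: cannot distinguish, treat as match
            matches += n
    return cols, matches


def _best_hit(query: str, target: str):
    """Best end-to-end placement of query in target (edlib infix mode).

    Returns (edit_distance, identity_pct, start, end_inclusive) or None.
    """
    res = edlib.align(query, target, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    cols, matches = _cigar_stats(res["cigar"])
    identity = 100.0 * matches / cols
    start, end = res["locations"][0]
    return res["editDistance"], identity, start, end


def _kmer_screen_set(members: list[PanelMember], k: int = 20) -> set[str]:
    # every member k-mer, both strands: the mate-side scan may then stride
    kmers: set[str] = set()
    for m in members:
        seq = m.sequence
        for i in range(max(1, len(seq) - k + 1)):
            kmers.add(seq[i : i + k])
    kmers |= {reverse_complement(s) for s in list(kmers)}
    return kmers


def _mate_hits_screen(mate: str, kmers: set[str], k: int = 20, stride: int = 10) -> bool:
    for i in range(0, max(1, len(mate) - k + 1), stride):
        if mate[i : i + k] in kmers:
            return True
    return mate[-k:] in kmers


def classify_read_pairs(
    panel: ReferencePanel,
    reads: list[ReadPair],
    min_identity: float = 98.0,
    min_flank_cov: int = 50,
    max_insert: int = 1000,
) -> SupportCounts:
    """Count read pairs supporting each panel member.

    A fast exact-k-mer prescreen discards pairs that cannot reach the
    identity threshold on any member (a 150 bp mate at >= 98% identity has
    at most 3 edits and therefore always retains an exact 29 bp run, which
    the stride-10 20-mer scan is guaranteed to hit).
    """
    counts = SupportCounts(pair_id=panel.pair_id)
    counts.per_member = {m.label: 0 for m in panel.members}
    screen = _kmer_screen_set(panel.members)

    for pair in reads:
        if not (_mate_hits_screen(pair.mate1, screen) and _mate_hits_screen(pair.mate2, screen)):
            counts.unmatched_pairs += 1
            continue
        best_dist = None
        best_members: set[str] = set()
        best_confs: set[str] = set()
        for m in panel.members:
            hit = _evaluate_member(pair, m, min_identity, min_flank_cov, max_insert)
            if hit is None:
                continue
            if best_dist is None or hit < best_dist:
                best_dist = hit
                best_members = {m.label}
                best_confs = {m.conformation}
            elif hit == best_dist:
                best_members.add(m.label)
                best_confs.add(m.conformation)
        if best_dist is None:
            counts.unmatched_pairs += 1
        elif len(best_confs) > 1:
            counts.ambiguous_pairs += 1
        else:
            label = min(best_members)
            counts.per_member[label] += 1
            if "original" in best_confs:
                counts.master_pairs += 1
            else:
                counts.alternative_pairs += 1
    return counts


def _evaluate_member(
    pair: ReadPair,
    member: PanelMember,
    min_identity: float,
    min_flank_cov: int,
    max_insert: int,
) -> int | None:
    """Total edit distance of the best valid inward-facing placement,
    or None if the pair does not support this member."""
    target = member.sequence
    best: int | None = None
    for fwd, rev in ((pair.mate1, pair.mate2), (pair.mate2, pair.mate1)):
        h1 = _best_hit(fwd, target)
        h2 = _best_hit(reverse_complement(rev), target)
        if h1 is None or h2 is None:
            continue
        d1, id1, s1, e1 = h1
        d2, id2, s2, e2 = h2
        if id1 < min_identity or id2 < min_identity:
            continue
        if s1 > s2:  # not inward-facing in this orientation
            continue
        insert = e2 - s1 + 1
        if insert > max_insert or insert < max(len(fwd), len(rev)):
            continue
        up_cov = _span_cov(s1, e1, s2, e2, 0, member.flank_up)
        down_cov = _span_cov(
            s1, e1, s2, e2, len(target) - member.flank_down, len(target)
        )
        if up_cov < min_flank_cov or down_cov < min_flank_cov:
            continue
        total = d1 + d2
        if best is None or total < best:
            best = total
    return best


def _span_cov(s1: int, e1: int, s2: int, e2: int, lo: int, hi: int) -> int:
    """Bases of [lo, hi) covered by the union of two inclusive spans."""
    spans = [(s1, e1 + 1), (s2, e2 + 1)]
    spans.sort()
    merged = [list(spans[0])]
    for a, b in spans[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return sum(max(0, min(b, hi) - max(a, lo)) for a, b in merged)


# ---------------------------------------------------------------------------
# Rates and cohort summary

def recombination_rate(counts: SupportCounts) -> float:
    """Percent of informative pairs supporting the alternative conformation,
    to 2 decimals (half-up)."""
    denom = counts.master_pairs + counts.alternative_pairs
    if denom == 0:
        raise UndefinedRateError(f"pair {counts.pair_id}: no informative read pairs")
    rate = Decimal(100 * counts.alternative_pairs) / Decimal(denom)
    return float(rate.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _median(values: list[Decimal]) -> Decimal:
    vals = sorted(values)
    n = len(vals)
    mid = n // 2
    if n % 2:
        return vals[mid]
    return (vals[mid - 1] + vals[mid]) / 2


def _q2(x: Decimal) -> float:
    return float(x.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize_events(events: list[RecombinationEvent]) -> RecombinationSummary:
    """Cohort statistics over recombination events.

    The median of an even-sized cohort is the midpoint of the two central
    values; "small" repeats are those shorter than 100 bp.
    """
    if not events:
        raise ValueError("summarize_events requires at least one event")
    rates = [Decimal(str(e.rate_pct)) for e in events]
    lengths = [e.length_bp for e in events]
    small = [e for e in events if e.length_bp < 100]
    small_rates = [Decimal(str(e.rate_pct)) for e in small]

    tab_order: dict[tuple[str, str], int] = {}
    tab_genes: dict[tuple[str, str], int] = {}
    for d in ("direct", "inverted"):
        for s in ("changed", "unchanged"):
            tab_order[(d, s)] = 0
        for s in ("affected", "unaffected"):
            tab_genes[(d, s)] = 0
    for e in events:
        tab_order[(e.direction, e.gene_order_state)] += 1
        tab_genes[(e.direction, "affected" if e.genes_affected else "unaffected")] += 1

    n_gt100 = sum(1 for x in lengths if x > 100)
    return RecombinationSummary(
        n_events=len(events),
        n_species=len({e.species for e in events}),
        rate_median_pct=_q2(_median(rates)),
        rate_min_pct=_q2(min(rates)),
        rate_max_pct=_q2(max(rates)),
        mean_repeat_length=int(
            (Decimal(sum(lengths)) / len(lengths)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        ),
        n_repeats_gt100=n_gt100,
        pct_repeats_gt100=float(
            (Decimal(100 * n_gt100) / len(events)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
        ),
        n_small=len(small),
        rate_median_small_pct=_q2(_median(small_rates)) if small_rates else None,
        n_order_changed=sum(1 for e in events if e.gene_order_state == "changed"),
        contingency_direction_by_order_change=tab_order,
        contingency_direction_by_genes_affected=tab_genes,
    )
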