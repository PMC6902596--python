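"""Synthetic circular mitogenomes and paired-end reads with ground truth.

The generator emulates the architecture the analysis targets: a 20-150 kb
circular genome carrying a liverwort-like gene set (genes with optional
group I/II introns separated by intergenic spacers), dispersed repeat
pairs planted into spacers at configurable length/identity/direction, and
an Illumina-style 2x150 bp paired-end read pool drawn from a mixture of
the master circle and the recombinant molecules each repeat would create.
Every read records the molecule it came from, so downstream estimates can
be checked against planted truth.

Recombinant molecules are full-length circles: for an inverted pair the
inter-copy segment is inverted in place; for a direct pair the inter-copy
segment plus one repeat copy is excised as a subcircle, and reads are
drawn from the two product circles in proportion to their lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome import AnnotatedGenome, Feature, ReadPair, reverse_complement
from .intervals import CircularInterval
from .repeats import RepeatPair

# liverwort-like mitochondrial gene complement (protein, rRNA, tRNA)
GENE_POOL = [
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "nad7", "nad9",
    "cob", "cox1", "cox2", "cox3",
    "atp1", "atp4", "atp6", "atp8", "atp9",
    "ccmB", "ccmC", "ccmFC", "ccmFN",
    "rps1", "rps2", "rps3", "rps4", "rps7", "rps8", "rps10", "rps11",
    "rps12", "rps13", "rps14", "rps19",
    "rpl2", "rpl5", "rpl6", "rpl16",
    "rrn5", "rrn18", "rrn26",
    "trnM", "trnS", "trnW", "trnY",
]

STOPS = ("TAA", "TAG", "TGA")
BASES = np.array(list("ACGT"))


class CapacityError(ValueError):
    """Requested features exceed the genome length."""


@dataclass(frozen=True)
class PlantedRepeat:
    length: int
    direction: str = "direct"  # direct | inverted
    identity_pct: float = 100.0
    min_copy_gap: int = 1000

    def __post_init__(self) -> None:
        if self.length < 50:
            raise ValueError("planted repeat lengths must be >= 50 bp")
        if self.direction not in {"direct", "inverted"}:
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class SimulationConfig:
    genome_length: int = 50_000
    n_genes: int = 25
    gene_length_range: tuple[int, int] = (300, 2000)
    intron_rate: float = 0.3
    gc_fraction: float = 0.45
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    alt_fraction_per_repeat: list[float] = field(default_factory=list)
    coverage: float = 100.0
    read_length: int = 150
    insert_mean: int = 350
    insert_sd: int = 35
    base_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.gc_fraction <= 1:
            raise ValueError("gc_fraction must be in [0,1]")
        if not 0 <= self.base_error_rate <= 1:
            raise ValueError("base_error_rate must be in [0,1]")
        for f in self.alt_fraction_per_repeat:
            if not 0 <= f <= 1:
                raise ValueError("alt fractions must be in [0,1]")
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must not exceed insert_mean")
        if self.alt_fraction_per_repeat and len(self.alt_fraction_per_repeat) != len(
            self.planted_repeats
        ):
            raise ValueError("alt_fraction_per_repeat must align with planted_repeats")


@dataclass
class SimulationTruth:
    genome: AnnotatedGenome
    planted_pairs: list[RepeatPair]
    molecule_pool: list[tuple[str, float]] = field(default_factory=list)
    read_provenance: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def _random_cds(rng: np.random.Generator, n_codons: int, gc: float) -> str:
    """ATG + random internal codons (no in-frame stops) + stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3, gc)
        if c not in STOPS and c != "ATG":
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


# catalog-known insertion positions per gene, used so simulated introns
# carry recognizable names; loaded lazily to avoid an import cycle
def _catalog_positions() -> dict[str, list[tuple[int, str]]]:
    from .composition import load_intron_catalog

    by_gene: dict[str, list[tuple[int, str]]] = {}
    for (gene, pos), group in load_intron_catalog().items():
        by_gene.setdefault(gene, []).append((pos, group))
    for v in by_gene.values():
        v.sort()
    return by_gene


def generate_genome(config: SimulationConfig) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Deterministically generate an annotated circular genome with
    planted repeats; identical config+seed gives identical output."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    lo, hi = config.gene_length_range
    catalog = _catalog_positions()

    if config.n_genes > len(GENE_POOL):
        raise CapacityError(f"at most {len(GENE_POOL)} distinct genes supported")
    names = list(GENE_POOL[: config.n_genes])

    genes = []
    total_gene_bp = 0
    for name in names:
        n_codons = max(20, int(rng.integers(lo, hi + 1)) // 3)
        cds = _random_cds(rng, n_codons, config.gc_fraction)
        intron = None
        if rng.random() < config.intron_rate:
            known = [(p, g) for p, g in catalog.get(name, []) if p < len(cds) - 3]
            if known:
                pos, _ = known[int(rng.integers(len(known)))]
            else:
                pos = int(rng.integers(30, len(cds) - 30))
            intron_seq = _random_seq(rng, int(rng.integers(150, 400)), config.gc_fraction)
            intron = (pos, intron_seq)
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append((name, cds, intron, strand))
        total_gene_bp += len(cds) + (len(intron[1]) if intron else 0)

    spacer_total = L - total_gene_bp
    n_spacers = len(genes)
    if spacer_total < 200 * n_spacers:
        raise CapacityError(
            f"requested features ({total_gene_bp} bp of genes) leave too little "
            f"spacer in a {L} bp genome"
        )
    props = rng.dirichlet(np.full(n_spacers, 3.0))
    spacer_lens = np.maximum(100, (props * spacer_total).astype(int))
    spacer_lens[-1] += spacer_total - int(spacer_lens.sum())
    if spacer_lens[-1] < 100:
        raise CapacityError("spacer allocation infeasible; increase genome length")

    # assemble: spacer_0 gene_0 spacer_1 gene_1 ...
    blocks: list[tuple[str, str, object]] = []  # (type, seq, payload)
    for i, g in enumerate(genes):
        blocks.append(("spacer", _random_seq(rng, int(spacer_lens[i]), config.gc_fraction), None))
        blocks.append(("gene", "", g))

    seq_parts: list[str] = []
    features: list[Feature] = []
    spacer_spans: list[tuple[int, int]] = []
    pos = 0
    for btype, bseq, payload in blocks:
        if btype == "spacer":
            seq_parts.append(bseq)
            spacer_spans.append((pos, pos + len(bseq)))
            pos += len(bseq)
            continue
        name, cds, intron, strand = payload
        if intron is None:
            body = cds if strand == "+" else reverse_complement(cds)
            gid = f"gene_{name}"
            kind = "rRNA" if name.startswith("rrn") else ("tRNA" if name.startswith("trn") else "gene")
            features.append(
                Feature(
                    id=gid,
                    kind=kind,
                    interval=CircularInterval(pos, pos + len(body), L),
                    strand=strand,
                    gene_name=name,
                )
            )
            seq_parts.append(body)
            pos += len(body)
            continue
        ipos, iseq = intron
        body_plus = cds[:ipos] + iseq + cds[ipos:]
        body = body_plus if strand == "+" else reverse_complement(body_plus)
        gid = f"gene_{name}"
        glen = len(body)
        kind = "rRNA" if name.startswith("rrn") else ("tRNA" if name.startswith("trn") else "gene")
        features.append(
            Feature(
                id=gid,
                kind=kind,
                interval=CircularInterval(pos, pos + glen, L),
                strand=strand,
                gene_name=name,
            )
        )
        if strand == "+":
            cuts = [(0, ipos, "exon"), (ipos, ipos + len(iseq), "intron"), (ipos + len(iseq), glen, "exon")]
        else:
            # minus strand: plus-coordinate layout mirrors the coding layout
            a = len(cds) - ipos
            cuts = [(0, a, "exon"), (a, a + len(iseq), "intron"), (a + len(iseq), glen, "exon")]
        for n_c, (s, e, kind) in enumerate(cuts, 1):
            features.append(
                Feature(
                    id=f"{gid}_{kind}{n_c}",
                    kind=kind,
                    interval=CircularInterval(pos + s, pos + e, L),
                    strand=strand,
                    gene_name=name,
                    attributes={"parent": gid},
                )
            )
        seq_parts.append(body)
        pos += glen

    sequence = list("".join(seq_parts))
    assert len(sequence) == L, (len(sequence), L)

    planted_pairs = _plant_repeats(rng, sequence, spacer_spans, config)
    genome = AnnotatedGenome(id=f"sim{config.seed}", sequence="".join(sequence), features=features)
    truth = SimulationTruth(genome=genome, planted_pairs=planted_pairs)
    return genome, truth


def _plant_repeats(
    rng: np.random.Generator,
    sequence: list[str],
    spacer_spans: list[tuple[int, int]],
    config: SimulationConfig,
) -> list[RepeatPair]:
    L = config.genome_length
    pairs = []
    used: list[tuple[int, int]] = []
    for n, spec in enumerate(config.planted_repeats, 1):
        slots = _free_slots(spacer_spans, used, spec.length + 20)
        placed = None
        for _ in range(200):
            if len(slots) < 2:
                break
            i1, i2 = rng.choice(len(slots), size=2, replace=False)
            s1 = _place_in_slot(rng, slots[int(i1)], spec.length)
            s2 = _place_in_slot(rng, slots[int(i2)], spec.length)
            if s1 > s2:
                s1, s2 = s2, s1
            gap_fwd = s2 - (s1 + spec.length)
            gap_rev = L - (s2 + spec.length) + s1
            if gap_fwd >= spec.min_copy_gap and gap_rev >= spec.min_copy_gap:
                placed = (s1, s2)
                break
        if placed is None:
            raise CapacityError(
                f"cannot place planted repeat #{n} ({spec.length} bp, "
                f"gap >= {spec.min_copy_gap}) in available spacers"
            )
        s1, s2 = placed
        rep = _random_seq(rng, spec.length, config.gc_fraction)
        copy2, n_mut = _mutate_copy(rng, rep, spec.identity_pct)
        copy2_genomic = reverse_complement(copy2) if spec.direction == "inverted" else copy2
        sequence[s1 : s1 + spec.length] = list(rep)
        sequence[s2 : s2 + spec.length] = list(copy2_genomic)
        used += [(s1, s1 + spec.length), (s2, s2 + spec.length)]
        identity = 100.0 * (spec.length - n_mut) / spec.length
        pairs.append(
            RepeatPair(
                id=f"planted{n}",
                copy1=CircularInterval(s1, s1 + spec.length, L),
                copy2=CircularInterval(s2, s2 + spec.length, L),
                direction=spec.direction,
                identity_pct=round(identity, 2),
                aligned_length=spec.length,
                alignment=(rep, copy2),
                score=float(spec.length),
            )
        )
    return pairs


def _free_slots(
    spacer_spans: list[tuple[int, int]], used: list[tuple[int, int]], need: int
) -> list[tuple[int, int]]:
    slots = []
    for a, b in spacer_spans:
        cuts = sorted([u for u in used if u[0] >= a and u[1] <= b])
        lo = a
        for ua, ub in cuts:
            if ua - lo >= need:
                slots.append((lo, ua))
            lo = ub
        if b - lo >= need:
            slots.append((lo, b))
    return slots


def _place_in_slot(rng: np.random.Generator, slot: tuple[int, int], length: int) -> int:
    a, b = slot
    return int(rng.integers(a + 10, b - length - 10 + 1))


def _mutate_copy(rng: np.random.Generator, rep: str, identity_pct: float) -> tuple[str, int]:
    """Interior point substitutions (>= 5 bp from either end) so planted
    repeat boundaries stay well defined."""
    n_mut = int(round((100.0 - identity_pct) / 100.0 * len(rep)))
    if n_mut == 0:
        return rep, 0
    interior = np.arange(5, len(rep) - 5)
    if n_mut > len(interior):
        raise ValueError("identity too low for repeat length")
    sites = rng.choice(interior, size=n_mut, replace=False)
    out = list(rep)
    for s in sites:
        choices = [b for b in "ACGT" if b != out[s]]
        out[s] = choices[int(rng.integers(3))]
    return "".join(out), n_mut


# ---------------------------------------------------------------------------
# Recombinant molecules and read simulation

def recombinant_molecules(genome: AnnotatedGenome, pair: RepeatPair) -> list[tuple[str, str]]:
    """Full-length product molecule(s) of one recombination event.

    Crossover is taken at the repeat boundaries, so for diverged copies
    each product carries one intact parental repeat copy.
    """
    S = genome.sequence
    c1, c2 = pair.copy1, pair.copy2
    if c1.wraps or c2.wraps:
        raise ValueError("recombinant construction requires non-wrapping planted copies")
    if pair.direction == "inverted":
        inv = S[: c1.end] + reverse_complement(S[c1.end : c2.start]) + S[c2.start :]
        return [(f"{pair.id}_inv", inv)]
    main = S[: c1.start] + S[c2.start :]
    sub = S[c1.start : c2.start]
    return [(f"{pair.id}_main", main), (f"{pair.id}_sub", sub)]


def simulate_read_pairs(
    genome: AnnotatedGenome, truth: SimulationTruth, config: SimulationConfig
) -> list[ReadPair]:
    """Draw 2x``read_length`` inward-facing pairs from the molecule mixture.

    The number of pairs is ``floor(coverage * genome_length /
    (2 * read_length))``; insert sizes are normal, truncated (clipped) to
    ``[2*read_length, insert_mean + 4*insert_sd]``; sequencing errors are
    i.i.d. substitutions. Updates ``truth`` with the molecule pool and
    per-read provenance.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.genome_length
    n_pairs = int(config.coverage * L // (2 * config.read_length))
    if n_pairs == 0:
        raise ValueError("coverage too low: zero read pairs")

    alt = config.alt_fraction_per_repeat or [0.0] * len(truth.planted_pairs)
    master_w = 1.0 - sum(alt)
    if master_w < 0:
        raise ValueError("alt fractions sum above 1")
    molecules: list[tuple[str, str, float]] = [("master", genome.sequence, master_w)]
    for pair, f in zip(truth.planted_pairs, alt):
        if f <= 0:
            continue
        prods = recombinant_molecules(genome, pair)
        tot = sum(len(s) for _, s in prods)
        for mid, s in prods:
            molecules.append((mid, s, f * len(s) / tot))

    weights = np.array([w for _, _, w in molecules])
    weights = weights / weights.sum()
    counts = rng.multinomial(n_pairs, weights)
    truth.molecule_pool = [(mid, float(w)) for (mid, _, _), w in zip(molecules, weights)]

    rl = config.read_length
    lo_ins, hi_ins = 2 * rl, config.insert_mean + 4 * config.insert_sd
    reads: list[ReadPair] = []
    idx = 0
    for (mid, mseq, _), n in zip(molecules, counts):
        if n == 0:
            continue
        D = mseq + mseq
        mlen = len(mseq)
        starts = rng.integers(0, mlen, size=n)
        inserts = np.clip(
            np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n)),
            lo_ins,
            min(hi_ins, mlen),
        ).astype(int)
        for s, ins in zip(starts, inserts):
            frag = D[s : s + ins]
            m1, m2 = frag[:rl], reverse_complement(frag[-rl:])
            rid = f"read{idx}"
            idx += 1
            reads.append(ReadPair(id=rid, mate1=m1, mate2=m2, source_molecule=mid))
            truth.read_provenance[rid] = mid

    if config.base_error_rate > 0:
        reads = _add_errors(rng, reads, config.base_error_rate)
        for r in reads:
            truth.read_provenance[r.id] = r.source_molecule
    return reads


def _add_errors(
    rng: np.random.Generator, reads: list[ReadPair], rate: float
) -> list[ReadPair]:
    out = []
    for r in reads:
        out.append(
            replace(
                r,
                mate1=_mutate_read(rng, r.mate1, rate),
                mate2=_mutate_read(rng, r.mate2, rate),
            )
        )
    return out


def _mutate_read(rng: np.random.Generator, seq: str, rate: float) -> str:
    hits = np.where(rng.random(len(seq)) < rate)[0]
    if hits.size == 0:
        return seq
    s = list(seq)
    for i in hits:
        choices = [b for b in "ACGT" if b != s[i]]
        s[i] = choices[int(rng.integers(3))]
    return "".join(s)
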