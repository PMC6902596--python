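"""Core domain types: annotated circular genomes, features, read pairs."""

from __future__ import annotations

from dataclasses import dataclass, field

from .intervals import CircularInterval, CoordinateError, interval_overlap

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = frozenset(
    {"gene", "exon", "intron", "tRNA", "rRNA", "ORF", "repeat", "SSR"}
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeError(ValueError):
    """Genome or annotation violates an invariant."""


@dataclass
class Feature:
    """One annotated element with circular coordinates.

    ``gene_name`` carries the gene symbol (e.g. ``cox1``); exon/intron
    features point at their parent gene through ``attributes['parent']``.
    """

    id: str
    kind: str
    interval: CircularInterval
    strand: str = "+"
    gene_name: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise GenomeError(f"unknown feature kind {self.kind!r} for {self.id}")
        if self.strand not in {"+", "-"}:
            raise GenomeError(f"feature {self.id}: strand must be + or -")

    @property
    def parent(self) -> str:
        return self.attributes.get("parent", "")


@dataclass
class ReadPair:
    """A sequenced fragment's two inward-facing ends (as sequenced)."""

    id: str
    mate1: str
    mate2: str
    source_molecule: str = ""

    def __post_init__(self) -> None:
        if not self.mate1 or not self.mate2:
            raise GenomeError(f"read pair {self.id}: both mates must be non-empty")


@dataclass
class AnnotatedGenome:
    """A circular (or linear) genome plus its typed features."""

    id: str
    sequence: str
    features: list[Feature] = field(default_factory=list)
    topology: str = "circular"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise GenomeError(f"genome {self.id}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeError(
                f"genome {self.id}: ambiguity codes other than N are rejected "
                f"(found {sorted(bad)})"
            )
        if self.topology not in {"circular", "linear"}:
            raise GenomeError(f"genome {self.id}: bad topology {self.topology!r}")
        self._validate_features()

    @property
    def length(self) -> int:
        return len(self.sequence)

    def _validate_features(self) -> None:
        ids: set[str] = set()
        by_id: dict[str, Feature] = {}
        for f in self.features:
            if f.interval.genome_length != self.length:
                raise CoordinateError(
                    f"feature {f.id}: interval on circle of length "
                    f"{f.interval.genome_length}, genome is {self.length}"
                )
            if f.interval.span() >= self.length:
                raise CoordinateError(f"feature {f.id}: spans the whole circle")
            if f.id in ids:
                raise GenomeError(f"duplicate feature id {f.id!r}")
            ids.add(f.id)
            by_id[f.id] = f
        for f in self.features:
            if f.kind in {"exon", "intron"}:
                if f.parent not in by_id:
                    raise GenomeError(
                        f"{f.kind} {f.id} references missing parent gene {f.parent!r}"
                    )
        self._validate_gene_structure(by_id)

    def _validate_gene_structure(self, by_id: dict[str, Feature]) -> None:
        children: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.kind in {"exon", "intron"} and f.parent:
                children.setdefault(f.parent, []).append(f)
        for gid, kids in children.items():
            gene = by_id[gid]
            exons = [k for k in kids if k.kind == "exon"]
            introns = [k for k in kids if k.kind == "intron"]
            for i in introns:
                for e in exons:
                    if interval_overlap(i.interval, e.interval) > 0:
                        raise GenomeError(
                            f"gene {gid}: intron {i.id} overlaps exon {e.id}"
                        )
            if exons:
                covered = sum(k.interval.span() for k in kids)
                if covered != gene.interval.span():
                    raise GenomeError(
                        f"gene {gid}: exons+introns cover {covered} bp, "
                        f"gene spans {gene.interval.span()} bp"
                    )

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def genes(self, kinds: set[str] | frozenset[str] = frozenset({"gene", "tRNA", "rRNA"})) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


def subsequence(genome: AnnotatedGenome, interval: CircularInterval, strand: str = "+") -> str:
    """Extract the bases of an arc; ``strand='-'`` reverse-complements.

    Wrapping arcs concatenate the suffix and prefix of the linearized
    sequence, so the result always has ``interval.span()`` bases.
    """
    if interval.genome_length != genome.length:
        raise CoordinateError(
            f"interval on circle of length {interval.genome_length}, "
            f"genome {genome.id} is {genome.length}"
        )
    if interval.span() == genome.length and interval.start != 0:
        # whole-circle rotation: valid for sequence extraction
        s = genome.sequence[interval.start:] + genome.sequence[: interval.start]
    else:
        s = "".join(genome.sequence[a:b] for a, b in interval.segments())
    return reverse_complement(s) if strand == "-" else s
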