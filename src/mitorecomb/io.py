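"""Readers and writers for FASTA, FASTQ, GFF3 and GenBank flat files.

External files keep their native conventions (1-based inclusive
coordinates, origin-spanning features as two-segment joins); everything is
normalized to 0-based half-open :class:`~mitorecomb.intervals.CircularInterval`
objects on the way in and converted back on the way out. Writers are
deterministic: identical inputs produce byte-identical files.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
import gffutils.iterators

from .genome import AnnotatedGenome, Feature, GenomeError, ReadPair
from .intervals import CircularInterval, CoordinateError, from_one_based, to_one_based

# GFF3/SO type names <-> internal feature kinds
_GFF_TO_KIND = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ORF": "ORF",
    "open_reading_frame": "ORF",
    "repeat_region": "repeat",
    "dispersed_repeat": "repeat",
    "microsatellite": "SSR",
}
_KIND_TO_GFF = {
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "ORF": "ORF",
    "repeat": "repeat_region",
    "SSR": "microsatellite",
}


class ParseError(ValueError):
    """A file does not parse under the named standard."""


# ---------------------------------------------------------------------------
# FASTA / FASTQ

def read_fasta(path: str | os.PathLike) -> tuple[str, str]:
    """Return (id, sequence) of the single record in a FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ParseError(f"{path}: expected exactly one FASTA record, found {len(records)}")
    return records[0].id, str(records[0].seq).upper()


def write_fasta(path: str | os.PathLike, genome: AnnotatedGenome, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.id} topology={genome.topology}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


def read_read_pairs(path1: str | os.PathLike, path2: str | os.PathLike) -> list[ReadPair]:
    """Load mates from a pair of FASTQ files, matching records by order.

    Singleton tails (one file longer than the other) are skipped and
    counted, mirroring how orphaned mates are dropped upstream.
    """
    r1 = list(SeqIO.parse(str(path1), "fastq"))
    r2 = list(SeqIO.parse(str(path2), "fastq"))
    n = min(len(r1), len(r2))
    pairs = []
    for a, b in zip(r1[:n], r2[:n]):
        pairs.append(ReadPair(id=a.id.split("/")[0], mate1=str(a.seq).upper(), mate2=str(b.seq).upper()))
    return pairs


def write_read_pairs(
    path1: str | os.PathLike, path2: str | os.PathLike, pairs: Iterable[ReadPair], quality: int = 40
) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = chr(quality + 33) * len(p.mate1)
            q2 = chr(quality + 33) * len(p.mate2)
            f1.write(f"@{p.id}/1\n{p.mate1}\n+\n{q1}\n")
            f2.write(f"@{p.id}/2\n{p.mate2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# GFF3

def _merge_wrapping_segments(
    segs: list[tuple[int, int]], genome_length: int, fid: str
) -> CircularInterval:
    """Merge 1-based inclusive segments of one feature id.

    A single segment maps directly; two segments form an origin-spanning
    join iff one ends at the genome end and the other starts at base 1.
    """
    if len(segs) == 1:
        s, e = segs[0]
        return from_one_based(s, e, genome_length)
    if len(segs) == 2:
        segs = sorted(segs)
        (s1, e1), (s2, e2) = segs
        if e2 == genome_length and s1 == 1:
            # wrapping: suffix (s2..L) then prefix (1..e1)
            return CircularInterval(s2 - 1, e1, genome_length)
    raise ParseError(f"feature {fid}: segments {segs} do not form a valid circular join")


def read_gff3(path: str | os.PathLike, genome_length: int) -> list[Feature]:
    """Parse a GFF3 file into normalized features.

    Multiple lines sharing an ID are treated as a discontinuous feature
    and merged into one (possibly wrapping) interval.
    """
    text = open(path).read()
    if text.strip() and "##gff-version 3" not in text.splitlines()[0]:
        raise ParseError(f"{path}: missing '##gff-version 3' pragma on first line")
    groups: dict[str, dict] = {}
    order: list[str] = []
    for n, rec in enumerate(gffutils.iterators.DataIterator(str(path))):
        if rec.featuretype not in _GFF_TO_KIND:
            raise ParseError(
                f"{path}: line {n + 1}: unsupported feature type {rec.featuretype!r}"
            )
        if rec.start < 1 or rec.end > genome_length:
            raise CoordinateError(
                f"{path}: feature at {rec.start}..{rec.end} outside [1, {genome_length}]"
            )
        fid = rec.attributes.get("ID", [f"feature{n + 1}"])[0]
        g = groups.setdefault(
            fid,
            {
                "kind": _GFF_TO_KIND[rec.featuretype],
                "strand": rec.strand if rec.strand in "+-" else "+",
                "name": rec.attributes.get("Name", [""])[0],
                "parent": rec.attributes.get("Parent", [""])[0],
                "segs": [],
            },
        )
        if fid not in order:
            order.append(fid)
        g["segs"].append((rec.start, rec.end))
    features = []
    for fid in order:
        g = groups[fid]
        iv = _merge_wrapping_segments(g["segs"], genome_length, fid)
        attrs = {}
        if g["parent"]:
            attrs["parent"] = g["parent"]
        features.append(
            Feature(
                id=fid,
                kind=g["kind"],
                interval=iv,
                strand=g["strand"],
                gene_name=g["name"],
                attributes=attrs,
            )
        )
    return features


def write_gff3(path: str | os.PathLike, genome: AnnotatedGenome) -> None:
    """Serialize features to GFF3; wrapping arcs become two-segment joins."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {genome.length}\n")
        for f in genome.features:
            attrs = [f"ID={f.id}"]
            if f.gene_name:
                attrs.append(f"Name={f.gene_name}")
            if f.parent:
                attrs.append(f"Parent={f.parent}")
            segs = to_one_based(f.interval)
            # emit the suffix segment first so round-tripping is stable
            for s, e in sorted(segs, key=lambda t: -t[0]) if len(segs) > 1 else segs:
                fh.write(
                    "\t".join(
                        [
                            genome.id,
                            "mitorecomb",
                            _KIND_TO_GFF[f.kind],
                            str(s),
                            str(e),
                            ".",
                            f.strand,
                            ".",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# GenBank (read-only)

_GB_TO_KIND = {
    "gene": "gene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "exon": "exon",
    "intron": "intron",
    "repeat_region": "repeat",
    "CDS": None,  # CDS duplicates gene/exon structure; skipped
    "source": None,
    "misc_feature": None,
}


def read_genbank(path: str | os.PathLike) -> AnnotatedGenome:
    """Read a GenBank flat file; joins across the origin become one
    wrapping interval."""
    try:
        rec = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # Biopython raises plain ValueError
        raise ParseError(f"{path}: {exc}") from exc
    length = len(rec.seq)
    topology = rec.annotations.get("topology", "circular")
    features: list[Feature] = []
    counter = 0
    for gf in rec.features:
        kind = _GB_TO_KIND.get(gf.type, None)
        if kind is None:
            continue
        counter += 1
        segs = [(int(p.start) + 1, int(p.end)) for p in gf.location.parts]
        fid = gf.qualifiers.get("locus_tag", [f"{gf.type}{counter}"])[0]
        iv = _merge_wrapping_segments(segs, length, fid)
        features.append(
            Feature(
                id=fid,
                kind=kind,
                interval=iv,
                strand="-" if gf.location.strand == -1 else "+",
                gene_name=gf.qualifiers.get("gene", [""])[0],
                attributes=(
                    {"parent": gf.qualifiers["parent"][0]} if "parent" in gf.qualifiers else {}
                ),
            )
        )
    return AnnotatedGenome(
        id=rec.id, sequence=str(rec.seq).upper(), features=features, topology=topology
    )


# ---------------------------------------------------------------------------
# Front door

def read_genome(
    path: str | os.PathLike,
    format: str = "fasta+gff3",
    gff_path: str | os.PathLike | None = None,
) -> AnnotatedGenome:
    """Load an annotated genome.

    ``format='fasta+gff3'`` expects the FASTA at ``path`` and the GFF3 at
    ``gff_path`` (default: ``path`` with a .gff3 suffix); ``'genbank'``
    reads a single flat file.
    """
    if format == "genbank":
        return read_genbank(path)
    if format != "fasta+gff3":
        raise ValueError(f"unknown format {format!r}")
    gid, seq = read_fasta(path)
    if gff_path is None:
        base = str(path)
        for ext in (".fasta", ".fa", ".fna"):
            if base.endswith(ext):
                base = base[: -len(ext)]
                break
        gff_path = base + ".gff3"
    features = read_gff3(gff_path, len(seq))
    topology = "circular"
    with open(path) as fh:
        header = fh.readline()
        if "topology=linear" in header:
            topology = "linear"
    return AnnotatedGenome(id=gid, sequence=seq, features=features, topology=topology)
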