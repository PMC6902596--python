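"""Genome composition and intron inventory.

The circle is partitioned into exonic, intronic and intergenic-spacer
bases (precedence exon > intron > spacer; genes without annotated
exon/intron substructure count as exonic throughout, as do tRNA/rRNA).
Spacers are then decomposed into ORF, dispersed-repeat and SSR content,
each reported as merged base coverage so nothing is double counted within
a category.

Intron identity follows the standard nomenclature: host gene + "i" +
the nucleotide position in the gene's coding sequence after which the
intron inserts + group tag, e.g. ``cox1i44g2``.
"""

from __future__ import annotations

import contextlib
import os
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .genome import AnnotatedGenome, reverse_complement
from .intervals import CircularInterval
from .repeats import RepeatPair

STOP_CODONS = {"TAA", "TAG", "TGA"}

# minimum perfect-tandem copy number per motif length (microsatellite
# convention: 10 mononucleotide, 6 dinucleotide, 5 for tri- through hexa-)
DEFAULT_SSR_MIN_COUNTS = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass
class CompositionProfile:
    genome_id: str
    total_bp: int
    exon_bp: int
    intron_bp: int
    spacer_bp: int
    spacer_orf_bp: int | None = None
    spacer_repeat_bp: int | None = None
    spacer_ssr_bp: int | None = None
    # annotations discovered while profiling (0-based half-open segments)
    orf_segments: list[tuple[int, int, str]] = field(default_factory=list)
    ssr_segments: list[tuple[int, int, str]] = field(default_factory=list)

    def percent(self, part_bp: int, of: str = "total") -> float:
        denom = self.total_bp if of == "total" else self.spacer_bp
        return round(100.0 * part_bp / denom, 2) if denom else 0.0


@dataclass
class IntronRecord:
    name: str
    gene: str
    insertion_pos: int
    group: str  # g1 | g2 | unknown
    present_in: dict[str, bool] = field(default_factory=dict)
    novel: bool = False


def intron_name(gene: str, insertion_pos: int, group: str) -> str:
    return f"{gene}i{insertion_pos}{group}"


_NAME_RE = re.compile(r"^(?P<gene>[A-Za-z0-9]+?)i(?P<pos>\d+)(?P<group>g[12]|unknown)$")


def parse_intron_name(name: str) -> tuple[str, int, str]:
    m = _NAME_RE.match(name)
    if not m:
        raise ValueError(f"cannot parse intron name {name!r}")
    return m.group("gene"), int(m.group("pos")), m.group("group")


# ---------------------------------------------------------------------------
# Partition

def _mask(genome_length: int, intervals: list[CircularInterval]) -> np.ndarray:
    m = np.zeros(genome_length, dtype=bool)
    for iv in intervals:
        for a, b in iv.segments():
            m[a:b] = True
    return m


def _category_masks(genome: AnnotatedGenome) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    L = genome.length
    genes_with_parts = {f.parent for f in genome.features if f.kind in {"exon", "intron"}}
    exon_ivs = [f.interval for f in genome.features if f.kind == "exon"]
    exon_ivs += [
        f.interval
        for f in genome.features
        if f.kind in {"gene", "tRNA", "rRNA"} and f.id not in genes_with_parts
    ]
    intron_ivs = [f.interval for f in genome.features if f.kind == "intron"]
    exon = _mask(L, exon_ivs)
    intron = _mask(L, intron_ivs) & ~exon
    spacer = ~(exon | intron)
    return exon, intron, spacer


def partition_genome(genome: AnnotatedGenome) -> CompositionProfile:
    """Exon/intron/spacer partition; the three fractions tile the circle."""
    exon, intron, spacer = _category_masks(genome)
    return CompositionProfile(
        genome_id=genome.id,
        total_bp=genome.length,
        exon_bp=int(exon.sum()),
        intron_bp=int(intron.sum()),
        spacer_bp=int(spacer.sum()),
    )


# ---------------------------------------------------------------------------
# Spacer decomposition

def _spacer_runs(spacer: np.ndarray) -> list[tuple[int, int]]:
    """Maximal spacer segments, merging a run that wraps the origin."""
    L = len(spacer)
    if spacer.all():
        return [(0, L)]
    diff = np.diff(spacer.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if spacer[0]:
        starts = [0] + starts
    if spacer[-1]:
        ends = ends + [L]
    runs = list(zip(starts, ends))
    if len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == L:
        # wrapping spacer: start it at the pre-origin segment
        first, last = runs[0], runs[-1]
        runs = runs[1:-1] + [(last[0], first[1] + L)]
    return runs


def _find_orfs_linear(seq: str, min_codons: int) -> list[tuple[int, int]]:
    """ATG..stop open frames (stop included), both strands, >= min_codons."""
    found = []
    n = len(seq)
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            i = frame
            while i + 3 <= n:
                if s[i : i + 3] == "ATG":
                    j = i + 3
                    while j + 3 <= n:
                        if s[j : j + 3] in STOP_CODONS:
                            codons = (j + 3 - i) // 3
                            if codons >= min_codons:
                                if strand == "+":
                                    found.append((i, j + 3))
                                else:
                                    found.append((n - (j + 3), n - i))
                            i = j  # restart scan after this ORF
                            break
                        j += 3
                i += 3
    return found


def _merge_segments(segs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not segs:
        return []
    segs = sorted(segs)
    merged = [list(segs[0])]
    for a, b in segs[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(s) for s in merged]


def find_ssrs(
    seq: str, min_counts: dict[int, int] = DEFAULT_SSR_MIN_COUNTS
) -> list[tuple[int, int, str]]:
    """Perfect tandem motifs (1-6 bp) meeting per-motif-length minimum
    copy counts; returns (start, end, motif) with end-start a multiple of
    the motif length. Non-primitive motifs (e.g. 'ATAT') report at their
    primitive period."""
    hits = []
    n = len(seq)
    covered = np.zeros(n, dtype=bool)
    for k in sorted(min_counts):
        min_len = k * min_counts[k]
        i = 0
        while i + k <= n:
            # extend a run with period k starting at i
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            run = j - i
            if run >= min_len:
                motif = seq[i : i + k]
                if _is_primitive(motif) and not covered[i:j].all():
                    end = i + (run // k) * k
                    hits.append((i, end, motif))
                    covered[i:end] = True
                i = j
            else:
                i += 1
    return hits


def _is_primitive(motif: str) -> bool:
    k = len(motif)
    for p in range(1, k):
        if k % p == 0 and motif == motif[:p] * (k // p):
            return False
    return True


def profile_spacers(
    genome: AnnotatedGenome,
    repeats: list[RepeatPair] | None = None,
    orf_min_codons: int = 100,
    ssr_motif_min_counts: dict[int, int] = DEFAULT_SSR_MIN_COUNTS,
) -> CompositionProfile:
    """Full composition profile: partition plus spacer ORF/repeat/SSR content."""
    profile = partition_genome(genome)
    _, _, spacer = _category_masks(genome)
    L = genome.length
    D = genome.sequence + genome.sequence

    orf_cov = np.zeros(L, dtype=bool)
    ssr_cov = np.zeros(L, dtype=bool)
    for a, b in _spacer_runs(spacer):
        seg = D[a:b]
        for s, e in _find_orfs_linear(seg, orf_min_codons):
            lo, hi = a + s, a + e
            for p in range(lo, hi):
                orf_cov[p % L] = True
            profile.orf_segments.append((lo % L, ((hi - 1) % L) + 1, "+"))
        for s, e, motif in find_ssrs(seg, ssr_motif_min_counts):
            lo, hi = a + s, a + e
            for p in range(lo, hi):
                ssr_cov[p % L] = True
            profile.ssr_segments.append((lo % L, ((hi - 1) % L) + 1, motif))

    rep_cov = np.zeros(L, dtype=bool)
    for pair in repeats or []:
        for iv in (pair.copy1, pair.copy2):
            for s, e in iv.segments():
                rep_cov[s:e] = True

    profile.spacer_orf_bp = int((orf_cov & spacer).sum())
    profile.spacer_ssr_bp = int((ssr_cov & spacer).sum())
    profile.spacer_repeat_bp = int((rep_cov & spacer).sum())
    return profile


# ---------------------------------------------------------------------------
# Intron inventory

def load_intron_catalog(path: str | os.PathLike | None = None) -> dict[tuple[str, int], str]:
    """(gene, insertion_pos) -> group, from the packaged reference catalog."""
    if path is None:
        src = resources.files("mitorecomb").joinpath("data/intron_catalog.tsv")
        text = src.read_text()
    else:
        text = open(path).read()
    catalog: dict[tuple[str, int], str] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#") or line.startswith("gene\t"):
            continue
        gene, pos, group = line.split("\t")
        catalog[(gene, int(pos))] = group
    return catalog


def intron_insertion_position(genome: AnnotatedGenome, intron_id: str) -> tuple[str, int]:
    """(gene symbol, coding-coordinate insertion position) of an intron.

    The insertion position is the number of exonic bases of the host gene
    that precede the intron, walking the gene 5'->3'.
    """
    intron = genome.feature_by_id(intron_id)
    gene = genome.feature_by_id(intron.parent)
    exons = [
        f
        for f in genome.features
        if f.kind == "exon" and f.parent == gene.id
    ]
    L = genome.length
    origin = gene.interval.start
    span = gene.interval.span()

    def offset(pos: int) -> int:
        return (pos - origin) % L

    intron_off = offset(intron.interval.start)
    preceding = sum(
        min(e.interval.span(), max(0, intron_off - offset(e.interval.start)))
        for e in exons
        if offset(e.interval.start) < intron_off
    )
    if gene.strand == "-":
        coding_len = sum(e.interval.span() for e in exons)
        preceding = coding_len - preceding
    _ = span
    return (gene.gene_name or gene.id), preceding


def build_intron_inventory(
    genomes: list[AnnotatedGenome],
    reference_catalog: dict[tuple[str, int], str] | None = None,
) -> list[IntronRecord]:
    """Presence/absence matrix rows over the union of observed introns.

    Introns missing from the catalog are named with group "unknown" and
    flagged novel. Records are sorted by (gene, insertion position).
    """
    if not genomes:
        raise ValueError("at least one genome required")
    if reference_catalog is None:
        reference_catalog = load_intron_catalog()
    records: dict[tuple[str, int], IntronRecord] = {}
    for g in genomes:
        for f in g.features:
            if f.kind != "intron":
                continue
            gene, pos = intron_insertion_position(g, f.id)
            key = (gene, pos)
            if key not in records:
                group = reference_catalog.get(key)
                records[key] = IntronRecord(
                    name=intron_name(gene, pos, group or "unknown"),
                    gene=gene,
                    insertion_pos=pos,
                    group=group or "unknown",
                    novel=group is None,
                )
            records[key].present_in[g.id] = True
    out = sorted(records.values(), key=lambda r: (r.gene, r.insertion_pos))
    for r in out:
        for g in genomes:
            r.present_in.setdefault(g.id, False)
    return out


def _open_out(dest):
    if hasattr(dest, "write"):
        return contextlib.nullcontext(dest)
    return open(dest, "w")


def write_intron_matrix(path, records: list[IntronRecord], genome_ids: list[str]) -> None:
    """0/1 matrix, genomes as columns, introns as rows, totals row last."""
    with _open_out(path) as fh:
        fh.write("intron\t" + "\t".join(genome_ids) + "\n")
        for r in records:
            fh.write(r.name + "\t" + "\t".join("1" if r.present_in.get(g, False) else "0" for g in genome_ids) + "\n")
        totals = [sum(1 for r in records if r.present_in.get(g, False)) for g in genome_ids]
        fh.write("total\t" + "\t".join(str(t) for t in totals) + "\n")


def write_composition_tsv(path, profiles: list[CompositionProfile]) -> None:
    with _open_out(path) as fh:
        fh.write(
            "genome\ttotal_bp\texon_bp\tintron_bp\tspacer_bp\t"
            "spacer_pct\torf_pct_of_spacer\trepeat_pct_of_spacer\tssr_pct_of_spacer\n"
        )
        for p in profiles:
            orf = p.percent(p.spacer_orf_bp, "spacer") if p.spacer_orf_bp is not None else ""
            rep = p.percent(p.spacer_repeat_bp, "spacer") if p.spacer_repeat_bp is not None else ""
            ssr = p.percent(p.spacer_ssr_bp, "spacer") if p.spacer_ssr_bp is not None else ""
            fh.write(
                f"{p.genome_id}\t{p.total_bp}\t{p.exon_bp}\t{p.intron_bp}\t{p.spacer_bp}\t"
                f"{p.percent(p.spacer_bp)}\t{orf}\t{rep}\t{ssr}\n"
            )
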