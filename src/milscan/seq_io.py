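"""Genome and annotation I/O with explicit coordinate conventions.

All internal coordinates are 0-based half-open; report tables and location
strings use 1-based inclusive intervals (``ChrI: 11548223–11548283``,
``rev(a–b)`` for the minus strand).  GFF3 input is the standard 1-based
inclusive dialect and is converted on load.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID_NT = set("ACGTN")

STRUCTURAL_KINDS = ("tRNA", "rRNA")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (involution)."""
    if set(seq) - _VALID_NT:
        bad = sorted(set(seq) - _VALID_NT)
        raise ValueError(f"non-nucleotide characters in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Ordered contig-name → uppercase DNA sequence (ACGTN)."""

    contigs: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
            extra = set(seq) - _VALID_NT
            if extra:
                raise ValueError(f"contig {name!r} has invalid characters {sorted(extra)}")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.contigs[contig][start:end]
        return seq if strand == "+" else reverse_complement(seq)


@dataclass(frozen=True)
class Feature:
    """An annotated interval: exon/intron/tRNA/rRNA, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    kind: str
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start},{self.end}) for {self.kind}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.kind in ("exon", "intron") and self.gene_id is None:
            raise ValueError(f"{self.kind} feature requires a gene_id")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationSet:
    """Features plus per-gene spans, with interval trees for fast queries."""

    features: List[Feature]
    gene_spans: Dict[str, Tuple[str, int, int, str]]
    _trees: Dict[Tuple[str, str], IntervalTree] = field(default_factory=dict, repr=False)
    _gene_tree: Dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for f in self.features:
            tree = self._trees.setdefault((f.contig, f.kind), IntervalTree())
            tree[f.start:f.end] = f
        for gid, (contig, start, end, strand) in self.gene_spans.items():
            tree = self._gene_tree.setdefault(contig, IntervalTree())
            tree[start:end] = (gid, strand)

    def features_overlapping(self, contig: str, start: int, end: int,
                             kinds: Optional[Sequence[str]] = None) -> List[Feature]:
        out: List[Feature] = []
        for (c, k), tree in self._trees.items():
            if c != contig or (kinds is not None and k not in kinds):
                continue
            out.extend(iv.data for iv in tree.overlap(start, end))
        out.sort(key=lambda f: (f.start, f.end, f.kind))
        return out

    def genes_overlapping(self, contig: str, start: int, end: int) -> List[Tuple[str, int, int, str]]:
        tree = self._gene_tree.get(contig)
        if tree is None:
            return []
        hits = [(iv.data[0], iv.begin, iv.end, iv.data[1]) for iv in tree.overlap(start, end)]
        hits.sort(key=lambda h: (h[1], h[2], h[0]))
        return hits

    def annotated_intervals(self, contig: str) -> List[Tuple[int, int]]:
        """Union components of gene spans + tRNA + rRNA on one contig."""
        ivs = [(s, e) for gid, (c, s, e, _st) in self.gene_spans.items() if c == contig]
        for f in self.features:
            if f.contig == contig and f.kind in STRUCTURAL_KINDS:
                ivs.append((f.start, f.end))
        return merge_intervals(ivs)


def merge_intervals(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Merge possibly-overlapping half-open intervals into a sorted disjoint union."""
    ivs = sorted(intervals)
    merged: List[Tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def load_genome(path) -> Genome:
    """Load a FASTA genome: sequences uppercased, U→T, record order kept."""
    contigs: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig name {rec.id!r}")
        contigs[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(contigs)


def load_annotation(path, genome: Genome) -> AnnotationSet:
    """Load GFF3 (1-based inclusive) into internal 0-based half-open features.

    Recognizes ``gene`` (span), ``exon`` (child of a gene, possibly through an
    mRNA), ``tRNA`` and ``rRNA`` records.  Introns are derived as the gaps
    between consecutive exons of the same gene when not explicitly annotated.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )

    def check(contig: str, start0: int, end0: int, what: str) -> None:
        if contig not in genome.contigs:
            raise ValueError(f"{what}: unknown contig {contig!r}")
        if end0 > len(genome.contigs[contig]) or start0 < 0:
            raise ValueError(f"{what}: interval [{start0},{end0}) beyond contig {contig!r}")

    gene_spans: Dict[str, Tuple[str, int, int, str]] = {}
    for g in db.features_of_type("gene"):
        gid = g.id
        s, e = g.start - 1, g.end
        check(g.seqid, s, e, f"gene {gid}")
        gene_spans[gid] = (g.seqid, s, e, g.strand)

    def owning_gene(feat) -> Optional[str]:
        cur = feat
        for _ in range(4):
            parents = list(db.parents(cur, level=1))
            if not parents:
                return None
            cur = parents[0]
            if cur.featuretype == "gene":
                return cur.id
        return None

    features: List[Feature] = []
    exons_by_gene: Dict[str, List[Tuple[int, int]]] = {}
    explicit_introns = set()
    for ft in ("exon", "intron"):
        for f in db.features_of_type(ft):
            gid = owning_gene(f)
            if gid is None:
                raise ValueError(f"{ft} at {f.seqid}:{f.start}-{f.end} has no gene parent")
            s, e = f.start - 1, f.end
            check(f.seqid, s, e, f"{ft} of {gid}")
            gc, gs, ge, gstrand = gene_spans[gid]
            if f.seqid != gc or s < gs or e > ge:
                raise ValueError(f"{ft} of {gid} outside its gene span")
            features.append(Feature(f.seqid, s, e, gstrand, ft, gid))
            if ft == "exon":
                exons_by_gene.setdefault(gid, []).append((s, e))
            else:
                explicit_introns.add(gid)

    for gid, exons in exons_by_gene.items():
        exons.sort()
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping exons in gene {gid}")
        if gid in explicit_introns:
            continue
        contig, _gs, _ge, strand = gene_spans[gid]
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 > e1:
                features.append(Feature(contig, e1, s2, strand, "intron", gid))

    for kind in STRUCTURAL_KINDS:
        for f in db.features_of_type(kind):
            s, e = f.start - 1, f.end
            check(f.seqid, s, e, kind)
            features.append(Feature(f.seqid, s, e, f.strand, kind, None))

    features.sort(key=lambda f: (f.contig, f.start, f.end, f.kind))
    return AnnotationSet(features, gene_spans)


def intergenic_intervals(ann: AnnotationSet, genome: Genome) -> List[Tuple[str, int, int]]:
    """Complement of gene spans + tRNA/rRNA per contig; sorted, disjoint."""
    out: List[Tuple[str, int, int]] = []
    for contig, seq in genome.contigs.items():
        pos = 0
        for s, e in ann.annotated_intervals(contig):
            if s > pos:
                out.append((contig, pos, s))
            pos = max(pos, e)
        if pos < len(seq):
            out.append((contig, pos, len(seq)))
    return out


_LOC_RE = re.compile(
    r"^\s*(?P<contig>[^:\s]+)\s*:\s*(?P<rev>rev\()?\s*(?P<a>\d+)\s*[–-]\s*(?P<b>\d+)\s*(?(rev)\))\s*$"
)


def parse_location(text: str) -> Tuple[str, int, int, str]:
    """Parse ``Chr: a–b`` / ``Chr: rev(a–b)`` into (contig, start0, end0, strand)."""
    m = _LOC_RE.match(text)
    if not m:
        raise ValueError(f"unparseable location {text!r}")
    a, b = int(m.group("a")), int(m.group("b"))
    if a > b:
        raise ValueError(f"start > end in location {text!r}")
    strand = "-" if m.group("rev") else "+"
    return m.group("contig"), a - 1, b, strand


def format_location(contig: str, start: int, end: int, strand: str) -> str:
    """Format internal 0-based half-open coordinates as a 1-based report string."""
    body = f"{start + 1}–{end}"
    return f"{contig}: rev({body})" if strand == "-" else f"{contig}: {body}"
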