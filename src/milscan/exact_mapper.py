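"""Perfect-match read placement on both genome strands.

Seed-and-verify: a k-mer index (default k=12) proposes candidate positions,
each verified by full-length string comparison, so correctness does not
depend on the seed length.  All hits are reported; reads containing N never
map.  Minus-strand hits are reported at the forward-strand coordinates of
the matching interval.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, TextIO, Tuple

from .read_prep import UniqueRead
from .seq_io import Genome, reverse_complement


@dataclass(frozen=True, order=True)
class Alignment:
    contig: str
    start: int
    strand: str
    read: UniqueRead

    @property
    def end(self) -> int:
        return self.start + len(self.read.sequence)

    @property
    def count(self) -> int:
        return self.read.count


class SeedIndex:
    """Forward-strand k-mer → positions index."""

    def __init__(self, genome: Genome, k: int = 12):
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.genome = genome
        self.positions: Dict[str, List[Tuple[str, int]]] = defaultdict(list)
        for contig, seq in genome.contigs.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i:i + k]
                if "N" not in kmer:
                    self.positions[kmer].append((contig, i))

    def __len__(self) -> int:
        return sum(len(v) for v in self.positions.values())


def build_index(genome: Genome, k: int = 12) -> SeedIndex:
    return SeedIndex(genome, k)


def _scan_forward(seq: str, index: SeedIndex) -> List[Tuple[str, int]]:
    """All forward-strand exact occurrences of seq, seed-verified."""
    k = index.k
    if len(seq) < k:
        # fall back to direct scan for reads shorter than the seed
        hits = []
        for contig, cseq in index.genome.contigs.items():
            p = cseq.find(seq)
            while p != -1:
                hits.append((contig, p))
                p = cseq.find(seq, p + 1)
        return hits
    hits = []
    seed = seq[:k]
    for contig, pos in index.positions.get(seed, ()):
        cseq = index.genome.contigs[contig]
        if cseq[pos:pos + len(seq)] == seq:
            hits.append((contig, pos))
    return hits


def map_read(read, index: SeedIndex, genome: Genome = None) -> List[Alignment]:
    """All perfect-match placements of a read (UniqueRead or str) on ± strands."""
    if isinstance(read, str):
        read = UniqueRead(read, 1)
    seq = read.sequence
    if "N" in seq:
        return []
    alns = [Alignment(c, p, "+", read) for c, p in _scan_forward(seq, index)]
    rc = reverse_complement(seq)
    alns += [Alignment(c, p, "-", read) for c, p in _scan_forward(rc, index)]
    alns.sort(key=lambda a: (a.contig, a.start, a.strand))
    return alns


@dataclass
class MappedLibrary:
    alignments: List[Alignment]
    unique_reads: List[UniqueRead]
    hits_per_read: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.hits_per_read:
            counts: Dict[str, int] = defaultdict(int)
            for a in self.alignments:
                counts[a.read.sequence] += 1
            self.hits_per_read = dict(counts)

    @property
    def mapped_unique(self) -> int:
        return len({a.read.sequence for a in self.alignments})

    @property
    def mapped_total(self) -> int:
        seen = {}
        for a in self.alignments:
            seen[a.read.sequence] = a.read.count
        return sum(seen.values())

    @property
    def raw_unique(self) -> int:
        return len(self.unique_reads)

    @property
    def raw_total(self) -> int:
        return sum(u.count for u in self.unique_reads)

    def hits_of(self, sequence: str) -> List[Alignment]:
        return [a for a in self.alignments if a.read.sequence == sequence]

    def by_read(self) -> Dict[str, List[Alignment]]:
        out: Dict[str, List[Alignment]] = defaultdict(list)
        for a in self.alignments:
            out[a.read.sequence].append(a)
        return dict(out)


def map_library(unique: Sequence[UniqueRead], genome: Genome, k: int = 12,
                index: SeedIndex = None) -> MappedLibrary:
    if index is None:
        index = build_index(genome, k)
    alignments: List[Alignment] = []
    for u in unique:
        alignments.extend(map_read(u, index))
    return MappedLibrary(alignments, list(unique))


def write_sam_tsv(lib: MappedLibrary, handle: TextIO) -> None:
    """SAM-flavored TSV: QNAME, FLAG (0/16), RNAME, 1-based POS, SEQ, count tag."""
    by_read = lib.by_read()
    for i, u in enumerate(lib.unique_reads, start=1):
        for a in by_read.get(u.sequence, []):
            flag = 0 if a.strand == "+" else 16
            seq = a.read.sequence if a.strand == "+" else reverse_complement(a.read.sequence)
            handle.write(
                f"read{i}_x{u.count}\t{flag}\t{a.contig}\t{a.start + 1}\t{seq}\tXC:i:{u.count}\n"
            )
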