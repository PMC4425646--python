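"""sRNA-producing locus calling and Dicer-dependence comparison.

Loci are single-linkage chains of unique-read alignments (strand-blind):
alignments on the same contig whose starts are at most ``window`` bp apart
(default 300) are chained, and a chain is reported as a locus when it holds
at least ``min_unique`` distinct read sequences (default 4).  Loci are then
classified by the annotation class with the largest bp overlap and by the
orientation of their members, and Dicer-dependent loci are those of a
Dicer-proficient library with no interval-overlapping locus in the
Dicer-deficient library.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

from .exact_mapper import Alignment
from .seq_io import AnnotationSet, STRUCTURAL_KINDS

LOCUS_CLASSES = ("exon", "intron", "tRNA", "rRNA", "intergenic")
# tie-break priority: structural classes dominate
_CLASS_PRIORITY = {"rRNA": 0, "tRNA": 1, "exon": 2, "intron": 3, "intergenic": 4}


@dataclass
class LocusConfig:
    window: int = 300
    min_unique: int = 4

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_unique < 1:
            raise ValueError("window and min_unique must be >= 1")


@dataclass
class SRNALocus:
    contig: str
    start: int
    end: int
    members: List[Alignment]
    feature_class: Optional[str] = None
    feature_orientation: Optional[str] = None

    @property
    def unique_sequences(self) -> int:
        return len({m.read.sequence for m in self.members})

    @property
    def strand_content(self) -> str:
        strands = {m.strand for m in self.members}
        if strands == {"+", "-"}:
            return "both"
        return "plus_only" if strands == {"+"} else "minus_only"

    def overlaps(self, other: "SRNALocus") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def call_loci(alignments: Sequence[Alignment], cfg: LocusConfig = None) -> List[SRNALocus]:
    """Chain alignments per contig (strand-blind) and keep chains with
    >= min_unique distinct read sequences."""
    cfg = cfg or LocusConfig()
    per_contig: Dict[str, List[Alignment]] = defaultdict(list)
    for a in alignments:
        per_contig[a.contig].append(a)

    loci: List[SRNALocus] = []
    for contig in sorted(per_contig):
        alns = sorted(per_contig[contig], key=lambda a: (a.start, a.end, a.strand))
        chain: List[Alignment] = []
        for a in alns:
            if chain and a.start - chain[-1].start > cfg.window:
                loci.extend(_emit(contig, chain, cfg))
                chain = []
            chain.append(a)
        loci.extend(_emit(contig, chain, cfg))
    return loci


def _emit(contig: str, chain: List[Alignment], cfg: LocusConfig) -> List[SRNALocus]:
    if len({a.read.sequence for a in chain}) < cfg.min_unique:
        return []
    start = min(a.start for a in chain)
    end = max(a.end for a in chain)
    return [SRNALocus(contig, start, end, list(chain))]


def _overlap_bp(locus: SRNALocus, s: int, e: int) -> int:
    return max(0, min(locus.end, e) - max(locus.start, s))


def classify_locus(locus: SRNALocus, ann: AnnotationSet) -> Tuple[str, str]:
    """(feature_class, feature_orientation) for a called locus.

    feature_class = annotated class with maximal bp overlap of the envelope
    (intergenic if none); exon/intron orientation is member strand vs feature
    strand ({both, sense_only, antisense_only}); tRNA/rRNA/intergenic use
    {both, strand_specific}.
    """
    overlap: Dict[str, int] = defaultdict(int)
    best_bp: Dict[str, int] = defaultdict(int)
    strand_of_class: Dict[str, str] = {}
    for f in ann.features_overlapping(locus.contig, locus.start, locus.end):
        bp = _overlap_bp(locus, f.start, f.end)
        if bp > 0:
            overlap[f.kind] += bp
            # strand of the class = strand of its largest overlapping feature
            if bp > best_bp[f.kind]:
                best_bp[f.kind] = bp
                strand_of_class[f.kind] = f.strand

    candidates = [(k, v) for k, v in overlap.items() if v > 0]
    if not candidates:
        feature_class = "intergenic"
    else:
        candidates.sort(key=lambda kv: (-kv[1], _CLASS_PRIORITY[kv[0]]))
        feature_class = candidates[0][0]

    member_strands = {m.strand for m in locus.members}
    if feature_class in ("exon", "intron"):
        fstrand = strand_of_class[feature_class]
        orients = {"sense" if s == fstrand else "antisense" for s in member_strands}
        if orients == {"sense", "antisense"}:
            orientation = "both"
        elif orients == {"sense"}:
            orientation = "sense_only"
        else:
            orientation = "antisense_only"
    else:
        orientation = "both" if len(member_strands) == 2 else "strand_specific"

    locus.feature_class = feature_class
    locus.feature_orientation = orientation
    return feature_class, orientation


@dataclass
class LocusSummary:
    per_class: Dict[Tuple[str, str], int] = field(default_factory=lambda: defaultdict(int))
    total_loci: int = 0

    @property
    def both_strand_total(self) -> int:
        return sum(n for (cls, orient), n in self.per_class.items() if orient == "both")


def summarize(loci: Sequence[SRNALocus]) -> LocusSummary:
    summary = LocusSummary()
    summary.total_loci = len(loci)
    for locus in loci:
        if locus.feature_class is None:
            raise ValueError("locus not classified; call classify_locus first")
        summary.per_class[(locus.feature_class, locus.feature_orientation)] += 1
    return summary


@dataclass
class DicerLocusCall:
    wt_locus: SRNALocus
    status: str  # dicer_dependent_both | dicer_dependent_single | dicer_independent


def compare_loci(wt: Sequence[SRNALocus], mut: Sequence[SRNALocus]) -> List[DicerLocusCall]:
    """Dicer-dependence by >=1 bp interval overlap against the mutant loci."""
    mut_by_contig: Dict[str, List[SRNALocus]] = defaultdict(list)
    for m in mut:
        mut_by_contig[m.contig].append(m)

    calls: List[DicerLocusCall] = []
    for w in wt:
        if any(w.overlaps(m) for m in mut_by_contig.get(w.contig, ())):
            status = "dicer_independent"
        elif w.strand_content == "both":
            status = "dicer_dependent_both"
        else:
            status = "dicer_dependent_single"
        calls.append(DicerLocusCall(w, status))
    return calls


def dependent_counts(calls: Sequence[DicerLocusCall]) -> Tuple[int, int, int]:
    """(both, single, total) Dicer-dependent locus counts."""
    both = sum(1 for c in calls if c.status == "dicer_dependent_both")
    single = sum(1 for c in calls if c.status == "dicer_dependent_single")
    return both, single, both + single


def write_bed(loci: Sequence[SRNALocus], handle: TextIO) -> None:
    """BED6: name = locus id, score = #unique reads, strand ('.' = both)."""
    for i, locus in enumerate(loci, start=1):
        strand = {"both": ".", "plus_only": "+", "minus_only": "-"}[locus.strand_content]
        handle.write(
            f"{locus.contig}\t{locus.start}\t{locus.end}\tlocus{i}"
            f"\t{locus.unique_sequences}\t{strand}\n"
        )


def write_summary_table(summaries: Dict[str, LocusSummary], handle: TextIO) -> None:
    """Locus-characterization table: rows per class/orientation, one column per library."""
    names = list(summaries)
    handle.write("row\t" + "\t".join(names) + "\n")
    handle.write(
        "total number of sRNA-loci\t"
        + "\t".join(str(summaries[n].total_loci) for n in names) + "\n"
    )
    handle.write(
        "loci with sRNAs on both strands\t"
        + "\t".join(str(summaries[n].both_strand_total) for n in names) + "\n"
    )
    for cls in LOCUS_CLASSES:
        orients = (
            ("both", "sense_only", "antisense_only")
            if cls in ("exon", "intron")
            else ("both", "strand_specific")
        )
        for orient in orients:
            handle.write(
                f"{cls}:{orient}\t"
                + "\t".join(str(summaries[n].per_class.get((cls, orient), 0)) for n in names)
                + "\n"
            )
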