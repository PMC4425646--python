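"""Assign alignments to annotation categories and tally library composition.

Membership is by containment: an alignment belongs to an exon/intron/tRNA/
rRNA feature only when it lies fully inside it; a read straddling an
exon–intron junction inside a gene span is tallied at the gene level only.
A unique read contributes once per category it hits anywhere in the genome
(count-weighted in the total tally, once in the unique tally), so a
multi-mapping read may appear in several categories and the category sums
can exceed the mapped-read totals.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, List, Set, TextIO, Tuple

from .exact_mapper import Alignment, MappedLibrary
from .seq_io import AnnotationSet, STRUCTURAL_KINDS

CATEGORIES = ("gene", "exon", "intron", "tRNA", "rRNA", "intergenic")
ORIENTATIONS = ("sense", "antisense", "none")

CategoryCall = Tuple[str, str]  # (category, orientation)


def annotate_alignment(aln: Alignment, ann: AnnotationSet) -> FrozenSet[CategoryCall]:
    """Category calls for one alignment (containment rule, sense/antisense)."""
    calls: Set[CategoryCall] = set()
    start, end = aln.start, aln.end

    for f in ann.features_overlapping(aln.contig, start, end, kinds=STRUCTURAL_KINDS):
        if f.start <= start and end <= f.end:
            calls.add((f.kind, "sense" if f.strand == aln.strand else "antisense"))

    in_gene = False
    for gid, gs, ge, gstrand in ann.genes_overlapping(aln.contig, start, end):
        if gs <= start and end <= ge:
            in_gene = True
            orient = "sense" if gstrand == aln.strand else "antisense"
            calls.add(("gene", orient))
            for f in ann.features_overlapping(aln.contig, start, end, kinds=("exon", "intron")):
                if f.gene_id == gid and f.start <= start and end <= f.end:
                    calls.add((f.kind, orient))

    if not calls and not in_gene:
        calls.add(("intergenic", "none"))
    return frozenset(calls)


@dataclass
class CategoryCounts:
    """Per (category, orientation) tallies, total (count-weighted) and unique."""

    total: Dict[CategoryCall, int] = field(default_factory=lambda: defaultdict(int))
    unique: Dict[CategoryCall, int] = field(default_factory=lambda: defaultdict(int))
    # category-level tallies: a read counts once per category even if it hits
    # the category in both orientations
    total_by_category: Dict[str, int] = field(default_factory=lambda: defaultdict(int))
    unique_by_category: Dict[str, int] = field(default_factory=lambda: defaultdict(int))


def tabulate(lib: MappedLibrary, ann: AnnotationSet) -> CategoryCounts:
    """Tally the library: one increment per category per unique read."""
    counts = CategoryCounts()
    for sequence, alns in lib.by_read().items():
        read_count = alns[0].read.count
        calls: Set[CategoryCall] = set()
        for a in alns:
            calls |= annotate_alignment(a, ann)
        for call in calls:
            counts.total[call] += read_count
            counts.unique[call] += 1
        for category in {c for c, _o in calls}:
            counts.total_by_category[category] += read_count
            counts.unique_by_category[category] += 1
    return counts


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100·numerator/denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    value = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


_ROW_ORDER: List[Tuple[str, str]] = [
    ("gene", "Protein-coding genes"),
    ("exon", "Exon"),
    ("intron", "Intron"),
    ("tRNA", "tRNA"),
    ("rRNA", "rRNA"),
]


def write_category_table(counts: CategoryCounts, lib: MappedLibrary, handle: TextIO) -> None:
    """Library-composition table (raw/mapped totals, per-category tallies)."""
    handle.write("row\ttotal_reads\tunique_reads\n")
    handle.write(f"Raw reads\t{lib.raw_total}\t{lib.raw_unique}\n")
    handle.write(f"Mapped reads\t{lib.mapped_total}\t{lib.mapped_unique}\n")
    if lib.raw_total:
        handle.write(
            "Ratio\t{}%\t{}%\n".format(
                percent(lib.mapped_total, lib.raw_total, 2),
                percent(lib.mapped_unique, lib.raw_unique, 2),
            )
        )
    for category, label in _ROW_ORDER:
        handle.write(
            f"{label}\t{counts.total_by_category.get(category, 0)}"
            f"\t{counts.unique_by_category.get(category, 0)}\n"
        )
        for orient in ("sense", "antisense"):
            call = (category, orient)
            handle.write(
                f"  {orient}\t{counts.total.get(call, 0)}\t{counts.unique.get(call, 0)}\n"
            )
    call = ("intergenic", "none")
    handle.write(f"Intergenic\t{counts.total.get(call, 0)}\t{counts.unique.get(call, 0)}\n")
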