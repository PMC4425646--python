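"""TPTM normalization and per-read Dicer-dependence classification.

Counts are normalized to transcripts per ten million (TPTM) against the
count-weighted total of mapped, non-structural unique reads (each unique
sequence counted once, however many loci it hits).  Reads with any hit in a
tRNA/rRNA feature are "structural": they receive a TPTM against the same
denominator but are excluded from the denominator itself.

A unique read is Dicer-dependent when its normalized abundance drops by at
least 2-fold (log2 ratio <= -1) in the Dicer-deficient library, split into
absent (mutant TPTM = 0), strong (log2 <= -2) and slight (-2 < log2 <= -1)
classes; reads present only in the mutant are "mut_specific".
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, TextIO, Tuple

from .exact_mapper import MappedLibrary
from .read_prep import UniqueRead
from .seq_io import AnnotationSet, STRUCTURAL_KINDS

FIRST_NT = ("A", "C", "G", "U")
LENGTH_RANGE = range(15, 37)


@dataclass
class DifferentialConfig:
    scale: float = 1e7          # TPTM
    strong_log2: float = -2.0
    weak_log2: float = -1.0

    def __post_init__(self) -> None:
        if not (self.strong_log2 < self.weak_log2 < 0):
            raise ValueError("need strong_log2 < weak_log2 < 0")


@dataclass(frozen=True)
class NormalizedRead:
    read: UniqueRead
    tptm: float
    structural: bool


def structural_sequences(lib: MappedLibrary, ann: AnnotationSet) -> set:
    """Sequences with at least one hit overlapping a tRNA/rRNA feature."""
    out = set()
    for a in lib.alignments:
        if a.read.sequence in out:
            continue
        if ann.features_overlapping(a.contig, a.start, a.end, kinds=STRUCTURAL_KINDS):
            out.add(a.read.sequence)
    return out


def normalize_tptm(lib: MappedLibrary, ann: AnnotationSet,
                   cfg: DifferentialConfig = None) -> Dict[str, NormalizedRead]:
    """TPTM per mapped unique read; structural reads excluded from the denominator."""
    cfg = cfg or DifferentialConfig()
    structural = structural_sequences(lib, ann)
    mapped: Dict[str, UniqueRead] = {}
    for a in lib.alignments:
        mapped.setdefault(a.read.sequence, a.read)
    denominator = sum(u.count for s, u in mapped.items() if s not in structural)
    if denominator == 0:
        raise ValueError("TPTM denominator is zero (no non-structural mapped reads)")
    return {
        s: NormalizedRead(u, u.count * cfg.scale / denominator, s in structural)
        for s, u in mapped.items()
    }


def classify_read(tptm_wt: float, tptm_mut: float, cfg: DifferentialConfig = None) -> str:
    cfg = cfg or DifferentialConfig()
    if tptm_wt == 0 and tptm_mut == 0:
        raise ValueError("read absent from both libraries")
    if tptm_mut == 0:
        return "absent_in_mut"
    if tptm_wt == 0:
        return "mut_specific"
    ratio = math.log2(tptm_mut / tptm_wt)
    if ratio <= cfg.strong_log2:
        return "strong"
    if ratio <= cfg.weak_log2:
        return "slight"
    return "unchanged"


DICER_DEPENDENT_CATEGORIES = ("absent_in_mut", "strong", "slight")


@dataclass(frozen=True)
class DifferentialCall:
    sequence: str
    tptm_wt: float
    tptm_mut: float
    category: str

    @property
    def dicer_dependent(self) -> bool:
        return self.category in DICER_DEPENDENT_CATEGORIES


def differential_table(wt: Dict[str, NormalizedRead], mut: Dict[str, NormalizedRead],
                       cfg: DifferentialConfig = None) -> List[DifferentialCall]:
    """Per-sequence calls over the union of two normalized libraries."""
    cfg = cfg or DifferentialConfig()
    calls = []
    for seq in sorted(set(wt) | set(mut)):
        w = wt[seq].tptm if seq in wt else 0.0
        m = mut[seq].tptm if seq in mut else 0.0
        calls.append(DifferentialCall(seq, w, m, classify_read(w, m, cfg)))
    return calls


def count_dicer_dependent(calls: Iterable[DifferentialCall]) -> Tuple[int, int, int, int]:
    """(n_absent, n_strong, n_slight, n_total) over a call list."""
    n_absent = n_strong = n_slight = 0
    for c in calls:
        if c.category == "absent_in_mut":
            n_absent += 1
        elif c.category == "strong":
            n_strong += 1
        elif c.category == "slight":
            n_slight += 1
    return n_absent, n_strong, n_slight, n_absent + n_strong + n_slight


def length_histogram(unique: Sequence[UniqueRead], weighted: bool = False) -> Dict[int, int]:
    """Read-length histogram over 15–36 nt (count-weighted or per unique read)."""
    hist = {length: 0 for length in LENGTH_RANGE}
    for u in unique:
        hist[len(u.sequence)] = hist.get(len(u.sequence), 0) + (u.count if weighted else 1)
    return hist


def first_nt_by_length(unique: Sequence[UniqueRead]) -> Dict[Tuple[int, str], int]:
    """5'-nucleotide tallies per read length; T reported as U."""
    out: Dict[Tuple[int, str], int] = defaultdict(int)
    for u in unique:
        nt = u.sequence[0].replace("T", "U")
        out[(len(u.sequence), nt)] += 1
    return dict(out)


def first_nt_counts(sequences: Iterable[str]) -> Dict[str, int]:
    """Overall 5'-nucleotide tallies (U for T) for a set of sequences."""
    out = {nt: 0 for nt in FIRST_NT}
    for s in sequences:
        out[s[0].upper().replace("T", "U")] += 1
    return out


def first_nt_u_fraction(unique: Sequence[UniqueRead]) -> float:
    if not unique:
        raise ValueError("empty read set")
    n_u = sum(1 for u in unique if u.sequence[0] in "TU")
    return n_u / len(unique)


def write_differential_table(calls: Sequence[DifferentialCall], handle: TextIO) -> None:
    handle.write("sequence\ttptm_wt\ttptm_mut\tlog2_ratio\tcategory\n")
    for c in calls:
        if c.tptm_wt > 0 and c.tptm_mut > 0:
            ratio = f"{math.log2(c.tptm_mut / c.tptm_wt):.3f}"
        else:
            ratio = "NA"
        handle.write(f"{c.sequence}\t{c.tptm_wt:.3f}\t{c.tptm_mut:.3f}\t{ratio}\t{c.category}\n")
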