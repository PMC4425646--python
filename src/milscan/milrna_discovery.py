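"""Hairpin-based milRNA discovery.

A high-count read stack (default >= 10 counts, outside tRNA/rRNA) seeds two
candidate precursor windows excised around it (70 nt up / 20 nt down and the
mirror, covering the 43–89 nt precursor range seen for fungal milRNAs).
Each window is folded with a maximum-pairing (Nussinov-style) dynamic
program — pair scores WC = 2, G:U = 1, minimum loop 3, ties broken toward
stacked (adjacent) pairs — and the read signature within the window is
scored: the mature arm must sit on one stem arm with a compact duplex
partner, at least 60% of its bases paired, and at least 90% of the
(count-weighted) reads inside the window must fall entirely within the
mature, star or loop windows.  The candidate score is

    10 * signature_frac + 10 * paired_frac + 5 * [star reads present]
    + log2(1 + mature count)

with a default cutoff of 20.  The folding score is a pairing score, not a
thermodynamic free energy.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, TextIO, Tuple

import numpy as np
from numba import njit

from .dicer_differential import structural_sequences
from .exact_mapper import Alignment, MappedLibrary, SeedIndex, build_index, map_read
from .seq_io import Genome, AnnotationSet, format_location, parse_location

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@dataclass
class MilConfig:
    excise_up: int = 70
    excise_down: int = 20
    min_loop: int = 3
    min_paired_frac: float = 0.6
    min_signature_frac: float = 0.9
    score_cutoff: float = 20.0
    min_mature_count: int = 10
    # signature windows allow 2 nt of 5' and 5 nt of 3' read heterogeneity
    fuzz_5p: int = 2
    fuzz_3p: int = 5
    # the star arm must be an ungapped near-reverse-complement of the mature:
    # WC = 1, G:U = 0.5, identity fraction at least this
    min_duplex_ident: float = 0.75
    # fraction of mature partners that must lie on the majority arm, and how
    # many opportunistic base pairs inside the mature window are tolerated
    min_arm_frac: float = 0.75
    max_internal_pairs: int = 2
    min_fold_len: int = 8
    max_fold_len: int = 200

    def __post_init__(self) -> None:
        if min(self.excise_up, self.excise_down, self.min_loop, self.min_mature_count) < 1:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# folding engine

@njit(cache=True)
def _pair_score(a: int, b: int) -> int:
    if (a == 0 and b == 3) or (a == 3 and b == 0) or (a == 2 and b == 1) or (a == 1 and b == 2):
        return 2  # Watson-Crick
    if (a == 2 and b == 3) or (a == 3 and b == 2):
        return 1  # G:U wobble
    return 0


@njit(cache=True)
def _fill(codes, min_loop):
    # values encode (pair score, stacked-pair count) as score*1024 + stacks,
    # so integer max performs the lexicographic tie-break toward stacking
    n = codes.shape[0]
    W = np.zeros((n, n), dtype=np.int64)
    WX = np.zeros((n, n), dtype=np.int64)
    P = np.full((n, n), -1, dtype=np.int64)
    for span in range(1, n):
        for i in range(0, n - span):
            j = i + span
            best = W[i, j - 1]
            for k in range(i + 1, j):
                if j - k > min_loop and P[k, j] >= 0:
                    left = W[i, k - 1] if k - 1 >= i else 0
                    v = left + P[k, j]
                    if v > best:
                        best = v
            WX[i, j] = best
            s = _pair_score(codes[i], codes[j])
            if s > 0 and j - i > min_loop:
                inner = WX[i + 1, j - 1]
                if P[i + 1, j - 1] >= 0 and P[i + 1, j - 1] + 1 > inner:
                    inner = P[i + 1, j - 1] + 1
                P[i, j] = s * 1024 + inner
            w = WX[i, j]
            if P[i, j] > w:
                w = P[i, j]
            W[i, j] = w
    return W, WX, P


def _traceback(codes, min_loop: int, W, WX, P) -> List[Tuple[int, int]]:
    n = len(codes)
    pairs: List[Tuple[int, int]] = []
    stack = [("W", 0, n - 1)]
    while stack:
        op, i, j = stack.pop()
        if j <= i:
            continue
        if op == "W":
            if P[i, j] >= 0 and W[i, j] == P[i, j]:
                stack.append(("P", i, j))
            else:
                stack.append(("WX", i, j))
        elif op == "WX":
            target = WX[i, j]
            if W[i, j - 1] == target:
                stack.append(("W", i, j - 1))
                continue
            for k in range(i + 1, j):
                if j - k > min_loop and P[k, j] >= 0:
                    left = W[i, k - 1] if k - 1 >= i else 0
                    if left + P[k, j] == target:
                        stack.append(("P", k, j))
                        if k - 1 >= i:
                            stack.append(("W", i, k - 1))
                        break
        else:  # P
            pairs.append((i, j))
            s = _pair_score(codes[i], codes[j])
            rem = P[i, j] - s * 1024
            ii, jj = i + 1, j - 1
            if jj <= ii:
                continue
            if P[ii, jj] >= 0 and P[ii, jj] + 1 == rem:
                stack.append(("P", ii, jj))
            else:
                stack.append(("WX", ii, jj))
    return sorted(pairs)


@dataclass(frozen=True)
class HairpinStructure:
    sequence: str
    pairs: frozenset
    dot_bracket: str
    energy_score: float

    @property
    def pair_score(self) -> int:
        codes = [_CODE[c] for c in self.sequence]
        return sum(int(_pair_score(codes[i], codes[j])) for i, j in self.pairs)

    def partner_map(self) -> Dict[int, int]:
        out = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


def _is_wc(a: str, b: str) -> bool:
    return {a, b} in ({"A", "T"}, {"A", "U"}, {"G", "C"})


def _structure_from_pairs(seq: str, pairs: Sequence[Tuple[int, int]]) -> HairpinStructure:
    pairset = set(map(tuple, pairs))
    dots = ["."] * len(seq)
    for i, j in pairset:
        dots[i], dots[j] = "(", ")"
    stacked_wc = sum(
        1 for i, j in pairset if (i + 1, j - 1) in pairset and _is_wc(seq[i], seq[j])
    )
    energy = -(2 * stacked_wc + (len(pairset) - stacked_wc))
    return HairpinStructure(seq, frozenset(pairset), "".join(dots), float(energy))


def fold(seq: str, cfg: MilConfig = None) -> HairpinStructure:
    """Maximum-pairing nested structure of a 20–200 nt sequence."""
    cfg = cfg or MilConfig()
    if not (cfg.min_fold_len <= len(seq) <= cfg.max_fold_len):
        raise ValueError(f"sequence length {len(seq)} outside [{cfg.min_fold_len},{cfg.max_fold_len}]")
    codes = np.array([_CODE[c.upper()] for c in seq], dtype=np.int8)
    W, WX, P = _fill(codes, cfg.min_loop)
    pairs = _traceback(codes, cfg.min_loop, W, WX, P)
    return _structure_from_pairs(seq.upper().replace("U", "T"), pairs)


# ---------------------------------------------------------------------------
# precursor excision and scoring

@dataclass(frozen=True)
class PrecursorWindow:
    contig: str
    gstart: int
    gend: int
    strand: str
    sequence: str

    def to_window_coords(self, gstart: int, gend: int) -> Tuple[int, int]:
        """Map a genomic interval into precursor (5'→3') coordinates."""
        if self.strand == "+":
            return gstart - self.gstart, gend - self.gstart
        return self.gend - gend, self.gend - gstart


def excise_candidates(stack: Alignment, genome: Genome, cfg: MilConfig = None) -> List[PrecursorWindow]:
    """Two candidate precursor windows around a read stack, strand-aware."""
    cfg = cfg or MilConfig()
    clen = len(genome.contigs[stack.contig])
    s, e = stack.start, stack.end
    if stack.strand == "+":
        spans = [(s - cfg.excise_up, e + cfg.excise_down), (s - cfg.excise_down, e + cfg.excise_up)]
    else:
        spans = [(s - cfg.excise_down, e + cfg.excise_up), (s - cfg.excise_up, e + cfg.excise_down)]
    windows = []
    for a, b in spans:
        a, b = max(0, a), min(clen, b)
        windows.append(
            PrecursorWindow(stack.contig, a, b, stack.strand,
                            genome.fetch(stack.contig, a, b, stack.strand))
        )
    return windows


@dataclass
class MilRNACandidate:
    contig: str
    start: int           # 0-based half-open trimmed precursor envelope
    end: int
    strand: str
    precursor_seq: str
    mature_seq: str
    star_seq: str
    structure: HairpinStructure
    score: float
    signature_frac: float
    paired_frac: float
    star_reads: int
    mature_count: int
    tptm_per_library: Dict[str, float] = field(default_factory=dict)

    @property
    def location(self) -> str:
        return format_location(self.contig, self.start, self.end, self.strand)

    @property
    def precursor_length(self) -> int:
        return self.end - self.start

    @property
    def first_nt(self) -> str:
        return self.mature_seq[0].replace("T", "U")

    def reciprocal_overlap(self, other: "MilRNACandidate") -> float:
        if self.contig != other.contig or self.strand != other.strand:
            return 0.0
        ov = min(self.end, other.end) - max(self.start, other.start)
        if ov <= 0:
            return 0.0
        return min(ov / (self.end - self.start), ov / (other.end - other.start))


def _read_windows(window: PrecursorWindow, reads: Sequence[Alignment]) -> List[Tuple[int, int, int]]:
    """(pstart, pend, count) of alignments fully inside the window, same strand."""
    out = []
    for a in reads:
        if a.strand != window.strand or a.contig != window.contig:
            continue
        if a.start >= window.gstart and a.end <= window.gend:
            p0, p1 = window.to_window_coords(a.start, a.end)
            out.append((p0, p1, a.read.count))
    return out


def _signature_upper_bound(m0: int, m1: int, reads: Sequence[Tuple[int, int, int]],
                           cfg: MilConfig) -> float:
    """Cheap pre-fold bound: star+loop lie on one side of the mature, so the
    signature can never exceed mature-contained + best one-sided weight."""
    total = sum(c for *_ , c in reads)
    if total == 0:
        return 0.0
    w_m = w_left = w_right = 0
    for p0, p1, c in reads:
        if p0 >= m0 - cfg.fuzz_5p and p1 <= m1 + cfg.fuzz_3p:
            w_m += c
        elif p0 < m0:
            w_left += c
        elif p1 > m1:
            w_right += c
    return (w_m + max(w_left, w_right)) / total


_RC = str.maketrans("ACGTN", "TGCAN")


def _best_duplex(seq: str, m0: int, m1: int, star_on_right: bool,
                 cfg: MilConfig) -> Optional[Tuple[int, int]]:
    """Best ungapped near-reverse-complement of the mature on the star side.

    Scores WC pairs 1 and G:U wobbles 0.5 per position; returns the star core
    interval when the identity fraction reaches ``min_duplex_ident``.
    """
    Lm = m1 - m0
    rc = seq[m0:m1].translate(_RC)[::-1]
    lo, hi = (m1, len(seq) - Lm) if star_on_right else (0, m0 - Lm)
    best, best_o = 0.0, None
    for o in range(lo, hi + 1):
        s = 0.0
        for t in range(Lm):
            b = seq[o + t]
            r = rc[t]
            if b == r:
                s += 1.0
            elif (r == "C" and b == "T") or (r == "A" and b == "G"):
                s += 0.5  # G:U wobble between mature and star
        if s > best:
            best, best_o = s, o
    if best_o is None or best / Lm < cfg.min_duplex_ident:
        return None
    return best_o, best_o + Lm


def score_candidate(window: PrecursorWindow, mature: Alignment,
                    reads: Sequence[Alignment], cfg: MilConfig = None,
                    structure: HairpinStructure = None) -> Optional[MilRNACandidate]:
    """Score one excised window against its read signature; None = reject."""
    cfg = cfg or MilConfig()
    seq = window.sequence
    if len(seq) < cfg.min_fold_len:
        return None
    m0, m1 = window.to_window_coords(mature.start, mature.end)
    if m0 < 0 or m1 > len(seq):
        return None
    rwins = _read_windows(window, reads)
    if _signature_upper_bound(m0, m1, rwins, cfg) < cfg.min_signature_frac:
        return None

    if structure is None:
        structure = fold(seq, cfg)
    pairs = structure.pairs
    internal = sum(1 for i, j in pairs if m0 <= i < m1 and m0 <= j < m1)
    if internal > cfg.max_internal_pairs:
        return None
    partner = structure.partner_map()
    partners = [(i, partner[i]) for i in range(m0, m1)
                if i in partner and not (m0 <= partner[i] < m1)]
    if not partners:
        return None
    left = [j for _, j in partners if j < m0]
    right = [j for _, j in partners if j >= m1]
    major = left if len(left) >= len(right) else right
    if len(major) / len(partners) < cfg.min_arm_frac:
        return None
    paired_frac = len(major) / (m1 - m0)
    if paired_frac < cfg.min_paired_frac:
        return None

    star_on_right = major is right
    duplex = _best_duplex(seq, m0, m1, star_on_right, cfg)
    if duplex is None:
        return None
    star0, star1 = duplex
    # canonical 2-nt 3' overhang: extend the star's 3' (right) edge
    if star0 >= m1:  # star on the 3' side of the mature
        star1 = min(star1 + 2, len(seq))
        loop = (m1, star0)
    else:            # star on the 5' side
        star1 = min(star1 + 2, m0)
        loop = (star1, m0)
    loop = (loop[0], max(loop))

    def contained(p0: int, p1: int, w0: int, w1: int, pad: bool = True) -> bool:
        fz5, fz3 = (cfg.fuzz_5p, cfg.fuzz_3p) if pad else (0, 0)
        return p0 >= w0 - fz5 and p1 <= w1 + fz3

    total_w = sum(c for *_, c in rwins)
    if total_w == 0:
        return None
    sig_w = 0
    star_reads = 0
    for p0, p1, c in rwins:
        in_star = contained(p0, p1, star0, star1)
        if contained(p0, p1, m0, m1) or in_star or contained(p0, p1, *loop, pad=False):
            sig_w += c
        if in_star:
            star_reads += c
    signature_frac = sig_w / total_w
    if signature_frac < cfg.min_signature_frac:
        return None

    score = (
        10.0 * signature_frac
        + 10.0 * paired_frac
        + 5.0 * (star_reads >= 1)
        + math.log2(1 + mature.read.count)
    )
    if score < cfg.score_cutoff:
        return None

    t0, t1 = min(m0, star0), max(m1, star1)
    trimmed_pairs = [(i - t0, j - t0) for i, j in pairs if t0 <= i and j < t1]
    trimmed = _structure_from_pairs(seq[t0:t1], trimmed_pairs)
    if window.strand == "+":
        g0, g1 = window.gstart + t0, window.gstart + t1
    else:
        g0, g1 = window.gend - t1, window.gend - t0
    return MilRNACandidate(
        contig=window.contig, start=g0, end=g1, strand=window.strand,
        precursor_seq=seq[t0:t1], mature_seq=seq[m0:m1], star_seq=seq[star0:star1],
        structure=trimmed, score=score, signature_frac=signature_frac,
        paired_frac=paired_frac, star_reads=star_reads, mature_count=mature.read.count,
    )


# ---------------------------------------------------------------------------
# library-level prediction

class _AlignmentLookup:
    """Per (contig, strand) start-sorted alignments for window queries."""

    def __init__(self, lib: MappedLibrary):
        self._data: Dict[Tuple[str, str], List[Alignment]] = {}
        for a in sorted(lib.alignments, key=lambda a: a.start):
            self._data.setdefault((a.contig, a.strand), []).append(a)
        self._starts = {k: [a.start for a in v] for k, v in self._data.items()}

    def within(self, contig: str, strand: str, gstart: int, gend: int) -> List[Alignment]:
        alns = self._data.get((contig, strand), [])
        starts = self._starts.get((contig, strand), [])
        lo = bisect_left(starts, gstart)
        out = []
        for a in alns[lo:]:
            if a.start >= gend:
                break
            if a.end <= gend:
                out.append(a)
        return out


def predict_milrnas(lib: MappedLibrary, genome: Genome, ann: AnnotationSet,
                    cfg: MilConfig = None) -> List[MilRNACandidate]:
    """Full scan over qualifying stacks; overlapping candidates deduplicated
    keeping the highest score."""
    cfg = cfg or MilConfig()
    structural = structural_sequences(lib, ann)
    lookup = _AlignmentLookup(lib)
    candidates: List[MilRNACandidate] = []
    for seq, alns in sorted(lib.by_read().items()):
        read = alns[0].read
        if read.count < cfg.min_mature_count or seq in structural:
            continue
        for a in alns:
            for window in excise_candidates(a, genome, cfg):
                reads = lookup.within(window.contig, window.strand, window.gstart, window.gend)
                cand = score_candidate(window, a, reads, cfg)
                if cand is not None:
                    candidates.append(cand)

    candidates.sort(key=lambda c: (-c.score, c.contig, c.start, c.strand))
    kept: List[MilRNACandidate] = []
    for cand in candidates:
        if not any(
            k.contig == cand.contig and k.strand == cand.strand
            and k.start < cand.end and cand.start < k.end
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda c: (c.contig, c.start, c.strand))
    return kept


def merge_predictions(a: Sequence[MilRNACandidate], b: Sequence[MilRNACandidate],
                      min_reciprocal: float = 0.5) -> Tuple[List[MilRNACandidate], int]:
    """Union of two candidate sets; >=50% reciprocal precursor overlap merges.

    Returns (merged candidates, number shared); the higher-scoring record of
    a shared pair is kept.  |merged| = |a| + |b| − shared.
    """
    merged = list(a)
    shared = 0
    used: Set[int] = set()
    for cand in b:
        match = None
        for idx, kept in enumerate(merged):
            if idx in used:
                continue
            if kept.reciprocal_overlap(cand) >= min_reciprocal:
                match = idx
                break
        if match is None:
            merged.append(cand)
        else:
            shared += 1
            used.add(match)
            if cand.score > merged[match].score:
                merged[match] = cand
    merged.sort(key=lambda c: -c.score)
    return merged, shared


def precursor_length(loc) -> int:
    """Length of a 1-based inclusive interval, given as (start, end) or a
    location string like ``ChrI: 4059417–4059459`` / ``rev(a–b)``."""
    if isinstance(loc, str):
        _contig, s0, e0, _strand = parse_location(loc)
        return e0 - s0
    start, end = loc
    if start > end:
        raise ValueError("start > end")
    return end - start + 1


def count_genomic_occurrences(seq: str, genome: Genome, index: SeedIndex = None) -> int:
    """Perfect-match hit count of a sequence on both genome strands."""
    if index is None:
        index = build_index(genome, k=min(12, len(seq)))
    return len(map_read(seq.upper().replace("U", "T"), index))


def write_milrna_table(cands: Sequence[MilRNACandidate], handle: TextIO,
                       library_names: Sequence[str] = ()) -> None:
    cols = ["milRNA", "sequence"] + [f"tptm_{n}" for n in library_names] + [
        "score", "energy_score", "precursor_location", "structure"]
    handle.write("\t".join(cols) + "\n")
    for i, c in enumerate(cands, start=1):
        tptms = [f"{c.tptm_per_library.get(n, 0.0):.1f}" for n in library_names]
        row = [f"milR-{i}", c.mature_seq.replace("T", "U").lower(), *tptms,
               f"{c.score:.1f}", f"{c.structure.energy_score:.1f}", c.location,
               c.structure.dot_bracket]
        handle.write("\t".join(row) + "\n")
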