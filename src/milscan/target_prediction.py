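"""milRNA target-site prediction on hypothetical 3'-UTRs.

Because no UTR annotation exists for most fungal genomes, the 1-kb genomic
sequence downstream of each protein-coding gene (on the coding strand) is
used as a hypothetical 3'-UTR.  Two complementary scorers are run:

* an animal-style local-alignment score (miRanda-like): Watson-Crick +5,
  G:U +2, mismatch −3, gap −8, with substitution scores doubled at milRNA
  seed positions 2–8; and
* a plant-style ungapped penalty (TAPIR-like): mismatch 1, G:U 0.5,
  doubled at milRNA positions 2–13; a site qualifies at penalty <= 4.

Sites whose best match is the star arm rather than the mature milRNA are
flagged, mirroring the check used to spot milRNAs derived from UTRs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, TextIO, Tuple

from .seq_io import AnnotationSet, Genome

GAP_PENALTY = -8
MATCH_WC = 5
MATCH_GU = 2
MISMATCH = -3
SEED_ANIMAL = (2, 8)    # 1-based inclusive milRNA positions with doubled scores
SEED_PLANT = (2, 13)
PLANT_MISMATCH = 1.0
PLANT_GU = 0.5
DEFAULT_ANIMAL_THRESHOLD = 112.0   # 0.8 of a perfect 21-nt site (140)
DEFAULT_PLANT_THRESHOLD = 4.0
AGREEMENT_TOLERANCE = 3


@dataclass(frozen=True)
class UTRRegion:
    gene_id: str
    sequence: str
    truncated: bool = False

    def __post_init__(self) -> None:
        if len(self.sequence) > 1000:
            raise ValueError("hypothetical 3'-UTR longer than 1 kb")


def extract_utrs(ann: AnnotationSet, genome: Genome, length: int = 1000) -> List[UTRRegion]:
    """1-kb (default) downstream sequence of every gene, on the coding strand."""
    out = []
    for gid in sorted(ann.gene_spans):
        contig, start, end, strand = ann.gene_spans[gid]
        clen = len(genome.contigs[contig])
        if strand == "+":
            a, b = end, min(end + length, clen)
            seq = genome.contigs[contig][a:b]
        else:
            a, b = max(0, start - length), start
            seq = genome.fetch(contig, a, b, "-")
        out.append(UTRRegion(gid, seq, truncated=len(seq) < length))
    return out


def _comp_score(mil_base: str, utr_base: str) -> int:
    pair = mil_base + utr_base
    if pair in ("AT", "TA", "GC", "CG"):
        return MATCH_WC
    if pair in ("GT", "TG"):
        return MATCH_GU
    return MISMATCH


def score_animal(mil: str, utr: str) -> Tuple[int, int]:
    """Best local-alignment site of a milRNA on a UTR: (utr offset, score).

    The milRNA is reversed (3'→5') and aligned against the UTR (5'→3') so
    complementary bases face each other; ties break toward the leftmost site.
    """
    mil = mil.upper().replace("U", "T")
    utr = utr.upper().replace("U", "T")
    m, L = len(mil), len(utr)
    if m == 0 or L == 0:
        return 0, 0
    rev = mil[::-1]
    # substitution weight per reversed-mil row: doubled in seed positions 2-8
    weights = []
    for i in range(m):
        pos = m - i  # 1-based milRNA position of reversed index i
        weights.append(2 if SEED_ANIMAL[0] <= pos <= SEED_ANIMAL[1] else 1)

    best_score, best_start, best_end = 0, 0, 0
    prev_h = [0] * (L + 1)
    prev_s = list(range(0, L + 1))      # start offset of the alignment per cell
    for i in range(1, m + 1):
        cur_h = [0] * (L + 1)
        cur_s = [0] * (L + 1)
        w = weights[i - 1]
        base = rev[i - 1]
        for j in range(1, L + 1):
            diag = prev_h[j - 1] + w * _comp_score(base, utr[j - 1])
            up = prev_h[j] + GAP_PENALTY
            left = cur_h[j - 1] + GAP_PENALTY
            h, s = 0, j
            if diag >= h:
                h, s = diag, prev_s[j - 1] if prev_h[j - 1] > 0 else j - 1
            if up > h:
                h, s = up, prev_s[j] if prev_h[j] > 0 else j
            if left > h:
                h, s = left, cur_s[j - 1]
            cur_h[j] = h
            cur_s[j] = s
            if h > best_score or (h == best_score and h > 0 and (s, j) < (best_start, best_end)):
                best_score, best_start, best_end = h, s, j
        prev_h, prev_s = cur_h, cur_s
    return best_start, best_score


def score_plant(mil: str, utr: str) -> Tuple[int, float]:
    """Best ungapped window: (utr offset, penalty); lower penalty is better."""
    mil = mil.upper().replace("U", "T")
    utr = utr.upper().replace("U", "T")
    m, L = len(mil), len(utr)
    if m == 0 or L < m:
        return 0, float("inf")
    rev = mil[::-1]
    weights = [2.0 if SEED_PLANT[0] <= (m - i) <= SEED_PLANT[1] else 1.0 for i in range(m)]
    best_off, best_pen = 0, float("inf")
    for off in range(L - m + 1):
        pen = 0.0
        for i in range(m):
            s = _comp_score(rev[i], utr[off + i])
            if s == MISMATCH:
                pen += PLANT_MISMATCH * weights[i]
            elif s == MATCH_GU:
                pen += PLANT_GU * weights[i]
            if pen >= best_pen:
                break
        if pen < best_pen:
            best_off, best_pen = off, pen
    return best_off, best_pen


@dataclass
class TargetSite:
    milrna_id: str
    gene_id: str
    utr_offset: int
    animal_score: int
    plant_penalty: float
    supported_by: Set[str] = field(default_factory=set)
    agreement: bool = False
    star_only: bool = False


_RC = str.maketrans("ACGTN", "TGCAN")


def _best_identity(needle: str, haystack: str) -> float:
    """Best ungapped identity of needle inside (or against) haystack."""
    needle, haystack = needle.upper(), haystack.upper()
    if len(needle) > len(haystack):
        needle, haystack = haystack, needle
    if not needle:
        return 0.0
    best = 0
    for off in range(len(haystack) - len(needle) + 1):
        best = max(best, sum(a == b for a, b in zip(needle, haystack[off:])))
    return best / len(needle)


def flag_star(site_window: str, mature: str, star: str) -> bool:
    """True when the site belongs to the milRNA's own duplex, not a target.

    Fires when the star arm binds the window better than the mature does, or
    when the window sequence itself is the star arm (a hairpin lying inside a
    downstream window) rather than an independent complement of the mature.
    """
    mature = mature.upper().replace("U", "T")
    star = star.upper().replace("U", "T")
    if score_animal(star, site_window)[1] > score_animal(mature, site_window)[1]:
        return True
    rc_mature = mature.translate(_RC)[::-1]
    return _best_identity(star, site_window) > _best_identity(rc_mature, site_window)


@dataclass
class TargetConfig:
    animal_threshold: float = DEFAULT_ANIMAL_THRESHOLD
    plant_threshold: float = DEFAULT_PLANT_THRESHOLD
    agreement_tolerance: int = AGREEMENT_TOLERANCE


def predict_targets(milrnas: Sequence[Tuple[str, str, Optional[str]]],
                    utrs: Sequence[UTRRegion],
                    cfg: TargetConfig = None) -> List[TargetSite]:
    """Run both scorers over all (milRNA, UTR) pairs.

    ``milrnas`` holds (id, mature sequence, star sequence or None).  Only
    sites passing at least one scorer threshold are reported.
    """
    cfg = cfg or TargetConfig()
    sites: List[TargetSite] = []
    for mil_id, mature, star in milrnas:
        for utr in utrs:
            if not utr.sequence:
                continue
            a_off, a_score = score_animal(mature, utr.sequence)
            p_off, p_pen = score_plant(mature, utr.sequence)
            supported = set()
            if a_score >= cfg.animal_threshold:
                supported.add("animal")
            if p_pen <= cfg.plant_threshold:
                supported.add("plant")
            if not supported:
                continue
            agreement = (
                supported == {"animal", "plant"}
                and abs(a_off - p_off) <= cfg.agreement_tolerance
            )
            offset = a_off if "animal" in supported else p_off
            window = utr.sequence[offset:offset + len(mature) + 4]
            star_only = bool(star) and flag_star(window, mature, star)
            sites.append(
                TargetSite(mil_id, utr.gene_id, offset, a_score, p_pen,
                           supported, agreement, star_only)
            )
    return sites


def write_target_table(sites: Sequence[TargetSite], handle: TextIO) -> None:
    handle.write("milRNA\tgene\toffset\tanimal_score\tplant_penalty\tsupported_by\tagreement\tcomment\n")
    for s in sites:
        pen = "inf" if s.plant_penalty == float("inf") else f"{s.plant_penalty:g}"
        handle.write(
            f"{s.milrna_id}\t{s.gene_id}\t{s.utr_offset}\t{s.animal_score}\t{pen}"
            f"\t{'+'.join(sorted(s.supported_by))}\t{'yes' if s.agreement else 'no'}"
            f"\t{'star' if s.star_only else '-'}\n"
        )


def write_utr_fasta(utrs: Sequence[UTRRegion], handle: TextIO) -> None:
    for u in utrs:
        suffix = " truncated" if u.truncated else ""
        handle.write(f">{u.gene_id}{suffix}\n{u.sequence}\n")
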