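"""Adapter trimming, length filtering and read collapsing.

The preprocessing contract: 3' adapters are removed by exact prefix match
(minimum 5-nt overlap, no mismatches); reads without a recognizable adapter
are discarded; trimmed inserts are length-filtered (default 15–36 nt),
collapsed to unique sequences with multiplicities, and only unique reads
with a count of at least 10 (default) enter downstream analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, TextIO, Tuple

from Bio import SeqIO

# Illumina TruSeq small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

REJECT = None  # sentinel: read discarded (no adapter found)


@dataclass
class ReadFilterConfig:
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 15
    max_len: int = 36
    min_count: int = 10
    min_mean_quality: Optional[float] = None  # off by default

    def __post_init__(self) -> None:
        if not (0 < self.min_len <= self.max_len):
            raise ValueError("need 0 < min_len <= max_len")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")


@dataclass(frozen=True, order=True)
class UniqueRead:
    """A distinct read sequence with its multiplicity in one library."""

    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("count must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)


def trim_3prime_adapter(read: str, adapter: str, min_overlap: int = 5) -> Optional[str]:
    """Trim at the leftmost position where a prefix of the adapter matches.

    The adapter prefix must either reach the read's 3' end or be the complete
    adapter, with at least ``min_overlap`` matching bases.  Returns the insert
    (possibly empty) or ``REJECT`` (None) when no adapter is found — untrimmed
    reads are excluded from analysis.
    """
    if not read or not adapter:
        raise ValueError("read and adapter must be non-empty")
    n, alen = len(read), len(adapter)
    for p in range(0, n - min_overlap + 1):
        m = min(n - p, alen)
        if read[p:p + m] == adapter[:m]:
            return read[:p]
    return REJECT


def filter_length(read: str, cfg: ReadFilterConfig) -> bool:
    return cfg.min_len <= len(read) <= cfg.max_len


def collapse(reads: Iterable[str]) -> List[UniqueRead]:
    """Collapse to unique reads, sorted by descending count then sequence."""
    counts = Counter(reads)
    return [
        UniqueRead(seq, c)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_min_count(unique: Sequence[UniqueRead], cfg: ReadFilterConfig) -> List[UniqueRead]:
    return [u for u in unique if u.count >= cfg.min_count]


def preprocess_reads(raw_reads: Iterable[str], cfg: ReadFilterConfig) -> Tuple[List[UniqueRead], Dict[str, int]]:
    """Trim + length-filter + collapse + min-count filter, with stage counts."""
    stats = {"input": 0, "trimmed": 0, "length_ok": 0}
    kept: List[str] = []
    for read in raw_reads:
        stats["input"] += 1
        insert = trim_3prime_adapter(read, cfg.adapter)
        if insert is REJECT:
            continue
        stats["trimmed"] += 1
        if filter_length(insert, cfg):
            stats["length_ok"] += 1
            kept.append(insert)
    unique = collapse(kept)
    filtered = filter_min_count(unique, cfg)
    stats["unique"] = len(unique)
    stats["unique_min_count"] = len(filtered)
    return filtered, stats


def _mean_quality(qualities: Sequence[int]) -> float:
    return sum(qualities) / len(qualities) if qualities else 0.0


def read_fastq(path, cfg: Optional[ReadFilterConfig] = None) -> List[str]:
    """Read raw sequences from FASTQ; optional mean-quality filter (default off)."""
    reads: List[str] = []
    threshold = cfg.min_mean_quality if cfg is not None else None
    for rec in SeqIO.parse(str(path), "fastq"):
        if threshold is not None:
            quals = rec.letter_annotations.get("phred_quality", [])
            if _mean_quality(quals) < threshold:
                continue
        reads.append(str(rec.seq).upper().replace("U", "T"))
    return reads


def preprocess_fastq(path, cfg: ReadFilterConfig) -> Tuple[List[UniqueRead], Dict[str, int]]:
    return preprocess_reads(read_fastq(path, cfg), cfg)


def write_collapsed_fasta(unique: Sequence[UniqueRead], handle: TextIO) -> None:
    """Write collapsed reads as FASTA with ``readN_xCOUNT`` headers."""
    for i, u in enumerate(unique, start=1):
        handle.write(f">read{i}_x{u.count}\n{u.sequence}\n")


def read_collapsed_fasta(path) -> List[UniqueRead]:
    out: List[UniqueRead] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        out.append(UniqueRead(str(rec.seq).upper().replace("U", "T"), count))
    return out
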