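"""Synthetic genomes, annotations and paired sRNA libraries with ground truth.

The generator emulates the statistical structure a Dicer-knockout sRNA-seq
comparison assumes:

* a Dicer-dependent read class — 21-nt-peaked lengths, 5'-uracil biased —
  emitted from planted hairpin (milRNA) loci and from both strands of
  planted double-stranded sRNA loci;
* a Dicer-independent degradation background from rRNA/tRNA/exon sense
  strands with flat 15–36 nt lengths and no 5'-nt bias; and
* a paired "dicer-null" library in which the Dicer-dependent class is
  depleted by a configurable factor (default 16).

Reads are emitted as FASTQ inserts with the 3' adapter appended, so the
full preprocessing contract (trimming, collapsing, count filtering) can be
exercised end to end.  Every template carries a class label in the ground
truth so parameter-recovery tests can score the pipeline against what was
planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, TextIO, Tuple

import numpy as np

from .read_prep import DEFAULT_ADAPTER
from .seq_io import Genome, AnnotationSet, Feature, reverse_complement


@dataclass
class SimulationConfig:
    seed: int = 1
    n_contigs: int = 2
    contig_len: int = 50000
    n_genes: int = 40
    n_trna: int = 8
    n_rrna: int = 4
    n_hairpin_milrna: int = 10
    n_dsrna_loci: int = 20
    n_target_sites: int = 5
    dicer_len_mode: int = 21
    dicer_len_p: float = 0.5          # geometric tail around the mode
    dicer_len_range: Tuple[int, int] = (17, 25)
    dicer_5u_prob: float = 0.65
    background_len_range: Tuple[int, int] = (15, 36)
    depletion_factor: float = 16.0
    dicer_depth: float = 100.0        # expected reads per mature template
    degradation_depth: float = 30.0   # expected reads per background template
    star_fraction: float = 0.05
    star_noise: float = 0.10          # fraction of star positions mutated
    mature_len: int = 21
    loop_range: Tuple[int, int] = (8, 20)
    dsrna_locus_len: int = 250
    adapter: str = DEFAULT_ADAPTER


@dataclass
class PlantedMilRNA:
    contig: str
    start: int          # precursor envelope, 0-based half-open
    end: int
    strand: str
    mature_seq: str
    star_seq: str
    precursor_seq: str


@dataclass
class PlantedLocus:
    contig: str
    start: int
    end: int
    kind: str           # "exon" or "intergenic"


@dataclass
class PlantedTargetSite:
    gene_id: str
    milrna_index: int
    utr_offset: int


@dataclass
class GroundTruth:
    milrnas: List[PlantedMilRNA] = field(default_factory=list)
    dsrna_loci: List[PlantedLocus] = field(default_factory=list)
    target_sites: List[PlantedTargetSite] = field(default_factory=list)
    read_classes: Dict[str, str] = field(default_factory=dict)  # sequence -> dicer|background


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _mutate(rng: np.random.Generator, seq: str, frac: float) -> str:
    out = list(seq)
    n_mut = int(round(frac * len(seq)))
    for i in rng.choice(len(seq), size=n_mut, replace=False):
        out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def simulate_genome(cfg: SimulationConfig = None) -> Tuple[Genome, AnnotationSet, GroundTruth]:
    """Random genome with genes (1–3 exons), tRNA/rRNA features, intergenic
    hairpin milRNA genes, planted dsRNA loci and planted UTR target sites."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    contig_names = [f"chr{i + 1}" for i in range(cfg.n_contigs)]
    contig_seqs = {name: list(_random_seq(rng, cfg.contig_len)) for name in contig_names}

    # --- sequential feature packing with random gaps
    features: List[Feature] = []
    gene_spans: Dict[str, Tuple[str, int, int, str]] = {}
    gene_exons: Dict[str, List[Tuple[str, int, int]]] = {}

    slots: List[Tuple[str, int]] = []  # (kind, approx length) to place
    slots += [("gene", 0)] * cfg.n_genes
    slots += [("tRNA", 75)] * cfg.n_trna
    slots += [("rRNA", 500)] * cfg.n_rrna
    slots += [("hairpin", 0)] * cfg.n_hairpin_milrna
    order = rng.permutation(len(slots))

    cursors = {name: int(rng.integers(100, 300)) for name in contig_names}
    gene_i = 0
    for idx in order:
        kind, flen = slots[idx]
        contig = contig_names[int(rng.integers(0, cfg.n_contigs))]
        pos = cursors[contig]
        if kind == "gene":
            gene_i += 1
            gid = f"gene{gene_i:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            n_exons = int(rng.integers(1, 4))
            exon_lens = [int(rng.integers(120, 300)) for _ in range(n_exons)]
            intron_lens = [int(rng.integers(60, 120)) for _ in range(n_exons - 1)]
            start = pos
            exons = []
            p = start
            for i, el in enumerate(exon_lens):
                exons.append((p, p + el))
                p += el
                if i < len(intron_lens):
                    p += intron_lens[i]
            end = p
            if end + 1100 > cfg.contig_len:
                raise ValueError("infeasible packing: genome too small for requested features")
            gene_spans[gid] = (contig, start, end, strand)
            gene_exons[gid] = [(contig, s, e) for s, e in exons]
            for s, e in exons:
                features.append(Feature(contig, s, e, strand, "exon", gid))
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                features.append(Feature(contig, e1, s2, strand, "intron", gid))
            pos = end
        elif kind in ("tRNA", "rRNA"):
            strand = "+" if rng.random() < 0.5 else "-"
            end = pos + flen
            if end > cfg.contig_len:
                raise ValueError("infeasible packing: genome too small for requested features")
            features.append(Feature(contig, pos, end, strand, kind, None))
            pos = end
        else:  # hairpin milRNA gene, intergenic
            mature = _random_seq(rng, cfg.mature_len)
            if rng.random() < cfg.dicer_5u_prob:
                mature = "T" + mature[1:]
            else:
                mature = "ACG"[int(rng.integers(0, 3))] + mature[1:]
            loop = _random_seq(rng, int(rng.integers(cfg.loop_range[0], cfg.loop_range[1] + 1)))
            star = _mutate(rng, reverse_complement(mature), cfg.star_noise)
            hairpin = mature + loop + star
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = hairpin if strand == "+" else reverse_complement(hairpin)
            end = pos + len(hairpin)
            if end > cfg.contig_len:
                raise ValueError("infeasible packing: genome too small for requested features")
            contig_seqs[contig][pos:end] = list(embedded)
            truth.milrnas.append(
                PlantedMilRNA(contig, pos, end, strand, mature, star, hairpin)
            )
            pos = end
        # spacing always exceeds the 300-bp locus chaining window so adjacent
        # features never merge into one locus
        cursors[contig] = pos + int(rng.integers(310, 600))
        if cursors[contig] + 1500 > cfg.contig_len:
            raise ValueError("infeasible packing: genome too small for requested features")

    # --- dsRNA loci: half on exons, half in intergenic gaps past the cursor
    exon_pool = [
        (contig, s, e) for exons in gene_exons.values() for contig, s, e in exons
        if e - s >= 150
    ]
    rng.shuffle(exon_pool)
    n_exonic = min(cfg.n_dsrna_loci // 2, len(exon_pool))
    for contig, s, e in exon_pool[:n_exonic]:
        L = min(cfg.dsrna_locus_len, e - s)
        truth.dsrna_loci.append(PlantedLocus(contig, s, s + L, "exon"))
    for _ in range(cfg.n_dsrna_loci - n_exonic):
        contig = contig_names[int(rng.integers(0, cfg.n_contigs))]
        pos = cursors[contig]
        end = pos + cfg.dsrna_locus_len
        if end + 200 > cfg.contig_len:
            raise ValueError("infeasible packing: no intergenic room for dsRNA loci")
        truth.dsrna_loci.append(PlantedLocus(contig, pos, end, "intergenic"))
        cursors[contig] = end + int(rng.integers(350, 600))

    # --- planted target sites: near-complement of a planted mature milRNA
    # written into the downstream 1 kb of a gene; two mismatches (milRNA
    # positions 10 and 15) keep the site invisible to the perfect-match mapper
    if truth.milrnas and cfg.n_target_sites > 0:
        protected = [(m.contig, m.start, m.end) for m in truth.milrnas]
        gene_ids = sorted(gene_spans)
        chosen = rng.choice(len(gene_ids), size=min(cfg.n_target_sites, len(gene_ids)),
                            replace=False)
        for gi in chosen:
            gid = gene_ids[int(gi)]
            contig, gs, ge, strand = gene_spans[gid]
            mi = int(rng.integers(0, len(truth.milrnas)))
            mature = truth.milrnas[mi].mature_seq
            site = list(reverse_complement(mature))
            for pos1 in (10, 15):  # 1-based milRNA positions, outside the animal seed
                site_idx = len(mature) - pos1
                base = site[site_idx]
                site[site_idx] = "ACGT"[("ACGT".index(base) + 2) % 4]
            site = "".join(site)
            offset = int(rng.integers(20, 900 - len(site)))
            if strand == "+":
                a = ge + offset
                piece = site
            else:
                a = gs - offset - len(site)
                piece = reverse_complement(site)
            if a < 0 or a + len(site) > cfg.contig_len:
                continue
            # never overwrite a planted hairpin
            if any(c == contig and a < e and s < a + len(site) for c, s, e in protected):
                continue
            contig_seqs[contig][a:a + len(site)] = list(piece)
            truth.target_sites.append(PlantedTargetSite(gid, mi, offset))

    genome = Genome({name: "".join(seq) for name, seq in contig_seqs.items()})
    features.sort(key=lambda f: (f.contig, f.start, f.end, f.kind))
    ann = AnnotationSet(features, gene_spans)
    return genome, ann, truth


# ---------------------------------------------------------------------------
# read templates and libraries

@dataclass
class _Template:
    sequence: str
    rate: float          # expected count in the Dicer-proficient library
    cls: str             # dicer | background
    dicer_class: bool


def _dicer_length(rng: np.random.Generator, cfg: SimulationConfig) -> int:
    lo, hi = cfg.dicer_len_range
    while True:
        offset = int(rng.geometric(cfg.dicer_len_p)) - 1
        if rng.random() < 0.5:
            offset = -offset
        length = cfg.dicer_len_mode + offset
        if lo <= length <= hi:
            return length


def _biased_start(rng: np.random.Generator, seq: str, lo: int, hi: int,
                  u_prob: float) -> int:
    """Start position with P(base == T) == u_prob within [lo, hi)."""
    t_pos = [i for i in range(lo, hi) if seq[i] == "T"]
    other = [i for i in range(lo, hi) if seq[i] != "T"]
    pool = t_pos if (t_pos and rng.random() < u_prob) else (other or t_pos)
    return int(pool[int(rng.integers(0, len(pool)))])


def build_templates(genome: Genome, ann: AnnotationSet, truth: GroundTruth,
                    cfg: SimulationConfig, rng: np.random.Generator) -> List[_Template]:
    templates: List[_Template] = []

    # Dicer class: hairpin mature/star arms
    for mil in truth.milrnas:
        prec = mil.precursor_seq
        mature_len = len(mil.mature_seq)
        lengths = {mature_len}
        while len(lengths) < 3:
            lengths.add(_dicer_length(rng, cfg))
        for L in sorted(lengths):
            seq = prec[:min(L, len(prec))]
            rate = cfg.dicer_depth if L == mature_len else cfg.dicer_depth / 4
            templates.append(_Template(seq, rate, "dicer", True))
        star_start = len(prec) - len(mil.star_seq)
        templates.append(
            _Template(prec[star_start:], cfg.star_fraction * cfg.dicer_depth, "dicer", True)
        )

    # Dicer class: double-stranded loci, both strands
    for locus in truth.dsrna_loci:
        seq = genome.contigs[locus.contig]
        for strand in "+-":
            for _ in range(6):
                L = _dicer_length(rng, cfg)
                if locus.end - locus.start <= L:
                    continue
                if strand == "+":
                    s = _biased_start(rng, seq, locus.start, locus.end - L, cfg.dicer_5u_prob)
                    frag = seq[s:s + L]
                else:
                    rc = reverse_complement(seq[locus.start:locus.end])
                    s = _biased_start(rng, rc, 0, len(rc) - L, cfg.dicer_5u_prob)
                    frag = rc[s:s + L]
                templates.append(_Template(frag, cfg.degradation_depth, "dicer", True))

    # background degradation: rRNA (8) / tRNA (4) templates per feature and
    # 2 per gene from exon sense strands; flat lengths, no 5' bias.  Two
    # templates per gene stay below the 4-unique-read locus threshold, so
    # Dicer-null loci arise from structural RNAs, not coding genes.
    lo, hi = cfg.background_len_range

    def add_background(src: str, n: int) -> None:
        for _ in range(n):
            L = int(rng.integers(lo, hi + 1))
            if len(src) <= L:
                continue
            s = int(rng.integers(0, len(src) - L))
            templates.append(_Template(src[s:s + L], cfg.degradation_depth, "background", False))

    per_kind = {"rRNA": 8, "tRNA": 4}
    exons_of_gene: Dict[str, List] = {}
    for f in ann.features:
        if f.kind in per_kind:
            add_background(genome.fetch(f.contig, f.start, f.end, f.strand), per_kind[f.kind])
        elif f.kind == "exon":
            exons_of_gene.setdefault(f.gene_id, []).append(f)
    for gid in sorted(exons_of_gene):
        exons = exons_of_gene[gid]
        for _ in range(2):
            f = exons[int(rng.integers(0, len(exons)))]
            add_background(genome.fetch(f.contig, f.start, f.end, f.strand), 1)

    for t in templates:
        truth.read_classes.setdefault(t.sequence, t.cls)
    return templates


def sample_library(templates: Sequence[_Template], cfg: SimulationConfig,
                   rng: np.random.Generator, depleted: bool) -> List[str]:
    """Poisson-sample reads per template; Dicer-class rates divided by the
    depletion factor in the null library."""
    reads: List[str] = []
    for t in templates:
        rate = t.rate / cfg.depletion_factor if (depleted and t.dicer_class) else t.rate
        n = int(rng.poisson(rate))
        reads.extend([t.sequence] * n)
    perm = rng.permutation(len(reads))
    return [reads[i] for i in perm]


def write_fastq(reads: Sequence[str], handle: TextIO, prefix: str, adapter: str) -> None:
    for i, seq in enumerate(reads):
        full = seq + adapter
        handle.write(f"@{prefix}_{i:06d}\n{full}\n+\n{'I' * len(full)}\n")


def simulate_libraries(genome: Genome, ann: AnnotationSet, truth: GroundTruth,
                       cfg: SimulationConfig = None,
                       rng: Optional[np.random.Generator] = None,
                       ) -> Tuple[List[str], List[str], Dict[str, str]]:
    """(wt reads, dicer-null reads, template class labels), raw inserts."""
    cfg = cfg or SimulationConfig()
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    templates = build_templates(genome, ann, truth, cfg, rng)
    wt = sample_library(templates, cfg, rng, depleted=False)
    null = sample_library(templates, cfg, rng, depleted=True)
    return wt, null, dict(truth.read_classes)


def write_genome_fasta(genome: Genome, handle: TextIO) -> None:
    for name, seq in genome.contigs.items():
        handle.write(f">{name}\n")
        for i in range(0, len(seq), 70):
            handle.write(seq[i:i + 70] + "\n")


def write_annotation_gff3(ann: AnnotationSet, handle: TextIO) -> None:
    handle.write("##gff-version 3\n")
    for gid in sorted(ann.gene_spans):
        contig, s, e, strand = ann.gene_spans[gid]
        handle.write(f"{contig}\tsim\tgene\t{s + 1}\t{e}\t.\t{strand}\t.\tID={gid}\n")
    n = 0
    for f in ann.features:
        if f.kind == "exon":
            handle.write(
                f"{f.contig}\tsim\texon\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.gene_id}.e{f.start}ue;Parent={f.gene_id}\n"
            )
        elif f.kind in ("tRNA", "rRNA"):
            n += 1
            handle.write(
                f"{f.contig}\tsim\t{f.kind}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t"
                f"ID={f.kind}{n}\n"
            )
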