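import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from milscan.read_prep import ReadFilterConfig, preprocess_reads
from milscan.exact_mapper import map_library
from milscan.locus_caller import call_loci, classify_locus, compare_loci
from milscan.synthetic_data import SimulationConfig, simulate_genome, simulate_libraries


class SimBundle:
    """One full simulated experiment shared across the suite."""

    def __init__(self, seed: int = 1):
        self.cfg = SimulationConfig(seed=seed)
        self.genome, self.ann, self.truth = simulate_genome(self.cfg)
        wt, null, self.labels = simulate_libraries(self.genome, self.ann, self.truth, self.cfg)
        self.raw_wt, self.raw_null = wt, null
        read_cfg = ReadFilterConfig()
        self.unique_wt, self.stats_wt = preprocess_reads(
            [r + self.cfg.adapter for r in wt], read_cfg)
        self.unique_null, self.stats_null = preprocess_reads(
            [r + self.cfg.adapter for r in null], read_cfg)
        self.lib_wt = map_library(self.unique_wt, self.genome)
        self.lib_null = map_library(self.unique_null, self.genome)
        self.loci_wt = call_loci(self.lib_wt.alignments)
        self.loci_null = call_loci(self.lib_null.alignments)
        for locus in self.loci_wt + self.loci_null:
            classify_locus(locus, self.ann)
        self.dicer_calls = compare_loci(self.loci_wt, self.loci_null)


@pytest.fixture(scope="session")
def sim():
    return SimBundle(seed=1)


@pytest.fixture(scope="session")
def tiny_genome_files(tmp_path_factory):
    """A hand-written 2-contig genome + GFF3 annotation."""
    d = tmp_path_factory.mktemp("tiny")
    fasta = d / "genome.fasta"
    # chrA: 100 bp, chrB: 60 bp
    chra = (
        "ACGTACGTAC" "GTACGTACGT" "TTTTTTTTTT" "GGGGGGGGGG"
        "ACGTACGTAC" "CCCCCCCCCC" "ATATATATAT" "GCGCGCGCGC"
        "ACGTACGTAC" "TTTTGGGGCC"
    )
    chrb = "A" * 30 + "C" * 30
    fasta.write_text(f">chrA\n{chra}\n>chrB\n{chrb}\n")
    gff = d / "ann.gff3"
    gff.write_text(
        "##gff-version 3\n"
        # gene1 on +: exons [11,20] and [31,40] (1-based) -> intron [21,30]
        "chrA\tt\tgene\t11\t40\t.\t+\t.\tID=gene1\n"
        "chrA\tt\texon\t11\t20\t.\t+\t.\tID=gene1.e1;Parent=gene1\n"
        "chrA\tt\texon\t31\t40\t.\t+\t.\tID=gene1.e2;Parent=gene1\n"
        # gene2 on -: single exon [51,60]
        "chrA\tt\tgene\t51\t60\t.\t-\t.\tID=gene2\n"
        "chrA\tt\texon\t51\t60\t.\t-\t.\tID=gene2.e1;Parent=gene2\n"
        # tRNA at [66,75] on +, rRNA on chrB [11,30] on -
        "chrA\tt\ttRNA\t66\t75\t.\t+\t.\tID=trna1\n"
        "chrB\tt\trRNA\t11\t30\t.\t-\t.\tID=rrna1\n"
    )
    return fasta, gff


@pytest.fixture(scope="session")
def tiny(tiny_genome_files):
    from milscan.seq_io import load_annotation, load_genome

    fasta, gff = tiny_genome_files
    genome = load_genome(fasta)
    ann = load_annotation(gff, genome)
    return genome, ann
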