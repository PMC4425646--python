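import math
import random
import shutil
import subprocess
from functools import lru_cache

import pytest

from milscan.exact_mapper import Alignment, MappedLibrary, map_library
from milscan.milrna_discovery import (
    HairpinStructure, MilConfig, MilRNACandidate, count_genomic_occurrences,
    excise_candidates, fold, merge_predictions, precursor_length,
    predict_milrnas, score_candidate, PrecursorWindow,
)
from milscan.read_prep import UniqueRead, collapse
from milscan.seq_io import Genome, reverse_complement


def nussinov_oracle_score(seq: str, min_loop: int = 3) -> int:
    """Independent recursive maximum-pairing score (WC=2, G:U=1)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    s = [code[c] for c in seq.upper()]

    def ps(a, b):
        if (a, b) in ((0, 3), (3, 0), (2, 1), (1, 2)):
            return 2
        if (a, b) in ((2, 3), (3, 2)):
            return 1
        return 0

    @lru_cache(maxsize=None)
    def best(i, j):
        if j <= i:
            return 0
        value = best(i, j - 1)
        for k in range(i, j):
            if j - k > min_loop and ps(s[k], s[j]) > 0:
                left = best(i, k - 1) if k > i else 0
                value = max(value, left + ps(s[k], s[j]) + best(k + 1, j - 1))
        return value

    return best(0, len(s) - 1)


class TestFold:
    def test_perfect_stem(self):
        st = fold("GGGGAAAACCCC")
        assert st.dot_bracket == "((((....))))"
        assert len(st.pairs) == 4

    def test_no_complementarity(self):
        assert fold("A" * 21).pairs == frozenset()

    def test_energy_score_counts_stacked_wc(self):
        st = fold("GGGGAAAACCCC")
        # three of the four WC pairs sit on another pair
        assert st.energy_score == -(2 * 3 + 1 * 1)

    def test_pairs_respect_min_loop_and_nesting(self):
        rng = random.Random(1)
        cfg = MilConfig()
        for _ in range(50):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(15, 40)))
            st = fold(seq, cfg)
            pairs = sorted(st.pairs)
            for i, j in pairs:
                assert j - i > cfg.min_loop
            for (i1, j1) in pairs:
                for (i2, j2) in pairs:
                    if i1 < i2:  # nested or disjoint, never crossing
                        assert j2 < j1 or i2 > j1

    def test_matches_recursive_oracle(self):
        rng = random.Random(11)
        for _ in range(100):
            seq = "".join(rng.choice("ACGU") for _ in range(rng.randint(10, 30)))
            assert fold(seq).pair_score == nussinov_oracle_score(seq)

    def test_length_bounds(self):
        with pytest.raises(ValueError):
            fold("ACGU")
        with pytest.raises(ValueError):
            fold("ACGU" * 60)

    def test_designed_stem_agrees_with_rnafold(self, tmp_path):
        """External oracle: ViennaRNA folds a designed perfect stem identically."""
        rnafold = shutil.which("RNAfold")
        assert rnafold, "RNAfold expected on PATH"
        seq = "GGGCGGGCAUAAAAAUGCCCGCCC"
        out = subprocess.run([rnafold, "--noPS"], input=seq, text=True,
                             capture_output=True, check=True).stdout
        vienna_db = out.splitlines()[1].split()[0]
        assert fold(seq).dot_bracket == vienna_db


class TestExcision:
    def _stack(self, start, end, strand="+", count=50):
        return Alignment("c", start, strand, UniqueRead("T" * (end - start), count))

    def test_window_arithmetic(self):
        genome = Genome({"c": "A" * 1200})
        wins = excise_candidates(self._stack(1000, 1021), genome)
        assert [(w.gstart, w.gend) for w in wins] == [(930, 1041), (980, 1091)]

    def test_clipped_at_contig_start(self):
        genome = Genome({"c": "A" * 300})
        wins = excise_candidates(self._stack(5, 26), genome)
        assert wins[0].gstart == 0 and wins[0].gend == 46

    def test_minus_strand_mirrored(self):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(1200))
        genome = Genome({"c": seq})
        plus = excise_candidates(self._stack(1000, 1021, "+"), genome)
        minus = excise_candidates(self._stack(1000, 1021, "-"), genome)
        assert [(w.gstart, w.gend) for w in minus] == [(980, 1091), (930, 1041)]
        assert minus[1].sequence == reverse_complement(seq[930:1041])
        # the mature sits 70 nt into its "upstream-extended" window on either strand
        assert plus[0].to_window_coords(1000, 1021) == (70, 91)
        assert minus[0].to_window_coords(1000, 1021) == (70, 91)


def build_hairpin_case(count=100, star_count=10, extra=()):
    """A perfect synthetic hairpin embedded in flanking sequence, with reads."""
    rng = random.Random(17)
    mature = "T" + "".join(rng.choice("ACGT") for _ in range(20))
    loop = "TCTCGAATTCAG"
    hairpin = mature + loop + reverse_complement(mature)
    left = "".join(rng.choice("ACGT") for _ in range(70))
    right = "".join(rng.choice("ACGT") for _ in range(40))
    seq = left + hairpin + right
    genome = Genome({"c": seq})
    m0 = len(left)
    mature_read = Alignment("c", m0, "+", UniqueRead(mature, count))
    reads = [mature_read]
    if star_count:
        s0 = m0 + len(mature) + len(loop)
        reads.append(Alignment("c", s0, "+",
                               UniqueRead(seq[s0:s0 + len(mature)], star_count)))
    reads.extend(extra)
    window = PrecursorWindow("c", m0 - 20, m0 + len(mature) + 70, "+",
                             seq[m0 - 20:m0 + len(mature) + 70])
    return genome, window, mature_read, reads


class TestScoreCandidate:
    def test_perfect_hairpin_accepted_and_scored(self):
        _genome, window, mature, reads = build_hairpin_case()
        cand = score_candidate(window, mature, reads)
        assert cand is not None
        expected = (10 * cand.signature_frac + 10 * cand.paired_frac
                    + 5 + math.log2(1 + 100))
        assert cand.score == pytest.approx(expected)
        assert cand.score >= 20
        assert cand.star_reads >= 1
        assert cand.mature_seq == mature.read.sequence

    def test_low_signature_rejected_before_scoring(self):
        # scattered reads outside mature/star/loop dominate the window
        noise = [
            Alignment("c", 128 + 5 * i, "+", UniqueRead("ACGTACGTACGTACGTA", 40))
            for i in range(3)
        ]
        _genome, window, mature, reads = build_hairpin_case(extra=noise)
        assert score_candidate(window, mature, reads) is None

    def test_no_duplex_rejected(self):
        rng = random.Random(23)
        seq = "".join(rng.choice("AC") for _ in range(160))  # AC-only: no pairing
        window = PrecursorWindow("c", 0, 160, "+", seq)
        mature = Alignment("c", 70, "+", UniqueRead(seq[70:91], 100))
        assert score_candidate(window, mature, [mature]) is None

    def test_score_monotone_in_mature_count(self):
        scores = []
        for count in (10, 40, 160, 640):
            _g, window, mature, reads = build_hairpin_case(count=count)
            cand = score_candidate(window, mature, reads)
            assert cand is not None
            scores.append(cand.score)
        assert scores == sorted(scores)

    def test_star_reads_bonus(self):
        _g, window, mature, reads = build_hairpin_case(star_count=10)
        with_star = score_candidate(window, mature, reads)
        _g, window, mature, reads = build_hairpin_case(star_count=0)
        without = score_candidate(window, mature, reads)
        assert with_star.score == pytest.approx(without.score + 5)


class TestPredict:
    def test_planted_hairpins_recovered(self, sim):
        cands = predict_milrnas(sim.lib_wt, sim.genome, sim.ann)

        def overlaps(c, p):
            return (c.contig == p.contig and c.strand == p.strand
                    and c.start < p.end and p.start < c.end)

        recall = sum(
            any(overlaps(c, p) for c in cands) for p in sim.truth.milrnas
        ) / len(sim.truth.milrnas)
        precision = sum(
            any(overlaps(c, p) for p in sim.truth.milrnas) for c in cands
        ) / max(1, len(cands))
        assert recall >= 0.8
        assert precision >= 0.8

    def test_recovered_5u_fraction_tracks_planted_bias(self, sim):
        cands = predict_milrnas(sim.lib_wt, sim.genome, sim.ann)
        planted = {(p.contig, p.strand) for p in sim.truth.milrnas}
        u_frac = sum(c.first_nt == "U" for c in cands) / len(cands)
        planted_frac = sum(p.mature_seq[0] == "T" for p in sim.truth.milrnas) / len(sim.truth.milrnas)
        assert abs(u_frac - planted_frac) <= 0.25  # 10 planted genes: coarse check

    def test_shuffled_reads_yield_nothing(self, sim):
        rng = random.Random(99)
        shuffled = []
        for u in sim.unique_wt:
            letters = list(u.sequence)
            rng.shuffle(letters)
            shuffled.append(UniqueRead("".join(letters), u.count))
        lib = map_library(collapse([s.sequence for s in shuffled for _ in range(s.count)]),
                          sim.genome)
        assert predict_milrnas(lib, sim.genome, sim.ann) == []

    def test_no_qualifying_stack_gives_empty(self, sim):
        low = [UniqueRead(u.sequence, 1) for u in sim.unique_wt[:50]]
        lib = map_library(low, sim.genome)
        assert predict_milrnas(lib, sim.genome, sim.ann) == []

    def test_structural_stacks_never_seed(self, sim):
        cands = predict_milrnas(sim.lib_wt, sim.genome, sim.ann)
        for c in cands:
            hits = sim.ann.features_overlapping(c.contig, c.start, c.end,
                                                kinds=("tRNA", "rRNA"))
            assert not hits


def make_candidate(contig, start, end, score=25.0, strand="+"):
    st = HairpinStructure("A" * (end - start), frozenset(), "." * (end - start), 0.0)
    return MilRNACandidate(contig, start, end, strand, "A" * (end - start),
                           "A" * 21, "A" * 21, st, score, 1.0, 0.9, 1, 50)


class TestMerge:
    def test_shared_candidates_counted_once(self):
        a = [make_candidate("c", 100 * i, 100 * i + 60) for i in range(20)]
        b = [make_candidate("c", 100 * i, 100 * i + 60, score=30.0) for i in range(8)]
        b += [make_candidate("c", 5000 + 100 * i, 5000 + 100 * i + 60) for i in range(14)]
        merged, shared = merge_predictions(a, b)
        assert shared == 8
        assert len(merged) == 20 + 22 - 8 == 34

    def test_disjoint_sets_concatenate(self):
        a = [make_candidate("c", 100 * i, 100 * i + 60) for i in range(3)]
        b = [make_candidate("c", 9000 + 100 * i, 9000 + 100 * i + 60) for i in range(4)]
        merged, shared = merge_predictions(a, b)
        assert (len(merged), shared) == (7, 0)

    def test_identical_sets_collapse(self):
        a = [make_candidate("c", 100 * i, 100 * i + 60) for i in range(5)]
        merged, shared = merge_predictions(a, list(a))
        assert (len(merged), shared) == (5, 5)


class TestPrecursorLength:
    @pytest.mark.parametrize("loc,expected", [
        ("ChrI: 4059417–4059459", 43),
        ("ChrII: rev(3651114–3651202)", 89),
        ("ChrI: 11548223–11548283", 61),
        ((100, 100), 1),
    ])
    def test_examples(self, loc, expected):
        assert precursor_length(loc) == expected

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            precursor_length((10, 5))


class TestGenomicOccurrences:
    def test_planted_copies_counted(self):
        rng = random.Random(31)
        unit = "".join(rng.choice("ACGT") for _ in range(30))
        filler = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        genome = Genome({"c": filler(50) + unit + filler(60) + unit
                              + filler(40) + reverse_complement(unit) + filler(30)})
        assert count_genomic_occurrences(unit, genome) == 3

    def test_absent_sequence(self):
        genome = Genome({"c": "ACGT" * 30})
        assert count_genomic_occurrences("TTTTTTTTTTTTTTT", genome) == 0

    def test_unique_sequence(self):
        rng = random.Random(37)
        seq = "".join(rng.choice("ACGT") for _ in range(400))
        genome = Genome({"c": seq})
        assert count_genomic_occurrences(seq[100:121], genome) == 1
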