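"""Hairpin-based milRNA discovery on a simulated library.

High-count read stacks outside structural RNAs seed two excised precursor
windows each; windows are folded with the maximum-pairing engine and scored
on their read signature (mature / star / loop coverage), mature-arm pairing
and duplex quality.  Candidates scoring >= 20 are reported with their
precursor location and fold.
"""

from milscan import (
    MilConfig, ReadFilterConfig, SimulationConfig, count_genomic_occurrences,
    map_library, predict_milrnas, preprocess_reads, simulate_genome,
    simulate_libraries,
)

cfg = SimulationConfig(seed=1)
genome, annotation, truth = simulate_genome(cfg)
wt_reads, _null, _labels = simulate_libraries(genome, annotation, truth, cfg)
unique, _ = preprocess_reads([r + cfg.adapter for r in wt_reads], ReadFilterConfig())
lib = map_library(unique, genome)

candidates = predict_milrnas(lib, genome, annotation, MilConfig())
print(f"{len(candidates)} milRNA candidates (simulator planted {len(truth.milrnas)}):\n")
for i, c in enumerate(candidates, start=1):
    copies = count_genomic_occurrences(c.precursor_seq, genome)
    print(f"milR-{i:<3} {c.mature_seq.replace('T', 'U').lower()}  "
          f"score={c.score:5.1f}  5'{c.first_nt}  "
          f"precursor {c.precursor_length} nt @ {c.location}  copies={copies}")
print("\nfold of the first candidate precursor:")
print(candidates[0].precursor_seq)
print(candidates[0].structure.dot_bracket)
# score = 10*signature + 10*paired + 5*[star reads] + log2(1 + mature count);
# the energy_score is a pairing score (WC-rich stacked stems score lower/better).
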