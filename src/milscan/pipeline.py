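"""End-to-end orchestration: preprocess → map → annotate → loci →
differential → milRNAs → targets, with TSV reports and a run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from . import __version__
from .read_prep import ReadFilterConfig, preprocess_fastq, write_collapsed_fasta
from .exact_mapper import MappedLibrary, build_index, map_library, write_sam_tsv
from .feature_annotation import tabulate, write_category_table
from .locus_caller import (
    LocusConfig, call_loci, classify_locus, compare_loci, dependent_counts,
    summarize, write_bed, write_summary_table,
)
from .dicer_differential import (
    DifferentialConfig, count_dicer_dependent, differential_table,
    normalize_tptm, write_differential_table,
)
from .milrna_discovery import MilConfig, predict_milrnas, merge_predictions, write_milrna_table
from .target_prediction import (
    TargetConfig, extract_utrs, predict_targets, write_target_table, write_utr_fasta,
)
from .seq_io import load_annotation, load_genome


@dataclass
class PipelineConfig:
    genome: str = ""
    annotation: str = ""
    libraries: Dict[str, str] = field(default_factory=dict)  # name -> FASTQ path
    wt_library: str = ""      # Dicer-proficient library name
    null_library: str = ""    # Dicer-deficient library name
    outdir: str = "milscan_out"
    reads: ReadFilterConfig = field(default_factory=ReadFilterConfig)
    loci: LocusConfig = field(default_factory=LocusConfig)
    differential: DifferentialConfig = field(default_factory=DifferentialConfig)
    milrna: MilConfig = field(default_factory=MilConfig)
    targets: TargetConfig = field(default_factory=TargetConfig)
    utr_length: int = 1000
    seed_k: int = 12

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        def unyaml(key):
            # YAML parses bare null/true/false scalars; "null" is a perfectly
            # good library name here, so map them back to strings
            if key is None:
                return "null"
            if isinstance(key, bool):
                return "true" if key else "false"
            return key

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw = {unyaml(k): v for k, v in raw.items()}
        if isinstance(raw.get("libraries"), dict):
            raw["libraries"] = {unyaml(k): v for k, v in raw["libraries"].items()}
        for field_name in ("wt_library", "null_library"):
            if field_name in raw:
                raw[field_name] = unyaml(raw[field_name])
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config field {key!r}")
            current = getattr(cfg, key)
            if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
                for k2, v2 in value.items():
                    if k2 not in current.__dataclass_fields__:
                        raise ValueError(f"unknown config field {key}.{k2}")
                    setattr(current, k2, v2)
            else:
                setattr(cfg, key, value)
        return cfg

    def validate(self) -> None:
        for label, path in [("genome", self.genome), ("annotation", self.annotation),
                            *[(f"libraries.{n}", p) for n, p in self.libraries.items()]]:
            if not path:
                raise ValueError(f"config error: missing path for field {label!r}")
            if not Path(path).exists():
                raise ValueError(f"config error: {label!r} path does not exist: {path}")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class PipelineResult:
    libraries: Dict[str, MappedLibrary]
    loci: Dict[str, list]
    dicer_calls: Optional[list]
    differential: Optional[list]
    milrnas: Dict[str, list]
    merged_milrnas: list
    targets: list
    outdir: Path


def run_all(cfg: PipelineConfig, log=print) -> PipelineResult:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = load_genome(cfg.genome)
    ann = load_annotation(cfg.annotation, genome)
    index = build_index(genome, cfg.seed_k)
    log(f"[milscan] genome: {len(genome.contigs)} contigs, {genome.total_length} bp")

    libs: Dict[str, MappedLibrary] = {}
    loci: Dict[str, list] = {}
    norms: Dict[str, dict] = {}
    for name, path in cfg.libraries.items():
        unique, stats = preprocess_fastq(path, cfg.reads)
        log(f"[milscan] {name}: " + ", ".join(f"{k}={v}" for k, v in stats.items()))
        lib = map_library(unique, genome, index=index)
        log(f"[milscan] {name}: mapped_unique={lib.mapped_unique} mapped_total={lib.mapped_total}")
        libs[name] = lib

        with open(outdir / f"{name}.collapsed.fasta", "w") as fh:
            write_collapsed_fasta(unique, fh)
        with open(outdir / f"{name}.alignments.tsv", "w") as fh:
            write_sam_tsv(lib, fh)
        counts = tabulate(lib, ann)
        with open(outdir / f"{name}.categories.tsv", "w") as fh:
            write_category_table(counts, lib, fh)

        lib_loci = call_loci(lib.alignments, cfg.loci)
        for locus in lib_loci:
            classify_locus(locus, ann)
        loci[name] = lib_loci
        log(f"[milscan] {name}: {len(lib_loci)} sRNA-producing loci")
        with open(outdir / f"{name}.loci.bed", "w") as fh:
            write_bed(lib_loci, fh)
        norms[name] = normalize_tptm(lib, ann, cfg.differential)

    with open(outdir / "locus_summary.tsv", "w") as fh:
        write_summary_table({n: summarize(l) for n, l in loci.items()}, fh)

    dicer_calls = diff_calls = None
    if cfg.wt_library and cfg.null_library:
        dicer_calls = compare_loci(loci[cfg.wt_library], loci[cfg.null_library])
        both, single, total = dependent_counts(dicer_calls)
        log(f"[milscan] dicer-dependent loci: both={both} single={single} total={total}")
        diff_calls = differential_table(norms[cfg.wt_library], norms[cfg.null_library],
                                        cfg.differential)
        n_abs, n_str, n_sli, n_tot = count_dicer_dependent(diff_calls)
        log(f"[milscan] dicer-dependent unique reads: absent={n_abs} strong={n_str} "
            f"slight={n_sli} total={n_tot}")
        with open(outdir / "differential.tsv", "w") as fh:
            write_differential_table(diff_calls, fh)

    milrnas: Dict[str, list] = {}
    for name in ([cfg.wt_library] if cfg.wt_library else list(cfg.libraries)):
        if not name:
            continue
        cands = predict_milrnas(libs[name], genome, ann, cfg.milrna)
        for c in cands:
            for lname, norm in norms.items():
                rec = norm.get(c.mature_seq)
                c.tptm_per_library[lname] = rec.tptm if rec else 0.0
        milrnas[name] = cands
        log(f"[milscan] {name}: {len(cands)} milRNA candidates")

    names = list(milrnas)
    if len(names) >= 2:
        merged, shared = merge_predictions(milrnas[names[0]], milrnas[names[1]])
        log(f"[milscan] merged milRNAs: {len(merged)} ({shared} shared)")
    else:
        merged = list(milrnas[names[0]]) if names else []
    with open(outdir / "milrnas.tsv", "w") as fh:
        write_milrna_table(merged, fh, library_names=list(cfg.libraries))

    utrs = extract_utrs(ann, genome, cfg.utr_length)
    with open(outdir / "utrs.fasta", "w") as fh:
        write_utr_fasta(utrs, fh)
    mil_specs = [(f"milR-{i+1}", c.mature_seq, c.star_seq) for i, c in enumerate(merged)]
    targets = predict_targets(mil_specs, utrs, cfg.targets)
    log(f"[milscan] target sites: {len(targets)}")
    with open(outdir / "targets.tsv", "w") as fh:
        write_target_table(targets, fh)

    manifest = {
        "version": __version__,
        "parameters": {
            "reads": asdict(cfg.reads), "loci": asdict(cfg.loci),
            "differential": asdict(cfg.differential), "milrna": asdict(cfg.milrna),
            "targets": asdict(cfg.targets), "utr_length": cfg.utr_length,
            "seed_k": cfg.seed_k,
        },
        "inputs": {
            "genome": _sha256(cfg.genome),
            "annotation": _sha256(cfg.annotation),
            **{n: _sha256(p) for n, p in cfg.libraries.items()},
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(libs, loci, dicer_calls, diff_calls, milrnas, merged,
                          targets, outdir)
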