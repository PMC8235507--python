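"""End-to-end orchestration: QC -> align -> classify -> summarize.

`run_pipeline` chains the library stages over files on disk, producing a
filtered FASTQ, a segment-chain TSV, a calls TSV, a summary JSON and a log.
Outputs are deterministic for identical inputs and configuration; partial
outputs are removed if a stage fails.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .align import AlignParams, chains_to_tsv
from .classify import ClassifyParams, calls_to_tsv, classify_population
from .qc import QCParams, filter_reads
from .reference import ReferenceGenome, build_reference, load_reference, write_reference
from .simulate import (SimRead, load_reads, simulate_canonical, simulate_gdm,
                       simulate_icg, simulate_other, simulate_snapback,
                       write_fastq, write_metadata_tsv, write_truth_tsv)
from .stats import summarize_population

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reads: str | Path
    reference_fasta: str | Path
    features: str | Path
    out_dir: str | Path
    metadata: str | Path | None = None
    qc: QCParams = field(default_factory=QCParams)
    align: AlignParams = field(default_factory=AlignParams)
    classify: ClassifyParams = field(default_factory=ClassifyParams)
    n_bins: int = 20
    seed: int = 0
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, typ in (("qc", QCParams), ("align", AlignParams),
                         ("classify", ClassifyParams)):
            if key in raw and isinstance(raw[key], dict):
                sub = dict(raw[key])
                if key == "qc" and "length_bins" in sub:
                    sub["length_bins"] = tuple(tuple(b) for b in sub["length_bins"])
                raw[key] = typ(**sub)
        return cls(**raw)


@dataclass
class PipelineResult:
    summary: object
    calls: list
    paths: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run QC, segmentation, classification and summary over a read set."""
    for p in (config.reads, config.reference_fasta, config.features):
        if not Path(p).exists():
            raise FileNotFoundError(f"missing input: {p}")
    if config.metadata is not None and not Path(config.metadata).exists():
        raise FileNotFoundError(f"missing input: {config.metadata}")

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "filtered_fastq": out / "filtered.fastq",
        "chains_tsv": out / "chains.tsv",
        "calls_tsv": out / "calls.tsv",
        "summary_json": out / "summary.json",
        "log": out / "pipeline.log",
    }
    handler = logging.FileHandler(paths["log"], mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("aavsnap")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.verbosity.upper(), logging.INFO))
    try:
        ref = load_reference(config.reference_fasta, config.features)
        reads = load_reads(config.reads, config.metadata)
        log.info("loaded %d reads against a %d nt reference", len(reads), ref.length)

        kept = filter_reads(reads, config.qc)
        write_fastq(kept, paths["filtered_fastq"])

        calls, chains = classify_population(kept, ref, config.align,
                                            config.classify, return_chains=True)
        chains_to_tsv(chains, paths["chains_tsv"], seed=config.seed)
        calls_to_tsv(calls, paths["calls_tsv"], seed=config.seed)

        summary = summarize_population(calls, ref=ref, n_bins=config.n_bins)
        summary.to_json(paths["summary_json"], seed=config.seed)
        log.info("classified %d reads: %s", len(calls), summary.counts)
        return PipelineResult(summary=summary, calls=calls,
                              paths={k: str(v) for k, v in paths.items()})
    except Exception:
        for p in paths.values():
            if p != paths["log"]:
                Path(p).unlink(missing_ok=True)
        raise
    finally:
        handler.close()
        root.removeHandler(handler)


def make_fixtures(seed: int = 0, out_dir=None, ref: ReferenceGenome | None = None):
    """A small deterministic error-free population covering every configuration.

    One read per (category, subtype, strand) combination plus ten canonical
    reads; regeneration with the same seed is byte-identical.
    """
    ref = ref or build_reference()
    rng = np.random.default_rng(seed)
    L = ref.length
    reads: list[SimRead] = []

    def add(read):
        read.id = f"fix_{len(reads):03d}"
        reads.append(read)

    for strand in "+-":
        add(simulate_canonical(ref, strand))
    for side, cat in ((5, "SBG_5"), (3, "SBG_3")):
        for subtype, (a, b) in (("SYMMETRIC", (800, 800)), ("ASYMMETRIC", (1200, 700))):
            for strand in "+-":
                add(simulate_snapback(ref, side, a, b, strand))
    for strand in "+-":
        add(simulate_icg(ref, breakpoint=2000, strand=strand))
    for strand in "+-":
        add(simulate_gdm(ref, 1000, 3500, strand))
    add(simulate_other(np.random.default_rng(seed + 1), 1500))
    for i in range(10):
        add(simulate_canonical(ref, "+" if i % 2 == 0 else "-"))

    for r in reads:
        r.n_passes = 10
        r.predicted_accuracy = 0.999

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_reference(ref, out / "reference.fasta", out / "features.tsv")
        write_fastq(reads, out / "fixtures.fastq")
        write_truth_tsv(reads, out / "fixtures.truth.tsv", seed=seed)
        write_metadata_tsv(reads, out / "fixtures.meta.tsv", seed=seed)
    return reads, ref
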