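"""Synthetic single-virion read populations with known truth labels.

Emulates the mixture of genome configurations seen in wild-type AAV virion
populations sequenced as single molecules:

* CANONICAL — the full genome, plus or minus strand packaged 50/50;
* SBG_5 / SBG_3 — snapback genomes: the covalent single strand of a fold-back
  molecule, ``arm ++ revcomp(arm)``, anchored at the left (5') or right (3')
  genome terminus. Near-equal arms are symmetric (sSBG); unequal arms leave a
  single-stranded loop (aSBG), modeled purely as arm-length inequality;
* ICG — incomplete genomes: an intact terminal ITR plus partial coding
  sequence that never reaches the opposite ITR (aborted packaging);
* GDM — genome deletion mutants: both ITRs retained, an internal region lost;
* OTHER — uniform-random DNA standing in for host/helper-derived particles.

Residual consensus-read errors are applied per base (substitution, insertion,
deletion); rates default to the small residuals expected after a >= 0.99
predicted-accuracy consensus gate.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._io import write_tsv
from ._seq import revcomp
from .errors import InvalidParameterError
from .reference import ReferenceGenome

CATEGORIES = ("CANONICAL", "SBG_5", "SBG_3", "ICG", "GDM", "OTHER")
SUBTYPES = ("SYMMETRIC", "ASYMMETRIC", "NONE")

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class TruthRecord:
    category: str
    subtype: str = "NONE"
    strand: str = "+"
    arm_a: int | None = None
    arm_b: int | None = None
    breakpoint: int | None = None
    del_start: int | None = None
    del_end: int | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidParameterError(f"unknown category {self.category!r}")
        if self.subtype not in SUBTYPES:
            raise InvalidParameterError(f"unknown subtype {self.subtype!r}")
        if self.del_start is not None and (
                self.del_end is None or not self.del_start < self.del_end):
            raise InvalidParameterError("need del_start < del_end")


@dataclass
class SimRead:
    """One simulated HiFi-like read with consensus metadata and truth label."""

    id: str
    seq: str
    n_passes: int = 10
    predicted_accuracy: float = 0.999
    truth: TruthRecord | None = None

    def __post_init__(self):
        if not self.seq:
            raise InvalidParameterError(f"read {self.id}: empty sequence")
        if not 0.0 <= self.predicted_accuracy <= 1.0:
            raise InvalidParameterError(
                f"read {self.id}: predicted_accuracy must be in [0,1]")

    def __len__(self):
        return len(self.seq)


@dataclass(frozen=True)
class SimulationConfig:
    """Population mixture and error model.

    Proportions must sum to 1. The default arm/deletion/breakpoint margins keep
    every configuration comfortably resolvable (arms >= 300 nt, deletions
    >= 200 nt, breakpoints >= 200 nt clear of the ITRs).
    """

    n_reads: int = 1000
    proportions: tuple[tuple[str, float], ...] = (
        ("CANONICAL", 0.40), ("SBG_5", 0.15), ("SBG_3", 0.10),
        ("ICG", 0.20), ("GDM", 0.10), ("OTHER", 0.05),
    )
    sub_rate: float = 0.003
    ins_rate: float = 0.001
    del_rate: float = 0.001
    arm_min: int = 300
    arm_max: int = 2300
    symmetric_fraction: float = 0.5   # of SBGs
    sym_delta_max: int = 50           # |arm_a - arm_b| draw range for sSBG
    loop_mean: float = 300.0          # geometric mean loop length for aSBG
    sym_tol: int = 100                # truth-labeling threshold on |arm_a - arm_b|
    breakpoint_margin: int = 200      # ICG breakpoint clearance beyond the ITRs
    del_margin: int = 200             # GDM deletion clearance beyond the ITRs
    del_min: int = 200
    other_len_min: int = 500
    other_len_max: int = 3000
    qc_fail_fraction: float = 0.1
    quota: bool = True                # exact per-category counts vs multinomial
    seed: int = 0

    def __post_init__(self):
        total = sum(p for _, p in self.proportions)
        if abs(total - 1.0) > 1e-9:
            raise InvalidParameterError(f"proportions must sum to 1, got {total}")
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise InvalidParameterError(f"error rates must be in [0, 0.2], got {r}")

    @property
    def proportion_map(self) -> dict[str, float]:
        return dict(self.proportions)


def _oriented(payload: str, strand: str) -> str:
    if strand not in "+-":
        raise InvalidParameterError(f"strand must be '+' or '-', got {strand!r}")
    return payload if strand == "+" else revcomp(payload)


def simulate_canonical(ref: ReferenceGenome, strand: str | None = None,
                       rng: np.random.Generator | None = None,
                       read_id: str = "canonical") -> SimRead:
    """A full-length genome read; strand drawn 50/50 when unspecified."""
    rng = rng or np.random.default_rng()
    if strand is None:
        strand = "+" if rng.random() < 0.5 else "-"
    return SimRead(read_id, _oriented(ref.seq, strand),
                   truth=TruthRecord("CANONICAL", strand=strand))


def simulate_snapback(ref: ReferenceGenome, side: int, arm_a: int, arm_b: int,
                      strand: str = "+", rng=None, sym_tol: int = 100,
                      read_id: str = "sbg") -> SimRead:
    """A snapback read: the fold-back single strand ``arm_a ++ revcomp(arm_b)``.

    ``side=5`` anchors both arms at coordinate 0; ``side=3`` at the genome
    length. The fold junction sits at read position ``arm_a``.
    """
    L = ref.length
    if side not in (5, 3):
        raise InvalidParameterError(f"side must be 5 or 3, got {side}")
    for a in (arm_a, arm_b):
        if not 0 < a <= L:
            raise InvalidParameterError(f"arm length {a} outside (0, {L}]")
    if side == 5:
        payload = ref.seq[:arm_a] + revcomp(ref.seq[:arm_b])
        category = "SBG_5"
    else:
        payload = revcomp(ref.seq[L - arm_a:]) + ref.seq[L - arm_b:]
        category = "SBG_3"
    subtype = "SYMMETRIC" if abs(arm_a - arm_b) <= sym_tol else "ASYMMETRIC"
    return SimRead(read_id, _oriented(payload, strand),
                   truth=TruthRecord(category, subtype=subtype, strand=strand,
                                     arm_a=arm_a, arm_b=arm_b))


def simulate_icg(ref: ReferenceGenome, breakpoint: int | None = None,
                 strand: str = "+", rng=None, margin: int = 0,
                 read_id: str = "icg") -> SimRead:
    """An incomplete genome: right-anchored suffix ``ref[breakpoint:L]``.

    The retained terminal ITR plays the role of the packaging-origin 3'ITR.
    Unspecified breakpoints are drawn uniformly over the non-ITR interior
    (incomplete packaging as a random event).
    """
    lo, hi = ref.interior
    if breakpoint is None:
        rng = rng or np.random.default_rng()
        breakpoint = int(rng.integers(lo + margin, hi - margin))
    if not lo < breakpoint < hi:
        raise InvalidParameterError(
            f"breakpoint {breakpoint} must lie strictly inside the interior ({lo},{hi})")
    payload = ref.seq[breakpoint:]
    return SimRead(read_id, _oriented(payload, strand),
                   truth=TruthRecord("ICG", strand=strand, breakpoint=breakpoint))


def simulate_gdm(ref: ReferenceGenome, del_start: int, del_end: int,
                 strand: str = "+", rng=None, read_id: str = "gdm") -> SimRead:
    """A genome deletion mutant: both ITR-proximal blocks, interior missing."""
    lo, hi = ref.interior
    if not (lo <= del_start < del_end <= hi):
        raise InvalidParameterError(
            f"deletion [{del_start},{del_end}) must lie within the interior [{lo},{hi})")
    payload = ref.seq[:del_start] + ref.seq[del_end:]
    return SimRead(read_id, _oriented(payload, strand),
                   truth=TruthRecord("GDM", strand=strand,
                                     del_start=del_start, del_end=del_end))


def simulate_other(rng: np.random.Generator, length: int,
                   read_id: str = "other") -> SimRead:
    """Uniform-random DNA unrelated to the reference (host/helper stand-in)."""
    if length <= 0:
        raise InvalidParameterError(f"length must be > 0, got {length}")
    seq = "".join(_BASES[rng.integers(0, 4, size=length)])
    return SimRead(read_id, seq, truth=TruthRecord("OTHER"))


def apply_errors(seq: str, sub_rate: float, ins_rate: float, del_rate: float,
                 rng: np.random.Generator) -> str:
    """Apply independent per-base substitution/insertion/deletion errors.

    Insertions are placed before each base position (and after the last);
    deterministic for a fixed generator state.
    """
    for r in (sub_rate, ins_rate, del_rate):
        if not 0.0 <= r <= 0.2:
            raise InvalidParameterError(f"error rates must be in [0, 0.2], got {r}")
    n = len(seq)
    if n == 0 or (sub_rate == 0 and ins_rate == 0 and del_rate == 0):
        return seq
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    del_mask = rng.random(n) < del_rate
    sub_mask = (~del_mask) & (rng.random(n) < sub_rate)
    # substitute with one of the three other bases
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    idx = lut[codes]
    shifts = rng.integers(1, 4, size=n)
    sub_codes = np.frombuffer(b"ACGT", dtype=np.uint8)[(idx + shifts) % 4]
    codes[sub_mask] = sub_codes[sub_mask]
    kept = codes[~del_mask]
    ins_mask = rng.random(n + 1) < ins_rate
    ins_codes = np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=int(ins_mask.sum()))]
    if ins_codes.size:
        # map insertion slot i (before original base i) into the kept array
        kept_before = np.concatenate(([0], np.cumsum(~del_mask)))
        positions = kept_before[np.nonzero(ins_mask)[0]]
        kept = np.insert(kept, positions, ins_codes)
    return kept.tobytes().decode()


def _quota_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n reads over categories."""
    raw = {c: n * p for c, p in proportions.items()}
    counts = {c: int(np.floor(v)) for c, v in raw.items()}
    short = n - sum(counts.values())
    for c in sorted(raw, key=lambda c: (-(raw[c] - counts[c]), c))[:short]:
        counts[c] += 1
    return counts


def _draw_read(category: str, ref: ReferenceGenome, cfg: SimulationConfig,
               rng: np.random.Generator, read_id: str) -> SimRead:
    strand = "+" if rng.random() < 0.5 else "-"
    if category == "CANONICAL":
        return simulate_canonical(ref, strand, rng, read_id)
    if category in ("SBG_5", "SBG_3"):
        arm_a = int(rng.integers(cfg.arm_min, cfg.arm_max + 1))
        if rng.random() < cfg.symmetric_fraction:
            delta = int(rng.integers(-cfg.sym_delta_max, cfg.sym_delta_max + 1))
        else:
            loop = int(rng.geometric(1.0 / cfg.loop_mean))
            delta = loop if rng.random() < 0.5 else -loop
        arm_b = int(np.clip(arm_a + delta, cfg.arm_min, cfg.arm_max))
        side = 5 if category == "SBG_5" else 3
        return simulate_snapback(ref, side, arm_a, arm_b, strand,
                                 sym_tol=cfg.sym_tol, read_id=read_id)
    if category == "ICG":
        return simulate_icg(ref, None, strand, rng,
                            margin=cfg.breakpoint_margin, read_id=read_id)
    if category == "GDM":
        lo, hi = ref.interior
        lo += cfg.del_margin
        hi -= cfg.del_margin
        ds = int(rng.integers(lo, hi - cfg.del_min))
        de = int(rng.integers(ds + cfg.del_min, hi + 1))
        return simulate_gdm(ref, ds, de, strand, read_id=read_id)
    if category == "OTHER":
        length = int(rng.integers(cfg.other_len_min, cfg.other_len_max + 1))
        return simulate_other(rng, length, read_id)
    raise InvalidParameterError(f"unknown category {category!r}")


def _draw_qc_metadata(read: SimRead, cfg: SimulationConfig,
                      rng: np.random.Generator) -> None:
    if rng.random() < cfg.qc_fail_fraction:
        if rng.random() < 0.5:
            read.n_passes = int(rng.integers(1, 3))
            read.predicted_accuracy = round(0.99 + 0.01 * rng.random(), 6)
        else:
            read.n_passes = int(3 + rng.poisson(5.0))
            read.predicted_accuracy = round(0.95 + 0.0399 * rng.random(), 6)
    else:
        read.n_passes = int(3 + rng.poisson(5.0))
        read.predicted_accuracy = round(0.99 + 0.01 * rng.random(), 6)


def simulate_population(ref: ReferenceGenome, config: SimulationConfig,
                        out_prefix=None) -> tuple[list[SimRead], list[TruthRecord]]:
    """Generate a labeled mixed population; optionally write FASTQ + TSVs.

    Category counts follow the configured proportions exactly (quota mode,
    largest-remainder rounding) or as a multinomial draw. With ``out_prefix``
    set, writes ``<prefix>.fastq``, ``<prefix>.truth.tsv`` and
    ``<prefix>.meta.tsv``.
    """
    rng = np.random.default_rng(config.seed)
    props = config.proportion_map
    if config.quota:
        counts = _quota_counts(config.n_reads, props)
    else:
        cats = list(props)
        draw = rng.multinomial(config.n_reads, [props[c] for c in cats])
        counts = dict(zip(cats, (int(x) for x in draw)))
    order = [c for c in CATEGORIES if c in counts for _ in range(counts[c])]
    rng.shuffle(order)

    reads: list[SimRead] = []
    for i, category in enumerate(order):
        read = _draw_read(category, ref, config, rng, f"sim_{i:06d}")
        read.seq = apply_errors(read.seq, config.sub_rate, config.ins_rate,
                                config.del_rate, rng)
        _draw_qc_metadata(read, config, rng)
        reads.append(read)

    if out_prefix is not None:
        out_prefix = Path(out_prefix)
        out_prefix.parent.mkdir(parents=True, exist_ok=True)
        write_fastq(reads, out_prefix.with_suffix(".fastq"))
        write_truth_tsv(reads, out_prefix.with_suffix(".truth.tsv"), seed=config.seed)
        write_metadata_tsv(reads, out_prefix.with_suffix(".meta.tsv"), seed=config.seed)
    return reads, [r.truth for r in reads]


# ---------------------------------------------------------------- file I/O

def write_fastq(reads: list[SimRead], path) -> None:
    """Plain FASTQ with constant qualities (informational only)."""
    with open(path, "w", newline="\n") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")


def write_metadata_tsv(reads, path, seed=None) -> None:
    write_tsv(path, ("read_id", "n_passes", "predicted_accuracy"),
              [(r.id, r.n_passes, r.predicted_accuracy) for r in reads], seed=seed)


_TRUTH_COLS = ("read_id", "category", "subtype", "strand",
               "arm_a", "arm_b", "breakpoint", "del_start", "del_end")


def write_truth_tsv(reads, path, seed=None) -> None:
    rows = []
    for r in reads:
        t = r.truth
        rows.append((r.id, t.category, t.subtype, t.strand, t.arm_a, t.arm_b,
                     t.breakpoint, t.del_start, t.del_end))
    write_tsv(path, _TRUTH_COLS, rows, seed=seed)


def load_reads(fastq_path, metadata_path=None) -> list[SimRead]:
    """Load reads from FASTQ, merging consensus metadata from the sidecar TSV."""
    from Bio import SeqIO
    from ._io import read_tsv

    meta = {}
    if metadata_path is not None:
        df = read_tsv(metadata_path)
        for row in df.itertuples(index=False):
            meta[str(row.read_id)] = (int(row.n_passes), float(row.predicted_accuracy))
    reads = []
    for rec in SeqIO.parse(str(fastq_path), "fastq"):
        passes, acc = meta.get(rec.id, (10, 0.999))
        reads.append(SimRead(rec.id, str(rec.seq).upper(), passes, acc))
    return reads


def load_truth(truth_path) -> dict[str, TruthRecord]:
    from ._io import read_tsv

    def _int(v):
        return None if v != v or v == "" else int(float(v))

    out = {}
    for row in read_tsv(truth_path).itertuples(index=False):
        out[str(row.read_id)] = TruthRecord(
            row.category, row.subtype, row.strand,
            arm_a=_int(row.arm_a), arm_b=_int(row.arm_b),
            breakpoint=_int(row.breakpoint),
            del_start=_int(row.del_start), del_end=_int(row.del_end))
    return out
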