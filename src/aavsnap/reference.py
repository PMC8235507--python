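"""AAV reference genome model: sequence, ITRs and structural features.

The wild-type AAV genome is a ~4.7 kb single-stranded DNA flanked by GC-rich
palindromic inverted terminal repeats (ITRs). The left moiety carries the P5
and P19 promoters and the *rep* ORF; the right moiety carries the P40 promoter
and the *cap* ORF. This module builds a synthetic stand-in with that geometry
(perfect-palindrome ITRs, random interior) and reads/writes it as FASTA plus a
BED-like feature TSV.

Coordinates are 0-based half-open on the plus strand (the rep/cap sense).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import gc_fraction, revcomp
from .errors import FormatError, InvalidParameterError

ROLES = ("ITR_LEFT", "ITR_RIGHT", "P5", "P19", "P40", "REP_ORF", "CAP_ORF")


@dataclass(frozen=True)
class Feature:
    """One annotated interval on the reference (0-based half-open, plus strand)."""

    role: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.role not in ROLES:
            raise InvalidParameterError(f"unknown feature role {self.role!r}")
        if not 0 <= self.start < self.end:
            raise InvalidParameterError(
                f"feature {self.role}: need 0 <= start < end, got [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReferenceGenome:
    """An AAV reference sequence with its feature annotation."""

    seq: str
    features: tuple[Feature, ...]

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        roles = [f.role for f in self.features]
        if len(set(roles)) != len(roles):
            raise InvalidParameterError("feature roles must be unique per genome")
        for need in ("ITR_LEFT", "ITR_RIGHT"):
            if need not in roles:
                raise InvalidParameterError(f"missing required feature {need}")
        itr_l = self.feature("ITR_LEFT")
        itr_r = self.feature("ITR_RIGHT")
        if itr_l.start != 0:
            raise InvalidParameterError("ITR_LEFT must start at coordinate 0")
        if itr_r.end != self.length:
            raise InvalidParameterError("ITR_RIGHT must end at the genome length")
        if self.length < itr_l.length + itr_r.length + 1000:
            raise InvalidParameterError(
                "genome too short: need length >= 2 x ITR length + 1000")
        for f in self.features:
            if f.end > self.length:
                raise InvalidParameterError(
                    f"feature {f.role} [{f.start},{f.end}) exceeds genome length {self.length}")
        proms = [self.feature(r) for r in ("P5", "P19", "P40") if r in roles]
        starts = [p.start for p in proms]
        if starts != sorted(starts):
            raise InvalidParameterError("promoters must satisfy P5 < P19 < P40 by start")

    @property
    def length(self) -> int:
        return len(self.seq)

    def feature(self, role: str) -> Feature:
        for f in self.features:
            if f.role == role:
                return f
        raise KeyError(role)

    @property
    def interior(self) -> tuple[int, int]:
        """The non-ITR interval [ITR_LEFT.end, ITR_RIGHT.start)."""
        return self.feature("ITR_LEFT").end, self.feature("ITR_RIGHT").start


@dataclass(frozen=True)
class ReferenceConfig:
    """Layout of the synthetic reference.

    Feature positions are fractions of the total length; defaults keep P5/rep
    in the left moiety and P40/cap in the right moiety, i.e. the geometry that
    makes 5'-snapbacks carry P5+partial rep and 3'-snapbacks carry cap.
    """

    length: int = 4700
    itr_length: int = 144
    seed: int = 0
    p5_frac: float = 0.055
    p19_frac: float = 0.19
    p40_frac: float = 0.38
    promoter_length: int = 40
    rep_frac: tuple[float, float] = (0.06, 0.48)
    cap_frac: tuple[float, float] = (0.45, 0.95)


def make_itr(length: int, rng_seed: int = 0) -> str:
    """Build a perfect-palindrome, GC-rich ITR stand-in.

    The returned sequence ``s`` satisfies ``revcomp(s) == s`` exactly (hence
    the even-length requirement) with GC fraction >= 0.6.
    """
    if length % 2 != 0 or length < 20:
        raise InvalidParameterError(f"ITR length must be even and >= 20, got {length}")
    rng = np.random.default_rng(rng_seed)
    half = length // 2
    n_gc = int(round(0.7 * half))
    bases = [rng.choice(["G", "C"]) for _ in range(n_gc)]
    bases += [rng.choice(["A", "T"]) for _ in range(half - n_gc)]
    rng.shuffle(bases)
    h = "".join(bases)
    s = h + revcomp(h)
    assert revcomp(s) == s
    return s


def build_reference(config: ReferenceConfig = ReferenceConfig()) -> ReferenceGenome:
    """Construct the synthetic reference genome (deterministic for a fixed seed)."""
    L, itr_len = config.length, config.itr_length
    itr = make_itr(itr_len, config.seed)
    rng = np.random.default_rng(config.seed + 1)
    interior = "".join(rng.choice(list("ACGT"), size=L - 2 * itr_len))
    seq = itr + interior + itr  # right ITR: same palindrome, equal to its own revcomp

    def promoter(role, frac):
        start = int(round(frac * L))
        end = start + config.promoter_length
        if start < itr_len or end > L - itr_len:
            raise InvalidParameterError(f"{role} at [{start},{end}) overlaps an ITR")
        return Feature(role, start, end)

    features = (
        Feature("ITR_LEFT", 0, itr_len),
        Feature("ITR_RIGHT", L - itr_len, L),
        promoter("P5", config.p5_frac),
        promoter("P19", config.p19_frac),
        promoter("P40", config.p40_frac),
        Feature("REP_ORF", int(round(config.rep_frac[0] * L)), int(round(config.rep_frac[1] * L))),
        Feature("CAP_ORF", int(round(config.cap_frac[0] * L)), int(round(config.cap_frac[1] * L))),
    )
    return ReferenceGenome(seq=seq, features=features)


def write_reference(ref: ReferenceGenome, fasta_path, features_path, name: str = "AAV_ref") -> None:
    rec = SeqRecord(Seq(ref.seq), id=name, description="synthetic AAV reference")
    SeqIO.write([rec], str(fasta_path), "fasta")
    from ._io import write_tsv
    write_tsv(features_path, ("role", "start", "end", "strand"),
              [(f.role, f.start, f.end, f.strand) for f in ref.features])


def load_reference(fasta_path, features_path) -> ReferenceGenome:
    """Load a reference FASTA (single record) + feature TSV, validating invariants."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FormatError(f"{fasta_path}: expected exactly one FASTA record, found {len(records)}")
    seq = str(records[0].seq).upper()

    features = []
    with open(features_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{features_path}:{lineno}: expected >= 3 tab-separated fields")
            role, start, end = parts[0], parts[1], parts[2]
            strand = parts[3] if len(parts) > 3 else "+"
            try:
                feat = Feature(role, int(start), int(end), strand)
            except (ValueError, InvalidParameterError) as exc:
                raise FormatError(f"{features_path}:{lineno}: {exc}") from exc
            if feat.end > len(seq):
                raise FormatError(
                    f"{features_path}:{lineno}: feature end {feat.end} > genome length {len(seq)}")
            features.append(feat)
    return ReferenceGenome(seq=seq, features=tuple(features))
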