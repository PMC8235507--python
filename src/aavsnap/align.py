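"""Iterative fragment alignment of single-molecule reads to the AAV reference.

This is the categorization engine: each read is locally aligned to the
reference over both strands; the best qualifying hit is recorded and the
procedure recurses independently on the unmatched left and right flanks until
no qualifying hit remains, a flank is shorter than ``min_segment_len``, or the
recursion limit is reached. The resulting per-read segment chain is what the
classifier consumes — a canonical genome gives one full-length segment, a
snapback gives two opposite-strand segments sharing a terminal anchor, a
deletion mutant gives two collinear same-strand segments, and so on.

The aligner is an internal affine-gap local DP (see ``_kernels``). For speed
the default path seeds each strand with exact k-mer matches, chains them by
diagonal, and runs the banded DP over the chained band; reads with no seeds
(foreign DNA) fall back to a full score-only DP plus a banded traceback around
its optimum. Alignments are split into separate segments wherever a single
gap run reaches ``split_gap`` bases, so internal deletions surface as
collinear segment pairs instead of being absorbed into one gapped alignment.

Tie-breaking is total (score, then longest read span, then smallest ref_start,
then plus strand first), which makes segmentation deterministic.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernels import banded_affine_local, sw_best
from ._seq import encode, kmer_hashes, revcomp
from .errors import InvalidParameterError


@dataclass(frozen=True)
class AlignParams:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4        # score of the first base of a gap run
    gap_extend: int = -2      # each further base in the run
    min_segment_len: int = 50
    min_identity: float = 0.85
    max_depth: int = 6
    kmer_size: int = 13
    chain_diag_gap: int = 30  # diagonal jump that separates seed chains
    band_pad: int = 40        # extra diagonals around a chained band
    max_chains_per_strand: int = 2
    split_gap: int = 50       # gap run length that splits an alignment
    rescue_band: int = 250    # band half-width for the seedless fallback

    def __post_init__(self):
        if self.min_segment_len < 20:
            raise InvalidParameterError("min_segment_len must be >= 20")
        if not 0.5 < self.min_identity <= 1.0:
            raise InvalidParameterError("min_identity must be in (0.5, 1]")

    @property
    def min_qualifying_score(self) -> int:
        """Lower bound on the score of any segment passing both filters."""
        return int(math.floor(self.min_segment_len *
                              (self.min_identity * self.match +
                               (1 - self.min_identity) * self.mismatch)))


@dataclass(frozen=True)
class AlignmentSegment:
    """One local-alignment hit: read interval <-> reference interval."""

    read_start: int
    read_end: int
    ref_start: int
    ref_end: int
    strand: str
    identity: float
    score: int
    cigar: str | None = None

    def __post_init__(self):
        if not (self.read_start < self.read_end and self.ref_start < self.ref_end):
            raise InvalidParameterError("segment intervals must be non-empty")
        if not 0.0 <= self.identity <= 1.0:
            raise InvalidParameterError("identity must be in [0,1]")

    @property
    def read_span(self) -> int:
        return self.read_end - self.read_start

    @property
    def ref_span(self) -> int:
        return self.ref_end - self.ref_start

    def sort_key(self):
        """Total order: best score, longest span, smallest ref_start, + first."""
        return (-self.score, -self.read_span, self.ref_start,
                0 if self.strand == "+" else 1)


@dataclass
class SegmentChain:
    read_id: str
    read_length: int
    segments: list[AlignmentSegment] = field(default_factory=list)

    @property
    def uncovered(self) -> list[tuple[int, int]]:
        """Read intervals not covered by any segment (tiles with segments)."""
        out = []
        pos = 0
        for s in sorted(self.segments, key=lambda s: s.read_start):
            if s.read_start > pos:
                out.append((pos, s.read_start))
            pos = max(pos, s.read_end)
        if pos < self.read_length:
            out.append((pos, self.read_length))
        return out

    @property
    def covered_bases(self) -> int:
        return sum(s.read_span for s in self.segments)


def _ops_to_pieces(ops, qstart, rstart, params: AlignParams):
    """Split a traceback path at long gap runs; yield per-piece geometry.

    ``ops`` runs start -> end; codes: 0 match, 1 mismatch, 2 gap consuming
    reference, 3 gap consuming query. Returns a list of dicts with local query
    coordinates (the caller maps strand/offsets).
    """
    runs = []  # (op, length)
    for op in ops:
        if runs and runs[-1][0] == op:
            runs[-1][1] += 1
        else:
            runs.append([int(op), 1])

    pieces = []
    cur = None
    qpos, rpos = qstart, rstart
    for op, n in runs:
        big_gap = op in (2, 3) and n >= params.split_gap
        if big_gap:
            if cur is not None:
                pieces.append(cur)
                cur = None
        elif op in (0, 1) or cur is not None:
            # leading small gaps before any diagonal column are dropped
            if cur is None:
                cur = {"q0": qpos, "r0": rpos, "match": 0, "cols": 0,
                       "score": 0, "cigar": []}
            cur["cols"] += n
            if op == 0:
                cur["match"] += n
                cur["score"] += n * params.match
                cur["cigar"].append(f"{n}=")
            elif op == 1:
                cur["score"] += n * params.mismatch
                cur["cigar"].append(f"{n}X")
            else:
                cur["score"] += params.gap_open + (n - 1) * params.gap_extend
                cur["cigar"].append(f"{n}{'D' if op == 2 else 'I'}")
        if op in (0, 1):
            qpos += n
            rpos += n
        elif op == 2:
            rpos += n
        else:
            qpos += n
        if cur is not None:
            cur["q1"], cur["r1"] = qpos, rpos
    if cur is not None:
        pieces.append(cur)
    # strip trailing gap columns left by small runs at a piece edge
    for p in pieces:
        while p["cigar"] and p["cigar"][-1][-1] in "DI":
            tok = p["cigar"].pop()
            n = int(tok[:-1])
            p["cols"] -= n
            p["score"] -= params.gap_open + (n - 1) * params.gap_extend
            if tok[-1] == "D":
                p["r1"] -= n
            else:
                p["q1"] -= n
    return [p for p in pieces if p["match"] > 0]


class Aligner:
    """Reusable aligner bound to one reference sequence.

    ``ref`` may be a :class:`~aavsnap.reference.ReferenceGenome` or a plain
    sequence string (handy for toy references in tests).
    """

    def __init__(self, ref, params: AlignParams = AlignParams()):
        self.ref_seq = ref.seq if hasattr(ref, "seq") else str(ref).upper()
        self.params = params
        self._ref_codes = encode(self.ref_seq)
        hashes = kmer_hashes(self._ref_codes, params.kmer_size)
        pos = np.nonzero(hashes >= 0)[0]
        vals = hashes[pos]
        order = np.argsort(vals, kind="stable")
        self._hs = vals[order]
        self._pos = pos[order]

    # ------------------------------------------------------------ seeding

    def _chains(self, q_codes: np.ndarray):
        """Diagonal-clustered exact k-mer seed chains for one query strand."""
        k = self.params.kmer_size
        qh = kmer_hashes(q_codes, k)
        qpos = np.nonzero(qh >= 0)[0]
        if qpos.size == 0:
            return []
        qv = qh[qpos]
        left = np.searchsorted(self._hs, qv, side="left")
        right = np.searchsorted(self._hs, qv, side="right")
        cnt = right - left
        nz = cnt > 0
        if not nz.any():
            return []
        cl, cc, qp = left[nz], cnt[nz], qpos[nz]
        total = int(cc.sum())
        ends = np.cumsum(cc)
        starts = ends - cc
        idx = np.repeat(cl, cc) + (np.arange(total) - np.repeat(starts, cc))
        t = self._pos[idx]
        p = np.repeat(qp, cc)
        d = t - p
        order = np.lexsort((p, d))
        d_s, p_s = d[order], p[order]
        breaks = np.nonzero(np.diff(d_s) > self.params.chain_diag_gap)[0] + 1
        bounds = np.concatenate(([0], breaks, [d_s.size]))
        chains = []
        for a, b in zip(bounds[:-1], bounds[1:]):
            span = int(p_s[a:b].max() - p_s[a:b].min()) + k
            chains.append((int(b - a), span, int(d_s[a]), int(d_s[b - 1])))
        chains.sort(key=lambda c: (-c[0], -c[1], c[2]))
        return chains[:self.params.max_chains_per_strand]

    # ------------------------------------------------------- DP wrappers

    def _banded(self, q_codes, dlo, dhi):
        p = self.params
        dlo = max(dlo, -(q_codes.size - 1))
        dhi = min(dhi, self._ref_codes.size - 1)
        if dhi < dlo:
            return None
        score, qe, re_, qs, rs, t, ops = banded_affine_local(
            q_codes, self._ref_codes, dlo, dhi,
            p.match, p.mismatch, p.gap_open, p.gap_extend)
        if score <= 0:
            return None
        return _ops_to_pieces(ops[:t][::-1], qs, rs, p)

    def _candidates_for_strand(self, seq: str, strand: str, fallback: bool):
        p = self.params
        q = seq if strand == "+" else revcomp(seq)
        q_codes = encode(q)
        m = q_codes.size
        band_sets = []
        if not fallback:
            for _, _, dlo, dhi in self._chains(q_codes):
                band_sets.append((dlo - p.band_pad, dhi + p.band_pad))
        else:
            best, bi, bj = sw_best(q_codes, self._ref_codes, p.match,
                                   p.mismatch, p.gap_open, p.gap_extend)
            if best >= p.min_qualifying_score:
                d = bj - bi
                band_sets.append((d - p.rescue_band, d + p.rescue_band))
        out = []
        for dlo, dhi in band_sets:
            pieces = self._banded(q_codes, dlo, dhi) or []
            for pc in pieces:
                if strand == "+":
                    r0, r1 = pc["q0"], pc["q1"]
                    cigar = "".join(pc["cigar"])
                else:
                    r0, r1 = m - pc["q1"], m - pc["q0"]
                    cigar = "".join(reversed(pc["cigar"]))
                if r1 - r0 < p.min_segment_len:
                    continue
                identity = pc["match"] / pc["cols"] if pc["cols"] else 0.0
                if identity < p.min_identity:
                    continue
                out.append(AlignmentSegment(
                    read_start=r0, read_end=r1,
                    ref_start=pc["r0"], ref_end=pc["r1"],
                    strand=strand, identity=round(identity, 4),
                    score=pc["score"], cigar=cigar))
        return out

    def best_segment(self, seq: str) -> AlignmentSegment | None:
        """Best-scoring qualifying local alignment over both strands, or None."""
        if len(seq) < self.params.min_segment_len:
            return None
        cand = []
        for strand in "+-":
            cand.extend(self._candidates_for_strand(seq, strand, fallback=False))
        if not cand:
            for strand in "+-":
                cand.extend(self._candidates_for_strand(seq, strand, fallback=True))
        if not cand:
            return None
        return min(cand, key=AlignmentSegment.sort_key)

    def segment_read(self, read) -> SegmentChain:
        """Recursive left/right-flank re-alignment producing the segment chain."""
        seq = read.seq if hasattr(read, "seq") else str(read)
        read_id = getattr(read, "id", "read")
        chain = SegmentChain(read_id=read_id, read_length=len(seq))

        def recurse(sub: str, offset: int, depth: int):
            if len(sub) < self.params.min_segment_len or depth > self.params.max_depth:
                return
            seg = self.best_segment(sub)
            if seg is None:
                return
            chain.segments.append(AlignmentSegment(
                read_start=seg.read_start + offset, read_end=seg.read_end + offset,
                ref_start=seg.ref_start, ref_end=seg.ref_end, strand=seg.strand,
                identity=seg.identity, score=seg.score, cigar=seg.cigar))
            recurse(sub[:seg.read_start], offset, depth + 1)
            recurse(sub[seg.read_end:], offset + seg.read_end, depth + 1)

        recurse(seq, 0, 0)
        chain.segments.sort(key=lambda s: s.read_start)
        return chain


# ---------------------------------------------------- functional interface

def local_align(query: str, ref, params: AlignParams = AlignParams()):
    """Best local alignment of ``query`` against ``ref`` over both strands."""
    if not query:
        raise InvalidParameterError("query must be non-empty")
    return Aligner(ref, params).best_segment(query)


def segment_read(read, ref, params: AlignParams = AlignParams()) -> SegmentChain:
    """One-shot segment chain for a single read (builds a throwaway index)."""
    return Aligner(ref, params).segment_read(read)


# ------------------------------------------------------------- exports

_CHAIN_COLS = ("read_id", "read_start", "read_end", "ref_start", "ref_end",
               "strand", "identity", "score")


def chains_to_tsv(chains: list[SegmentChain], path, seed=None) -> None:
    from ._io import write_tsv
    rows = [(c.read_id, s.read_start, s.read_end, s.ref_start, s.ref_end,
             s.strand, s.identity, s.score)
            for c in chains for s in c.segments]
    write_tsv(path, _CHAIN_COLS, rows, seed=seed)


def chains_to_sam(chains: list[SegmentChain], ref, path,
                  ref_name: str = "AAV_ref") -> None:
    """Plain-text SAM export, one record per segment (supplementary style).

    Requires segments carrying CIGARs (i.e. produced by this aligner).
    """
    ref_len = len(ref.seq if hasattr(ref, "seq") else ref)
    with open(path, "w", newline="\n") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        fh.write(f"@SQ\tSN:{ref_name}\tLN:{ref_len}\n")
        for c in chains:
            for i, s in enumerate(sorted(c.segments, key=lambda s: s.read_start)):
                if s.cigar is None:
                    continue
                flag = (16 if s.strand == "-" else 0) | (2048 if i > 0 else 0)
                pre, post = s.read_start, c.read_length - s.read_end
                if s.strand == "-":
                    pre, post = post, pre
                cig = (f"{pre}S" if pre else "") + s.cigar + (f"{post}S" if post else "")
                fh.write(f"{c.read_id}\t{flag}\t{ref_name}\t{s.ref_start + 1}\t255\t"
                         f"{cig}\t*\t0\t0\t*\t*\tNM:i:0\n")
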