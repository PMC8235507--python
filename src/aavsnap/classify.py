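"""Assign each segment chain to a molecular-configuration category.

Decision tree (first match wins), operating on segment chains whose collinear
same-strand segments with sub-threshold gaps have first been merged:

1. no segments                                        -> OTHER
2. one (merged) segment covering >= ``full_genome_frac`` of the reference
   including both ITRs                                -> CANONICAL
3. fold point (adjacent opposite-strand segments anchored at the same
   reference terminus)                                -> SBG_5 / SBG_3
4. one segment retaining exactly one terminal ITR     -> ICG
5. >= 2 collinear same-strand segments, both ITRs, an internal reference gap
   of >= ``min_del``                                  -> GDM
6. anything else                                      -> OTHER

Priorities put stronger evidence first: full-length coverage pre-empts a fold,
a fold pre-empts truncation/deletion patterns. The ICG convention follows AAV
packaging biology: packaging initiates at the 3'ITR, so the single retained
terminal ITR of a truncated genome *is* its 3'ITR, whichever reference
terminus it maps to; consequently every ICG call has ``itr3_intact`` and not
``itr5_intact`` by construction. All reported reference coordinates are
plus-strand, 0-based, half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .align import Aligner, AlignParams, AlignmentSegment, SegmentChain
from .errors import InvalidParameterError
from .reference import ReferenceGenome
from .simulate import CATEGORIES

ANNOTATION_SBG5 = "tail-to-tail-dimer; dsRNA-capable; predicted Rep78 down-regulation"
ANNOTATION_SBG3 = "head-to-head-P40; double-enhancer; predicted cap up-regulation"


@dataclass(frozen=True)
class ClassifyParams:
    itr_cover_frac: float = 0.9   # ITR interval coverage needed to call it intact
    full_genome_frac: float = 0.95
    anchor_tol: int = 50          # SBG arm distance tolerance from a terminus
    sym_tol: int = 100            # symmetric vs asymmetric arm threshold
    min_del: int = 50             # minimum internal reference gap for GDM
    max_junction_gap: int = 50    # max unaligned read bases at an SBG junction

    def __post_init__(self):
        for frac in (self.itr_cover_frac, self.full_genome_frac):
            if not 0.0 < frac <= 1.0:
                raise InvalidParameterError("fractions must be in (0,1]")
        for tol in (self.anchor_tol, self.sym_tol, self.min_del, self.max_junction_gap):
            if tol < 0:
                raise InvalidParameterError("nt tolerances must be >= 0")


@dataclass(frozen=True)
class ConfigurationCall:
    read_id: str
    category: str
    subtype: str = "NONE"
    strand: str = "NA"
    itr5_intact: bool = False
    itr3_intact: bool = False
    fold_point_read: int | None = None
    arm_a: int | None = None
    arm_b: int | None = None
    loop_len: int | None = None
    breakpoint: int | None = None
    del_start: int | None = None
    del_end: int | None = None
    n_gaps: int | None = None
    annotation: str = "none"
    read_length: int | None = None
    ref_intervals: tuple = ()

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InvalidParameterError(f"unknown category {self.category!r}")
        if self.category == "ICG" and not (self.itr3_intact and not self.itr5_intact):
            raise InvalidParameterError("ICG requires intact 3'ITR and no 5'ITR")
        if self.category == "GDM" and not (
                self.itr5_intact and self.itr3_intact and self.del_start is not None):
            raise InvalidParameterError("GDM requires both ITRs and a deletion")
        if self.category.startswith("SBG") and (
                self.arm_a is None or self.arm_b is None or self.fold_point_read is None):
            raise InvalidParameterError("SBG requires arms and a fold point")


# ------------------------------------------------------------- helpers

def _union(intervals):
    out = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _covered_fraction(intervals, span):
    s0, e0 = span
    cov = 0
    for s, e in _union(intervals):
        cov += max(0, min(e, e0) - max(s, s0))
    return cov / (e0 - s0)


def _merge_collinear(segments: list[AlignmentSegment], params: ClassifyParams):
    """Merge adjacent same-strand collinear segments separated by gaps < min_del.

    Small gaps (read or reference side) are alignment noise; genuine deletions
    stay as separate segments. Returns the effective segment list sorted by
    read_start.
    """
    segs = sorted(segments, key=lambda s: s.read_start)
    if not segs:
        return []
    out = [segs[0]]
    for nxt in segs[1:]:
        prev = out[-1]
        read_gap = nxt.read_start - prev.read_end
        if prev.strand == nxt.strand == "+":
            ref_gap = nxt.ref_start - prev.ref_end
        elif prev.strand == nxt.strand == "-":
            ref_gap = prev.ref_start - nxt.ref_end
        else:
            ref_gap = None
        if (ref_gap is not None and -params.max_junction_gap <= ref_gap < params.min_del
                and 0 <= read_gap < params.min_del):
            merged = AlignmentSegment(
                read_start=prev.read_start, read_end=nxt.read_end,
                ref_start=min(prev.ref_start, nxt.ref_start),
                ref_end=max(prev.ref_end, nxt.ref_end),
                strand=prev.strand,
                identity=round((prev.identity * prev.read_span +
                                nxt.identity * nxt.read_span) /
                               (prev.read_span + nxt.read_span), 4),
                score=prev.score + nxt.score)
            out[-1] = merged
        else:
            out.append(nxt)
    return out


def detect_itr_coverage(chain: SegmentChain, ref: ReferenceGenome,
                        params: ClassifyParams = ClassifyParams()):
    """Coverage-based intactness of the left (5') and right (3') ITRs.

    An ITR is intact when >= ``itr_cover_frac`` of its reference interval is
    covered by the union of segment intervals. Reverse-complementing a read
    conjugates segment strands but leaves reference intervals unchanged, so
    the test is strand-invariant by construction.
    """
    intervals = [(s.ref_start, s.ref_end) for s in chain.segments]
    itr_l = ref.feature("ITR_LEFT")
    itr_r = ref.feature("ITR_RIGHT")
    itr5 = _covered_fraction(intervals, (itr_l.start, itr_l.end)) >= params.itr_cover_frac
    itr3 = _covered_fraction(intervals, (itr_r.start, itr_r.end)) >= params.itr_cover_frac
    return itr5, itr3


def find_fold_point(chain: SegmentChain, ref, params: ClassifyParams = ClassifyParams()):
    """Detect a snapback fold: adjacent opposite-strand arms sharing a terminus.

    Returns ``(fold_point_read, arm_a, arm_b, side)`` for the best (longest
    combined arms) such pair, else None. ``ref`` supplies the genome length
    for the right-terminus anchor test.
    """
    L = len(ref.seq) if hasattr(ref, "seq") else int(ref)
    segs = sorted(chain.segments, key=lambda s: s.read_start)
    best = None
    for a, b in zip(segs[:-1], segs[1:]):
        if a.strand == b.strand:
            continue
        if abs(b.read_start - a.read_end) > params.max_junction_gap:
            continue
        if a.ref_start <= params.anchor_tol and b.ref_start <= params.anchor_tol:
            side = 5
        elif a.ref_end >= L - params.anchor_tol and b.ref_end >= L - params.anchor_tol:
            side = 3
        else:
            continue
        arm_a, arm_b = a.ref_span, b.ref_span
        key = arm_a + arm_b
        if best is None or key > best[0]:
            best = (key, a.read_end, arm_a, arm_b, side)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def annotate_regulatory_potential(call: ConfigurationCall,
                                  ref: ReferenceGenome) -> str:
    """Regulatory-potential label from the covered promoters (pure rule lookup).

    A 5'-snapback whose duplex covers P5 can, in dimer form, transcribe
    convergently across the fold and yield dsRNA against the rep transcript;
    a 3'-snapback covering P40 puts two P40 copies head-to-head so enhancers
    act on both — no expression modeling, just the structural rule.
    """
    def covers(role):
        f = ref.feature(role)
        return any(s <= f.start and f.end <= e for s, e in _union(call.ref_intervals))

    if call.category == "SBG_5" and covers("P5"):
        return ANNOTATION_SBG5
    if call.category == "SBG_3" and covers("P40"):
        return ANNOTATION_SBG3
    return "none"


def classify_read(chain: SegmentChain, ref: ReferenceGenome,
                  params: ClassifyParams = ClassifyParams()) -> ConfigurationCall:
    """Apply the decision tree to one segment chain."""
    segs = _merge_collinear(chain.segments, params)
    base = dict(read_id=chain.read_id, read_length=chain.read_length)
    if not segs:
        return ConfigurationCall(category="OTHER", **base)

    intervals = tuple((s.ref_start, s.ref_end) for s in segs)
    base["ref_intervals"] = intervals
    itr5, itr3 = detect_itr_coverage(chain, ref, params)
    covered = _covered_fraction(intervals, (0, ref.length))

    # (2) canonical: one effective segment spanning essentially the whole genome
    if len(segs) == 1 and covered >= params.full_genome_frac and itr5 and itr3:
        return ConfigurationCall(category="CANONICAL", strand=segs[0].strand,
                                 itr5_intact=True, itr3_intact=True, **base)

    # (3) snapback fold
    fold = find_fold_point(SegmentChain(chain.read_id, chain.read_length, segs),
                           ref, params)
    if fold is not None:
        fold_point, arm_a, arm_b, side = fold
        subtype = "SYMMETRIC" if abs(arm_a - arm_b) <= params.sym_tol else "ASYMMETRIC"
        call = ConfigurationCall(
            category=f"SBG_{side}", subtype=subtype, strand=segs[0].strand,
            itr5_intact=itr5, itr3_intact=itr3, fold_point_read=fold_point,
            arm_a=arm_a, arm_b=arm_b, loop_len=abs(arm_a - arm_b), **base)
        return replace(call, annotation=annotate_regulatory_potential(call, ref))

    # (4) incomplete genome: exactly one retained terminal ITR (it is the 3'ITR)
    if len(segs) == 1 and itr5 != itr3:
        seg = segs[0]
        if itr3:  # right-anchored (the simulated orientation)
            breakpoint, strand = seg.ref_start, seg.strand
        else:     # left-anchored: the same truncation on the opposite sense
            breakpoint, strand = seg.ref_end, ("-" if seg.strand == "+" else "+")
        return ConfigurationCall(category="ICG", strand=strand,
                                 itr5_intact=False, itr3_intact=True,
                                 breakpoint=breakpoint, **base)

    # (5) genome deletion mutant: collinear same-strand blocks around a gap
    if len(segs) >= 2 and itr5 and itr3 and len({s.strand for s in segs}) == 1:
        strand = segs[0].strand
        ordered = sorted(segs, key=lambda s: s.ref_start)
        collinear = all(a.ref_end <= b.ref_start + params.max_junction_gap
                        for a, b in zip(ordered[:-1], ordered[1:]))
        gaps = [(a.ref_end, b.ref_start)
                for a, b in zip(ordered[:-1], ordered[1:])
                if b.ref_start - a.ref_end >= params.min_del]
        if collinear and gaps:
            del_start, del_end = max(gaps, key=lambda g: g[1] - g[0])
            return ConfigurationCall(category="GDM", strand=strand,
                                     itr5_intact=True, itr3_intact=True,
                                     del_start=del_start, del_end=del_end,
                                     n_gaps=len(gaps), **base)

    return ConfigurationCall(category="OTHER", itr5_intact=itr5,
                             itr3_intact=itr3, **base)


def classify_population(reads, ref: ReferenceGenome,
                        align_params: AlignParams = AlignParams(),
                        classify_params: ClassifyParams = ClassifyParams(),
                        return_chains: bool = False):
    """Segment and classify every read; one call per read, input order kept."""
    aligner = Aligner(ref, align_params)
    calls, chains = [], []
    for read in reads:
        chain = aligner.segment_read(read)
        calls.append(classify_read(chain, ref, classify_params))
        if return_chains:
            chains.append(chain)
    return (calls, chains) if return_chains else calls


# ------------------------------------------------------------------ I/O

_CALL_COLS = ("read_id", "category", "subtype", "strand", "itr5", "itr3",
              "fold_point", "arm_a", "arm_b", "loop_len", "breakpoint",
              "del_start", "del_end", "n_gaps", "annotation", "read_length")


def calls_to_tsv(calls: list[ConfigurationCall], path, seed=None) -> None:
    from ._io import write_tsv
    rows = [(c.read_id, c.category, c.subtype, c.strand, int(c.itr5_intact),
             int(c.itr3_intact), c.fold_point_read, c.arm_a, c.arm_b, c.loop_len,
             c.breakpoint, c.del_start, c.del_end, c.n_gaps, c.annotation,
             c.read_length) for c in calls]
    write_tsv(path, _CALL_COLS, rows, seed=seed)
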