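import numpy as np
import pytest

import aavsnap as av
from aavsnap._seq import revcomp
from aavsnap.align import AlignmentSegment, SegmentChain
from aavsnap.classify import (ANNOTATION_SBG3, ANNOTATION_SBG5, ClassifyParams,
                              ConfigurationCall, classify_read,
                              detect_itr_coverage, find_fold_point)
from aavsnap.errors import InvalidParameterError


def _seg(rs, re_, fs, fe, strand="+", identity=1.0):
    return AlignmentSegment(read_start=rs, read_end=re_, ref_start=fs,
                            ref_end=fe, strand=strand, identity=identity,
                            score=2 * (re_ - rs))


def _chain(read_length, *segs):
    return SegmentChain("t", read_length, list(segs))


# ------------------------------------------------ decision-tree unit cases

def test_full_cover_chain_is_canonical(ref):
    call = classify_read(_chain(4700, _seg(0, 4700, 0, 4700)), ref)
    assert call.category == "CANONICAL"
    assert call.strand == "+"
    assert call.itr5_intact and call.itr3_intact


def test_opposed_terminal_arms_are_sbg5(ref):
    call = classify_read(
        _chain(1600, _seg(0, 800, 0, 800, "+"), _seg(800, 1600, 0, 800, "-")), ref)
    assert (call.category, call.subtype) == ("SBG_5", "SYMMETRIC")
    assert call.fold_point_read == 800
    assert (call.arm_a, call.arm_b, call.loop_len) == (800, 800, 0)
    assert call.annotation == ANNOTATION_SBG5  # arms cover P5


def test_single_right_anchored_segment_is_icg(ref):
    call = classify_read(_chain(2700, _seg(0, 2700, 2000, 4700)), ref)
    assert call.category == "ICG"
    assert call.breakpoint == 2000
    assert call.itr3_intact and not call.itr5_intact


def test_collinear_segments_with_interior_gap_are_gdm(ref):
    call = classify_read(
        _chain(2200, _seg(0, 1000, 0, 1000), _seg(1000, 2200, 3500, 4700)), ref)
    assert call.category == "GDM"
    assert (call.del_start, call.del_end) == (1000, 3500)
    assert call.itr5_intact and call.itr3_intact


def test_empty_chain_is_other(ref):
    assert classify_read(_chain(1500), ref).category == "OTHER"


def test_interior_only_segment_is_other(ref):
    # neither terminal ITR retained -> not an ICG by definition
    call = classify_read(_chain(1000, _seg(0, 1000, 2000, 3000)), ref)
    assert call.category == "OTHER"
    assert not call.itr5_intact and not call.itr3_intact


def test_small_gaps_merge_into_canonical(ref):
    # two collinear blocks separated by a sub-threshold 30 nt gap: noise
    call = classify_read(
        _chain(4670, _seg(0, 2000, 0, 2000), _seg(2000, 4670, 2030, 4700)), ref)
    assert call.category == "CANONICAL"


def test_fold_beats_deletion_pattern(ref):
    # opposed arms anchored at the right terminus -> SBG_3 even though the
    # duplex covers only part of the genome
    call = classify_read(
        _chain(2000, _seg(0, 1000, 3700, 4700, "-"), _seg(1000, 2000, 3700, 4700, "+")),
        ref)
    assert call.category == "SBG_3"


# ------------------------------------------------------- helper operations

def test_itr_coverage_thresholds(ref):
    # 140 of 144 covered >= 0.9 -> intact; ICG-style chain: right only
    itr5, itr3 = detect_itr_coverage(_chain(200, _seg(0, 140, 0, 140)), ref)
    assert itr5 and not itr3
    itr5, itr3 = detect_itr_coverage(_chain(2700, _seg(0, 2700, 2000, 4700)), ref)
    assert (itr5, itr3) == (False, True)
    itr5, itr3 = detect_itr_coverage(_chain(100, _seg(0, 100, 0, 100)), ref)
    assert not itr5  # 100/144 < 0.9


def test_fold_point_with_junction_gap(ref):
    chain = _chain(1450, _seg(0, 800, 0, 800, "+"), _seg(850, 1450, 0, 600, "-"))
    fold = find_fold_point(chain, ref)
    assert fold == (800, 800, 600, 5)


def test_same_strand_collinear_pair_is_not_a_fold(ref):
    chain = _chain(2200, _seg(0, 1000, 0, 1000), _seg(1000, 2200, 3500, 4700))
    assert find_fold_point(chain, ref) is None


def test_interior_opposed_pair_is_not_a_fold(ref):
    # opposite strands but not anchored at a shared terminus
    chain = _chain(1000, _seg(0, 500, 1000, 1500, "+"), _seg(500, 1000, 1000, 1500, "-"))
    assert find_fold_point(chain, ref) is None


def test_sbg3_annotation_requires_p40(ref):
    short = classify_read(
        _chain(2000, _seg(0, 1000, 3700, 4700, "-"), _seg(1000, 2000, 3700, 4700, "+")),
        ref)
    assert short.annotation == "none"  # arms stop short of P40
    long_arm = classify_read(
        _chain(6000, _seg(0, 3000, 1700, 4700, "-"), _seg(3000, 6000, 1700, 4700, "+")),
        ref)
    assert long_arm.category == "SBG_3" and long_arm.annotation == ANNOTATION_SBG3


def test_icg_call_invariant_is_enforced():
    with pytest.raises(InvalidParameterError):
        ConfigurationCall(read_id="x", category="ICG",
                          itr5_intact=True, itr3_intact=True)


# ----------------------------------------------------- population behavior

def test_error_free_population_recovers_all_labels(ref, clean_pop_1k):
    reads, truth, calls = clean_pop_1k
    assert len(calls) == len(reads)
    assert all(c.category == t.category for c, t in zip(calls, truth))
    sbg = [(c, t) for c, t in zip(calls, truth) if t.category.startswith("SBG")]
    assert all(c.subtype == t.subtype for c, t in sbg)


def test_partition_every_read_gets_one_category(ref, clean_pop_1k):
    _, _, calls = clean_pop_1k
    counts = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    assert sum(counts.values()) == len(calls)
    assert set(counts) <= set(av.CATEGORIES)


def test_strand_symmetry_under_reverse_complement(ref):
    aligner = av.Aligner(ref)
    cases = [av.simulate_canonical(ref, "+"),
             av.simulate_icg(ref, 2000, "+"),
             av.simulate_gdm(ref, 1000, 3500, "+")]
    flip = {"+": "-", "-": "+"}
    for read in cases:
        fwd = classify_read(aligner.segment_read(read), ref)
        read_rc = av.SimRead(read.id, revcomp(read.seq))
        rev = classify_read(aligner.segment_read(read_rc), ref)
        assert rev.category == fwd.category
        assert rev.strand == flip[fwd.strand]
    # snapbacks: revcomp swaps the arms, so category/side/subtype must hold
    sbg = av.simulate_snapback(ref, 5, 1200, 700)
    fwd = classify_read(aligner.segment_read(sbg), ref)
    rev = classify_read(aligner.segment_read(av.SimRead("r", revcomp(sbg.seq))), ref)
    assert (rev.category, rev.subtype) == (fwd.category, fwd.subtype)
    assert {rev.arm_a, rev.arm_b} == {fwd.arm_a, fwd.arm_b}


def test_subtype_threshold_consistency(ref):
    """Classifier subtype equals truth whenever |arm_a - arm_b| is well away
    from the shared symmetric/asymmetric threshold."""
    aligner = av.Aligner(ref)
    params = ClassifyParams()
    for arms in ((900, 900), (1500, 1460), (1200, 900), (800, 1300)):
        read = av.simulate_snapback(ref, 5, *arms)
        call = classify_read(aligner.segment_read(read), ref, params)
        assert call.subtype == read.truth.subtype


def test_classification_is_deterministic(ref):
    cfg = av.SimulationConfig(n_reads=30, seed=21)
    reads, _ = av.simulate_population(ref, cfg)
    a = av.classify_population(reads, ref)
    b = av.classify_population(reads, ref)
    assert a == b
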