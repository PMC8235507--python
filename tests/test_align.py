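import numpy as np
import pytest

import aavsnap as av
from aavsnap._seq import revcomp
from aavsnap.align import Aligner, AlignParams


# ---------------------------------------------------------------- oracle

def _longest_match(read, target):
    """Longest common substring (read pos, target pos, length) by full DP."""
    m, n = len(read), len(target)
    best = (0, -1, -1)  # length, read_start, target_start
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [0] * (n + 1)
        ci = read[i - 1]
        for j in range(1, n + 1):
            if ci == target[j - 1]:
                L = prev[j - 1] + 1
                cur[j] = L
                cand = (L, i - L, j - L)
                # longest; ties -> smallest target start
                if L > best[0] or (L == best[0] and cand[2] < best[2]):
                    best = cand
        prev = cur
    return best


def exact_decomposition(read, ref_seq, min_len):
    """Exhaustive exact-substring decomposition mirroring flank recursion.

    Repeatedly takes the longest exact match against either strand (ties:
    smaller ref_start, then plus strand) and recurses on both flanks.
    Independent of the DP aligner: pure string enumeration.
    """
    segments = []

    def recurse(sub, offset):
        if len(sub) < min_len:
            return
        Lp, rp, tp = _longest_match(sub, ref_seq)
        rc = revcomp(sub)
        Lm, rm_rc, tm = _longest_match(rc, ref_seq)
        cand = []
        if Lp >= min_len:
            cand.append((-Lp, tp, 0, rp, tp, Lp, "+"))
        if Lm >= min_len:
            rm = len(sub) - rm_rc - Lm  # map revcomp coords back to the read
            cand.append((-Lm, tm, 1, rm, tm, Lm, "-"))
        if not cand:
            return
        _, _, _, r0, t0, L, strand = min(cand)
        segments.append((offset + r0, offset + r0 + L, t0, t0 + L, strand))
        recurse(sub[:r0], offset)
        recurse(sub[r0 + L:], offset + r0 + L)

    recurse(read, 0)
    return sorted(segments)


def _chain_tuples(chain):
    return sorted((s.read_start, s.read_end, s.ref_start, s.ref_end, s.strand)
                  for s in chain.segments)


# ----------------------------------------------------------------- tests

def test_exact_substring_alignment(aligner, ref):
    seg = av.local_align(ref.seq[100:600], ref)
    assert (seg.read_start, seg.read_end) == (0, 500)
    assert (seg.ref_start, seg.ref_end, seg.strand) == (100, 600, "+")
    assert seg.identity == 1.0


def test_reverse_complement_maps_to_same_interval(aligner, ref):
    seg = aligner.best_segment(revcomp(ref.seq[100:600]))
    assert (seg.ref_start, seg.ref_end, seg.strand) == (100, 600, "-")


def test_random_queries_produce_no_hit(aligner):
    bases = np.array(list("ACGT"))
    for seed in range(20):
        rng = np.random.default_rng([seed, 4242])
        q = "".join(bases[rng.integers(0, 4, size=500)])
        assert aligner.best_segment(q) is None


def test_non_acgt_characters_never_match(aligner, ref):
    q = list(ref.seq[200:400])
    for pos in (60, 100, 140):
        q[pos] = "N"
    seg = aligner.best_segment("".join(q))
    assert seg is not None and seg.identity < 1.0
    assert seg.read_span >= 190  # Ns are carried as mismatches, not breaks


def test_canonical_read_gives_single_full_segment(aligner, ref):
    chain = aligner.segment_read(av.simulate_canonical(ref, "+"))
    assert len(chain.segments) == 1
    seg = chain.segments[0]
    assert seg.read_span >= 0.99 * ref.length
    assert seg.strand == "+"
    assert chain.uncovered == []


def test_snapback_read_gives_two_opposite_arms(aligner, ref):
    chain = aligner.segment_read(av.simulate_snapback(ref, 5, 800, 800))
    assert _chain_tuples(chain) == [(0, 800, 0, 800, "+"), (800, 1600, 0, 800, "-")]


def test_gdm_read_gives_two_collinear_segments(aligner, ref):
    chain = aligner.segment_read(av.simulate_gdm(ref, 1000, 3500))
    assert _chain_tuples(chain) == [(0, 1000, 0, 1000, "+"),
                                    (1000, 2200, 3500, 4700, "+")]


def test_palindromic_itr_ties_resolve_to_plus_left(aligner, ref):
    """Inside a perfect-palindrome ITR, +/- and left/right scores tie; the
    total order must resolve to the plus strand at the left terminus."""
    seg = aligner.best_segment(ref.seq[:144])
    assert (seg.ref_start, seg.strand) == (0, "+")


def test_segmentation_is_deterministic(aligner, ref):
    cfg = av.SimulationConfig(n_reads=20, seed=3)
    reads, _ = av.simulate_population(ref, cfg)
    a = [_chain_tuples(aligner.segment_read(r)) for r in reads]
    b = [_chain_tuples(aligner.segment_read(r)) for r in reads]
    assert a == b


def test_lower_identity_threshold_never_reduces_coverage(ref):
    cfg = av.SimulationConfig(n_reads=12, sub_rate=0.02, seed=4)
    reads, _ = av.simulate_population(ref, cfg)
    strict = Aligner(ref, AlignParams(min_identity=0.95))
    loose = Aligner(ref, AlignParams(min_identity=0.85))
    for r in reads:
        assert loose.segment_read(r).covered_bases >= \
            strict.segment_read(r).covered_bases


def test_chain_uncovered_tiles_the_read(aligner, ref):
    read = av.simulate_snapback(ref, 5, 900, 500)
    chain = aligner.segment_read(read)
    covered = sum(s.read_span for s in chain.segments)
    gaps = sum(e - s for s, e in chain.uncovered)
    assert covered + gaps == chain.read_length


# mismatches/gaps priced out so the DP optimum is provably the longest
# exact match and the comparison is structural, not data luck
EXACT_PARAMS = AlignParams(min_segment_len=20, mismatch=-999,
                           gap_open=-999, gap_extend=-999)


@pytest.mark.parametrize("builder", [
    lambda t: t[50:200],                          # exact interior substring
    lambda t: revcomp(t[100:260]),                # minus-strand substring
    lambda t: t[0:80] + revcomp(t[0:60]),         # fold-back
    lambda t: t[0:90] + t[210:300],               # internal deletion
    lambda t: revcomp(t[150:290]) + t[10:120],    # inverted junction
])
def test_segment_read_matches_exact_decomposition(toy_ref, builder):
    """On error-free reads over a small target, the recursive DP segmentation
    equals the exhaustive exact-substring decomposition."""
    read = builder(toy_ref)
    chain = Aligner(toy_ref, EXACT_PARAMS).segment_read(read)
    assert _chain_tuples(chain) == exact_decomposition(read, toy_ref, 20)


def test_random_read_empty_in_both_decompositions(toy_ref):
    rng = np.random.default_rng(99)
    read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=300)])
    chain = Aligner(toy_ref, EXACT_PARAMS).segment_read(read)
    oracle = exact_decomposition(read, toy_ref, 20)
    assert _chain_tuples(chain) == oracle == []
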