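import numpy as np
import pytest

import aavsnap as av
from aavsnap._seq import revcomp
from aavsnap.errors import InvalidParameterError

CLEAN = dict(sub_rate=0.0, ins_rate=0.0, del_rate=0.0)


def test_canonical_payloads_are_the_reference(ref):
    assert av.simulate_canonical(ref, "+").seq == ref.seq
    assert av.simulate_canonical(ref, "-").seq == revcomp(ref.seq)


def test_canonical_strands_packaged_equally():
    small = av.build_reference(av.ReferenceConfig(length=1300, itr_length=60))
    rng = np.random.default_rng(0)
    n = 10_000
    plus = sum(av.simulate_canonical(small, rng=rng).truth.strand == "+"
               for _ in range(n))
    sigma = (n * 0.25) ** 0.5
    assert abs(plus - n / 2) <= 3 * sigma


@pytest.mark.parametrize("side,arm_a,arm_b,subtype", [
    (5, 800, 800, "SYMMETRIC"),
    (5, 800, 600, "ASYMMETRIC"),
    (3, 1000, 1000, "SYMMETRIC"),
])
def test_snapback_payload_geometry(ref, side, arm_a, arm_b, subtype):
    read = av.simulate_snapback(ref, side, arm_a, arm_b)
    L = ref.length
    assert len(read.seq) == arm_a + arm_b
    if side == 5:
        assert read.seq == ref.seq[:arm_a] + revcomp(ref.seq[:arm_b])
        # the fold: the two arms are complementary over their shared prefix
        m = min(arm_a, arm_b)
        assert read.seq[:m] == revcomp(read.seq[len(read.seq) - m:])
    else:
        assert read.seq == revcomp(ref.seq[L - arm_a:]) + ref.seq[L - arm_b:]
    assert read.truth.subtype == subtype
    assert read.truth.subtype == ("SYMMETRIC" if abs(arm_a - arm_b) <= 100
                                  else "ASYMMETRIC")


def test_snapback_3_contains_cap_portion(ref):
    read = av.simulate_snapback(ref, 3, 1000, 1000)
    cap = ref.feature("CAP_ORF")
    assert ref.seq[max(cap.start, ref.length - 1000):cap.end] in read.seq


def test_snapback_rejects_oversized_arm(ref):
    with pytest.raises(InvalidParameterError):
        av.simulate_snapback(ref, 5, ref.length + 1, 100)


def test_icg_payload_is_right_anchored_suffix(ref):
    read = av.simulate_icg(ref, breakpoint=2000)
    assert len(read.seq) == 2700
    assert read.seq == ref.seq[2000:]
    itr_r = ref.feature("ITR_RIGHT")
    assert ref.seq[itr_r.start:itr_r.end] in read.seq   # intact retained ITR
    assert not read.seq.startswith(ref.seq[:50])        # never reaches the other ITR
    with pytest.raises(InvalidParameterError):
        av.simulate_icg(ref, breakpoint=50)  # inside the left ITR


def test_gdm_payload_lengths_and_bounds(ref):
    read = av.simulate_gdm(ref, 1000, 3500)
    assert len(read.seq) == 1000 + 1200
    assert read.seq == ref.seq[:1000] + ref.seq[3500:]
    with pytest.raises(InvalidParameterError):
        av.simulate_gdm(ref, 100, 500)  # overlaps the left ITR


def test_other_reads(ref):
    rng = np.random.default_rng(1)
    read = av.simulate_other(rng, 1500)
    assert len(read.seq) == 1500
    with pytest.raises(InvalidParameterError):
        av.simulate_other(rng, 0)


def test_apply_errors_identity_at_zero_rates(ref):
    rng = np.random.default_rng(0)
    assert av.apply_errors(ref.seq, 0, 0, 0, rng) == ref.seq


def test_apply_errors_substitution_rate_is_binomial():
    seq = "A" * 10_000
    subs = []
    for seed in range(100):
        rng = np.random.default_rng(seed)
        out = av.apply_errors(seq, 0.01, 0.0, 0.0, rng)
        subs.append(sum(b != "A" for b in out))
    mean = np.mean(subs)
    sigma = (10_000 * 0.01 * 0.99 / 100) ** 0.5
    assert abs(mean - 100) <= 3 * sigma


def test_apply_errors_net_deletion_shrinks_reads():
    seq = "ACGT" * 2500
    rng = np.random.default_rng(3)
    lengths = [len(av.apply_errors(seq, 0.0, 0.002, 0.01, rng)) for _ in range(50)]
    assert np.mean(lengths) < len(seq)


def test_population_quota_counts(ref):
    cfg = av.SimulationConfig(n_reads=1000, seed=5, **CLEAN)
    reads, truth = av.simulate_population(ref, cfg)
    assert len(reads) == len(truth) == 1000
    counts = {}
    for t in truth:
        counts[t.category] = counts.get(t.category, 0) + 1
    assert counts == {"CANONICAL": 400, "SBG_5": 150, "SBG_3": 100,
                      "ICG": 200, "GDM": 100, "OTHER": 50}


def test_population_reconstructs_from_truth(ref):
    """Error-free payloads are an exact function of their truth records."""
    cfg = av.SimulationConfig(n_reads=60, seed=9, **CLEAN)
    reads, _ = av.simulate_population(ref, cfg)
    L = ref.length
    for r in reads:
        t = r.truth
        if t.category == "CANONICAL":
            expect = ref.seq
        elif t.category == "SBG_5":
            expect = ref.seq[:t.arm_a] + revcomp(ref.seq[:t.arm_b])
        elif t.category == "SBG_3":
            expect = revcomp(ref.seq[L - t.arm_a:]) + ref.seq[L - t.arm_b:]
        elif t.category == "ICG":
            expect = ref.seq[t.breakpoint:]
        elif t.category == "GDM":
            expect = ref.seq[:t.del_start] + ref.seq[t.del_end:]
        else:
            continue
        assert r.seq == (expect if t.strand == "+" else revcomp(expect))


def test_population_fastq_is_byte_identical_for_same_seed(ref, tmp_path):
    cfg = av.SimulationConfig(n_reads=50, seed=13)
    av.simulate_population(ref, cfg, out_prefix=tmp_path / "a")
    av.simulate_population(ref, cfg, out_prefix=tmp_path / "b")
    assert (tmp_path / "a.fastq").read_bytes() == (tmp_path / "b.fastq").read_bytes()
    truth_a = (tmp_path / "a.truth.tsv").read_text().splitlines()
    assert len([l for l in truth_a if not l.startswith("#")]) == 50


def test_population_proportions_converge(ref):
    small = av.build_reference(av.ReferenceConfig(length=1300, itr_length=60))
    cfg = av.SimulationConfig(
        n_reads=10_000, seed=17, quota=False,
        proportions=(("CANONICAL", 0.5), ("ICG", 0.5)),
        breakpoint_margin=50, **CLEAN)
    _, truth = av.simulate_population(small, cfg)
    n_can = sum(t.category == "CANONICAL" for t in truth)
    sigma = (10_000 * 0.25) ** 0.5
    assert abs(n_can - 5000) <= 3 * sigma


def test_bad_proportions_rejected():
    with pytest.raises(InvalidParameterError):
        av.SimulationConfig(proportions=(("CANONICAL", 0.5), ("ICG", 0.4)))
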