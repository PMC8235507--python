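# aavsnap

Single-virion analysis of adeno-associated virus (AAV) genome configurations
from HiFi-like long reads.

Wild-type and recombinant AAV preparations are heterogeneous: alongside
canonical ~4.7 kb single-stranded genomes flanked by two inverted terminal
repeats (ITRs), virions package a zoo of aberrant molecules — classically
lumped together as defective interfering (DI) particles. Because each
high-accuracy circular-consensus read is one packaged molecule, long-read
sequencing can resolve this population particle by particle. `aavsnap`
implements that analysis as a tested pipeline for anyone studying AAV
populations, DI particles, or vector preparations:

* a **synthetic reference** generator — a 4700 nt AAV-like genome with
  perfect-palindrome GC-rich ITRs and the P5/P19/P40 + rep/cap layout;
* a **population simulator** producing labeled HiFi-like reads for the major
  configuration classes: canonical genomes (both strands packaged equally),
  5′- and 3′-**snapback genomes** (SBG — the covalent fold-back strand
  `arm ++ revcomp(arm)` anchored at one terminus; symmetric or asymmetric),
  **incomplete genomes** (ICG — an intact 3′ITR plus coding sequence that
  never reaches the other ITR), **genome deletion mutants** (GDM — both ITRs,
  interior lost), and foreign-DNA reads;
* the **iterative fragment-alignment loop**: affine-gap local alignment of
  each read against both reference strands, recursing on the unmatched left
  and right flanks until nothing qualifying remains;
* a **configuration classifier** turning each segment chain into a call
  (category, subtype, strand, fold point, arm lengths, ITR intactness,
  breakpoint or deletion, and a regulatory-potential annotation for
  snapbacks covering P5 or P40);
* **population statistics**: composition, ICG:SBG ratio, arm-asymmetry
  histogram, multi-run read accounting, and a chi-square test of ICG
  breakpoint uniformity (the formal version of "no packaging hot spots").

## The core procedure

For a read *r* and reference *G*, the segmentation is

```
segment(r):
    s <- best local alignment of r to G or revcomp(G)   (affine-gap DP)
    if s qualifies (span >= 50 nt, identity >= 0.85):
        record s; segment(r[0 : s.read_start]); segment(r[s.read_end :])
```

and the resulting chain is classified by a first-match decision tree:
one near-full-cover segment → CANONICAL; two adjacent opposite-strand
segments whose reference intervals share a terminus → SBG (5′ or 3′ by the
terminus; symmetric iff |arm_a − arm_b| ≤ 100 nt); one segment retaining
exactly one terminal ITR → ICG (the retained ITR is the packaging-origin
3′ITR, so every ICG has an intact 3′ITR and no 5′ITR); collinear same-strand
segments around an interior gap ≥ 50 nt with both ITRs → GDM; else OTHER.

## Worked example

```
$ python analysis/01_simulate_population.py --seed 1
reference: 4700 nt, ITRs 144 nt
simulated 2000 reads -> scratch/population/pop.fastq
  CANONICAL    800
  SBG_5        300
  ...
$ python analysis/02_classify_reads.py
QC: kept 1814 of 2000 reads (90.7%)
classified configuration calls:
  CANONICAL    720
  SBG_5        274
  SBG_3        183
  ICG          359
  GDM          188
  OTHER         90
$ python analysis/03_population_summary.py
run accounting: {'run1': 220645, 'run2': 189274} -> total 409919
population of 1814 calls
  ICG:SBG ratio = 0.786 (359 ICG / 457 SBG)
  symmetric fraction among SBGs = 0.637
  ICG breakpoints: chi2=21.4 df=19 p=0.313 -> consistent with uniform (no hot spots)
```

Reading this: of 2000 simulated virions, 186 failed the consensus-quality
gate (passes ≥ 3 and predicted accuracy ≥ 0.99); every retained read was
classified into exactly one configuration class, recovering the simulated
mixture; ICG truncation points show no positional hot spots (chi-square over
20 equal-width bins of the breakpoint support, p = 0.31), consistent with
incomplete packaging being a random event. `analysis/04_recovery_benchmark.py`
prints category/subtype recovery rates against the known truth labels and
writes the confusion matrices under `results/`.

The same stages are available as a CLI (`aavsnap simulate | qc | classify |
report | run | fixtures`) and as plain library calls
(`aavsnap.simulate_population`, `aavsnap.classify_population`, ...).

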