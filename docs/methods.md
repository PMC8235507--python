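# Methods

## Problem and model

An AAV virion packages one single-stranded DNA molecule. Sequencing each
packaged molecule as one high-accuracy consensus read turns population
heterogeneity into a per-read classification problem: every read is the
covalent strand of exactly one molecular configuration, and the configuration
is recoverable from how the read decomposes into locally aligned fragments of
the reference genome.

The configuration classes modeled here, and their error-free read payloads
for a reference `G` of length `L`:

| class      | payload (plus strand)                        | signature after segmentation |
|------------|----------------------------------------------|------------------------------|
| CANONICAL  | `G`                                          | one segment covering ~all of `G` |
| SBG_5      | `G[0:a] ++ revcomp(G[0:b])`                  | two opposite-strand segments, both reference intervals anchored at coordinate 0 |
| SBG_3      | `revcomp(G[L-a:L]) ++ G[L-b:L]`              | same, anchored at `L` |
| ICG        | `G[bp:L]`                                    | one segment touching exactly one terminal ITR |
| GDM        | `G[0:ds] ++ G[de:L]`                         | two collinear same-strand segments around a reference gap |
| OTHER      | uniform-random DNA                           | no qualifying segment |

Minus-strand molecules are the reverse complements of these strings. For a
snapback, the reverse complement of `arm_a ++ revcomp(arm_b)` is
`arm_b ++ revcomp(arm_a)` — the same molecule with the arms written in the
other order — so snapback "strand" is a labeling convention, not a
measurable property; category, side and subtype are.

## Reference model

The synthetic reference is 4700 nt: two identical 144 nt terminal repeats and
a uniform-random interior. Each repeat is a perfect palindrome
(`revcomp(s) == s`, even length) with GC fraction fixed at 0.7, capturing the
two properties that matter downstream: palindromy (a fold-back arm re-aligns
to the same terminal interval on either strand, so strand calls inside an ITR
are ties) and terminal self-complementarity. Feature layout (fractions of
4700): P5 at 0.055, P19 at 0.19, P40 at 0.38 (40 nt promoter intervals),
rep ORF [0.06, 0.48), cap ORF [0.45, 0.95). This preserves the operative
geometry — P5/rep in the left moiety so 5′-snapbacks carry them, P40/cap in
the right moiety so 3′-snapbacks carry them. Real AAV2 ITRs are ~145 nt
imperfect hairpins with flip/flop orientations; hairpin structure, rep-binding
motifs and ITR imperfection are deliberately out of scope, and no claim is
made about real AAV2 annotation coordinates.

## Read simulation

Default mixture (per-category quota with largest-remainder rounding;
multinomial draw available): CANONICAL 0.40, SBG_5 0.15, SBG_3 0.10,
ICG 0.20, GDM 0.10, OTHER 0.05. The published population composition is only
schematic, so these proportions are illustrative study conditions, not
estimates.

* Canonical strands are packaged 50/50.
* Snapback arms are Uniform(300, 2300) nt. Half the snapbacks are drawn
  near-symmetric (arm difference Uniform(−50, 50)); the rest get a geometric
  loop (mean 300 nt) of random sign. Truth subtype is then labeled from the
  *realized* arms: SYMMETRIC iff |arm_a − arm_b| ≤ 100 nt (`sym_tol`; the
  literature gives no numeric cutoff, so simulator and classifier share this
  parameter). The asymmetric loop is modeled purely as arm inequality — no
  non-templated loop sequence is inserted.
* ICG breakpoints are Uniform over the interior minus a 200 nt guard beyond
  each ITR (incomplete packaging as a random event); reads are right-anchored
  on the plus strand, minus-strand ICGs are their reverse complements.
* GDM deletion endpoints are uniform over the guarded interior with a 200 nt
  minimum deletion.
* Residual consensus errors: substitution 0.3%, insertion 0.1%, deletion
  0.1% per base, independent — small residuals consistent with a ≥ 0.99
  predicted-accuracy consensus gate. Consensus generation itself (polymerase
  passes, subreads) is not simulated; pass counts and predicted accuracies
  are drawn so that a configurable fraction (default 10%) fails QC.

What the simulator does **not** emulate: context-dependent or clustered
errors, chimeric host/helper junction structure (OTHER is plain random DNA),
ITR secondary-structure artifacts, length-dependent loading bias. Passing
tests therefore demonstrate correctness of the segmentation/classification
machinery under realistic error *rates*, not robustness to every real-data
artifact.

## QC

Inclusive thresholds, matching "min" semantics: keep reads with
passes ≥ 3 **and** predicted accuracy ≥ 0.99; boundary reads are kept.
Length stratification uses half-open 500 nt bins covering the genome length,
with an explicit `unbinned` bucket so binning partitions the input.

## Segmentation

`segment_read` aligns the read locally against both reference strands,
records the best qualifying hit (read span ≥ 50 nt, identity ≥ 0.85,
identity = matches / alignment columns), and recurses independently on the
unaligned left and right flank subsequences (recursion depth ≤ 6). Flanks are
disjoint by construction, so segments never overlap in read coordinates and
the chain plus its uncovered intervals tile the read.

The DP is an affine-gap local alignment (match +2, mismatch −4, first gap
base −4, each further gap base −2 — megablast-like defaults; all
user-tunable). Implementation details that affect results:

* **Seeded banding.** Exact 13-mers between query and reference are chained
  by diagonal (chains split at diagonal jumps > 30); the banded DP runs over
  the chain's diagonal range padded by 40. Up to two chains per strand are
  evaluated. Reads with no seed chains (foreign DNA) fall back to a full
  score-only DP; if its optimum could possibly qualify, a banded traceback
  (half-width 250) recovers the alignment. With ≤ 0.5% errors the diagonal
  drift of a true alignment is far below the band width, so the banded
  optimum equals the full-DP optimum in this regime; the oracle-equivalence
  test checks the segmentation against exhaustive exact-substring
  decomposition on a small target.
* **Gap splitting.** A traceback containing a single gap run ≥ 50 nt
  (`split_gap`) is split into separate segments at that run. Without this, a
  deletion mutant with long flanks would be bridged by the DP into one
  "full-length" segment and misread as canonical. 50 nt matches the
  classifier's `min_del`, so sub-threshold gaps stay inside one segment
  (treated as noise) exactly where the classifier would merge them anyway.
* **Tie-breaking.** Candidate order is total: higher score, then longer read
  span, then smaller ref_start, then plus strand before minus. Within one DP,
  equal-score optima resolve to the first cell in row-major order. Both rules
  exist for determinism; inside a perfect-palindrome ITR, plus/minus scores
  tie and resolve to plus, and classification never depends on strand calls
  made inside an ITR.
* Non-ACGT characters are encoded as N and never match (carried as
  mismatches, not alignment breaks).

## Classification

Before the decision tree, adjacent same-strand collinear segments separated
by read and reference gaps < `min_del` (50 nt) are merged — small gaps are
alignment noise. Decision tree, first match wins:

1. no segments → OTHER;
2. one merged segment covering ≥ 0.95 of the reference including both ITRs
   (ITR intact = ≥ 0.9 of its interval covered) → CANONICAL;
3. fold point → SBG_5/SBG_3: adjacent opposite-strand segments with read gap
   ≤ 50 nt whose reference intervals both end within 50 nt (`anchor_tol`) of
   the same terminus; arms are the two reference spans, fold point the read
   coordinate between them; best = longest combined arms;
4. one segment retaining exactly one terminal ITR → ICG. Packaging initiates
   at the 3′ITR, so the retained ITR *is* the 3′ITR whichever reference
   terminus it maps to: every ICG call has `itr3_intact` and not
   `itr5_intact` by construction, and a left-anchored single-ITR chain (not
   produced by the simulator, but possible adversarially) is reported with
   the strand flipped. Breakpoint = the interior end of the covered interval
   in plus-strand coordinates.
5. ≥ 2 collinear same-strand segments, both ITRs intact, largest internal
   reference gap ≥ 50 nt → GDM (deletion = largest gap; additional
   sub-threshold gaps are noise, additional qualifying gaps are counted in
   `n_gaps` but the call remains GDM);
6. otherwise OTHER (this includes truncated molecules retaining neither ITR:
   an ICG is *defined* by its intact 3′ITR).

Priorities put more specific evidence first (full-length cover beats a fold;
a fold beats truncation/deletion patterns), so a hypothetical folded-and-
deleted chimera classifies as SBG. Category thresholds (`itr_cover_frac`
0.9, `full_genome_frac` 0.95, `anchor_tol` 50, `sym_tol` 100, `min_del` 50,
`max_junction_gap` 50) are explicit parameters with these defaults because
the source analysis defines the categories qualitatively; none of them is
claimed to be the original authors' value. Snapbacks are typed by anchor
side; promoter content is then used only for the annotation
(SBG_5 covering P5 → "tail-to-tail-dimer; dsRNA-capable; predicted Rep78
down-regulation"; SBG_3 covering P40 → "head-to-head-P40; double-enhancer;
predicted cap up-regulation" — structural rules only, no expression model).

## Population statistics

The summary reports per-category counts/fractions, read-length quartiles,
symmetric fraction among snapbacks, the ICG:SBG ratio (reported as ICG/SBG
with both raw counts always emitted), per-run read accounting, and the
breakpoint-uniformity test: a Pearson chi-square of ICG breakpoints over 20
equal-width bins of the breakpoint support against the uniform expectation,
merging bins with expected count < 5 into a neighbor (df = bins − 1). Twenty
bins keep expected counts ≥ 5 for n ≥ 100. The test interval must be the
support of the breakpoint process: when summarizing simulated data the
200 nt generator guard is passed through (`breakpoint_interval`), otherwise
the two edge bins are spuriously depleted and the test rejects a truly
uniform process.

Degenerate inputs: an empty population yields a summary with `n_reads = 0`
and absent statistics; fewer than 2 usable bins raises; an empty chain is a
valid (OTHER) classification result, never an error.

## Problem sizes and determinism

The test suite exercises error-free recovery at n = 1000 (quota mixture,
100% category and subtype recovery required), default-error recovery and the
ICG ITR invariant at n = 10,000 (≥ 95% category, ≥ 90% subtype, zero
invariant violations), uniformity calibration with 500 replicates of 1000
breakpoints (observed type-I rate at α = 0.01 allowed 3 binomial sigmas
around 1%), and the acceptance script re-runs the pipeline at n = 1000
(clean) and n = 2000 (default errors) with 300 calibration replicates.
Every stochastic component takes a numpy `Generator` or an integer seed;
identical seeds give byte-identical FASTQ/TSV/JSON outputs. TSV and JSON
outputs begin with a provenance header (tool version, seed, config hash);
FASTQ cannot carry comments, so its provenance lives in the sidecar
metadata TSV.

## Known limitations

* The aligner is specialized to a ~5 kb reference: exact DP with seeding,
  no E-values, no spliced or long-gap model. It is not a general-purpose
  long-read mapper.
* Banded alignment is exact only while the true alignment stays inside the
  band; pathological inputs (error rates far above the QC gate, highly
  repetitive non-ITR references) could clip an optimum.
* OTHER is a single bucket: host/helper chimeras are neither simulated
  structurally nor sub-classified.
* Snapback strand identity is conventional (see above); strand-flip
  invariance is asserted for canonical/ICG/GDM only.
* Real-population quantities (composition, the published ICG:SBG value, GDM
  size distribution) require the deposited sequencing data; this package
  reproduces the machinery and its property-level behavior on synthetic
  populations with known truth.
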