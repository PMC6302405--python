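# Methods

## Problem and model

Paired-end Illumina reads of a short DNA fragment overlap in the middle (or,
for fragments shorter than the read length, run past each other into adapter
sequence — a *dovetailed* pair). `pairstitch` merges such pairs into a single
read spanning the fragment, which requires three models:

1. **Overlap alignment.** Every gapless placement of reverse-complemented R2
   against R1 is scored exhaustively. A placement is valid if its overlap is
   at least `min_overlap` (default 20 bp) columns and its mismatch fraction
   is at most `max_mismatch_frac` (default 0.1); among valid placements the
   lowest mismatch fraction wins. Ambiguous bases (N) count as neither
   matches nor mismatches: they are excluded from both the numerator and the
   denominator of the mismatch fraction, but they do count toward the
   geometric overlap length (overlap length describes the placement, not the
   sequence content). Dovetailed placements (negative offsets, or an R1
   3' overhang beyond R2's 5' end) are searched only when requested
   (`-d`) or in adapter-removal mode, where they are the entire point.

2. **Base resolution.** In the overlap, agreeing bases are kept; disagreeing
   bases are resolved to the higher-quality base; a single N is replaced by
   the mate's call at the mate's own quality; two Ns stay N. When two
   different bases carry *equal* quality there is no evidence favouring
   either, so the merged base is N — the merger does not invent evidence.

3. **Merged-base quality.** The probability that a merged base is wrong is
   not well predicted by combining the two claimed Phred scores
   (`Q = -10 log10 P`) under an independence assumption, because paired-read
   errors share a common mode: an error made while the fragment is first
   copied on the flow cell (first-strand synthesis) propagates through the
   whole cluster and appears in *both* reads at full quality. Three schemes
   are provided:
   * `fastqjoin` (default): match → max(q1, q2), mismatch → |q1 − q2|.
     Simple and conservative.
   * `sum`: match → q1 + q2, the value implied by independence; mismatch →
     max(q1, q2) (no reduction). Included for comparison; its mismatch rule
     is our approximation of merge tools that do not penalise mismatches,
     since no exact formula is published for them.
   * `matrix`: empirical match/mismatch lookup tables trained from
     truth-annotated data (below). This is the scheme the training pipeline
     exists for.

   Output qualities are capped (`-u`; default 40 for fastqjoin/matrix, 80
   for sum) and real (non-N) merged bases are floored at Q2; Q0/Q1 are left
   for ambiguous calls, and Q2 is the conventional floor of the Illumina
   scale. The two-N and equal-quality-tie cases emit the raw scheme value
   (0 for the fastqjoin difference rule) on an N base.

## Profile training

Training data is any set of merged reads with per-base truth: here, the
bundled simulator (the package's study conditions), in general SAM
alignments of PhiX control reads against the corrected reference.

* Every overlap column is tallied by `(q1, q2, match/mismatch)` and by
  whether the merged base matches the truth. Columns involving an input N,
  or resolved to N, are excluded.
* Counts become rates; a zero-error cell receives a pseudo-error count of
  0.5 (rate 0.5/count). Match cells with fewer than 1000 observations and
  mismatch cells with fewer than 100 are masked and left to the smoother.
* A **baseline profile** — local regression (lowess) of log10(error rate)
  on quality for the *original* reads — maps observed rates back to
  calibrated quality scores. The smoothed curve is projected onto the
  strictly-decreasing cone (isotonic regression) so it is invertible;
  outside the fitted range both directions extend linearly with the
  terminal slope. The local-regression span defaults to 30% of the points
  (raised automatically so a window never holds fewer than ~3 points).
* Each 2-D rate table is smoothed by a local linear regression with
  tricube weights over the span-nearest cells, evaluated on the full
  covered quality grid; smoothed rates pass through the baseline inverse
  and are clamped to [2, cap]. The match matrix is symmetrized by averaging
  (q1,q2) with (q2,q1) before rounding — the two reads are physically
  interchangeable. The mismatch matrix is *not* symmetrized: there (q1,q2)
  encodes which read supplied the surviving base.

Under independent errors with substitutions uniform over the three
alternative bases, the exact match-class error rate is p1·p2/3 — both reads
must err *and* agree — so the calibrated entry is q1 + q2 + 10·log10(3) ≈
q1 + q2 + 4.8 before capping. Unit tests verify this analytic value on
exact rate tables; with the default cap of 40 all realistic high-count
cells sit at the cap. With shared first-strand errors at rate ρ the match
error rate floors at ≈ρ regardless of the claimed scores. The single-read
baseline carries the same floor, so the calibrated match entries stay in
the low 40s across the whole grid instead of climbing toward the
independence prediction of q1 + q2 (80 at two Q40 bases, an error-rate
overstatement of more than four orders of magnitude) — this is why
empirically trained matrices never rise far above Q40, and the package's
simulations reproduce the collapse.

## Simulator

The generator emulates what matters for merging: truncated-normal fragment
lengths (default mean 150, sd 20, truncated to [40, 400]) sampled from a
random or user reference; 2 × 100 bp reads; standard TruSeq adapter
read-through on fragments shorter than the read length; per-cycle qualities
(default: linear 38 → 27 ramp with sd-2 integer noise, clamped to [2, 41] —
a realistic 2×100 profile; `constant` and discrete `levels` modes exist for
controlled experiments); independent substitution errors injected at exactly
10^(−q/10) per base, uniform over the three alternatives; optional N-masking;
and shared first-strand errors written into the fragment template itself at
per-base rate ρ before either read is taken, so both reads inherit the same
wrong base at unreduced quality. Each pair's random stream derives from
(seed, pair index): output is byte-identical for a seed and stable under
growth of `n_pairs`.

It does not model indels, optical duplicates, PCR amplification errors,
per-tile artefacts, or instrument-specific quality distributions (NextSeq
two-channel chemistry in particular). Tests passing on simulator output
therefore demonstrate the correctness of the algorithms and the stated
error-structure mechanisms, not instrument-calibrated absolute rates.

## Reference utility

The bundled NC_001422.1 phiX174 genome (5386 bp) is corrected with the five
consistently observed variants (587 G→A, 833 G→A, 2731 A→G, 2811 C→T,
3133 C→T) and circularly extended by its first 1 kb to 6386 bp, so that
fragments spanning the origin align contiguously. `apply_variants` verifies
the expected reference base at every edit position before substituting.

## Numerical and design choices

* Offsets are 0-based; intervals half-open. Alignment ties (equal mismatch
  fraction) prefer the larger overlap, then the smaller |offset| —
  deterministic, and the physically longer explanation first.
* The production aligner computes all offsets at once via per-base
  indicator cross-correlations; the per-offset scalar scorer remains the
  public reference API, and tests assert the two are identical.
* Degenerate training inputs fail loudly: fewer than 5 usable quality
  levels is a baseline fit error (with a pointer to the theoretical
  10^(−q/10) relation), a fully masked rate table is a build error, and a
  flat baseline degenerates to a near-constant profile with a warning.
* Matrix lookups are exact: a (q1, q2) outside the trained range raises
  rather than extrapolating silently.
* Problem sizes in the test suite: alignment oracle checks run on 1000
  pairs; the error-correction direction check on 50,000 pairs (~2.5M
  overlap bases); profile training on ~26,000 pairs (~1.2M overlap
  columns), enough for the highest-count quality cells to exceed 10,000
  observations. Training runs use binned quality levels (27/31/34/37/40),
  mirroring the discrete Q-score bins real base callers emit; a continuous
  noisy ramp never places Q40 cycles inside overlaps (overlaps occupy the
  reads' 3' ends), which would leave the (40,40) cell untrainable. At
  ~10⁶-column scale the mismatch-cell count threshold is set to 10 rather
  than its default 100 — the default presumes the billions of aligned
  bases of full control datasets, and 10 preserves the intent (mask cells
  whose rate is dominated by sampling noise) at a thousandfold smaller run.

## Context from real-instrument studies (not recomputed here)

Published PhiX analyses report that, after reference correction, claimed
quality tracks observed quality closely (claimed Q40 ≈ effective Q38.6);
that ~96.7% of overlap bases agree between mates; and that sum-style
schemes' Q80 bases show error rates around 1.3–1.8 × 10⁻⁴, four orders of
magnitude above the 10⁻⁸ the score claims. Those numbers require
instrument data this package does not ship; they are context for why the
empirical (matrix) scheme exists, not quantities this package recomputes.
The packaged example matrices under `src/pairstitch/data/` are trained on
the package's own simulator output and are labelled synthetic; they are
illustrative defaults, not instrument calibrations.
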