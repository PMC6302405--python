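# pairstitch

Merging overlapping paired-end Illumina reads into single reads that span
the original DNA fragment — with merged-base quality scores that actually
reflect error rates.

## The problem

When a sequencing library's fragments are shorter than twice the read
length, the two reads of a pair overlap; if a fragment is shorter than one
read length, each read runs past its mate's start into adapter sequence (a
*dovetailed* pair). Merging the pair recovers the full fragment and lets
the overlap correct errors — but assigning a quality score to a merged base
is subtle. A Phred score encodes Q = −10·log₁₀ P(base wrong). If the two
reads' errors were independent, two agreeing Q40 bases would deserve
Q40 + Q40 = 80 (P = 10⁻⁸). They are not independent: an error made during
first-strand synthesis on the flow cell propagates through the whole
cluster and appears in **both** reads at full quality, so empirical
combined error rates floor near the shared-error rate and measured merged
qualities never rise far above 40.

`pairstitch` is a library and command-line tool for scientists working
with paired-end data (amplicon/metabarcoding, targeted resequencing,
control-library QC) that implements:

* **stitch mode** — exhaustive gapless overlap alignment (all offsets,
  dovetail-aware; minimum overlap 20 bp, ≤10% mismatches in the overlap,
  Ns count as neither match nor mismatch) and merging with pluggable
  quality schemes: `fastqjoin` (max / difference), `sum` (q1+q2,
  independence-assuming), or empirically trained `matrix` profiles;
* **adapter mode** — clip the 3′ adapter overhangs of dovetailed pairs
  without merging;
* **profile training** — tally merged-base errors by (q1, q2,
  match/mismatch) against per-base truth, smooth log₁₀ rates (1-D lowess
  baseline, 2-D tricube local regression), and back-transform through the
  baseline into integer match/mismatch quality matrices;
* **error statistics** — per-quality-score error rates from SAM
  alignments, plus the corrected, circularly extended phiX174 reference
  (NC_001422.1 with its five consistently observed variants, extended by
  1 kb to 6386 bp);
* **a truth-tracking simulator** — quality-aware paired reads with
  adapters, independent Phred-rate errors, N-masking, and correlated
  first-strand errors, so every stage above is testable without any
  external data.

See `docs/methods.md` for the models, parameters, and limitations.

## Worked example

```sh
pairstitch simulate -o run --n-pairs 2000 --seed 7 --n-rate 0.002
pairstitch stitch -1 run_1.fastq -2 run_2.fastq \
    -o merged.fastq -f failed -d -j events.tsv
```

prints (to stderr):

```
pairs: 2000  merged: 1868  failed: 132  Ns corrected: 428
```

2000 simulated pairs (fragments ~N(150, 20) bp, 2×100 bp reads): 1868
merge — the 132 failures are fragments longer than ~180 bp, whose overlap
falls below the 20-bp minimum and which are written to `failed_[12].fastq`
as intact pairs — and 428 overlap columns where one read called N were
restored from the mate. `events.tsv` logs every overlap disagreement:

```
read_id  position  r1_base  r1_qual  r2_base  r2_qual  chosen_base  chosen_qual  class
sim1/1   68        A        27       T        28       T            2            mismatch
sim11/1  71        T        30       A        30       N            0            mismatch
```

At position 68 the bases disagreed and the Q28 call won with merged
quality 28 − 27 = 2 (the fastq-join-style difference rule, floored at 2);
at position 71 the conflicting calls carried *equal* quality, so no
evidence favours either base and the merged base is N.

Train a quality profile from simulator truth and merge with it:

```sh
pairstitch profile -1 run_1.fastq -2 run_2.fastq --truth run_truth.tsv \
    -o prof --min-match 200 --min-mismatch 10
pairstitch stitch -1 run_1.fastq -2 run_2.fastq -o merged2.fastq -d \
    -w prof.match.tsv -x prof.mismatch.tsv
```

A synthetic example profile trained on simulator output ships with the
package (`pairstitch.quality.example_matrix_model()`); it is illustrative,
not an instrument calibration.

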