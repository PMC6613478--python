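# Methods

This note documents the models and procedures implemented in `cagecall`,
the parameter defaults and the reasoning behind the open design choices.

## Coordinates and input model

All internal coordinates are 0-based half-open (BED/BigWig convention);
a CTSS at basepair `p` is the interval `[p, p+1)`.  1-based inclusive
coordinates appear only in printed cluster names (`chr1:101-200;+`) and
at annotation I/O (GTF).  Input is one stranded track pair per sample,
BigWig or 4-column bedGraph, holding integral per-basepair 5'-end
counts.  Minus-strand tracks may store counts as negative values (a
common CAGE dialect); the reader takes absolute values.  Values that are
non-integral beyond 1e-6, or positions on chromosomes absent from the
supplied `chrom.sizes`, are hard errors.

The multi-sample CTSS table is sparse: a position table sorted by
(chromosome, strand, position) plus a CSR count matrix whose column
order is fixed by the design table.  TPM normalization divides by the
library size `L_j` (total mapped 5' ends per sample), and the pooled
signal is the per-position TPM sum over samples.  "Support" counts
samples strictly exceeding a threshold, mirroring the "expressed at
more than x" convention; all support-style filters in the package use
strict `>` against the threshold and `>=` against the sample count.

## Tag clustering (TSS candidates)

Slice-reduce on the pooled signal, per chromosome and strand: keep
positions with `pooled > cutoff` (default cutoff 0, i.e. no
pre-threshold), merge kept neighbours `p < q` when `q − p <= mergeDist`
(default 20 bp), and span the outermost members half-open.  The peak is
the member with maximal pooled signal, leftmost on ties, which makes
output independent of record order.  Cluster score = sum of member
pooled values.  Defaults for the support filter are > 1 TPM in >= 4
samples; a common rule of thumb is to set the sample threshold near the
size of the smallest experimental group, and both values are plain CLI
flags.

## Bidirectional clustering (enhancer candidates)

For midpoint `m` with window `w` (default 200 bp), the arms are
upstream `[m−w, m)` and downstream `(m, m+w]`; the midpoint basepair
belongs to neither.  With arm masses `D⁺` (downstream plus), `U⁻`
(upstream minus), `U⁺`, `D⁻` and total `T`, the balance score is the
Bhattacharyya coefficient against the ideal (½, ½, 0, 0) divergent
configuration:

    B = sqrt(0.5 · D⁺/T) + sqrt(0.5 · U⁻/T),   B = 0 when T = 0.

`B = 1` exactly when all mass is split evenly between the two correct
arms; a one-armed site scores `sqrt(0.5) ≈ 0.707`, safely below the
0.95 default threshold.  Candidate midpoints are pre-filtered to
basepairs with signal on both correct arms; this is an exact
optimization (a midpoint outside the set is one-armed or empty and can
never pass a threshold above 0.707), verified in tests against
brute-force evaluation of every basepair.  Runs of qualifying midpoints
separated by gaps <= `w` merge into one unstranded cluster spanning
`[min−w, max+w+1)`, so an isolated midpoint yields the minimum width
`2w + 1 = 401`.

Peak choice: among the run's maximally balanced midpoints the *median*
tied position is taken, not the leftmost.  A perfectly balanced site
produces a wide plateau of `B = 1` midpoints between its two arms, and a
leftmost rule would systematically park the peak at the plateau edge;
the median is equally deterministic and order-invariant but central.
Note a structural property of midpoint exclusion on sparse data: when
the two arms carry unequal mass, balance is maximized *on* the innermost
tag of the heavier arm (excluding it rebalances the arms), so peaks can
sit up to about one arm-offset from the true site center.  Peak-position
accuracy claims should therefore be read at arm-offset resolution.

Bidirectionality of a cluster is the number of samples with nonzero
counts on *both* correct arms around the peak; the default filter keeps
clusters bidirectional in >= 1 sample.  After annotation, only
intergenic and intronic bidirectional clusters are retained as enhancer
candidates, since bidirectional clustering also detects bidirectional
promoters.

## Annotation hierarchy

Transcript models come from GTF/GFF3 (attributes `transcript_id` /
`gene_id`, or `ID`/`Parent`) or BED12 (exons from blocks, CDS from
thickStart/thickEnd).  Categories are derived per transcript:

* promoter — annotated TSS ± 100 bp (`promoterPad`);
* proximal — from 1000 bp (`proximalUpstream`) upstream of the TSS to
  the promoter pad's edge;
* fiveUTR / CDS / threeUTR — exonic sequence partitioned by the CDS span
  for coding transcripts; `exon` is the exonic sequence of non-coding
  transcripts; `intron` the rest of the span.

The two pad values follow the defaults of established CAGE tooling and
are exposed as flags.  The query point is the cluster peak.  Stranded queries exhaust
same-strand categories in priority order before `antisense`
(opposite-strand span overlap); unstranded (enhancer) queries test both
strands per category and never receive `antisense`.  Every cluster gets
exactly one category.

Transcript membership uses the span extended upstream through the
proximal region; gene assignment collects all same-strand candidate
genes at the peak and keeps the one whose nearest annotated transcript
start is closest, ties broken to the lexicographically smallest gene id
(a deterministic refinement of the distance-to-nearest-TSS rule).
Gene-level counts are plain sums of member TSS-cluster counts and are
exactly conservative.  The composition filter drops TSSs not exceeding
10% of their gene's per-sample total in >= 5 samples (defaults).

## Shape, links, stretches

Shape IQR orders a cluster's members 5'→3' (reverse genomic order on
minus), accumulates pooled-signal fractions and takes
`|q(0.9) − q(0.1)|` in bp, where `q(f)` is the *first* member reaching
cumulative fraction `f` (no interpolation; a fraction within 1e-9 of the
target counts as reaching it, so exact rational ties are unaffected by
float rounding).  `IQR < 10` bp (strict) classifies a promoter as Sharp.
Shape is only meaningful for well-expressed clusters; the CLI defaults
to mean pooled TPM >= 10.

Links pair every TSS with every enhancer whose peak lies within 50 kb on
the same chromosome (peak-to-peak distance; shared-peak pairs are
degenerate and dropped).  Orientation is upstream/downstream of the TSS
respecting its strand.  Correlation is Kendall's τ_b on per-sample TPM
vectors (scipy's tie-corrected implementation; exact null enumeration
for n <= 10 without ties, normal approximation otherwise).  A
zero-variance vector leaves τ undefined: the pair is kept with a missing
estimate and p = 1.  p-values are reported raw, matching common
practice for exploratory link screens; a Benjamini–Hochberg flag is
available.

Stretches are single-linkage groups of enhancers whose intervals lie
within 12.5 kb end-to-start gaps; groups with >= 5 members are reported
with the mean pairwise τ over member TPM vectors.

## Exact 2×2 enrichment

`fisher_exact_2x2` performs the conditional analysis with both margins
fixed: under odds ratio ψ the top-left cell follows Fisher's noncentral
hypergeometric distribution.  The two-sided p sums all point
probabilities `<=` the observed one at ψ = 1 (with the customary
1 + 1e-7 relative slack for float ties) — the "sum of smaller tails"
rule, not tail doubling.  The estimate is the conditional MLE (ψ whose
noncentral mean equals the observed cell) and the CI inverts the two
one-sided tail tests at α/2, with 0/∞ bounds for boundary tables.
Probabilities are computed in log space and normalized over the support,
so tables with tens of thousands of counts are handled without overflow.

Root finding uses Brent's classical *zeroin* with stopping rule
`2·eps·|b| + tol/2` at `tol = eps^0.25`, the termination criterion the
reference conditional-inference implementations inherit — the quoted
estimate and CI bounds are conventionally defined by that procedure, and
a generic solver with a different stopping rule reproduces them only to
~4 decimals.  A `tol` argument converges them to the exact roots (used
in tests against direct likelihood maximization, agreement to 1e-6
relative).  `motif_enrichment` applies the test per motif column of a
boolean cluster × motif matrix against a per-cluster indicator, with
optional BH adjustment; motif scanning itself is out of scope and the
matrix is consumed from TSV.

## Synthetic data generator

`cagecall.simulate` emulates the structure (not the empirical count
distributions) of a multi-sample CAGE experiment on a toy genome of two
4 Mb chromosomes.  Reference conditions: 11 samples in two classes
(5 + 6), 50 sharp + 50 broad TSSs, 30 enhancers of which 6 form one
stretch (gaps 7–11 kb), background noise at 1e-5 positions per bp per
strand per sample with zero-truncated Poisson(1) counts, library sizes
uniform in [1e6, 2e6].

Placement: features are laid out left-to-right with inter-unit gaps
uniform in [30, 60] kb — comfortably above the 2 kb minimum needed to
keep features from merging, and wide enough that singleton enhancers can
never chain into a spurious >= 5-member stretch at the 12.5 kb merge
distance.  40% of the non-stretch enhancers are planted as co-activated
pairs: a TSS and an enhancer 20–45 kb downstream sharing a latent
activity group, with an independent decoy enhancer at the mirrored
distance upstream, so correlation-based link detection can be scored
against distance-matched negatives.

Expression: per sample, each activity group draws a log-normal
multiplier (σ = 0.8, unit mean); feature counts are Poisson around
`mean_tpm · activity · L_j / 1e6` with mean TPM log-uniform in [20, 200]
for TSSs and [5, 20] for enhancers.  Sharp TSS tags spread over ± 2 bp
with a Gaussian-weighted profile, broad TSS tags uniformly over ± 30 bp.
Enhancer tags split Binomial(½) between a minus-strand arm at anchor
− 90 bp and a plus-strand arm at + 90 bp (jitter ± 3 bp), with a 2%
wrong-strand fraction — arms sit inside the 200 bp balance windows and
the expected balance stays above 0.95.  Everything is reproducible from
the seed, including byte-identical bedGraph output; minus-strand tracks
are written negated to exercise the signed dialect.

What passing tests on this generator do *not* show: robustness to
mapping artifacts, G-addition bias, promoter-proximal antisense signal,
overdispersed (non-Poisson) counts, or realistic genome-wide noise
structure.  The generator is a structural test bed, not a statistical
replica of real CAGE libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline on the
reference generator conditions above (~5,000 CTSS positions), plus
randomized-oracle checks (1,000 random tracks for clustering, 500
vector pairs for τ, exhaustive small-margin enumeration for the exact
test, 1,000 simulated motifs for type-I calibration); the whole suite
completes in well under a minute.  Degenerate inputs are defined
explicitly: empty cluster sets propagate as empty, empty clusters are
errors for shape computation, constant vectors yield missing τ with
p = 1, and boundary 2×2 tables yield 0/∞ estimates and bounds.

## Known limitations

* No per-sample (non-pooled) clustering, paraclu/density clustering, or
  TSS-shift statistics.
* No read alignment, BAM parsing or G-correction; input starts at CTSS
  tracks.
* Differential expression is deliberately delegated: the package exports
  count matrices and consumes a DE indicator for enrichment.
* Enhancer peak positions are accurate to about one arm offset on sparse
  data (see the midpoint-exclusion note above).
* The bidirectionality filter's default (>= 1 sample) is a convention,
  not a printed value; users with many samples should raise it.
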