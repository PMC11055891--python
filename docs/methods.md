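# Methods

This note documents the models, rules and numerical choices implemented in
`rdcscan`, and what the synthetic benchmarks do and do not demonstrate.

## Junction handling

Coordinates are 0-based half-open internally; TLX-style 1-based positions
are shifted on read, BED is taken as-is.  The strand→orientation convention
("+" prey junction = Dcen, "−" = Dtel) is a file-format convention exposed
as a parameter, not biology.  All statistics use interchromosomal junctions
only: on the bait (viewpoint) chromosome the assay recovers downstream break
ends 15–25% more efficiently, biasing Dcen/Dtel ratios, so the viewpoint
chromosome is excluded rather than corrected.  Off-target CRISPR cut sites,
whose cutting is dose-independent, anchor library-size normalization:
weight(c) = mean off-target count across conditions / count of condition c.
The mean (not a designated reference condition) is the normalization
reference.

## RDC calling

Pileup: each junction contributes a ±50 kb interval; bin value = number of
intervals overlapping the bin.  The grid is 1 kb so the 10-kb gap rule is
exact.  Background: negative binomial fitted by method of moments per
chromosome/condition/orientation on all bins (no masking of candidate
regions; genome-wide fit, configurable).  When sample variance ≤ mean the
fit degenerates to Poisson(mean).  Method of moments rather than MLE keeps
the fit deterministic and robust to the heavy right tail the clusters
themselves create.  Per-bin significance is the upper tail P(X ≥ observed);
raw p-values are thresholded at 0.01 (seeds) and 0.1 (extension) with no
multiple-testing correction, mirroring the source procedure.

Island construction: seed runs allow internal non-significant gaps of
≤ 10 kb (strict ≤); seeds join into islands across gaps ≤ 100 kb; islands
extend over contiguous sub-0.1 bins only (extension does not jump gaps);
orientation-specific islands that overlap or touch merge, and the merged
interval is kept iff it contains ≥ 100 kb below p < 0.01 in any orientation
and spans ≥ 300 kb.  Adjacent (gap-0) islands merge.  An independent
brute-force implementation (transitive-closure clustering over bins) backs
the caller in the test suite; both agree exactly on randomized tracks.

## Replication features

Fraction rows are depth-scaled, Gaussian-smoothed along the genome
(default σ = 1 bin), and each 50-kb bin column is scaled to unit sum.  The
50-kb bin reflects labeling kinetics: at 1.8 kb/min a fork incorporates
≥ 54 kb of BrdU in a 30-min pulse, so one bin is the smallest unit a single
fork fully traverses.  Bins are BIRCH-clustered (80 clusters; threshold
0.02 because unit-sum 16-vectors have small norms; genomic input order
fixed, making the clustering deterministic) and each cluster's corrected
fraction is the argmax of its centroid, earliest fraction on ties.

Feature rules operate on the run-length encoding of corrected fractions:

* **TTR** — maximal chain of runs with all steps strictly monotone in one
  direction and every run ≤ 3 bins.  An equal-fraction run longer than
  3 bins breaks the chain and is excluded entirely; a run shared between an
  ascending and a descending chain (a sharp local extremum) stays with the
  left chain so TTRs remain disjoint.  Ascending left→right = rightward
  fork.
* **late CTR** — constant runs > 3 bins at corrected fraction ≥ 12
  (threshold configurable; "late" is not restated in the feature source and
  the default re-derives it as the last ~quarter of S phase).
* **IZ** — runs below both neighbors; **small TZ** — runs above both
  neighbors spanning ≤ 100 kb.  Missing (unmappable) bins break all
  features.

## Termination prediction

BIRCH-derived features miss termination zones broader than ~100 kb, so
termination meeting points are predicted from the Repli-seq matrix with a
compact fully-convolutional network.  Reference labels come from OK-seq
RFD = (R − F)/(R + F): under this sign convention RFD ascends through zero
at initiation and descends at termination.  RFD is LOESS-smoothed (span
adaptive, ~15 bins ≈ 750 kb, well under the inter-origin distance);
ascending crossings are IZ anchors, descending crossings TZ anchors, and
only IZs flanked by TZs on both sides are kept.  Descending-crossing TZ
labels replace an external HMM segmentation; they are the standard TZ
signature and recover planted termination points to ±1 bin on clean
simulations.

Training windows are 30 bins with stride 24 (3 shared context bins per
side; only the central 24 are scored), built at the native 50-kb grid and a
2×-merged 100-kb grid so windows span 1.5 and 3 Mb, pooled; a window must
contain a labeled IZ and TZ.  The network: an inception block over the
genomic axis (kernel widths 5/7/9, five filters each, plus a width-3
max-pool branch with a width-1 reduction conv), concatenated to 20
channels, then width-1, width-1 and width-9 convolutions to one channel;
SELU activations (LeCun-normal init), sigmoid output.  Training: Adam,
learning rate 10⁻³, mini-batch 32, dropout 0.9 on the inception output,
Dice loss masked to the core bins.  The net is implemented directly in
numpy (forward and backward), which keeps runs bit-reproducible under a
fixed seed on a single thread; the backward pass is verified against
finite differences in the test suite.  Evaluation is 10-fold
cross-validation scoring predicted anchors (local probability maxima
≥ 0.5) against labeled TZ bins at a one-bin (50-kb) tolerance.

## Forks and classification

Each IZ edge connects to the nearest termination anchor on its side
(rightward segment to the right, leftward to the left); segments under one
bin (50 kb) are unresolvable and dropped; TTRs contribute segments with
their own direction.  Replicate consistency is a base-pair-wise
intersection keeping positions where both maps assign the same single
direction; the pipeline also applies this rule to a single assembled map to
discard positions claimed by conflicting directions.  Classification per
RDC, after merging overlapping same-direction stretches: ≥ 3 stretches =
complex; one direction = unidirectional; rightward left of leftward
(converging, compared by midpoints) = inward; the reverse = outward; no
overlapping stretch (≥ 50 kb) = undetermined.  Flags: contains_ttr, and
contains_broad_lateCTR for late CTRs > 500 kb.  The optional biphasic flag
(two S-phase signal bands: ≥ 2 fraction-profile maxima ≥ 4 fractions apart
in ≥ 20% of bins) is a heuristic, off by default.

## TRC statistics

Within an RDC, every (fork, active gene) overlap is a compartment: head-on
if fork and transcription oppose, co-directional otherwise; activity is
GRO-seq RPKM ≥ 0.05.  A compartment counts only its matched orientation —
Dcen under rightward forks, Dtel under leftward — because the stalled-fork
break model ties break-end orientation to fork direction.  P_HO aggregates
matched counts over all compartments of the RDC before dividing
(aggregate-then-divide); P_HO + P_CD = 100 whenever any matched junction
exists.  R_s = compartment bins / distinct corrected fractions spanned.
Relative DSB count = log₂[P_RDC/(ΣRDC/5)] over the five-dose series with a
0.5 pseudocount for zero numerators.  Dual-strand hybrids are positional
plus/minus DRIPc peak overlaps; RDCs with ≤ 2 are "low", the rest split at
the upper tertile (inclusive) into "mid"/"high".  Peak densities are peaks
per 100 kb of gene length, compared by two-sided Mann-Whitney (exact null
below n = 20 without ties, mid-rank normal approximation otherwise).
Degenerate two-group t-tests (zero variance in both groups) return p = 1
for equal means and the perfect-separation limit p = 0 otherwise.

## Synthetic data

The generator is the package's study condition, not a test fixture.  Each
origin i fires at fraction f_i and sends forks outward at constant speed v;
t(x) = min_i[f_i + |x − o_i|/v] capped at 16; adjacent origins meet at
x* = (o_i + o_{i+1})/2 + v(f_{i+1} − f_i)/2.  Defaults: one 100-Mb
chromosome, 50-kb bins, origins every 2 Mb (mammalian IZ spacing) with
firing fractions cycling 1–6, v = 150 kb/fraction, fraction-axis Gaussian
width 1.5 fractions (the banded look of real 16-fraction heatmaps),
Poisson depth 100 per bin for Repli-seq and OK-seq, |RFD| = 0.8 inside
pure fork regions.  Junction background is NB(mean 10, dispersion 10) per
50-kb bin (~20k junctions per chromosome, the scale of real ~30k-junction
libraries); planted RDCs multiply the rate by a per-condition fold
(default 1/2/3/4/6× across the dose series), orientation deterministically
follows local fork direction, and each enriched junction lands in a
head-on compartment with probability θ.  Off-target counts are
condition-invariant Poisson; a bait chromosome receives filler junctions
for the viewpoint filter to remove.

What the simulations do not emulate: mappability gaps, copy-number and
GC biases, replication-timing heterogeneity between cells, biphasic
(mixed-program) regions by default, junction resection/micro-homology
structure, and correlated noise between Repli-seq fractions.  Passing the
benchmarks therefore demonstrates correctness of the algorithms under the
stated generative model, not robustness to every artifact of real
libraries.

## Problem sizes and numerical notes

Benchmark scales were chosen to run on one CPU: caller recovery and null
false-positive rates use 100-Mb genomes (10 planted + 50 null); the
termination predictor trains on a 200-Mb genome (~170 windows, 40 epochs,
10 folds, ~20 s); the head-on bias recovery uses 50 RDCs × ~10⁴ junctions.
All randomness flows through seeded numpy generators; simulator output is
byte-identical for equal configs.  Degenerate inputs (all-zero tracks,
empty gene sets, zero off-target counts, sub-50-kb forks) raise or warn as
documented in the API rather than returning silent zeros.

## Known limitations

Gene-name assignment to RDCs is nearest/overlap only.  The distinction
between "undetermined" and "complex" when features exist but directions
conflict follows the documented consensus rule and is configurable.
"Twin-peak" vs "single-peak" break-density morphology is reported
descriptively, not modeled.  The head-on proportion is undefined (and the
RDC skipped) when no compartment holds a matched junction.
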