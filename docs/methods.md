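# Methods

This note records the models, parameter choices, and numerical
conventions behind `tadremodel`, including the places where the design
was genuinely open and what the synthetic-data tests do and do not show.

## Contact-matrix model and preprocessing

A contact matrix is a symmetric, binned count matrix stored as its upper
triangle over a bin table (uniform bins, or restriction fragments from
in-silico digestion). Digestion follows the DpnII convention: cut sites at
motif occurrences, fragments shorter than 150 bp absorbed into the
following fragment, fragments longer than 1000 bp split into equal pieces
of at most 1000 bp. The absorb-forward direction is a fixed convention
chosen for determinism.

**Balancing** is iterative proportional fitting (ICE-style): weights
b_i are updated by the corrected row sums until their coefficient of
variation over unmasked bins falls below `tol` (default 0.01). The
contract is equal marginals, verified by direct summation in the tests;
everything downstream depends only on that contract, not on the specific
balancing algorithm. Bins with zero marginal are always masked. The
low-coverage filter masks bins below the 2nd percentile of nonzero
marginals *only when they also fall below half the median marginal*: on
clean matrices the lowest-coverage bins are the genuinely insulated
border bins (roughly 20% below the median), and discarding them would
suppress the very signal under study. The half-median floor separates
coverage artifacts (orders of magnitude low) from biology.

**Observed/expected.** The expected profile is the mean corrected count
per diagonal offset per chromosome, counting implicit zero pixels. The
O/E matrix keeps the sparse pixel pattern — an unstored pixel genuinely
has ratio 0 — and inter-chromosomal pixels are excluded.

**Per-bin-pair log2 fold change** between conditions aggregates both
matrices to 5-kb bins and reports
`log2((c_a + 1)/s_a) − log2((c_b + 1)/s_b)` with library-size totals s.
This size-factor/pseudocount form replaces a dispersion-modeling fit; it
is a deliberate simplification and is labeled as such.

## TAD-separation score and border calling

The score of bin i for window w is the mean corrected count over the
diamond upstream×downstream of i (rows i−w..i−1, columns i+1..i+w),
z-scored per chromosome and averaged over the window set (10, 20, 30 kb;
window sizes in bp are converted to bins with a minimum of 2). Masked
bins are excluded cell-wise via a validity summed-area table; a bin's
score is defined wherever at least one window fits. A numerically
constant track (standard deviation below 1e−9 relative) is mapped to
z = 0 rather than amplifying float noise.

Border candidates are local minima with topographic **prominence**
≥ 0.04; the prominence is the reported delta, with 0.08 the strong
threshold. Prominence, rather than the difference to the mean of
flanking maxima, is used because noise ripple inside one broad insulation
valley otherwise yields duplicate calls: a secondary dip's prominence is
bounded by the ripple amplitude, while the valley's main minimum carries
the full depth.

Each candidate receives a one-sided rank-sum p-value comparing the
inter-domain diamond against the pooled flanking intra-domain triangles,
computed on **O/E-normalized** contacts — diamond and triangle cells sit
at different diagonal offsets, so raw counts would confound the test with
distance decay. P-values are BH-adjusted over all candidates; the cutoff
is 0.01. Borders closer than the 5-kb minimum TAD width are resolved by
keeping the larger delta.

**Robustness**: a border is robust if the border list called after 20%
binomial down-sampling contains a border of the same strength class
within 2 kb (nearest-neighbor, ties to the leftmost). The down-sampling
seed is always explicit.

**Cross-condition classification** walks the WT robust strong borders:
a knockdown border at the same position (within `same_tol`) that is
strong → maintained, weak → weakened; within 2 kb → fuzzy (shift
recorded); otherwise lost. Knockdown strong borders with no WT strong
border nearby → new. Matching is greedy by distance and each knockdown
border is consumed once. `same_tol` defaults to one median bin width with
a 600-bp floor (the fragment-scale median is ~529 bp). Because called
positions are quantized to bins, the matching radius is
`max(fuzzy_tol, same_tol)`: at 5-kb bins a one-bin jitter (5 kb) exceeds
the 2-kb fuzzy tolerance and would otherwise turn identical borders into
lost + new pairs. Distances are center-to-center.

## Loop calling

The donut-filter scheme at 2-kb resolution: for each candidate pixel
(nonzero, more than `window` bins off the diagonal, within 1 Mb), four
local expectations are formed as `E_ij × (ΣC_filter / ΣE_filter)` over
the donut, horizontal, vertical, and lower-left footprints (outer radius
10, excluded peak radius 5), computed by FFT convolution on the dense
per-chromosome corrected and expected maps. Poisson upper tails
(regularized incomplete gamma, valid for non-integer corrected counts)
are BH-adjusted per filter over the nonzero candidates — restricting the
BH family to nonzero pixels keeps it meaningful, since zero-count pixels
can never be peaks. A peak needs all four q ≤ 0.05 and enrichment 1.75×
(donut, lower-left) and 1.5× (horizontal, vertical). Significant pixels
within 20 kb (Chebyshev) merge to the smallest-q representative;
singleton clusters must additionally have q ≤ 0.02 *or* 2× enrichment
over both donut and lower-left expectations. This maps the conventional
threshold vector 0.02/1.5/1.75/2: the 2× rule exists precisely so that
strongly enriched single-pixel peaks survive. Lambda-chunking is replaced
by the direct Poisson tails.

Loop comparison matches anchors within one resolution bin, greedily by
total anchor distance: both anchors matched → maintained, one → partially
maintained, none → lost; a matched knockdown loop must itself be a called
loop. APA averages O/E submatrices (halfwidth 15 bins) around loop
pixels at least 2×halfwidth from the diagonal; the center score divides
the center cell by the mean of the lower-left corner block (size
halfwidth//3). Anchor annotation precedence is P > E > G > O, with
promoters the strand-aware 1-kb windows upstream of TSSs.

## Compartments and saddle

Per chromosome (whole chromosomes; an arm table can be supplied by
splitting the bin table), the leading eigenvector of the Pearson
correlation matrix of the dense O/E map, masked bins removed pairwise and
constant rows dropped; chromosomes with fewer than 20 usable bins, plus
chromosomes 4 and Y by default, are masked. The eigenvector is scaled by
the square root of its eigenvalue and negated when its correlation with
per-bin GC content is negative; A = positive, B = negative.

The saddle ranks unmasked bins by eigenvector value after trimming to
the [2.5%, 97.5%] quantile interval, into 30 equal-occupancy groups.
Grid cell (p, q) is the mean intra-chromosomal **O/E** between groups p
and q. The strength is `mean(AA corner, BB corner) / mean(AB, BA)` over
10×10 corner blocks of the nonnormalized grid. Using O/E rather than
correlation values for the grid is a deliberate choice: it fixes the
no-structure baseline at exactly 1 (a correlation-valued grid has corner
means near zero under the null, making the ratio numerically unstable),
while preserving the monotone relationship with compartmentalization
that the strength statistic is meant to capture. Any display
normalization across conditions is applied at render time only, never to
the strength.

## Expression association

Segments between the union of WT and knockdown border positions inherit
the displacement of their containing WT TAD's two borders (distance to
the nearest knockdown border): both within `same_tol` → conserved-two;
exactly one beyond the fuzzy threshold → conserved-one; both beyond →
knockdown-specific; both moved but within it → fuzzy. As in border
classification, the displacement threshold is `max(2 kb, same_tol)` —
never finer than one bin. Telomeric segments outside any WT TAD are
"unassigned" and excluded from testing.

The permutation test redraws each region's start uniformly within its
chromosome's universe span, preserving widths and counts (the
`randomizeRegions` scheme), fully vectorized; 1000 permutations by
default, p = (1 + #{null ≥ obs})/(1 + N) with a reported z. Upper-tail
enrichment is the default; depletion is available via `alternative`.
Because the statistic is an integer overlap count, the test is
conservative when few regions are tested (ties at the observed value
inflate p); calibration to nominal level needs a few hundred regions,
which the synthetic study conditions provide.

Housekeeping genes are those in the top 40% of expression in every
sample ("top 40th percentile" is read as top 40%; the alternative
reading is switchable via the percentile argument). DEG status is
re-derived from padj ≤ 0.05 and |log2FC| ≥ 2 for consistency (1.0 is the
conventional relaxation for loop/compartment analyses); the DEG table
itself is an input — differential-expression model fitting is out of
scope.

## Signal tracks, occupancy classes, pausing, PWM

Border heatmaps sample a track into 50 columns of 100 bp across the
5-kb window (length-weighted means; uncovered bases are zero). Dialects:
ChIP — winsorize at the 5% quantile of negative and 95% quantile of
positive values, positives scaled to (0, 1], negatives shown as 0;
DNase — negative cutoff 0, positive cutoff the 75% quantile; nascent
transcription — additionally negatives scaled to [−1, 0). Rows are
ordered by decreasing reference (BEAF-32) window signal when a reference
track is given.

Occupancy classes follow the quartile rules (no / extra-low / low /
medium / high / extra-high) on each window's per-bin raw signal. The
cut-off is the median of positive window sums pooled across datasets,
recomputed per input collection — the published cut-off value is a
dataset property, never hard-coded. Since the rules compare quartiles
(per-bin scale) with a sum-scale cut-off, the cut-off is divided by the
number of window columns before comparison; zeros fall through to "low",
and values exactly at the cut-off take the lower class.

The pausing index is the promoter (TSS−200..TSS+50) to gene-body
(TSS−50..end) ratio of mean signal, strand-aware; nonpositive or
undefined indices are discarded.

PWM scanning uses log-odds matrices (`log2((counts+0.8)/Σ / 0.25)`),
both strands, with the relative-score threshold
`t·(max−min)+min` at t = 0.85; windows containing N are skipped and
overlapping sites all count. The scanner is verified against per-window
brute force. Group comparisons use the Mann-Whitney U test — exact for
groups of ≤ 12 without ties, normal approximation with tie correction
otherwise — and 2×2 proportions use the two-sided Fisher exact test,
both cross-checked against exhaustive enumeration.

## Synthetic data

The generator's intensity model for a chromosome is multiplicative:
`λ_ij = scale · (1+d)^−α · Π(border factors) · checkerboard · loop bumps`,
Poisson-sampled, with α = 1 by default (a typical Hi-C decay). Crossing a
border of depth D divides intensity by D (depths multiply for pairs
spanning several borders); the checkerboard multiplies same-label pairs
by √f and different-label pairs by 1/√f so the within:between ratio is f;
loops are 2-D Gaussian bumps (σ = 1 bin at 2 kb) peaking at the planted
enrichment. The scale is set so expected total contacts equal `depth`.
GC content is 0.40 + 0.10·(A label) + N(0, 0.02), which orients the
eigenvector correctly in expectation.

Condition pairs regenerate the knockdown from the edited layout using
the same seed, and the truth table records each feature's intended
status under the classifier's own definitions. Genes are placed
uniformly along the chromosome, rejecting positions that span borders —
uniform placement matters: it makes gene density proportional to TAD
length, which is the permutation test's null model, so calibration under
odds 1 is exact up to count discreteness (a fixed per-TAD quota would
underdisperse the observed statistic and make the test conservative).
DEG status is then drawn with odds multiplied in reorganized TADs, and
log2FC/padj values are drawn consistent with the thresholds. ChIP-like
tracks are Gaussian bumps (amplitude = snr × noise SD, half-width 500 bp)
over unit Gaussian noise in 100-bp steps; the divergent mode places an
antisymmetric bump pair around the border.

What the generator does *not* emulate: restriction-fragment bin-width
heterogeneity coupled to mappability, copy-number and repeat artifacts,
trans contacts, condition-dependent library biases, and dispersion beyond
Poisson. Passing tests therefore demonstrate correctness of the
statistics and the recovery machinery under the stated model, not
robustness to every artifact of real libraries.

## Problem sizes and determinism

The validation suite uses one synthetic chromosome per scenario: 5 Mb at
5-kb bins with 10⁶ contacts for border recovery (20 seeds), 2 Mb at
500-bp bins with 5×10⁶ contacts for classifier correctness (the 500-bp
scale makes a 1.5-kb shift resolvable against a one-bin identity
tolerance, mirroring the ~529-bp fragment scale), 2 Mb at 2-kb bins with
4×10⁶ contacts for loops plus 100 one-megabase null simulations, 5 Mb at
10-kb bins for compartments, and 500/100 replicates for permutation
calibration/power with ~240 and ~100 DEGs respectively. Every stochastic
step takes an explicit seed; simulation, calling, and the pipeline are
bit-reproducible under a fixed seed, and the text writers round-trip
losslessly through their readers.

## Known limitations

- The TAD-separation operator is a documented reconstruction (diamond
  z-score mean, prominence delta, rank-sum p), not a byte-level
  reimplementation of any published tool; thresholds keep their
  conventional meanings.
- Statuses sensitive to sub-bin displacement are only defined up to one
  bin width; analyses needing the 2-kb fuzzy class should run at ≤ 1-kb
  (ideally fragment-scale) bins.
- The permutation test inherits regioneR-style conservativeness for
  small region sets.
- Inter-chromosomal loops, nested TAD hierarchies, and sub-compartment
  clustering are out of scope.
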