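# Methods

This note documents the models and procedures calscope implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Contact-matrix model

A `ContactMap` holds one dense symmetric matrix per chromosome plus a
per-bin exclusion mask and a state tag (`raw → balanced →
observed_over_expected → correlation`). All analyses are intra-chromosomal;
inter-chromosomal (trans) counts read from triplet files are kept only for
total-read accounting. Coordinates are 0-based half-open throughout;
on disk the formats are HiC-Pro sparse triplet text (1-based global bin
indices, upper triangle) with a BED bin table, BED/BEDPE/bedGraph/TSV for
everything else. Replicates are merged by raw count summation — the only
operation consistent with Poisson-like count data.

### ICE balancing

Iterative correction divides the matrix by the outer product of marginal
biases until every unmasked marginal is within `tol` (default 1e-5,
relative) of the mean, or `max_iter` (200) is reached; non-convergence sets
a flag rather than raising. Bins in the bottom `low_coverage_quantile`
(default 0.02) of nonzero marginals, and all-zero bins, are masked first —
standard practice that prevents divergence on sparse rows. The result is
rescaled so the mean unmasked marginal is 1; the discarded global scale is
kept in `metadata["ice_scale"]`.

### Expected, correlation, p(s), QC

The expected value at separation *d* is the per-chromosome mean of unmasked
entries at that separation, with no smoothing (the simplest faithful model;
a smoothed expected could be added behind the same interface). O/E entries
at separations with zero expected are set to 0. The correlation matrix is
the Pearson correlation of unmasked O/E rows; constant rows are auto-masked
with a warning. p(s) counts interactions per separation (multiples of the
bin size), divides by the number of available bin pairs at that separation,
and renormalizes the curve to sum to 1 — so it is invariant to global
rescaling and computable from raw or balanced counts (default raw, since
the procedure is defined by counting interactions). Replicate QC is the
Pearson correlation over all unmasked intra-chromosomal pairs with
separation ≤ 2 Mb, because the entry distribution is dominated by proximal
contacts.

## Compartments

PC1 is the leading eigenvector of each chromosome's unmasked correlation
submatrix (dense `eigh`; one eigenvector per chromosome, no
cross-chromosome PCA). Eigenvector sign is arbitrary, so PC1 is oriented
per chromosome to correlate positively with an activity covariate; A ⇔
PC1 > 0. The pipeline uses each cell type's own per-bin mean log2(FPKM+1)
as the covariate when an expression table is available, and gene (TSS)
density otherwise. Expression is preferred deliberately: gene density is a
static genome feature, and in a cell type whose compartments have switched
extensively the density can anti-correlate with that cell type's PC1 and
invert every label — we observed exactly this on synthetic data. If the
covariate is uninformative (zero correlation), the component with the
largest magnitude is made positive, keeping labels deterministic.
Chromosomes with fewer than 10 unmasked bins are masked entirely.

Switch detection is per-replicate and strict: a bin switches A→B versus the
reference only when both reference replicates are positive and both
comparison replicates negative (B→A symmetric). Any sign disagreement
within a replicate pair makes the bin *discordant*, never a switch. This is
the stricter of the two possible readings (per-replicate on both sides
rather than merged-vs-merged).

Compartment classes: k-means with k = 2 (scikit-learn, 50 seeded restarts,
best inertia) on raw PC1 profiles of switching bins across cell types — no
standardization, since all dimensions share units. The cluster with the
higher mean reference-cell PC1 is the *activation* class. Contiguous
same-label runs define compartment intervals; masked gaps of up to one bin
are bridged when flanking labels agree, because a low-coverage masked bin
is not evidence of a compartment boundary (without bridging, a single
masked bin artificially splits an interval and silently discards the CAL
status of every loop spanning it).

### Concordance test

Per gene, the statistic is the covariance between the FPKM vector and the
PC1 vector across cell types (gene → bin by TSS; a gene-body-majority
option exists). The null shuffles the gene's FPKM vector `n_perm` (1000)
times; `p = (1 + #{null > observed}) / (n_perm + 1)`. Two choices here
deserve explanation:

- **Strict exceedance** (`>` rather than `≥`): with 5 cell types there are
  only 120 distinct permutations, so the drawn shuffle equals the identity
  arrangement with probability 1/120 and a `≥` count has expectation ≥
  n_perm/120 ≈ 8.3, capping the attainable p near 0.01 regardless of effect
  size. The strict count with the add-one correction still guarantees
  p > 0 and calibrates correctly (null rejection 0.015 at α = 0.01, KS
  uniformity not rejected).
- **One-sided (upper tail) by default**: concordance means expression and
  compartment status move in the *same* direction, and with 5 points the
  anti-aligned arrangement's |covariance| frequently rivals the aligned
  one, which halves two-sided power. A `two_sided=True` option remains.

Genes with a constant FPKM (or PC1) vector get covariance 0 and p = 1;
genes over a masked bin in any cell type are excluded and listed in
`attrs["excluded"]`. FPKM is used as-is (a log option exists).

## TADs

DI uses a 2-Mb window (the established convention; the window is not
restated by most users of the statistic). At chromosome ends the sums use
the available truncated span. Segmentation is a 3-state Gaussian HMM
(hmmlearn, diagonal covariance, 100 EM iterations, 10 seeded restarts
keeping the best log-likelihood, Viterbi decoding for global consistency);
states are named by emission mean (most positive = downstream bias). An
all-constant DI track short-circuits to the `none` state. TAD assembly:
open at a downstream-run start, close at the end of the last upstream run
before the next downstream run; TADs shorter than 3 bins are dropped.
Inter-TAD gaps < 400 kb are boundaries; longer gaps are recorded as
unorganized regions, not boundaries.

Insulation: mean of the w×w square crossing each bin (default window
500 kb; 200 kb in small tests), reported as log2 ratio to the chromosome
mean; bins within w of a chromosome end are NaN. The TAD meta-profile
linearly interpolates each TAD ± half its length onto a common grid
(n_points spanning −0.5 to +1.5 TAD lengths) and averages NaN-aware.

Five-type classification per reference TAD, precedence unique → split →
merged → stable → reorganized (structurally decisive cases first):
*unique* = no overlap; *split* = ≥ 2 other-set TADs each ≥ 50% of their own
length inside the reference TAD; *merged* = one other-set TAD covering
≥ 50% of the reference TAD and of at least one sibling; *stable* = best
reciprocal overlap (intersection/union) > 0.70 (a one-sided option exists);
*reorganized* = the rest. The 0.70 threshold is the one stated constant;
the 50% piece threshold and the precedence order are this package's
choices.

## Loops and CALs

APA extracts the O/E submatrix centered on the anchor-midpoint bins
± `flank_bins` (default 5 at 40-kb test resolution; use 25-kb matrices for
the conventional setting), averages across loops, and scores center over
the mean of the lower-left (flank/2)² corner block. Loops with anchor
separation < 2× the window (or too near a chromosome end) are excluded so
the corner block stays off the diagonal.

A loop is a CAL iff both anchor midpoints map into the same contiguous
compartment interval — boundary-crossing loops are excluded by
construction. CAL class = majority class of the interval's classified
(switching) bins; CALs in unclassified intervals are dropped with a
warning. Gene sets use loop-span overlap by default (anchors mode
available); genes overlapping both aCAL and repressed-CAL spans go to the
side with larger total overlap, ties to aCALs.

The peak-overlap test compares regions against length-matched controls
placed uniformly on the same chromosome (seeded; masked bins avoided, up
to 50 placement attempts), in a 2×2 Fisher exact test (two-sided). The
pipeline tests aCAL *anchor* intervals rather than full spans: at realistic
CTCF densities (~30 peaks/Mb) any multi-hundred-kb span — real or control —
contains a peak and span overlap saturates at 1.0 on both sides.

## ChIP and expression summaries

Per compartment interval, the signal statistic is the sum over contained
1-kb bins of log2((treatment + ε)/(input + ε)) with ε = 0.5 RPM (avoids
log 0 while preserving ordering; set ε = 0 to reproduce the exact
log2-fold-sum on strictly positive tracks). Peaks are assigned to the
compartment label of the bin containing their midpoint (deterministic
single assignment; any-overlap exists as an option). Expression group
comparisons are two-sided Mann-Whitney rank-sum tests on log2(FPKM+1) with
median differences reported.

## Synthetic data: the stated world

The generator plants, at simulation resolution (40-kb bins, two 20-Mb
chromosomes in the standard profile):

- alternating A/B compartment intervals of 1.2–4 Mb aligned to 400 kb (so
  compartment-resolution bins are label-pure), ~30% of intervals switching;
  each non-reference cell type flips a switching interval independently
  (probability 0.35 for the related stem-cell-like types, 0.9 for the
  distant ones, at least one flip), which mirrors a reference stem cell
  resembling other adult stem cells and differing from iPSC/somatic cells
  and gives genes heterogeneous compartment profiles. At least two
  activation and two repression intervals are guaranteed per genome so the
  desk-scale fixture always contains both classes.
- TADs of 10–40 bins with occasional gaps (~90% coverage), shared across
  cell types; loops planted inside compartment intervals (CAL-generating)
  and across interval boundaries (non-CAL), anchors one bin wide;
- expected Hi-C intensity λ(i,j) = s^(−1) × contrast^(±1) (×3 within the
  same compartment label, ÷3 across) × 3 within a TAD × 3 in a ±1-bin focal
  window at loop anchors, scaled to the requested depth (3–5 × 10⁶ reads
  per replicate) and drawn independently per replicate as Poisson counts —
  no overdispersion by default;
- genes at ~20/Mb with 2.5× density in reference-A bins; log2 FPKM =
  baseline + 2·1[A in that cell type] + N(0, 0.5), so genes in switching
  intervals track their compartment profile automatically (these are the
  planted concordant genes);
- CTCF-like peaks at ~30/Mb, ×3 in A bins, ×5 near loop anchors, with
  smoothed-density treatment and flat-noise input tracks at 1-kb bins.

All draws flow from one seeded generator (`numpy` SeedSequence spawning);
fixed seeds give byte-identical bundles.

**What it does not emulate** — and hence what a green test does not
establish: no fragment-level or mappability bias structure beyond a single
multiplicative per-bin bias in dedicated tests; no nested/hierarchical
TADs; no graded compartment strength (labels are binary, so called PC1
magnitude is uninformative beyond its sign); no trans contacts; Poisson
(not overdispersed) counts; loop anchors exactly one bin wide. Recovery
rates measured here bound what the method can do when its model is right;
they say nothing about robustness to artifacts the generator lacks.

Because the label signal across only five cell types gives the permutation
test limited resolution (near-ties among the 120 arrangements), bundle-level
concordance recall is modest by design; the test's calibration and power
criteria are therefore measured on continuous-PC1 fixtures where effect
size is controlled directly.

## Known limitations

- Dense per-chromosome matrices: fine up to a few thousand bins per
  chromosome (the resolutions used here), not for 10-kb whole-genome work.
- The HMM is a plain 3-state Gaussian on DI, not a mixture-emission model;
  at very low depth the DI distribution's heavy tails can split states.
- CAL identification depends on compartment-interval contiguity, so single
  mislabeled bins can split intervals; masked-gap bridging mitigates only
  the masked case.
- The Fisher overlap test treats shuffled controls as independent draws;
  heavy region overlap would understate the variance.
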