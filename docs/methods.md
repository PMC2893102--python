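# Methods

This note documents the statistical models behind `cnexpress`, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
choice existed.

## Copy-number segmentation

Observed per-SNP copy-number ratios r (tumor vs. the two copies expected in
a diploid cell) are transformed to y = log2 r and segmented per chromosome
and sample by the fused-lasso signal approximator

    minimize over b:  ½ Σᵢ (yᵢ − bᵢ)² + λ₁ Σᵢ |bᵢ| + λ₂ Σᵢ |bᵢ − bᵢ₋₁|.

The solver is exact and deterministic: total-variation denoising with
penalty λ₂ by Condat's direct taut-string algorithm (one O(n) pass),
followed by soft-thresholding at λ₁. This two-step composition solves the
joint objective exactly — a known property of the fused-lasso signal
approximator — and is cross-checked in the test suite against a generic
convex QP solver (SLSQP on the epigraph formulation) on instances of up to
20 points, to 1e-6 in objective value.

Because no iterative tuning is involved, the only free parameters are the
penalties. λ₁ defaults to 0 (no shrinkage toward the diploid baseline).
λ₂ defaults to the universal threshold σ√(2 log n) per chromosome and
sample, with σ estimated from the median absolute successive difference
(median |yᵢ−yᵢ₋₁| / (0.6745·√2)), which is robust to the sparse true jumps.
Both are exposed in the configuration; there is no canonical published
value for an FDR-tuned penalty, so this is a package decision.

Gain/loss calls threshold the fitted values on the ratio scale:
loss below 0.93, gain above 1.07 by default, with a stringent preset
(0.7, 1.4) for burden summaries. The genome-altered fraction is the
SNP-weighted share of non-neutral calls per sample (base-pair weighting is
deliberately not the default: probe coverage, not physical length, is the
sampling unit of array data).

## Transcript copy number

A transcript's copy number per sample is the arithmetic mean of the
segmented (denoised) ratios of a SNP set chosen by precedence: all
overlapping SNPs when ≥ 5 overlap; else the 5 SNPs closest to the interval
among those within a 250 kb window on either side; else all 1–4 SNPs in
the window; else the transcript is unmapped (a data condition, not an
error). Internal coordinates are 0-based half-open; annotation files are
read as 1-based inclusive. Distance from a SNP to a transcript is 0 inside
the interval, else base pairs to the nearer boundary; overlapping SNPs are
therefore eligible (at distance 0) for the closest-5 rule — the natural
reading where the source procedure is silent. Ties at the fifth-closest
distance break deterministically by (position, SNP id). The implementation
is verified against an exhaustive brute-force distance scan on randomized
layouts.

## Expression filtering and renormalization

Four elimination rules run in a fixed order (the retained set is
order-independent; the removal log attributes each transcript to the first
failing rule): (1) no alignment information or non-unique alignment,
(2) sex chromosome (X, Y) or mitochondrial (MT, M) location, matched
case-insensitively with or without a "chr" prefix, (3) fewer than 3
samples with log2 expression above 3, (4) inter-quartile range below 0.1
(type-7 linear-interpolation quantiles).

The second normalization is reconstructed from its stated goal — medians
near zero with comparable variation across samples and transcripts — as a
median/MAD transform Y → (Y − Ỹ)/median(|Y − Ỹ|) applied first to each
sample (column) and then to each transcript (row). After the pass every
row has median 0 and median absolute deviation 1. A vector with zero MAD
is centered only, with a logged warning. The column-before-row order is a
configuration-visible decision; the exact formula in the source procedure
is typographically incomplete, so this transform is a reconstruction and
is flagged as such.

**Known leakage property.** Per-sample median centering subtracts a term
that tracks each sample's genome-wide dosage response. When the genome has
only a handful of independent copy-number segments, every null
transcript's normalized expression acquires a negative correlation with
copy number, inflating the histogram-based signal-proportion estimate
(observed up to ~+0.15 on a 4-chromosome toy genome with arm-sized
segments). With segment granularity matching observed tumor burden
statistics (dozens of independent segments per genome) the leakage is
negligible (null mean correlation ≈ −0.02). This is a property of
median-centering dosage-structured data, not of the estimator; analysts
applying the pipeline to genomes dominated by a few arm-level events
should expect an upward-biased signal proportion.

## Dosage association

Per transcript, expression is regressed on the log2 transcript copy-number
ratio by iteratively reweighted least squares with the Huber ψ (tuning
constant 1.345, the conventional 95%-efficiency choice) and MAD-estimated
scale, converged at a 1e-8 coefficient change or 50 iterations (the
statsmodels RLM implementation under the hood). The slope's two-sided
p-value uses the t distribution with N−2 degrees of freedom. The plain
Pearson correlation is reported alongside; the robust slope is the tested
quantity.

Multiplicity: Benjamini–Hochberg step-up at FDR 1% (Storey's q-value could
be substituted; BH is the standard reading of an unspecified "FDR"
procedure). Signal proportion: 1 − π̂₀ with π̂₀ = #{p > λ}/(M(1−λ)) at
λ = 0.5, clipped to [0, 1] — the standard upper-tail histogram estimator;
how the source analysis derived its proportion from the p-value
distribution is not recoverable, so this is a stated stand-in.

Dose–response uses six half-open, upper-inclusive ratio bins
(0, 0.5], (0.5, 0.93], (0.93, 1.07], (1.07, 2], (2, 4], (4, ∞), reporting
per-bin counts, quartiles, means, and mean shifts relative to the
no-change bin with fold-change equivalents 2^|Δ| rounded to one decimal.
The genome scan reports −log10 p per transcript in genome order with the
Bonferroni line at α/M (α = 0.01) and flags clustered regions: maximal
runs of ≥ 5 consecutive super-threshold transcripts within a chromosome.

## Independent-cohort screening

Case/control association is the t-statistic ("Z-score") of the slope from
least-squares regression of expression on the 0/1 case indicator,
computed in closed form for all transcripts at once; it equals the
pooled-variance two-sample t, and its square equals the regression F on
one numerator degree of freedom (asserted in tests). The disease-associated
flag defaults to |Z| > 6; a signed variant (Z > 6) is available — the
source cutoff is quoted one-sided, the absolute-value default is the
package's decision and is configurable.

Survival association fits, per transcript, a Cox proportional-hazards
model with covariates (expression, age, sex dummy) on tumor cases,
counting only cancer-specific deaths as events and censoring other deaths.
Event-free subjects with follow-up under 4 months are excluded (the
co-morbidity rule); subjects who died of the cancer within 4 months are
retained, since the exclusion targets unobserved early censoring, not
observed disease deaths. The survival-associated cutoff defaults to
|Z| > 1.96; no published value exists, so this is a reconstruction.

Set enrichment compares the candidate set's statistic with B = 1000 random
same-size subsets drawn without replacement from the screened universe;
the default statistic is the count of members exceeding the flag cutoff
(the downstream selections are cutoff-based), with mean |Z| and the
two-sample Kolmogorov–Smirnov distance as alternatives, all three reported
by the pipeline. The empirical p-value uses the add-one correction
(1 + #{null ≥ observed})/(B + 1), which is never zero and is valid under
the subset-sampling null (uniformity verified by simulation).

## PC risk scores and landmark ROC

The expression of a flagged transcript set is summarized by the first two
principal components (per-transcript centering, SVD; loadings unit-norm and
orthogonal; each component's sign fixed so its largest-magnitude loading is
positive). PCs are computed once on the full analysis cohort and held fixed
during the jackknife; only the Cox coefficients are re-fit per fold (the
fully nested alternative is a configuration switch).

Cox models — {stage}, {PC1, PC2}, {stage, PC1, PC2}, for each of the two
transcript sets — use Efron tie handling (lifelines), with stage coded as
a continuous integer 1–4. Hazard ratios are exp(β̂) with Wald 95% CIs.
Per-subject risk scores are jackknifed: subject i's linear predictor is
evaluated under the model fit without subject i, centered on the training
fold's covariate means.

The 2-year (24-month) ROC is the cumulative-case / dynamic-control
estimator in its Kaplan–Meier form: with S the KM survivor function of the
cohort and S_c the KM survivor function among subjects with score above
cutpoint c,

    TPR(c) = (1 − S_c(t))·P(X > c)/(1 − S(t)),
    FPR(c) = S_c(t)·P(X > c)/S(t),

without nearest-neighbor smoothing. With no censoring before the landmark
this reduces exactly to the empirical cases-vs-controls ROC (asserted in
tests). AUC is the trapezoid over the curve points plus (0,0)/(1,1)
endpoints, sorted by (FPR, TPR) so tied-FPR vertical runs contribute no
area; the estimator can be mildly non-monotone under heavy censoring, in
which case this sort gives the standard rearranged curve. Two models'
AUCs are compared by a paired bootstrap over subjects (default B = 2000)
with an add-one-corrected two-sided p-value; the comparison method behind
the published analysis is not documented, and the bootstrap is chosen for
generality.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Genome layout** — a few chromosomes of ~64 Mb with uniformly scattered
  SNPs; chromosome 1 carries a structured tail (an isolated 3-SNP cluster
  beyond a >1 Mb SNP desert and a region with no SNP within 250 kb) plus
  pinned transcripts so that every mapping rule, including unmapped, is
  exercised by construction. Most other transcripts are anchored on runs
  of 5 SNPs, as on real arrays where the dense-overlap rule dominates.
* **Copy number** — per sample, breakpoints form a Poisson process at
  0.2 /Mb and segment ratios are drawn from six levels
  {0.3, 0.7, 1.0, 1.5, 3.0, 4.5} with probabilities
  {.05, .15, .5, .2, .07, .03}, spanning every dose–response bin.
  The rate and level weights were calibrated so the per-sample
  genome-altered fraction reproduces observed node-metastatic tumor burden
  (mean ≈ 0.49, SD ≈ 0.10, range ≈ 0.27–0.72). Measurement noise is
  multiplicative log-normal (2^N(0, 0.15) by default), keeping ratios
  positive.
* **Expression** — a configurable fraction (default 0.3) of mapped
  transcripts is dosage-responsive: log2 expression = baseline(U(5,10)) +
  β·log2(CN ratio) + N(0, 0.3), β defaulting to exactly 1 for clean
  recovery arithmetic (a β spread is available).
* **Testing cohort** — cases carry a mean shift (default 1.2 log2 units)
  on designated transcripts; case survival is exponential under a
  proportional-hazards model, log-hazard linear in the standardized
  expression of designated risk transcripts (default HR 1.5 per SD each)
  and in stage (HR 1.5 per stage unit), baseline median survival
  24 months, independent exponential censoring (0.02 /month), ~10% of
  deaths relabeled non-cancer-specific, ages uniform on 23–84, sex
  Bernoulli(½).

All randomness descends from one integer seed via `numpy` SeedSequence
spawning; identical arguments give bit-identical outputs.

What the generator does **not** emulate: probe-level intensities, batch
and GC effects, correlated expression modules, genome-position-dependent
SNP density, recurrent (cohort-shared) CNA regions, competing risks, or
covariate-dependent censoring. Passing recovery tests therefore certify
the statistical machinery under the stated generative model, not
robustness to those real-data complications.

## Problem sizes in the shipped checks

The test suite and the acceptance script run at desk scale, chosen to keep
estimator behavior representative: discovery cohorts of 20 samples with
700–4,000 SNPs and 150–2,000 transcripts over 2–4 chromosomes; testing
cohorts of ~150 cases and 30–45 controls; 100–200 replicates for coverage
and calibration suites; permutation and bootstrap counts of 150–1,000.
Calibration checks (uniform null p-values, Benjamini–Hochberg false
discovery control) use the closed-form screening route for replicated
simulation and the full robust-regression route for single-cohort checks.

## Known limitations

* The survival screen loops a full Cox fit per transcript; at tens of
  thousands of transcripts this is the pipeline's slowest stage (a
  score-test screen would be faster and is a natural extension).
* The fused-lasso penalty default is a denoising heuristic, not an
  FDR-calibrated choice; burden estimates near the call thresholds are
  sensitive to it at high noise.
* The leakage property of median renormalization (above) biases the
  signal-proportion estimate upward on coarse-segment genomes.
* Empirical enrichment p-values are bounded below by 1/(B+1).
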