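# Methods

## Problem and model

Somatic mutations recur at specific short genomic windows ("hotspots")
either because the site is under positive selection in the tumor or because
the local background mutation rate is elevated. Distinguishing the two
requires a background model that is both *position*-specific (sequence
context, chromatin state, replication timing, regional rate) and
*patient*-specific (mutation burden, signature activity). `hotscan`
implements that separation in three stages.

**Background model.** The mutation status of a (patient *i*, position *j*)
pair is modelled as an independent Bernoulli trial,

    P(y_ij = 1) = logistic( beta0 + beta . x_j + gamma . z_i )

where `x_j` are position-level covariates and `z_i` are sample-level
covariates. Separate models are intended for SNVs and indels, which arise
from different mutational processes; the variant class is a first-class
parameter throughout.

Position-level covariates are: the strand-collapsed sequence context of the
site (center-base pyrimidine class, 1-bp and 2-bp flanks, trinucleotide and
pentanucleotide, each one-hot encoded with the lexicographically first level
dropped), a homopolymer-run indicator for indel models (a mononucleotide
run longer than 5 bp overlapping the site), the cohort's local mutation
rate in 100-kb bins, and any user-supplied binary (BED) or continuous
(bedGraph/bigWig) track. Sample-level covariates are ln(mutation count + 1),
centered on the cohort mean, plus optional user columns (signature
proportions, subtype indicators).

**Feature selection.** Candidate position-level covariates are filtered by
stability selection: the model is refitted with an L1 penalty on 100
subsamples of 50% of the training rows (m-out-of-n without replacement),
the penalty chosen per subsample by 10-fold cross-validation with the 1-SE
rule, and a covariate is retained when its selection frequency strictly
exceeds 0.90 (sequence-context features) or 0.75 (all others). Sample-level
covariates bypass selection and always enter the final model. The final
fit is unpenalized maximum likelihood.

**Recurrence test.** Every analyzable nucleotide is a hypothesis: a window
of length l (default 21, chosen because TF-binding motifs are mostly
shorter than 20 bp) centered on it. Windows holding mutations from at
least n distinct samples (default 2) are evaluated; all other positions
carry p = 1. The test statistic is the number of distinct mutated samples
K in the window, and its null law is Poisson-binomial with per-sample
success probabilities

    q_i = 1 - prod_{j in window} (1 - p_ij),

i.e., independence of positions within the window. The exact tail
P(K >= k_obs) is computed by dynamic-programming convolution of the pmf
(O(N^2), exact to machine precision; verified against 2^N enumeration).
Benjamini-Hochberg correction runs over all analyzable nucleotides
(genome mode) or all analyzable nucleotides of the regions of interest
(region mode); the p = 1 padding is folded into the step-up analytically,
which is algebraically identical to running textbook BH on the padded
vector.

## Case-control intercept correction

The model is fitted on a balanced case-control sample (up to 1M mutated
events and as many non-mutated position-sample pairs), which inflates the
fitted intercept by ln(f1/f0), where f1 and f0 are the sampling fractions
of the two classes. At prediction time the intercept is corrected by
subtracting ln(f1/f0) so probabilities are on the genome-wide prior scale.
Without this correction the absolute probabilities are wrong by orders of
magnitude and the Poisson-binomial test loses calibration entirely; the
correction leaves slope coefficients untouched (case-control logistic
regression is consistent for them) and is validated by the
control-doubling invariance test and the decile-calibration study.

## Numerical and design choices

* **Coordinates.** All interval types are 0-based half-open (BED);
  mutation positions are 1-based (VCF). Conversions happen only in the IO
  layer.
* **Strand collapse.** Contexts are reported on the pyrimidine strand of
  the center base, the standard mutation-signature convention; the
  involution property (a genome and its reverse complement give identical
  collapsed contexts at mirrored positions) is property-tested.
* **Standardization.** Continuous covariates are divided by their
  training-sample SD before penalized fitting so the L1 penalty is
  comparable across features; mean-centering is omitted because the
  intercept absorbs it and omitting it keeps one-hot blocks sparse.
  Binary covariates stay 0/1. Coefficients for continuous features are
  therefore per-SD.
* **Path solver.** The L1-logistic path is computed by an in-package
  warm-started proximal-Newton coordinate-descent solver (working set =
  active coordinates plus KKT violators; weighted Gram on the working set;
  step halving on the penalized objective). A pathwise solver is needed
  because stability selection refits the cross-validated path on every
  subsample; generic single-penalty solvers make that loop orders of
  magnitude slower. Solutions agree with scikit-learn's saga L1 fits to
  ~1e-8 at matched penalties (unit-tested). The path stops early once the
  per-step gain in explained-deviance fraction falls below 1e-5
  (normalized to a 100-point, 4-decade grid) — the standard pathwise-
  solver stall rule; without it cross-validation compares against deeply
  overfit penalties it would never select.
* **1-SE rule.** lambda_1se is the largest penalty whose mean CV deviance
  is within one standard error (across folds) of the minimum; folds are
  stratified by label. On pure-noise data the rule returns the empty
  support in ~90% of runs; the residual fold-split sensitivity is shared
  by reference pathwise implementations and is documented in the unit
  test.
* **Windows straddling masked bases.** Masked or context-less positions
  contribute nothing to q_i (skipped in the product); a candidate center
  must itself be analyzable. This keeps the BH hypothesis count equal to
  the analyzable-mask size.
* **Merging.** Overlapping significant windows sharing at least one
  mutated position are reported as one hotspot spanning their union, with
  the minimum p-value and its window as representative. Merging is
  report-level only; the BH correction runs on the unmerged per-center
  p-values, which is conservative.
* **Degenerate fits.** Constant and aliased design columns are dropped
  with a warning (QR with pivoting on the centered design); separation or
  non-convergence triggers a ridge-stabilized Newton refit (alpha = 1e-4)
  with standard errors from the regularized information matrix.
* **Threads.** The scan can partition candidate windows across threads;
  chunks are reassembled in deterministic order, so results are
  byte-identical for any thread count.

## Baseline strategies

Four simpler backgrounds are available for comparison, sharing the scan
and correction machinery: (1) a shared binomial rate
(total mutations / (mask x samples)); (2) per-sample rates burden_i/mask;
(3) per-sample rates modulated by the relative mutation rate of
replication-timing quantile bins; (4) additionally modulated by the
100-kb local-rate bin's relative rate. Note that under sample-distinct
recurrence counting, moving from (1) to (2) does not guarantee fewer
calls: at fixed total rate, P(K>=2) ~ (S^2 - sum q_i^2)/2 is maximal for
homogeneous q, so heterogeneity can only shrink p-values. The covariate
corrections (3, 4) do reliably suppress calls, because they raise the
background exactly where mutation clusters form.

## Synthetic data and what the studies show

The generator emulates the model family itself: i.i.d. bases at a set GC
content; binary tracks as random non-overlapping 1-kb intervals at a set
coverage; continuous tracks as a standardized sinusoid plus noise (a
replication-timing stand-in); mutations drawn Bernoulli-per-(sample,
position) from the logistic model; spiked hotspots that override the
per-sample *window* success probability. Because generation matches the
fitted family, parameter-recovery and calibration results are clean
in-family checks: they validate the estimator and the test machinery, not
the adequacy of the covariate set for real tumors. Real-data features the
generator does not emulate: mutational-signature-specific context biases
beyond the configured coefficients, copy-number and clonality structure,
calling artifacts, and correlated tracks.

### Reference study conditions (hotscan.studies)

* **Exactness** — Poisson-binomial tail vs exhaustive enumeration
  (N <= 12, 100 random vectors, all k) and vs the binomial survival
  function for homogeneous q up to N = 500; BH vs textbook BH on
  explicitly padded vectors (100 random cases).
* **Planted-support recovery** — 10-Mb genome, 30 samples, 20 candidate
  binary tracks of which 3 carry effects (1.2, -1.0, 0.8), ~200,000
  training rows. Study-scale selection settings: 20 bootstraps, 5-fold
  CV, 25-point penalty grid over two decades (library defaults are 100
  bootstraps, 10 folds, 100 points over four decades; the planted effects
  are strong enough that the frequency estimates separate cleanly at the
  smaller scale, with selection frequencies of 1.0 vs 0.0).
* **FDR calibration and spike-in power** — a low-burden cohort
  (10 Mb, 30 samples, ~0.15 mutations/Mb/sample, as in pediatric tumor
  genomes), intercept-only background. Null cohorts are expected to
  produce zero calls; spiked cohorts carry ten 21-bp windows with
  per-sample success 0.15. The background rate for this condition was set
  by power arithmetic on the Poisson-binomial tail: two mutated samples in
  a window must remain significant after correction over 1e7 hypotheses,
  which bounds the admissible background rate from above; higher-rate
  cohorts would need proportionally more recurrence, not a different
  method. A corollary of working in this regime is that a *chance*
  two-sample cluster — expected about once per ~200 null cohorts — is
  also genuinely significant and will be called; the BH procedure bounds
  the frequency of such events, not their existence, so occasional null
  runs with one call are expected behavior, not a calibration defect.
* **Calibration** — 1-Mb genome, 30 samples, 2e-4 background, one binary
  and one continuous covariate with effects (1.0, -0.5), burden
  heterogeneity 0.4 log-odds SD; decile-binned predicted vs observed
  mutation frequencies agree within 3 Monte-Carlo SDs.
* **Mode consistency / determinism** — identical windows receive
  identical p-values in genome and region mode (only the BH hypothesis
  count differs); end-to-end reruns, including different thread counts,
  produce byte-identical hotspot tables.

## Known limitations

* The local-rate covariate includes the tested window's own mutations
  (no leave-one-out), a potential mild circularity inherited from the
  method's design; at 100-kb bin width a single hotspot's contribution is
  negligible.
* Indel support is plumbing-complete (classification, homopolymer
  feature, separate scans) but the validation studies focus on SNVs.
* bigWig input requires pyBigWig; bedGraph is the fully supported
  text path.
* The O(N^2) Poisson-binomial convolution is exact and fast up to a few
  thousand samples; far larger cohorts would warrant an FFT or
  Refined-Normal approximation.
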