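# Methods

`ctcsig` re-implements, as a tested pipeline, the analysis used to profile
circulating tumor cells (CTCs) captured from blood of metastatic
castration-resistant prostate cancer patients by EpCAM immunomagnetic
enrichment. The enriched fraction is never pure: it carries non-specifically
isolated blood cells (mostly lymphocytes). Both arms of the analysis revolve
around subtracting that background — on arrays by discarding everything the
healthy-donor samples express, on qPCR by normalizing against the leukocyte
marker CD45.

## Discovery arm (arrays)

**Inputs.** One spot-level table per array in an Agilent
Feature-Extraction-style tab-delimited dialect (probe name, gene symbol,
processed and background-subtracted signals, per-spot background estimate,
QC flags, control type). The processed signal is used for analysis; the
background-subtracted signal is retained but not used by default, because
processed signals show lower replicate variation. Intensities are stored
linear; the log2 transform happens during preprocessing because the QC
criteria are defined on raw signals.

**Spot QC.** Three criteria per array, applied in order with each failing
spot attributed to the first criterion it fails:

- (a) non-uniform pixel outliers and population replicate outliers, read
  from the upstream feature-extraction flags;
- (b) spots not distinguishable from their own background, read from the
  upstream above-background flag (the per-spot background test belongs to
  the scanner software and is consumed, not recomputed);
- (c) spots in the range of the negative controls: processed signal at or
  below mean + k·SD of the array's negative-control processed signals.
  k defaults to 3, the conventional choice; k = 0 disables the criterion
  (with k > 0, an array without negative controls is a configuration
  error). The SD is the sample SD (ddof = 1; zero for a single control).

A probe is **detected** on an array iff it passes all three criteria.
Control spots never propagate downstream.

**Normalization.** Signals are log2-transformed (floored at 2^-10 to keep
zeros finite) and quantile-normalized across all arrays: each sample's
rank-r value is replaced by the across-sample mean of rank-r values; a run
of tied values receives the mean of the substitutes for the ranks it
occupies (the limma `ties=TRUE` behaviour). After normalization the sorted
columns are identical for tie-free data; with ties inside a column the
equality holds up to tie-averaging.

Normalization runs over the **full experimental probe set**, not over the
probes passing QC in every array. Restricting to the everywhere-passing set
would remove exactly the probes whose patient-restricted detection defines
the CTC signature (a CTC probe is, by design, in the negative-control range
of every healthy array), and random per-array outlier flags would discard a
large fraction of the design across 15 arrays. Every spot has a measured
signal, so the full matrix is well defined; detection stays a parallel
boolean layer (normalize first, filter later — the limma convention).

**Probe collapse.** Gene value = median of its probes per sample (robust to
a single aberrant probe); a gene is detected when any constituent probe is.
Probes without a gene annotation keep their probe id as gene name and are
reported as unannotated.

**Signature rule.** With patient presence count `p_g` and healthy presence
count `h_g` per gene (counted on the detection matrix, not on intensities),
a gene is CTC-specific iff `h_g <= max_healthy_count` (default 0: any
healthy detection excludes, the strict reading of background subtraction)
and `p_g >= min_patient_count` (default 5, against the 9-patient / 6-donor
cohort design). Selection is monotone in both parameters and the output
order (descending patient count, then name) is deterministic. "Presence" is
evaluated at gene level after collapse; both thresholds are configurable.

## Validation arm (qPCR)

**Scoring.** Replicate wells (duplicates by default) are averaged first.
With cycle floor `F` (default 40, the last cycle the instrument reads; wells
that never amplify sit at the floor), the marker score is

    score = (F - mean Ct_gene) - (F - mean Ct_CD45) = Ct_CD45 - Ct_gene,

a log2-like expression level relative to the lymphocyte content of the
capture. Higher score = higher expression; a fully undetected marker scores
-(F - Ct_CD45). The direction of the subtraction is a convention choice
made so that "high expression" sorts high. A sample missing a marker is
missing, not zero; a sample missing CD45 is an error naming the sample. The
1:10 dilution and 14-cycle pre-amplification used upstream of the Ct table
are wet-lab bookkeeping with no computational correction.

**Per-marker tests.** Two-tailed Mann-Whitney U (U counts x>y pairs, ties
half). Small untied samples (min n <= 8) use the exact null distribution;
otherwise the tie-corrected normal approximation with continuity
correction. p-values are adjusted across markers by Benjamini-Hochberg
step-up FDR (the default meaning of "FDR adjustment"; adjustment spans all
markers in the table, including non-significant ones). Per-marker
discrimination is the AUC, which equals U/(n1·n2) exactly; its confidence
interval uses the DeLong structural-component variance, truncated to [0,1].

**Combined panel.** A binomial-logit model on the marker scores
(complete cases; needs at least genes+2 of them), fit by iteratively
reweighted least squares to relative deviance change < 1e-8 (max 100
iterations). The panel score is the linear predictor; the panel ROC/AUC is
computed on it. Logit is the canonical binary-outcome choice for building a
combined ROC; perfectly separated data have no finite MLE, so the fit stops
at the iteration cap, flags the separation, and the AUC (1.0) remains
valid. Weights are floored at 1e-12 and the linear predictor clipped at
±30 for numerical stability.

**Correlation.** Pearson product-moment r with the two-sided t-test on
n-2 df, for continuous clinical covariates (PSA, LDH, alkaline
phosphatase). Zero-variance input is an error rather than a silent NaN.

**Dichotomization.** low ⟺ score <= cut. Cuts: median, 70th percentile by
the nearest-rank definition (the ceil(0.7·n)-th order statistic —
deterministic and software-independent), or a fixed number so published
marker cutoffs (-3.8, -4.1, 0.4, -4.0, 0.5, -2.0 for HOXB13, MAOA, FGD4,
MOSPD1, QKI, SDK1) can be replayed exactly.

## Survival analysis

Follow-up in months; event = observed progression/death, otherwise
right-censored; at tied times events precede censorings.

- **Kaplan-Meier**: product-limit estimator with Greenwood variance.
  Median = smallest time with S(t) <= 0.5 (NaN = not reached), with a
  log(-log) pointwise-band confidence interval.
- **"Mean" survival** is reported as the restricted mean: the area under
  the KM curve up to the largest observed time, with the standard
  large-sample variance (sum over event times of the squared remaining
  area times d/(n(n-d))) — the convention of mainstream clinical-stats
  software, stated explicitly because "mean survival" is otherwise
  undefined under censoring.
- **Log-rank**: two-group observed-minus-expected with hypergeometric
  variance, χ² on 1 df.
- **Cox**: Newton-Raphson on the partial likelihood, Breslow tie handling
  by default (Efron available), convergence at max |score| < 1e-8 within 50
  iterations, Wald SEs from the inverse observed information. Covariates
  are standardized internally (results mapped back) so the divergence guard
  is scale-free; a coefficient drifting past 15 internal units marks a
  monotone likelihood (separation in time order) — the fit stops, warns,
  and reports the capped coefficients. The score test at β = 0 is exposed;
  on tie-free two-group data it equals the log-rank χ².
- **Marker report**: per marker, dichotomize, KM restricted mean ± 95% CI
  per group, log-rank p — one low/high row pair per marker, reproducing the
  published table layout. Log-rank p-values in this report are unadjusted.
  A marker whose cut empties a group is skipped with a warning.

## Synthetic cohorts

The generator provides ground truth for every stage; it is emitted in a
separate structure the pipeline never reads, so recovery tests cannot leak
labels. Fixed seeds make all outputs bit-reproducible.

**Arrays** (defaults: 9 patients, 6 healthy donors, 2000 genes × 2 probes,
100 negative controls, 40 spiked CTC genes at 70% per-patient presence).
Log2 intensities are Gaussian: blood-background genes at mean 8, SD 1 in
every sample; spiked CTC genes add a +6 log2 shift in the patient arrays
that carry them; everything unexpressed (CTC genes elsewhere, negative
controls) sits on a noise floor at mean 4, SD 0.5. The above-background
flag encodes the generator's truth that a spot carries signal — the
analogue of the scanner's per-spot background test, which this package
consumes rather than recomputes. Outlier flags land on a random 2% of
spots. With these margins, detection recovers the spiked occupancy pattern
exactly (up to the rare event that every probe of a spiked gene is
outlier-flagged on the same array). About 5% of non-spiked genes carry no
annotation, to exercise the unannotated bookkeeping.

**qPCR** (defaults: 28 patients, 15 controls, duplicates, replicate noise
SD 1 cycle, floor 40). CD45 sits near cycle 25 (SD 1.5 across samples); a
marker's true score is a per-gene baseline plus a +2 patient shift for the
six validated markers (0 for ARL4A, which was not significant). Baselines
are anchored so each validated marker's patient-group mean equals its
published cutoff — those cutoffs were quantiles of the real patient
scores, so a realistic cohort must straddle them. Ct values are generated
as CD45 Ct minus the true score plus replicate noise, clipped at the floor.

**Survival.** Event times are exponential with log relative hazard
Σ coefs·scores, mean-centered so the baseline rate (median 8 months at the
cohort-average score, a PFS-like scale) fixes the time scale wherever the
scores sit; the default coefficients put +0.3 per score unit on the six
validated markers. A record is censored with probability `censor_rate`
(default 0.2), at a uniform time before its event — equivalent to uniform
censoring over the follow-up window conditional on being censored, which
makes the realized censoring fraction equal the configured rate.

**What the generator does not emulate:** amplification bias of whole-
transcriptome amplification, dye/spatial artifacts (assumed corrected
upstream of the files read), probe cross-hybridization, correlated marker
scores within a sample, qPCR efficiency differences, or informative
censoring. Passing tests therefore demonstrate that the statistics and the
selection logic are implemented correctly and calibrated under the design
assumptions — not that the biological signature would replicate in new
patients.

## Problem sizes used by tests and the acceptance script

Spike-in recovery runs the full 15-array × 2000-gene design (seconds).
Null calibrations use 2000 replicate qPCR cohorts (Mann-Whitney, α = 0.05
band 0.04-0.06) and 1000 replicate survival cohorts (log-rank, band
0.03-0.07). Estimator recovery uses n = 500 (Cox, true log-HR 0.7) and
n = 2000 × 8 replicates (logistic, true coefficients 2 and -1; averaging
replicates measures estimator bias rather than single-draw sampling
noise, whose SE per draw is ~0.07).

## Known limitations

- The published headline gene counts (54 selected / 50 annotated, ~48% of
  spots filtered) belong to the deposited patient cohort; reproducing them
  requires downloading the GEO series (GSE153514) and running `discover`
  on those files with the default policy. Nothing in this package depends
  on network access.
- Exact Mann-Whitney enumeration is used only for untied samples with
  min(n) <= 8; the asymptotic path is mildly conservative at the
  validation-cohort sizes (empirical size ≈ 0.042-0.05 at α = 0.05).
- The Cox implementation targets small clinical cohorts (risk-set sums are
  O(n²) in the number of event times); it is not tuned for biobank-scale
  data.
- DeLong confidence intervals are truncated to [0, 1] and degenerate at
  AUC = 1 (zero variance), where the separation flag is the meaningful
  output.
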