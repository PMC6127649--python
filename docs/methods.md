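# Methods

This note records the models, estimators and numerical choices behind
`qeegkit`, and what the synthetic-data tests do and do not establish
about real EEG.

## Scalp spectra

Resting EEG (19-channel 10/20 montage, linked-ear reference, 100 Hz in
the default configuration) is cut into non-overlapping, contiguous
256-sample epochs; epochs containing any sample above a configurable
absolute-amplitude threshold are dropped, and a recording with fewer
than 20 clean epochs is rejected as unusable.  Amplitude thresholding is
a deliberately simple stand-in for dedicated artifact-removal tooling;
it catches the planted transients the generator can produce but not
real ocular or muscular artifact structure.

The cross-spectrum is the Bartlett estimate: the average over epochs of
X(f) X(f)^H / N^2, with X the DFT of the demeaned epoch and no taper.
The per-epoch mean is removed because the DC bin is outside the analysis
band anyway and demeaning reduces leakage from slow drifts.
Discontinuities between concatenated clean segments are ignored.  The
one-sided, non-doubled periodogram convention is used throughout:
epoch variance = p_0 + p_{N/2} + 2 sum(interior bins), a relation the
test suite asserts to 1e-8 relative (Parseval).

The analysis grid keeps the DFT bins of the epoch inside
[0.78, 19.14] Hz inclusive: spacing fs/N = 0.390625 Hz, 48 bins
(1-based indices 2..49), hence 19 x 48 = 912 scalp features.  Band
limits printed to two decimals are accepted with a 0.005-Hz tolerance so
that 0.78 selects the bin at 0.78125 Hz.

Global amplitude differences between subjects are removed by geometric
power correction: every cell is divided by the geometric mean of power
over the in-band cells.  The correction is computed over the analysis
band only, not the full spectrum, because every downstream feature
lives in-band.  Power is then natural-log transformed toward
Gaussianity.

## Normative model and z-spectra

Each of the 912 features gets an age regression of the mean and of the
spread of log power:

* mu(age): least squares on a polynomial basis in log(age), degree 2 by
  default.  The degree and basis are configurable; nothing deeper than
  "smooth in log-age" is claimed.
* sigma(age): least squares of log squared residuals on the same basis,
  back-transformed with the chi-square smearing constant
  E[log chi2_1] = psi(1/2) + log 2 so that sigma is unbiased under
  Gaussian residuals, with residuals inflated by sqrt(n/(n-p)) for the
  mean-fit degrees of freedom, and floored at 1e-6.

A subject's z-spectrum is (x - mu(age)) / sigma(age) cellwise.  Ages
outside the fitted range extrapolate with a warning rather than error;
a cohort with a single age falls back to per-feature mean/SD with a
warning.  On data generated from the model family, held-out z-scores
are N(0, 1) within Monte-Carlo tolerance (pooled mean within ±0.1, SD
within 0.9–1.1 at n = 200); this calibration is the module's core
acceptance property and is recomputed by `scripts/acceptance.py`.

## Group statistics: max-t permutation test

Per feature, a two-sample t statistic (pooled variance by default;
unequal-variance option available) compares the two groups' z-spectra.
Familywise error over the 912-cell grid is controlled by the
max-statistic permutation test: whole feature vectors are relabeled
jointly, preserving the cross-feature correlation; the null is the
maximum |t| over features per permutation (two-sided inference — the
direction of change is reported per cluster); the threshold is the
empirical 95th percentile of that null (10,000 permutations by
default); corrected p-values use (1 + #{null >= |t|}) / (n_perm + 1).
Ties at the threshold are non-significant.  When the groups admit no
more distinct relabelings than requested permutations the test
enumerates all of them exactly; the suite checks the exhaustive and
Monte-Carlo answers against each other on 3-vs-3 fixtures and the
familywise error rate on null cohorts (target 0.05, accepted band
0.03–0.07 over 500 simulations).

Permutations exchange labels freely, ignoring any age matching; the
z-transform has already removed the age trend, but matched-pair
structure, if present in real data, is not exploited — a documented
limitation.  The reported t convention is mean(first group sorted
lexically) minus mean(second); an effect planted as an increase in
group B therefore appears with negative t.

Significant cells are grouped into clusters by broad band and channel;
the default band partition is delta 0.78–3.5, theta 3.9–7.4,
alpha1 7.8–10.2, alpha2 10.5–13.3, beta1 13.7–19.1 Hz (edges chosen to
cover the grid without overlap).

## Simplified source imaging

The tomographic stage is intentionally minimal: given a lead field K
(electrodes x sources) and the graph Laplacian L of the source
adjacency, the inverse operator is T = (K'K + lambda L'L)^{-1} K', and
source power per bin is diag(T S(f) T^H), real and nonnegative for
Hermitian PSD S(f), floored at zero against roundoff.  A single global
lambda (choosable by generalized cross-validation on a calibration
matrix) replaces any variable-resolution weighting; sources are
abstract grid points on a chain, with no head model or atlas.  Two
structural facts are tested: exact recovery in the square noiseless
lambda→0 limit, and exact agreement between the source and scalp
pipelines under an identity lead field.  Because the Laplacian has a
null space (the constant source pattern), ||T|| shrinks monotonically
with lambda to a small floor rather than to zero.

## Graded-response IRT

Ordinal visual-reading items follow the logistic graded-response model
P(Y_j >= k | theta) = expit(a_j' theta - b_jk) with strictly increasing
thresholds.  Fitting is marginal maximum likelihood by EM:

* E-step on a fixed latent grid — 61 points on [-6, 6] for one factor,
  15 x 15 on the square for two — with standard-normal prior weights.
* M-step per item by L-BFGS-B in an unconstrained parameterization
  (threshold gaps through log), warm-started at the current values, so
  the observed-data log-likelihood is monotone non-decreasing (asserted
  every run).  Convergence is an absolute log-likelihood change below
  1e-4 by default.
* Two-factor fits use the echelon constraint (first item loads only on
  the first factor); categories observed fewer than 5 times are merged
  into neighbours before fitting.

Standardized loadings are a / sqrt(|a|^2 + c^2) with the logistic
scaling constant c = 1.702.  EAP scores are posterior means on the
quadrature grid.  Model order is compared by AIC = 2k - 2 loglik.

After EM reaches its tolerance, the fit is polished by direct L-BFGS
maximization of the marginal log-likelihood with the analytic MML score
(gradient verified against finite differences), so reported maxima do
not depend on the EM stopping point.

A caution on model-order selection: the comparison of one vs two
factors is statistically non-regular.  At the null — all second-factor
loadings zero — the marginal-likelihood score with respect to every
second-factor loading vanishes identically (the posterior of the unused
factor equals its prior), so the extra-factor likelihood-ratio
statistic is heavier-tailed than any chi-square and does not improve
with sample size.  In consequence AIC prefers the one-factor model on
unidimensional data *typically* (roughly four times in five on the
five-item instrument at 250 observations, at fully polished optima) but
not near-uniformly; a single observed "AIC increases with a second
factor" outcome is the expected behaviour, while a guarantee at, say,
the 90% level is not achievable for this model class.  This is a
property of the comparison itself, not of the estimator: the EM-plus-
polish optimum agrees with direct maximization of the marginal
likelihood to ~1e-9, and refining the quadrature raises rather than
lowers the two-factor likelihood.

The latent group test refits the one-factor model with a latent
regression: subject traits are N(beta * group, 1) (reference group mean
fixed at 0, variance fixed at 1 for identification), every row of a
subject — one per rater — shares the subject's latent value, and each
rater beyond the first contributes a fixed additive offset on the
trait, a deliberate simplification of a crossed random-effects design
that is identifiable with two raters.  The EM alternates item updates,
rater-offset line searches and the closed-form group-mean update; the
Wald standard error of beta comes from the empirical Fisher information
(sum of outer products of per-subject score vectors, obtained by
central differences of the per-subject marginal log-likelihood).  Test
calibration: type-I error within the binomial band around 0.05 on null
simulations, and essentially full power with the correct sign for a
1-SD planted shift at 50 + 50 subjects with two raters.

## Biomarker construction

Stability selection repeats, independently per iteration: a stratified
70/30 resplit; the IndFeat univariate screen
|m1 - m2| / sqrt(s1^2/n1 + s2^2/n2) at threshold 2 (the threshold is a
documented choice) on the training part; and an elastic-net-penalized
logistic regression (mixing parameter 0.5) on the survivors, with the
penalty strength chosen by inner 5-fold cross-validation on AUC using
the one-standard-error rule — the strongest penalty within one standard
error of the best — and with an iteration selecting nothing when even
the best penalty performs at chance.  Features with nonzero
coefficients count as selected; features selected in strictly more than
half of the (default 1000) iterations are retained.

A structural limitation worth stating plainly: resampled splits of one
fixed cohort cannot reject a feature whose *whole-cohort* association is
spurious but strong — the same lucky feature re-validates on every
split.  With p pure-noise features the maximum null screening statistic
grows like sqrt(2 log p), so a handful of noise features (a few out of
200) typically survive retention.  What the procedure does guarantee,
and what the suite verifies, is that noise retention stays rare (>= 97%
of noise features not retained in the planted design) while genuinely
informative features are retained reliably.

The retained set is evaluated by a further independent series of
stratified resplits (default 1000): a standardized logistic model is
fitted on the training part and scored on the held-out part; each
repetition yields an ROC curve (threshold sweep) and a trapezoidal AUC.
The median ROC is the pointwise median over a common false-positive
grid, made monotone; the AUC distribution is summarized by a Gaussian
kernel density (Scott bandwidth).  Closed-form oracle: for a single
unit-variance Gaussian feature with mean gap delta, population AUC is
Phi(delta / sqrt 2); the median cross-validated AUC reproduces
Phi(sqrt 2) ~ 0.921 within ±0.03 at n = 100 + 100.  Null
cross-validated AUC carries the standard small-test-set pessimistic
bias (median ~0.44 at 30 + 30 test splits), approaching 0.5 as the
test sets grow.

## Synthetic-data generator

The generator is the pipeline's ground-truth source and defines the
study conditions of every statistical test.

*Signals.*  Random-phase spectral shaping: the full-length rfft
amplitudes are fixed to the target one-sided density s1(f) (amplitude
sqrt(n fs s1 / 2)), phases are uniform.  Realized variance matches the
density integral exactly; the expected Bartlett bin power is
s1(f) * binwidth / 2 up to Fejér-kernel leakage (within ~6% per bin on
the default sloped spectrum).  The default density is a 1/f background
with an age-declining amplitude plus three Gaussian bumps: an alpha
bump whose centre rises ~7.6→9.1 Hz and whose amplitude grows over ages
5–11, an age-declining theta bump, and a small fixed beta bump.  The
exact coefficients are configuration, not claims about development.
Between-subject variability is log-normal: per-channel power gains
(log-SD 0.25) and a global amplitude factor (log-SD 0.4) that geometric
power correction removes.  An optional 25-Hz low-pass emulation exists
but defaults off; the band ends at 19.14 Hz so it is immaterial.

*Cohorts.*  Normative cohorts draw ages uniformly over a range (default
5–11 years, 60-s recordings, hence 23 epochs).  Study cohorts plant
effects by multiplying group B's density, over the full-resolution
window of each targeted (electrode, bin) cell, by exp(magnitude *
sigma_log); the window is widened by half a bin so epoch-window leakage
does not dilute the realized shift (~0.96 of nominal at the targeted
bins).  sigma_log comes from a fitted normative model when supplied
(per cell and age), else from the closed-form approximation
sqrt(tau^2 + trigamma(n_epochs)).  The default effect layout plants the
four-band cluster pattern (increased theta at T4/Pz/O2, decreased
alpha1 fronto-centrally, increased alpha2 temporo-parieto-occipitally,
increased beta1 at T4/T5/P4) at ±1.25 z.

*Items and lead fields.*  Item tables are sampled from the
graded-response model with latent N(group shift, 1) traits and additive
rater offsets; the default five-item bank mimics one near-uninformative
item (background frequency) among four discriminating abnormality
items.  Toy lead fields are Gaussian matrices smoothed along a chain of
sources, with an identity option for exactness tests.

What passing tests show — and what they do not: the generator's signals
are stationary, Gaussian, artifact-free and follow the normative model
family exactly, so the calibration results (z ~ N(0,1), FWER ~ alpha,
planted-effect recovery) validate the *estimators and their wiring*,
not their robustness to non-stationary, artifact-laden, or
norm-misspecified real recordings.

## Problem sizes in the shipped suites

The repeated-simulation studies run at sizes chosen to make their
binomial acceptance bands meaningful while keeping the default run
practical: 500 null cohorts at 500 permutations for FWER; 50
planted-cluster runs at the study's 46 + 62 group sizes with 1000
permutations; 50 model-order simulations at 250 rows; 200
stability-selection iterations on the 5 + 195 planted design; 400 ROC
repetitions for the AUC oracle.  The full 10,000-permutation default is
exercised through the API defaults and the pipeline configuration.

## I/O and pipeline

Recordings travel as TSV + JSON sidecar (the native fixture format) or
EDF: reading goes through MNE, writing through a minimal 16-bit EDF
writer (one-second records, per-channel physical scaling; round trip
exact to quantization).  All derived artifacts are TSV/JSON; the
end-to-end pipeline writes a manifest naming every file, its producing
stage and a configuration hash, and is deterministic given the
configured seed.
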