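# Methods

This note documents the models, algorithms and design choices behind
`ramanchemo`, and what the synthetic studies used by the tests do and do
not demonstrate about real data.

## Data model

A *scan* is a point Raman spectrum: a strictly increasing shift grid
(cm⁻¹) with intensities in arbitrary units. A *sample* is one dried
cell spot measured by several repeated scans (20 in the emulated
design); a *biological replicate* is an independently grown culture
contributing several samples; a *condition* is a growth-medium class,
here parameterized by the concentration of one added stimulus. All
modelling operates on a `SpectraSet`: an n × p intensity matrix on one
shared grid plus a metadata table. Grid alignment uses linear
interpolation onto the grid of the first manifest entry by default
(adequate at the ~13 cm⁻¹ optical resolution of the emulated
instrument; an exact set-intersection policy is available for grids
that should already agree).

## Preprocessing

Per sample, in this fixed order: (1) pointwise mean of its scans;
(2) truncation to the closed interval [400, 1800] cm⁻¹, the fingerprint
window containing most biomolecular bands; (3) Goldindec baseline
removal; (4) division by the euclidean norm. Averaging precedes
baselining so the polynomial is fitted once per sample on a spectrum
with √20-fold reduced noise; normalization comes last so all downstream
quantities live on the unit sphere and are comparable across samples.

### Goldindec baseline

Fluorescence background is modelled as a polynomial of degree 3 in the
shift. The fit minimizes an asymmetric truncated-quadratic cost:
residuals at or below the current baseline (and small positive
residuals) are penalized quadratically, while residuals above a
threshold *s* — peak points — contribute a constant, i.e. zero weight
in the iteratively reweighted least-squares step. The threshold is
driven by the *estimated peak ratio* p (default 0.5): at each iteration
*s* is the (1 − p) quantile of the current residuals, floored at zero,
so about a fraction p of the spectrum may sit above the background
without pulling it up.

Numerical choices:

* Shifts are affinely mapped to [−1, 1] before building the Vandermonde
  basis (conditioning).
* Before fitting, the signal is smoothed with a Savitzky–Golay filter of
  `smooth_window` points (default 5) whose local degree equals the
  baseline degree. This filter reproduces any polynomial of that degree
  exactly, edges included, which gives the scheme a clean fixed point:
  on a peakless polynomial input the first residual vector is zero, no
  point is down-weighted, and the result *is* the ordinary
  least-squares fit. A plain moving average would not have this
  property (its edge handling perturbs polynomial inputs).
* Convergence: relative change of the coefficient vector < 1e-6, cap of
  100 iterations. Because the coefficients are a deterministic function
  of the peak/background partition, a revisited partition means the
  iteration is flapping a few points across the threshold at working
  precision; this is also accepted as convergence. A genuine failure
  raises an error carrying the last iterate.
* The baseline is fitted on the smoothed signal but subtracted from the
  raw one.
* The scheme is exactly equivariant under intensity offsets: adding a
  constant shifts the fitted baseline by that constant and leaves the
  corrected spectrum unchanged.

On the generator's spectra (cubic baselines up to 1.5× the largest peak
amplitude, 2% noise) the recovered baseline's RMSE against the true
cubic is ~0.5–0.9% of the largest peak amplitude.

## PCA, outliers, DAPC

PCA is the standard mean-centered full decomposition (all components
kept; scores reconstruct the data to numerical precision). Outlier
screening flags spectra whose score on any of the first k PCs (default
5) exceeds z standard deviations of that component's scores (default
z = 3); components with zero variance are skipped. The rule and
threshold are configuration-exposed because no single criterion is
canonical for spectra.

DAPC is linear discriminant analysis on the first `n_pcs` PC scores
with equal class priors. The canonical variates solve the generalized
symmetric eigenproblem **S_b v = λ S_w v** (between-class vs pooled
within-class scatter of the retained scores), are ordered by decreasing
λ, scaled so the pooled within-class variance along each variate is 1,
and sign-oriented so the first class's centroid coordinate is ≤ 0
(reproducible plots). At most C − 1 variates exist for C classes. A
singular within-class scatter receives a small ridge (1e-8 on the mean
diagonal scale) with a logged warning. Classification assigns the
nearest class centroid in canonical space; exact ties break to the
lexicographically first label. `n_pcs` defaults to the smallest count
reaching 99% cumulative variance.

## Leave-one-out validation

For each spectrum, PCA **and** DAPC are refit from scratch on the
remaining spectra with the same `n_pcs`, and the held-out spectrum is
projected through the fold's basis and classified. The refit-everything
policy is the conservative reading of "presented with an unknown
spectrum": the held-out scan contributes nothing to centering, the PC
basis, or the discriminant axes (a property the tests verify by
rebuilding a fold manually). Metrics are one-vs-rest sensitivity and
specificity per class plus overall accuracy, reported next to the
uniform-random-classifier baselines 100/C % and 100·(1 − 1/C) %.

Label-permutation control: the per-fold PCA does not depend on labels,
so the fold bases are computed once and only DAPC is refit per shuffle.
One point to be aware of when interpreting it: LOO under permuted
labels is *expected* to score slightly below nominal chance (here
roughly 2 points below 25% on 36 spectra), because the held-out
spectrum's class always has one fewer training member than the others.
The control therefore checks that nominal chance lies well inside the
permutation distribution (within 3 of its per-shuffle standard
deviations), not that the permuted mean equals 25% to within its
standard error — the latter would reject any correct LOO implementation
about half the time purely from this structural bias.

## Distance statistics

TPD, TSD and TCD all share the form Σᵢ √((vₓ,ᵢ − v_ref,ᵢ)²) =
Σᵢ |vₓ,ᵢ − v_ref,ᵢ| — the square root applies per term, so these are L1
(city-block) distances, deliberately *not* euclidean norms; the
implementation follows the printed formula literally. TPD runs over the
first five PC scores (all available if fewer, with a logged warning and
the covered variance share), TSD over all normalized intensities, TCD
over the first five canonical variates (truncated to the C − 1 that
exist). The reference is either a named sample or a condition-group
centroid; the usual choice is the control-medium centroid, and the
pipeline defaults to the condition with the lowest concentration when
none is named (configurable, since some designs use the *native* medium
at a nonzero concentration as control). Group means are arithmetic
means of the per-spectrum rows.

## Downstream statistics

One-way ANOVA on a distance column against the condition factor uses
classical sums of squares with the F tail from `scipy.stats.f`; zero
within-group variance is flagged degenerate (F = ∞, p reported as a
machine-epsilon bound). Tukey HSD computes
q = |Δmean| / √(MSW/2 · (1/nᵢ + 1/nⱼ)) with adjusted p from the
studentized-range distribution (Tukey–Kramer for unequal sizes); for
two groups this coincides with the pooled t-test. An optional additive
two-way layout (condition + replicate, no interaction) is provided via
statsmodels because the replicate factor is the only other structured
factor in the design. Regression and Pearson correlation wrap
`scipy.stats.linregress`/`pearsonr`; a perfectly flat response is
reported as slope 0, R = 0 rather than NaN. Summary significance flags
use α = 0.05; exact p-values are always reported.

## Band–analyte correlation

A band intensity is the mean normalized intensity over the grid points
within center ± half-window (default 6 cm⁻¹ ≈ half the emulated
spectral resolution; the nearest grid point when the window is
degenerate). Correlations are computed on condition × biological
replicate means (4 × 3 = 12 points in the default design) rather than
bare condition means: that is the resolution at which chromatography
reference measurements are actually taken (one culture = one
measurement), and with only 4 condition means a Pearson |R| ≥ 0.7 would
arise by chance ~30% of the time, making the statistic nearly
uninformative about an unrelated analyte. With 12 points the null
probability of |R| ≥ 0.7 drops to ~1%.

## The synthetic study generator

Each scan is Σₖ aₖ gₖ(ν) + cubic baseline + gaussian noise, with
unit-height Gaussian/Lorentzian lines at typical biomass band positions
(FWHM ≥ 13 cm⁻¹), a per-sample random cubic baseline up to 1.5× the
largest peak amplitude, and noise SD of 2% of that amplitude. The
defaults mirror the emulated experiment: 4 classes at 0/7.5/15/30 mM,
biological triplicate, 3 samples per replicate, 20 scans per sample,
400–1800 cm⁻¹ at 2 cm⁻¹ steps. Replicate-to-replicate biology is
multiplicative lognormal jitter (σ = 0.05) on all peak amplitudes — no
replicate-variance model is canonical, and a single multiplicative
scale is the simplest structure that makes replicates cluster. All
randomness flows through one seeded generator; a (config, seed) pair
reproduces the study bit for bit.

Marker bands carry the dose response, linear in concentration:
phenylalanine-like 1005 and lipid-CH₂-like 1445 cm⁻¹ at +0.04 of base
amplitude per mM, carotenoid-like 1157 and 1520 cm⁻¹ at −0.025 and
−0.03 per mM. The opposing signs are deliberate twice over: stress
responses typically *reallocate* composition (protein/lipid signals up,
carotenoids down) rather than scaling the whole spectrum; and a
uniform-sign response is nearly invisible after vector normalization,
because the norm grows with the markers and cancels their relative
change.

Matched analyte tables emulate UPLC/GC-FID outputs: one level per
condition × replicate × analyte, affine in that cell's *noiseless
normalized* marker band intensity with multiplicative gaussian noise of
configurable CV (default 10%), clamped at zero. Using the normalized
(composition) quantity rather than the raw amplitude mirrors what
per-milligram-dry-weight chemistry measures, and makes the noise-free
table correlate with the measured bands at R ≈ 1 (not exactly 1: the
measured value still passes through baseline correction).

### What passing tests do and do not show

The generator produces smooth additive backgrounds, i.i.d. gaussian
noise, symmetric line shapes, and a strictly linear dose response. Real
spectra add cosmic-ray spikes, detector etaloning, photobleaching
drift within a scan series, band shifts and shape changes, and
saturating dose responses — none of which are modelled. Passing the
recovery suites therefore demonstrates that the *computational chain*
is correct and well-conditioned under the stated noise model, not that
any particular organism's phenotypes are separable; on real data the
preprocessing assumptions (polynomial background, stable band
positions) must hold for the downstream guarantees to transfer.

### Problem sizes

The default study (720 scans → 36 sample spectra) is the unit of the
end-to-end checks: leave-one-out over 36 folds with full refits, a
200-shuffle permutation control (reusing fold PCAs), 100-spectrum
baseline-recovery benchmarks, 200-seed null-correlation simulations and
1000-replicate type-I-error checks all complete in seconds on one CPU,
so the full suite runs comfortably on a laptop.

## Known limitations

* SPC/WDF binary readers are out of scope; spectra must be exported to
  two-column text (or simple JCAMP-DX).
* The outlier criterion is a pragmatic per-PC z-score, not a formal
  robust-distance test.
* DAPC assumes shared within-class covariance (inherited from LDA);
  strongly heteroscedastic classes would call for quadratic or
  regularized variants that are deliberately not included.
* "First five" components in TPD/TCD is a convention of the method, not
  an optimized choice; datasets whose variance is spread more thinly
  will under-represent differences beyond PC 5.
* Tukey HSD p-values assume balanced-ish groups and normal residuals;
  the package reports exact p-values and leaves multiple-α policy to
  the analyst.
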