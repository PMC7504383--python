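# Methods

## Scope

`phytospec` implements a leaf-spectroscopy modelling chain for pulse-
amplitude-modulation (PAM) chlorophyll-fluorescence traits: computation of
the fifteen quenching parameters from raw fluorescence yields, partial
least squares regression (PLSR) of those traits on 1-nm leaf reflectance
(350–2500 nm) with permutation-based validation and variable-importance
diagnostics, narrow-band vegetation indices, and multivariate phenotyping
of treatment groups from whole spectral signatures (PERMANOVA, PCoA,
PLS-DA).  A synthetic-data generator provides coupled spectra/fluorescence
studies with an ozone-treatment structure so that every stage is testable
without field data.

## Fluorescence parameters

From the five raw yields (F0, Fm dark-adapted; Fs, Fm', F0' light-adapted)
the standard parameters are computed verbatim:
Fv/Fm = (Fm−F0)/Fm, ΦPSII = (Fm'−Fs)/Fm', Fv'/Fm' = (Fm'−F0')/Fm',
ETR = ΦPSII·PPFD·0.5·0.84, qP = (Fm'−Fs)/(Fm'−F0'),
qN = (Fm−Fm')/(Fm−F0'), NPQ = (Fm−Fm')/Fm', qL = qP·F0'/Fs,
P = (Fv'/Fm')·qP, D = 1−Fv'/Fm'.  The constants 0.5 (PSII/PSI partition)
and 0.84 (leaf absorptance) are module constants.  Readings are validated
against the physical ordering 0 < F0 < Fm, 0 < F0' ≤ Fs < Fm' ≤ Fm; the
degenerate denominator Fm' = F0' is excluded by these preconditions and is
rejected with a validation error rather than returning NaN.  P ≡ ΦPSII and
D ≡ 1−Fv'/Fm' are algebraic identities and are enforced to machine
precision by the test suite.  The default PPFD is 270 µmol m⁻² s⁻¹ (the
actinic level of the emulated protocol).

## Spectra

Spectra are unitless reflectances on a strictly increasing integer-nm
grid.  Preprocessing follows the minimal-intervention convention for
untransformed reflectance: splice-jump correction and interpolation only.

* **Splice correction.** Detector boundaries are fixed at 1000/1001 and
  1800/1801 nm.  The discontinuity is estimated by least squares over a
  ±50 nm window as the step coefficient of a cubic-trend-plus-step model,
  and each segment right of a boundary is rigidly shifted; the VNIR
  segment anchors the spectrum.  A locally cubic spectrum is left
  unchanged; the operation is idempotent.  The estimator degree/window
  were chosen by a design sweep on clean synthetic output to maximise the
  margin between noise (SD 0.005 per channel) and the 0.01 flag threshold.
* **Resampling** is linear interpolation onto an inclusive 1-nm grid;
  extrapolation is refused.
* **Replicate averaging** is the per-wavelength arithmetic mean, with the
  replicate count recorded.
* **Quality control** targets three operational failure modes with
  configurable thresholds: mean visible reflectance (400–700 nm) above
  0.15 (`VIS_ELEVATED`); a splice-step estimate above 0.01 at either
  boundary (`SPLICE_JUMP`); and an inverted red edge — positive quadratic
  curvature over 700–750 nm together with a negative fitted slope over
  735–750 nm (`REDEDGE_CONCAVE`).  The curvature/slope tests are
  least-squares versions of the second/first differences; raw
  single-channel differences would be dominated by channel noise at the
  default noise level.
* All modelling is restricted to 400–2400 nm (noisy sensor edges
  discarded).

## PLSR

PLS1 is implemented by NIPALS with X-deflation only (y-deflation is
unnecessary for a univariate response given score orthogonality).
Predictors and response are centred and autoscaled by default, which makes
standardized coefficients and VIP well defined on reflectance data; the
raw-unit coefficient path is retained for prediction.  Regression
coefficients are b = W(PᵀW)⁻¹q.  At A = min(n−1, p) components on
full-rank data the solution equals ordinary least squares; the tests use a
normal-equations solve and scikit-learn's PLS as independent oracles.
Zero-norm weight vectors (rank exhaustion) truncate the component count
with a warning.  Convergence tolerance for the iterative PLS2 variant is
1e-10 with at most 500 iterations per component.

Component choice uses leave-one-out PRESS.  Two rules are exposed:
`"min"` (argmin) and the default `"onesigma"` — the smallest count whose
PRESS is within 5% (relative) of the minimum, a guard against overfitting.
Variable importance follows Wold's definition,
VIPⱼ = sqrt(p·Σₐ SSYₐ(wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ) with SSYₐ = qₐ²tₐᵀtₐ, so
Σⱼ VIPⱼ² = p on every fitted model.

The per-trait spectral ranges and component counts used as modelling
defaults (e.g. 600–900 nm with 8 components for F0, 400–2400 nm with 12
for ETR and P) are the published configuration for this trait set and are
taken as given, not re-derived.

## Model assessment

Fit statistics: R² is the squared Pearson correlation of observed and
predicted (the convention in the spectra–trait literature, which reports
observed-vs-predicted regressions), RMSE in trait units, bias =
mean(predicted − observed), %RMSE = 100·RMSE/range(observed).

The assessment protocol is: (i) outlier screening — union of QC failures,
leave-one-out residuals beyond 2.5 residual SDs, and trait values beyond
3 IQR from the median (≈10% of samples are expected to be defective in
the emulated study); (ii) a one-off ~20% external hold-out drawn by seed;
(iii) a 500-iteration ensemble of uniform (unstratified) 80:20
calibration/validation splits recording fit statistics, standardized
coefficients and VIP per iteration; (iv) external validation applying the
element-wise mean of the per-iteration coefficient vectors (a single
refit on all modelling data is the exposed alternative); (v) batch
prediction restricted to traits with external R² ≥ 0.55.

## Phenotyping

PERMANOVA uses Euclidean distances, SS_total = (1/n)Σ_{i<j}d²ᵢⱼ, the
analogous per-group sums for SS_within, pseudo-F =
[SS_among/(g−1)]/[SS_within/(n−g)], and unrestricted label permutations
(default 10,000) with the +1 correction so p is never exactly zero.  On
univariate data the pseudo-F equals the classical one-way ANOVA F.

PCoA double-centres the squared distance matrix (B = −½JD²J), takes the
eigendecomposition, and scales eigenvectors by the square root of the
non-negative eigenvalues; on Euclidean distances it reproduces PCA scores
up to axis sign.

PLS-DA regresses a one-hot class matrix on spectra by PLS2/NIPALS and
decodes by argmax (ties to the lexicographically first label).  The grid
search crosses calibration:validation ratios {50:50, 70:30, 80:20} with a
component grid over 500 stratified random splits; stratification is used
here (unlike the trait ensembles) because with 8 samples per class
unstratified 50:50 splits frequently lose a class.  Components are capped
at calibration size − 2; infeasible cells are skipped with a warning.
Selection is by highest mean validation kappa, ties preferring fewer
components, then the larger calibration fraction.  Note that per-split
kappa on very small validation sets carries a finite-sample negative bias
(of order −0.1 at 6 validation samples); null checks therefore use
validation sizes of ~24.

## Treatment statistics

Traits and indices predicted for the phenotyping plants are tested per
trait by Shapiro–Wilk (on residuals), a plain between-subjects one-way
ANOVA — each plant is measured once, so there is no within-subject factor
to model — and Tukey's HSD (Tukey–Kramer for unequal sizes) with a
compact letter display computed by insert-and-absorb over the
non-significance graph.  Significance level 0.05.

## Synthetic generator

The generator emulates the study design: 102 paired spectra+PAM samples
for model building (treatments cycled for balance, three plots per
treatment) and 8 plants × 3 ozone levels (AA ambient, MO moderate, EO
elevated) for phenotyping.  Elevated ozone multiplies the ΦPSII latent by
1−0.30 and the qN latent by 1+0.21; MO is generated like AA, and
dark-adapted Fv/Fm carries no treatment effect.

Yields are drawn so the quenching algebra is internally consistent:
Fv/Fm ~ N(0.78, 0.04²) truncated to (0.5, 0.87); Fm ~ N(0.45, 0.05²)
truncated to (0.2, 0.7) on the instrument-normalised scale (the scale is
a modelling decision — only error magnitudes constrain it); F0 derived;
F0' = F0·u with u ~ N(0.85, 0.05²) on (0.65, 1); qN ~ N(0.50, 0.05²) on
(0.05, 0.9) and ΦPSII ~ N(0.52, 0.05²) on (0.30, 0.75) as latents, with
Fm' = Fm − qN(Fm−F0') and Fs = Fm'(1−ΦPSII).  ΦPSII is capped at
0.98·Fv'/Fm' (equivalently qP ≤ 0.98); the cap binds for <1% of samples,
so the realised EO/AA mean ratios match the configured effects within 2%
at large n (asserted by test).

Spectra are a smooth continuum — visible floor 0.10, logistic red-edge
ramp centred at 715 nm to a 0.45 NIR plateau, a small green bump at
550 nm — minus Gaussian absorption features whose depths are affine in
noisy copies of the latent traits: 625 nm (Fv/Fm), 682 nm (ΦPSII), 705 nm
(qN) for the chlorophyll region, and 1450/1940 nm water plus 1700 nm
protein features tied to the ΦPSII/qP family for full-range signal.
Trait copies carry Gaussian noise with SD = 0.05 × the trait's realised
data range (the same range convention as %RMSE), making spectra
informative but imperfect proxies; channel noise SD is 0.005 and
reflectance is clipped to [0, 1].  Defects are planted in a configured
fraction of spectra (default 10%), one uniformly chosen defect each:
+0.15 visible offset, +0.05 step from 1001 nm, or a mirrored (inverted)
red edge over 700–750 nm — magnitudes chosen to sit clearly above the QC
thresholds.

What the generator does **not** emulate: radiative-transfer realism (no
leaf optical model), the radiance/white-reference division, instrument
line shapes, scattering or BRDF effects, plot-level random effects, and
day-of-measurement drift.  Passing tests therefore demonstrate the
correctness and statistical calibration of the algorithms under the
assumed signal structure, not field performance.

## Problem sizes and numerical choices

Library defaults follow the emulated study (500 ensemble iterations,
10,000 PERMANOVA permutations, 500 PLS-DA iterations).  The test suite
and the acceptance script use reduced iteration counts (50–200) where the
check does not depend on the count, keeping the full run in minutes on
one CPU.  Ties in component selection go to the smaller count; PERMANOVA
p-values use the +1 correction; eigenvalues below zero in PCoA (numerical
noise under Euclidean input) are clamped at zero for scoring.  The
`onesigma` PRESS rule uses a relative 5% tolerance.

## Known limitations

* The qN/NPQ pair is generated from a single qN latent; NPQ prediction
  quality is therefore tied to qN's and the two are not independently
  controllable.
* External validation at ~20 samples has wide sampling variability in R²;
  threshold decisions near 0.55 can flip between seeds.
* PLS-DA kappa estimates on few validation samples are biased low; grid
  summaries should be read comparatively, not absolutely.
* The ANOVA treats plants as independent; plot-level autocorrelation, if
  present in real data, is not modelled.
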