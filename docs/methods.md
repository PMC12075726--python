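# Methods

## Signal models and units

All computation uses b in ms/µm² (file readers divide s/mm² tables by
1,000), diffusion coefficients in µm²/ms, lengths in µm and times in
ms.  The four forward models of the normalized decay S(b)/S(0) are the
mono-exponential `exp(-b*ADC)`, the stretched exponential
`exp(-(b*DDC)^alpha)`, the fractional-order-calculus (FROC) decay

    exp(-D * mu^(2(beta-1)) * (gamma*G_d*delta)^(2 beta)
        * (Delta - (2 beta - 1)/(2 beta + 1) * delta))

and the continuous-time random walk (CTRW) decay
`E_alpha(-(b*D)^beta)`.  The CTRW argument is written as
`E_alpha(-(bD)^beta)`: the alternative grouping `(-bD)^beta` is
non-real for non-integer beta, so the standard real decay form is the
only consistent reading.

The FROC model needs the gradient timing.  delta = 15 ms,
Delta = 35 ms and gamma = 2.675e5 rad·ms⁻¹·mT⁻¹ are configuration
defaults on `BValueProtocol`; the gradient amplitude per b is
back-computed from `b = (gamma*G_d*delta)^2 (Delta - delta/3)`, which
also means the implementation only ever needs the ratio
`b / (Delta - delta/3)`.  FROC mu values are comparable only between
runs with identical timing.

### FROC identifiability

At fixed timing the FROC exponent depends on (D, mu) only through the
product `D * mu^(2(beta-1))` — D and mu are a gauge pair, and the FROC
decay as a function of b is exactly the stretched-exponential family
`exp(-(b*DDC_eq)^beta)`.  This is why the two-stage procedure exists:
the low-b mono-exponential estimate pins D, and mu absorbs the
remaining scale.  Consequences adopted throughout the package:

* recovery studies score FROC on its identifiable pair — beta and the
  composite diffusivity (reported either as the raw product or as the
  stretched-exponential-equivalent diffusivity `DDC_eq = K^(1/beta)`,
  which is the noise-robust D-type scale);
* a joint refit of (D, beta, mu) is deliberately not offered a
  "recover the truth" interpretation: the optimizer reaches residual
  zero anywhere along the ridge;
* fitted beta_FROC coincides with alpha_SEM up to optimizer tolerance,
  because with D fixed both fits optimize the same two-parameter
  family.  Published tables show them close but not equal, which would
  require additional constraints (e.g. different b-subsets) not stated
  with the equations.

## Mittag-Leffler evaluation

Only the completely monotone branch (order alpha in (0, 1], argument
z <= 0) is needed.  Three regimes:

* alpha = 1: `exp(z)`;
* `|z|^(1/alpha) <= 8`: the power series, evaluated in log space; the
  cap keeps the largest alternating term below ~3e3 so cancellation
  stays near 1e-11;
* otherwise the Gorenflo–Mainardi spectral representation, a smooth
  positive integrand after the substitution u = r^alpha, integrated
  with a fixed 200-node Gauss–Legendre rule mapped to [0, inf).  As
  alpha -> 1 the integrand sharpens into a Lorentzian of width
  sin(alpha*pi); beyond alpha = 0.96 the fixed rule under-resolves it
  and the implementation falls back to adaptive quadrature with an
  explicit breakpoint at the peak.

Validation: closed forms E_1(z) = exp(z) and
E_{1/2}(-x) = exp(x^2) erfc(x) agree to ~5e-13 over x in [0, 15]; the
series and integral branches cross-check to <1e-9 in their overlap.
One caveat recorded for reference work: near alpha = 0.25, |z| = 2 a
double-precision power-series *reference* itself carries ~3e-9 of
truncation/cancellation error, so oracle comparisons there use 400
terms and stop at |z| = 1.95.

## Fitting

`fit_decay` mirrors the clinical two-stage convention.  Stage 1 for
FROC/CTRW is the closed-form through-origin regression of ln S on b
over b <= 1 ms/µm² — identically the least-squares mono-exponential
fit in log-signal space, and therefore exactly reproducible by an
independent log-linear computation.  Stage 2 fits the shape parameters
over all b with D fixed; `FitConfig.refit_d=True` switches to a joint
refit initialized at the stage-1 value (used for CTRW recovery
studies, where all three parameters are jointly identifiable; not
meaningful for FROC, see above).  ADC and SEM are single-stage fits
over the full protocol; `FitConfig.adc_b_max` optionally restricts the
ADC fit, which matters when the decay is non-Gaussian and is therefore
explicit configuration (default: all b).

Numerics: box constraints (D-type in [1e-4, 5] µm²/ms, exponents in
[0.01, 1], mu in [0.1, 50] µm) are enforced by a logistic
reparameterization so the unconstrained Levenberg–Marquardt solver
applies; 5 starts (one deterministic from the log-linear D and shape
parameters at 0.9, the rest seeded Gaussian perturbations in the
transformed space) with the lowest residual kept; convergence
tolerances 1e-12, numerical Jacobians.  Voxels are fit independently
(no spatial regularization), so parameter maps are iteration-order
invariant; voxels with non-positive b=0 signal are flagged invalid in
all nine maps rather than fitted.

Two properties measured under these defaults (and recomputed by the
acceptance harness): noiseless round-trips recover the identifiable
parameters to ~1e-11 relative; at Rician SNR 50 the median
noise-induced relative error of the four D-type estimators (ADC, DDC,
FROC DDC_eq, CTRW stage-1 D) is <= ~4%.  Noise robustness is measured
against each estimator's own noiseless value: the two-stage estimators
carry a deterministic convention bias relative to generating FROC/CTRW
truth (the low-b decay of those models is not mono-exponential), which
is a property of the estimation convention, not of the noise, and is
already exposed by the noiseless round-trip checks.

## Synthetic cohort and phantom

The cohort generator reproduces the statistical structure the analysis
assumes: two groups of 23 and 45 nodes; the nine diffusion parameters
drawn per group from normals with the published means/SDs, truncated to
the physical bounds above; minimal-axial-diameter (MiAD) drawn by
category (frequencies 13/9/1 benign, 21/8/16 metastatic over [6,8),
[8,10), [10,20] mm) and uniformly within category; morphology, sex and
age fields with the published frequencies.  The bounds sit far in the
tails — every mean moves < 0.5% under truncation; the worst SD change
is −1.2% (benign CTRW alpha, whose ceiling of 1 lies 2.8 SD out), an
irreducible consequence of the published summaries.

Parameters are independent across the nine metrics by default (no
covariance is published).  A single-latent-factor `correlation` knob
couples them with signs oriented along the benign/metastatic axis (the
published ADC–DDC correlation of ~0.8 motivates sensitivity studies);
a moment-matched skew-normal option exists for individual parameters.
Neither claims fidelity to the original data.  Sampling is at node
level; within-patient clustering of the original 68-nodes-from-59-
patients design is ignored, as it was in the original tests.

Phantoms place non-overlapping elliptical nodes with per-node
generating parameters on a 3-D grid, render the noiseless decay, and
apply Rician noise `sqrt((S + sigma*e1)^2 + (sigma*e2)^2)` with
sigma = 1/SNR at unit b=0 signal; optional concentric necrotic cores
decay like free water (ADC 2.5 µm²/ms) and are exported as exclusion
masks, mimicking regions an observer would exclude from an ROI.  What
the phantom does *not* emulate: partial volume, motion/eddy artifacts,
EPI distortion, registration error, anatomically realistic geometry —
so passing recovery tests demonstrates correctness of the estimator
chain, not robustness to those real-world effects.

## Statistics

* Normality gate: Shapiro–Wilk per group at 0.05 selects pooled
  (Student) t versus Mann–Whitney per parameter.  Pooled rather than
  Welch variance: only the pooled form reproduces the published t
  statistics from the printed summaries.
* Mann–Whitney: midrank ties, tie-corrected normal approximation with
  continuity correction; the Z score is reported (the exact
  permutation test is used only as a small-sample oracle in tests).
* Chi-square: Pearson without continuity correction (a Yates flag
  exists for 2×2); empty categories are dropped before testing in the
  characteristics table.
* ROC: metastatic is the positive class; parameters lower in
  metastatic nodes (the D-type coefficients and CTRW alpha) are
  negated before analysis so AUC >= 0.5, with cutoffs mapped back to
  original units.  AUC is the midrank U/(n1·n2) (identically the
  trapezoidal area); the operating point maximizes the Youden index
  with ties broken toward higher specificity, and the reported Youden
  equals sensitivity + specificity − 1 exactly by construction.
* Binormal AUC `Phi(|mu1-mu2|/sqrt(sd1^2+sd2^2))` serves as the
  closed-form consistency bridge between group summaries and empirical
  AUCs.
* DeLong: structural components via midranks (Sun & Xu), covariance of
  paired AUCs, two-sided z test; zero-variance differences (identical
  or rank-equivalent scores) return p = 1 by convention.
* Logistic regression: statsmodels maximum likelihood with Wald CIs;
  odds ratios for diffusion metrics are reported per 0.001 parameter
  units (per-raw-unit ORs would be unreadably far from 1; the scale is
  recorded on every fit), node size per mm.  Complete or
  quasi-separation raises an explicit error rather than returning a
  divergent fit.  The multivariable procedure is forward stepwise with
  Wald entry p < 0.05 over the univariably significant parameters —
  the smallest procedure consistent with a single-survivor published
  model.  The "combined" score is the fitted probability of the
  beta_CTRW + MiAD model.
* ICC: two-way random effects, absolute agreement, single measurement
  (ICC(2,1) / McGraw–Wong A,1) from the ANOVA decomposition with the
  F-based 95% CI; `pingouin` serves as an independent oracle in tests.
* No multiple-testing correction anywhere, matching the original
  analysis.

## Replicate significance pattern

`significance_frequencies` repeats the 23/45 cohort draw and the group
tests; the per-parameter frequency of p < 0.05 equals statistical
power at the published effect sizes.  The heterogeneity exponents and
non-Gaussian diffusivities have standardized differences of 1.1–1.9
and replicate at >= 0.99 (mu_FROC ~0.85); ADC's standardized
difference of ~0.6 yields ~0.62, and CTRW alpha sits near the 0.05/0.5
boundary (~0.5).  A single observed significant p (as published for
ADC) is entirely consistent with ~60% replicate power — the frequency
table makes that explicit rather than treating observed significance
as a reproducibility guarantee.

## Problem sizes

Defaults chosen to keep every check comfortably interactive: recovery
studies use 25 noiseless draws per model and 50 Rician curves per
model; AUC simulations 2,000 replicates; the significance pattern 200
replicates; phantoms a 24×24×1 grid with ~25-voxel nodes.  All are
parameters, not limits.

## Known limitations

2-D single-slice ROIs and phantom nodes (the original analysis was
also 2-D); no perfusion (IVIM) compartment, so low-b perfusion effects
would alias into D; no covariance structure in the default cohort; the
Mann–Whitney Z for skewed parameters cannot be recomputed from
mean±SD summaries, so published Z values for the beta exponents are
not reproduction targets; mu_FROC absolute values depend on the
unpublished sequence timing.
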