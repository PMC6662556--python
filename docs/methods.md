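# Methods

## Scope

`telogel` reimplements, as a reusable tested pipeline, the analysis of
nestling telomere length (TL) in a paired brood-size-manipulation experiment
with reciprocal cross-fostering: densitometric quantification of telomere
restriction fragment (TRF) gel smears, reduction of twelve distribution
metrics to a single principal-component TL score, mid-parent/offspring
heritability estimation with a mixed-effects structure, and an all-subsets
AICc multimodel analysis of TL determinants. A synthetic-data module
generates gel images and cross-fostered pedigrees with known parameters so
that every stage has parameter-recovery tests.

## Densitometry model

A TRF assay separates restriction-digested genomic DNA by size; a probe that
binds once per telomere makes the telomeric fragments visible as a smear.
Because binding is one probe per molecule, optical density (OD) at a pixel
row is proportional to the number of telomere molecules whose size migrates
to that row. The pipeline therefore treats the lane profile as a weighted
distribution: position = kb(row) via a cubic calibration fitted by least
squares to the central ladder lane, weight = background-subtracted OD.

Key numerical choices:

- The cubic is fitted as kb on pixel row directly (a log-kb option exists but
  is off by default); the fit is rejected unless the mapped curve is strictly
  monotone over the ladder range, since a non-invertible migration map makes
  the gel unusable.
- The analysis window is 1.636–40 kb (the outermost visible markers of a
  1-kb extension ladder); rows mapping outside it are discarded, in-window
  rows with OD at or below background are kept with weight zero.
- Background is a single scalar per lane, the mean intensity along a
  horizontal line just below the lowest marker, restricted to the lane width
  (a per-row linear background is deliberately out of scope).
- OD is averaged across the configurable lane width (default 12 px).
- No Jacobian correction is applied when re-interpreting row weights on the
  kb axis: the molecule-count argument assigns counts to rows, not kb
  intervals. The synthetic renderer is the exact inverse: expected row
  intensity = mixture density in kb × |d(kb)/d(row)|, so the round trip is
  consistent by construction. Users supplying true densities on the kb axis
  should apply the Jacobian themselves before using these weights.
- Peak detection uses prominence-ranked local maxima with deterministic
  tie-breaking (lower row wins), so calibrations are reproducible.

## Distribution metrics and the TL score

Twelve metrics summarize each individual's distribution: weighted mean,
weighted skewness and kurtosis (population form, weights normalized;
kurtosis non-excess, Gaussian = 3), and the nine deciles P10–P90 of the
weighted empirical CDF with mid-block linear interpolation (two equal
weights at 5 and 10 kb give a median of 7.5 kb). All metrics are invariant
to rescaling the weights and equivariant to shifting the kb axis; the test
suite asserts both as property tests.

Because the metrics are strongly mutually correlated, a PCA reduces them to
one score. Default scaling is the covariance matrix (the convention of the
R `princomp` function used in the emulated analysis; correlation mode is
exposed since the original choice is not documented). The component sign is
fixed so the `mean_kb` loading is non-negative: high PC1 = long telomeres.
Repeated standards across gels are summarized as a coefficient of variation
for QC only; no correction is applied.

## Synthetic data

`render_gel` paints ladder bands (Gaussian profiles at the inverse migration
map of the rung sizes) and sample smears (row intensity proportional to the
molecule count of a lognormal mixture — lognormal because real smears are
right-skewed on the kb scale; a normal family is available), then applies
Gaussian blur, a background level/gradient, and Gaussian noise clipped at
zero. Ground-truth metrics are computed from the mixture in closed form
(raw moments) or by root-finding on the mixture CDF (deciles), never from
the rendered image.

`simulate_population` emulates the paired design: nests paired and matched
on hatch date, brood size and female age; one nest per pair enlarged by
three donor chicks from non-experimental nests (donors keep their own
genetic parents and natal box); half of each brood (rounded down) reciprocally
swapped. TL transmission follows the infinitesimal model — offspring
breeding value = mid-parent breeding value + segregation deviation with
variance σ²A/2 — with independent natal-box, rearing-box, treatment and
residual effects; parental phenotypes carry environmental noise equal to
the chicks' total environmental variance so that the mid-parent regression
slope equals h² = σ²A/(σ²A+σ²N+σ²R+σ²E) exactly in expectation. Defaults:
39 pairs, control broods 5.07 ± 0.67, +3 enlargement, h² = 0.8
(σ²A = 0.8, σ²N = 0.03, σ²R = 0.05, σ²E = 0.12), treatment effect on TL
−0.3, fledging logit −1.5 for enlargement over a base of +2.5 with a
0.7-SD rearing-box intercept. Chick "quality" enters growth as an additive
per-chick offset shared by the three morphometrics at every age — matching
the random-intercept structure of the fitted growth model, which is what
makes the null calibration of the measurement×group test exact — and the
treatment deficit grows linearly with measurement number, so day-0 sizes
are unaffected. Chicks that fail to fledge die before day 12 with
probability one half; dead chicks carry no TL score or day-12 morphometrics.

What the generator does not emulate: extra-pair paternity, egg/incubation
maternal effects, inter-gel intensity drift, gel warping ("smiles"), and
measurement-error correlation between gels. Passing recovery tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to those real-data complications.

## Mixed models

All LMMs share one structure — fixed effects plus crossed random intercepts
(natal box, rearing box, genetic father; plus chick id for the repeated
growth measures) with independent variances. They are fitted by a dedicated
profiled (RE)ML solver: with V = σ²(I + ZDZ'), the Woodbury identity turns
each likelihood evaluation into a Cholesky factorization of a q×q system
(q = total random levels), and the profiled criterion is optimized over log
variance ratios with analytic gradients. This exploits the models' special
structure and is what makes 600-replicate Monte-Carlo studies and
all-subsets enumeration affordable; the solver is verified against
statsmodels MixedLM (agreement ~1e-6) and against lme4/lmerTest on a frozen
fixture. Variance ratios reaching the lower bound are reported as zero with
a singular-fit warning. Satterthwaite denominator degrees of freedom are
computed by the delta method: Var(se²) from the numerically evaluated
observed REML information in the variance parameters (components estimated
at zero are held fixed); agreement with lmerTest is ~1e-3 relative.

Heritability: h² is the slope of chick TL on mid-parent TL (unweighted mean
of the two parents — no single-parent doubling), controlling for treatment,
with natal box, rearing box and genetic father as random intercepts, fitted
by REML; the F statistic uses the Satterthwaite denominator df and the 95%
CI is the corresponding t-interval. A brood-level variant averages chick TL
within each genetic pair and uses ordinary least squares (treatment is not
included there). Only chicks with both genetic parents known and alive at
day 12 enter either model.

The fledging model is a logit-link binomial GLMM (treatment fixed; natal
and rearing box random) fitted by the Laplace approximation: penalized
Newton for the random-effect mode, the log-determinant correction, and
joint outer optimization of fixed effects and log variances — the same
scheme as lme4's default; agreement with glmer on a frozen fixture is
~0.1%. Significance comes from a likelihood-ratio test against the
no-treatment model (χ², 1 df). No frequentist GLMM with crossed random
intercepts exists in the scientific Python stack, which is why this
component is implemented here.

## AICc multimodel inference

Candidate models vary only in fixed effects (brood manipulation, maternal
and paternal TL, maternal and paternal minimum age, chick sex, day-12 size
PC1, within-brood mass rank, and sex×term interactions); the random
structure is constant. Conventions:

- ML (not REML) for every candidate, since fixed-effect structures differ;
  REML is reserved for the heritability model where the fixed part is fixed.
- Complete-case filtering happens once, before enumeration, so all
  candidates share n (required for AICc comparability).
- k counts fixed coefficients + 3 random-intercept variances + the residual
  variance (an intercept+slope model with the three random terms has k=7).
- AICc = −2logL + 2k + 2k(k+1)/(n−k−1); marginality is enforced (an
  interaction only with both mains present); ordering is AICc, then fewer
  terms, then lexicographic.
- Models within ΔAICc ≤ 2 (configurable) are retained; weights
  exp(−Δ/2) are renormalized over the retained set — the convention that
  reproduces published weight columns summing to 1.
- Full averages set absent coefficients to zero; conditional averages
  renormalize over containing models. Unconditional SE =
  Σᵢ wᵢ √(seᵢ² + (βᵢ−β̄)²); the adjusted variant scales each seᵢ by
  t(0.975, n−kᵢ)/z(0.975) first (small-sample adjustment). z tests use the
  adjusted SE with a two-sided normal reference. Full averages shrink
  toward zero relative to conditional ones whenever importance < 1; the
  suite asserts this invariant.
- Relative importance of a term = sum of retained-model weights containing
  it, with the containing-model count reported alongside.
- VIF diagnostics (1/(1−R²) per predictor) run on the full design; aliased
  columns are flagged as infinite.

## Problem sizes and tolerances in the tests

The suite's Monte-Carlo studies use 200 replicates of 40 nest pairs per
true h² ∈ {0.2, 0.5, 0.8} for slope recovery (bias tolerance 0.05) with CI
coverage pooled across the 600 fits (accepted band 93–97%); densitometry
round trips use 50 lanes (noiseless: mean within 2%, deciles within 0.2 kb;
noisy: decile correlation > 0.98); null calibrations of the growth
interaction use 25 replicates of 6 pairs (KS test at α = 0.01). These sizes
were chosen to keep each check's Monte-Carlo error comfortably inside its
tolerance; the observed margins (e.g. |bias| < 0.01, decile errors
~0.02 kb) are an order of magnitude inside the bounds.

## Known limitations

- No automatic lane finding, gel-warp correction, or inter-gel intensity
  normalization beyond the standards' CV report.
- The Laplace GLMM (like glmer's default) can be biased for very sparse
  binary data; adaptive quadrature is not implemented.
- Satterthwaite df falls back to n−p when the variance-parameter information
  is numerically singular (e.g. all components at zero).
- The simulator draws one breeding season; no multi-year dynamics or
  extra-pair paternity.
- Heritability here is a mid-parent regression slope, not an animal-model
  (pedigree-BLUP) estimate; maternal-effect variance is not decomposed.
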