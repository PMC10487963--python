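# Methods

This note documents the statistical models implemented in `immunoclock`, the
design of the synthetic-data generator, the numerical choices, and the known
limitations.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Centile models

All three models estimate age-conditional percentile curves of a biomarker
bounded in [0, 1] at the level set τ ∈ {0.03, 0.15, 0.50, 0.85, 0.97} —
five curves roughly one Gaussian SD apart, spanning mean ± 2 SD.

### LMS (Box-Cox Cole-Green) model

The response is mapped to a strictly positive working variable

    t = logit(clip(y, ε, 1 − ε)) + s,     ε = 1e-4,  s = 12,

(the fixed shift is required because the Box-Cox Cole-Green distribution is
defined for positive responses while logit(y) is negative over most of
(0, 1)), and modelled as BCCG:

    z = ((t/μ)^λ − 1) / (λσ) ~ N(0, 1),

with three age-varying parameter curves: the skewness λ(age) (identity link),
the median μ(age) (log link), and the coefficient of variation σ(age)
(log link).  Each curve is a cubic B-spline smooth (defaults: 6 basis
functions for μ, 4 for σ, a constant for λ) with a quadratic penalty on
second divided differences of the coefficients at the Greville sites, whose
null space is exactly the straight lines.  Fitting maximizes the penalized
log-likelihood by backfitting: cycle over the three coefficient blocks,
optimizing each by L-BFGS-B with analytic gradients

    ∂ℓ/∂log μ = −λ + z·(t/μ)^λ/σ,   ∂ℓ/∂log σ = z² − 1,
    ∂ℓ/∂λ     = log(t/μ) − z·∂z/∂λ,

until the relative change of the objective drops below 1e-6 (cap 200 cycles;
non-convergence raises an error carrying the iteration trace).  The usual
LMS/BCCG truncation correction (z > −1/(λσ)) is ignored, as in standard
growth-chart practice, because σ is small on the working scale.

Percentile curves invert the distribution, t_τ = μ(1 + λσ z_τ)^{1/λ}, and
back-transform.  Beyond the training age range the three parameter curves are
frozen at their boundary values.  Individual centiles are F(y | age) = Φ(z).
On well-specified simulations the probability integral transform of training
data is uniform and the centiles are uncorrelated with age by construction;
both are asserted in the test suite.

### Linear quantile regression (LQR)

Per level τ, the line (b₀, b₁) minimizing the pinball loss
Σ (τ − 1{y < q})(y − q) is found *exactly* by linear programming (HiGHS).
Exactness matters: a property test checks the solution against the
basic-solution oracle (the best line through two data points) on small data.
Extrapolation beyond the data range is linear.  All ages identical makes the
slope unidentifiable and is an error; an intercept-only mode returns the
empirical τ-quantile instead.

### Spline quantile regression (NQR)

Per level τ, cubic B-spline coefficients (default basis size 8) minimize the
pinball loss plus a penalty λ·Σ|D c| with D the second-divided-difference
matrix at the Greville sites — an L1 roughness penalty chosen so the whole
problem remains a single exact linear program and so that λ → ∞ collapses the
curve onto the LQR line.  When no penalty is given, a shared λ is selected on
the median fit by a Schwarz-type criterion, n·log(mean pinball) +
½·df·log n with df the number of interpolated points, over the grid
10^{−2..3}.  Spline quantile curves are never extrapolated: evaluation
outside the fitted age range raises.

### Shared prediction contract

Predicted quantile matrices are monotone-rearranged (sorted across τ at each
age) so percentile curves never cross, then clipped to [0, 1] for bounded
responses.  Rearrangement preserves each marginal fit; it does not modify the
fitted coefficients.  Per-τ empirical coverage of the training data is stored
as a fit diagnostic and asserted within binomial tolerance in the tests.

## Aging types and agreement

The five curves at a subject's age partition the biomarker axis into six
ordered categories (1 = below P03, …, 6 = at/above P97).  Boundary ties go to
the upper (faster) category, making the partition exhaustive and
deterministic; a value exactly on P50 is type 4.

Krippendorff's α = 1 − D_o/D_e is computed from the coincidence matrix over
pairable values (units with ≥ 2 non-missing codes).  The default difference
function is ordinal (squared cumulative-marginal spans), matching the ordered
categories; nominal 0/1 is available.  If every pairable code is identical,
D_e = 0 and α is undefined — an error, deliberately not 1.0.  Confidence
intervals are a percentile bootstrap over units (default B = 1000, seeded);
degenerate resamples are skipped and it is an error if they exceed half.

## Reference curves, EYOL, and the age gap

A reference curve is the model P50 (LMS or LQR) evaluated on a 0.1-year age
grid from 18 to 100, isotonized by pool-adjacent-violators, with linear
extrapolation slopes taken from the mean slope over the outer 5 grid-years.
The spline model is excluded: it cannot extrapolate, which EYOL requires.
The hypothetical HYP reference instead evaluates the LMS model at an
age-increasing percentile profile — linear from (19 y, 0.5 %) to
(99 y, 99.5 %), i.e. 1.2375 ≈ 1.24 % per year — with the curve pinned to
IMMAX 0 at age 18 and 1 at age 100, so every IMMAX value maps into the adult
age range and no extrapolation slopes exist.

EYOL inverts the curve by linear interpolation; flat segments return the
midpoint of the matching age interval; values outside the curve's range use
the boundary slopes and may land above 100 or below 18 years (including
negative ages) — for a P50 reference this is expected, not an error.  The age
gap is EYOL − age with no further rounding, so gap and EYOL differ by exactly
the age passed in.  By construction the P50-based age gap is uncorrelated
with age and almost perfectly rank-correlated with the individual centile,
while the HYP-based gap is negatively correlated with age (its reference
percentile rises with age); all three behaviours are asserted in the tests.

## Longitudinal change

`change_from_baseline` pairs each subject's baseline and follow-up visit and
reports ΔIMMAX, Δcentile (LMS centiles at each visit's own age), and per
reference ΔEYOL and ΔAge gap.  ΔAge gap is computed as ΔEYOL − FPL so the
identity ΔEYOL = ΔAge gap + FPL holds exactly on every record.  The report
runs Wilcoxon signed-rank tests of each delta against zero (exact for n ≤ 25
without ties, continuity-corrected normal approximation otherwise,
zero differences dropped; all-zero columns are reported as degenerate rather
than raised), pairwise signed-rank comparisons of ΔEYOL across references
with Holm adjustment (the multiplicity family is the reference comparisons),
Spearman correlations among the deltas, and rank-sum comparisons between the
sexes when both are present with at least 6 subjects each.

## Synthetic-data generator

The generator emulates a pooled cross-sectional adult cohort and 5-year
follow-up pairs.  Ages are drawn from a mixture of uniform components
(defaults 18–40 y with weight 0.45, 40–65 y with 0.35, 65–97 y with 0.20,
approximating heterogeneous multi-study coverage).  Each subject receives a
latent centile u ~ U(0, 1), stored in the output as an oracle, and

    IMMAX = invlogit( μ(a) + σ(a) · z_skew(u) ),
    μ(a) = μ₀ + μ₁·a,   σ(a) = σ₀ + σ₁·a,

with z_skew the *median-centred* standard skew-normal quantile, so the median
curve is invlogit(μ(a)) regardless of the skew.  The five biomarkers are
monotone transforms (exp for the four ratios, inverse-logit for the CD28neg
fraction) of loading · logit(IMMAX) plus independent Gaussian noise of
comparable magnitude, with fixed offsets placing them on realistic scales.
Follow-up records advance age by the follow-up period (saturating at 100 y,
the oldest age the schema represents) and perturb the latent centile on the
probit scale (SD `centile_drift_sd`, clamped to (0.001, 0.999)); IMMAX is
recomputed from the oracle quantile function, so zero drift preserves every
subject's centile exactly.  Age-stratified subsampling uses half-open 10-year
bins from age 18 and largest-remainder proportional allocation, so subsample
and remainder always partition the cohort.

### Default calibration

The defaults (μ₀ = −0.62, μ₁ = 0.013 /yr, σ₀ = 0.065, σ₁ = 0.0005 /yr,
skew 0.8, drift SD 0.05) were fixed once, by the following design argument,
and define the study conditions for all seeded tests.  With near-constant σ
the quantile family is an *age-shift* family — each subject's centile curve
is the median curve displaced along the age axis — so a subject who keeps
their centile over a follow-up advances along the reference at exactly one
year per year, the defining property of the EYOL scale.  Two deviations from
that ideal are controlled by the parameters: (i) the inverse-logit median
must be close to linear in age over 18–100, otherwise subjects on its flatter
parts advance more slowly through a *linear* (LQR) reference — hence a median
rising moderately from 0.35 to 0.62 across adulthood; and (ii) the mean ΔEYOL
equals mean ΔIMMAX divided by the fitted LQR slope, so its sampling
variability is the slope's relative error, which scales with σ₀/μ₁ — the
cross-sectional age-gap SD, set to ≈ 5 equivalent years, the magnitude
typical of biological-age clocks.  The conditional IMMAX spread this implies
(P03–P97 band ≈ 0.12 wide) is narrower than real pooled immune-profiling
data; the generator trades spread realism for an exactly interpretable
EYOL calibration.

### What the generator does not emulate

Real flow-cytometry measurement error structure, multi-study batch effects,
sex differences, non-monotone biomarker–age relationships, and more than one
latent axis of immune aging.  Passing tests therefore demonstrate the
correctness and internal coherence of the estimators on data satisfying their
assumptions — parameter recovery, coverage, PIT uniformity, agreement — not
that the models fit any particular real cohort.

## Numerical choices

- Logit clipping ε = 1e-4 (both the LMS transform and the PCR index).
- LMS working-scale shift +12; backfitting tolerance 1e-6, cap 200 cycles.
- Reference grid step 0.1 y, giving a 0.05-y round-trip tolerance for EYOL;
  extrapolation slopes from the outer 5 grid-years.
- Non-crossing by monotone rearrangement (sorting), a documented limitation:
  it guarantees ordering but is not a joint fit of all quantiles.
- Krippendorff bootstrap B = 1000, percentile intervals.
- LP solves use scipy's HiGHS; quantile-regression ties are resolved by the
  solver, and oracle tests compare losses, not coefficients.
- Boundary ties in aging-type rating go to the upper category.

## Limitations

- The PCR recipe for IMMAX (component count, transforms, target) is exposed
  as configuration; the index's published coefficients are not reproduced —
  tests supply the synthetic latent immune age as the regression target.
- The LMS model fits skewness through the Box-Cox shape on the shifted-logit
  scale; data skewed in other ways are only approximated (the rating and
  agreement results are robust to this, the individual centiles less so).
- Rank correlation between *changes* in centile and in P50-based age gap has
  an intrinsic ceiling around 0.93–0.95 under this generator: the centile
  compresses latent shifts through the Gaussian CDF while the gap compresses
  them through the inverted reference curve, two different monotone maps.
  The cross-sectional correlation between centile and age gap is near 1.
- Only two-visit designs are supported; no mixed-effects trajectory
  modelling.
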