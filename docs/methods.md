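# Methods

This note records the models, assumptions, parameter defaults and numerical
choices behind `thiomon`, and what the synthetic-data experiments do and do
not establish about real primary-care data.

## Synthetic cohort generator

**What it emulates.** One row per adult established on primary-care
thiopurine treatment, followed from six months after the first primary-care
prescription for up to five years. Predictor marginals match the development
cohort: age ~ truncated normal (42, 17) on [18, 95]; 50.9% female;
mercaptopurine-equivalent dose a discrete mixture over common azathioprine
doses (24.05–96.2 mg/day) weighted to give median 48.1 and IQR (36.1, 72.1);
BMI drawn by published category (renormalised over non-missing: 5.3% / 42.1%
/ 30.2% / 22.3%) then uniformly within the band; 16.4% current smokers;
alcohol in five levels renormalised over non-missing records; disease
IBD/RA/SLE/seronegative spondyloarthropathy at 88.9/3.8/4.1/3.2%; comorbidity
and co-prescription flags at their observed prevalences. Smoking collapses
non/ex/not-recorded into the reference.

**Event times.** Exponential with hazard `λ0·exp(βX)`, where the published
pre-shrinkage coefficients act as the generating truth. Competing
exponential censoring clocks (transfer out of practice, 90-day prescription
gap without abnormality, death at the negligible observed rate of 2.5e-4/yr)
plus administrative censoring at 5 years. `λ0` and the total censoring rate
are solved (closed-form competing-exponential expectations over a fixed
20,000-profile probe sample) so the expected crude incidence is 25.13/1000
person-years and mean follow-up 16117/5982 ≈ 2.69 years; together these
imply the ~6.8% event fraction. The calibrated `λ0 ≈ 0.0116/yr` gives an
analytic all-zero 5-year survival of ≈ 0.944, closely consistent with the
published baseline survival of 0.938. No competing-risks model is used
(deaths are ~0.07% of the development cohort). The constant baseline hazard
is a modelling choice — the source analysis implies no particular baseline
shape — and a piecewise-constant variant can be built by passing a custom
`TrueModel`.

**Missingness.** BMI (13.6%), alcohol (24.0%) and dose (10.5%) are masked
missing-at-random conditional on age, sex and non-IBD disease (logistic
score `0.35·z_age + 0.25·female + 0.30·non-IBD` with the intercept solved
per field to hit the target rate); MCAR is available as an option. MAR is
the default because chained-equation imputation assumes it.

**What passing tests do not show.** The generator draws predictors
independently (no age–smoking or disease–drug correlation), uses a constant
baseline hazard, injects missingness with a known mechanism, and contains no
measurement error, practice-level clustering or calendar effects. Parameter
recovery and calibration results on these cohorts therefore validate the
*pipeline machinery*, not the transportability of any fitted model to real
records.

## Outcome ascertainment and predictor derivation

Discontinuation with an abnormal blood test requires a prescription gap of
at least 90 days (between consecutive prescriptions, or after the final
prescription) with an outcome-grade abnormality or qualifying diagnostic
code within ±60 days of the last prescription date; the event time is
anchored to that date. Outcome-grade thresholds (strict inequalities as
printed): leucocytes < 3.5, neutrophils < 1.6, platelets < 140 (×10⁹/l),
ALT/AST > 100 IU/ml, creatinine rise > 26 μmol/l versus the subject's latest
preceding value. Mild-grade thresholds (the prior-abnormality predictor):
neutrophils < 2, leucocytes < 4, platelets < 150, ALT/AST > 35. The
mild-grade definition applies to the six months of thiopurine prescription
preceding follow-up; the published equation footnote attributes this window
to methotrexate, which we read as a copy error for thiopurine. Clinical
covariates take the latest record in the two years up to the index date
(window closed at the index, open at the far side; dates are integer days,
6 months = 183 days, 2 years = 730 days, years = days/365.25); drug flags
use the prior six months. Gaps anchored before follow-up start are
pre-history and ignored. "CKD progression by medical code" has no published
operational definition, so synthetic coded events carry an opaque
`qualifying` flag. Azathioprine doses convert to mercaptopurine equivalents
at 0.481 (the unique factor consistent with 100 → 48.1 mg/day); the factor
is configurable.

## Imputation

Chained equations over BMI, alcohol and dose, visited in ascending
missingness, 10 sweeps per imputation (the source is silent; 10 is ample for
three fields). Every conditional model contains all candidate predictors,
the Nelson–Aalen cumulative hazard at the subject's exit time, and the event
indicator. Continuous fields use type-1 predictive-mean matching with 5
donors and Bayesian draws of the regression parameters (plain normal draws
available); alcohol uses a multinomial logistic model refit on a bootstrap
of the observed rows, a standard approximation to drawing its parameters.
Analysis is fit-per-dataset then Rubin's-rules pooling (never stacked
estimation). One master seed spawns per-imputation substreams, so the first
m′ datasets of an m-imputation run coincide with an m′-imputation run.
Observed cells are never altered (asserted in tests).

## Development

All 21 parameters stay in the model (no selection). Per-dataset fits use
lifelines with Efron tie handling (day-granularity data produces ties);
coefficients are pooled by Rubin's rules. The pooled covariance carries
Rubin total variances on the diagonal and the average within-imputation
covariances off-diagonal — between-imputation off-diagonal terms are
ignored, a documented approximation. First-order fractional polynomials over
powers {−2, −1, −0.5, 0, 0.5, 1, 2, 3} are compared to the linear term by a
1-df deviance test on the mean partial log-likelihood across imputations
(transformed covariates are standardised, which leaves the test invariant;
non-positive predictors are shifted). Proportional hazards are checked by
scaled-Schoenfeld rank-time correlation per parameter and log(−log S)
curves. The baseline survival S₀(t) is a Breslow estimate referenced to the
all-zero covariate profile — required for the published equation to read as
written — averaged across imputations; horizons beyond the last event time
warn and carry the last value.

The minimum-sample-size routine implements the shrinkage criterion
n = p/((S−1)·ln(1−R²cs/S)) plus two companions (bounding the optimism in
apparent R²cs by 0.05, and estimating the overall outcome proportion at the
horizon within ±0.05, the last via a binomial bound on
φ = 1−exp(−rate·horizon)); the binding maximum is returned with the implied
event count. At the published inputs the shrinkage criterion binds: 1748
participants, 95 events.

## Internal validation and shrinkage

Subjects are resampled with replacement within each imputation (seeded
substreams); the full model is refit per resample. Apparent performance is
measured on the resample (the apparent calibration slope is exactly 1, an
MLE identity), test performance on the original dataset using the resample
model's linear predictor without re-estimated baseline (slope-on-linear-
predictor convention). Optimism is the mean apparent-minus-test difference;
corrected = apparent − optimism holds exactly by construction, and corrected
intervals are the apparent intervals shifted by the optimism. The uniform
shrinkage factor is the mean test calibration slope per imputation, averaged
over imputations. Resamples whose refit fails (monotone likelihood;
zero-variance columns are dropped with coefficient zero first) are dropped
and counted, not retried. Applying shrinkage keeps the coefficients and
stores the factor; the Breslow baseline is recomputed with the shrunken
linear predictor as a fixed offset, which restores mean predicted risk to
the observed risk within ±0.005 on synthetic data.

For repeated refits the package uses its own vectorised Newton solver for
the Efron partial likelihood (`thiomon._cox`), cross-checked against
lifelines to ~1e-6 in the unit suite; lifelines' per-fit overhead would
dominate a 500-resample bootstrap. Linear predictors are clipped at ±200
before exponentiation; steps larger than 50 or non-finite likelihoods mark
the fit failed rather than raising.

## Performance metrics

Royston's D uses Blom's approximation (α = 3/8) for the normal scores —
exact rankits are unnecessary at these sample sizes — and a model-based
standard error (the source does not state its interval method). The
calibration slope refits a univariate Cox model on the frozen linear
predictor; evaluation uses the scoring-scale predictor (shrinkage included),
so a correctly shrunken model has slope ≈ 1. Grouped calibration splits
subjects into ten equal groups of predicted risk (boundary ties broken by
stable subject order, so group sizes differ by at most one); observed risk
is the Kaplan–Meier complement with Greenwood intervals. Jackknife
pseudo-observations of F(t) are computed by exact leave-one-out
Kaplan–Meier via prefix-product identities (O(n log n)); they equal the
event indicators when no censoring precedes the horizon, their mean equals
the full-sample estimate to machine precision, and they may fall outside
[0, 1] by construction. The smooth calibration curve is a lowess
running-line of the pseudo-values on predicted risk (span 0.75,
configurable) interpolated onto an even grid. Metrics from an imputed stack
are Rubin-pooled on the metric scale; R² intervals are carried through the
D transform. Subgroup evaluation filters and re-evaluates without
refitting.

## Health economics

Ten decile-representative patients are the subjects at the 5th, 15th, …,
95th percentiles of predicted 5-year risk (exact order statistics above
n=100, seeded tie-break; interpolation with a warning below). Each is pushed
through a discrete event tree per strategy (3-, 6-, 12-, 24-monthly tests;
the biennial schedule tests within four years while abnormalities span all
five). The 5-year risk converts to a constant hazard λ = −ln(1−risk)/5 — the
within-horizon timing is otherwise unidentified. An abnormality arising
between tests is detected at the next scheduled test; monitoring then stops
and one additional appointment occurs. Appointments cost £24.09 and are
discounted at 3.5%/yr at their scheduled times; illness consequences are
discounted at the mid-point of the interval in which the abnormality arises
(half-cycle correction). Abnormalities arising after the last scheduled test
(biennial only) are never detected and use a dedicated probability. iNMB =
£20,000·ΔQALY + Δcost versus 3-monthly. The PSA draws illness probabilities
from beta distributions (mean preserved, effective sample size 100) and
costs from gammas (CV 0.3); QALY losses stay fixed by default. A zero-
variance PSA reproduces the deterministic analysis exactly.

**Non-canonical parameters.** The clinician-elicited illness probabilities,
acute costs and QALY losses of the original appendix are not available. The
defaults (three illness classes — severe infection, hepatotoxic illness,
acute kidney injury — with excess probabilities of 0.5–4% per abnormality
rising with the detection delay, costs £1,500–3,000 and QALY losses
0.05–0.10) are synthetic placeholders chosen once, erring toward
over-stating illness risk, and exposed as first-class configuration. They
reproduce the qualitative base-case ordering (every extended interval beats
3-monthly in every decile; the biennial-vs-annual gain narrows with risk,
and tripling the illness risks moves high-risk deciles to annual), but no
monetary magnitude from this module should be read as an estimate of the
original analysis.

## Problem sizes in the test suite

Simulation-backed tests run at the sizes their statistical purpose needs:
coefficient-recovery coverage at n=2000 over 150 replicates with
profile-likelihood (LRT-inversion) intervals, which stay near-nominal where
Wald intervals fail (rare binary predictors with monotone partial
likelihoods; a capped offset of ±20 stands in for the likelihood supremum);
self-consistency calibration at n=3000 so the lowest-risk tenth retains
roughly ten events, below which Greenwood intervals lose nominal coverage;
bootstrap-shrinkage behaviour at n=150 and n=5000 under an elevated-event
stress regime (baseline hazard 0.30/yr) so 21-parameter fits are feasible at
n=150, with ×1.5-amplified coefficients in the well-powered regime so the
asymptotic shrinkage → 1 behaviour is visible; oracle-equivalence checks at
n≈30 where brute force is exact. Pipeline drivers default to the published
design sizes (n=5982/3573, m=10/5, B=500) with flags to scale down.

## Known limitations

- Predictors are generated independently; joint structure in real records
  (e.g. disease–drug confounding) is absent.
- The pooled covariance ignores between-imputation off-diagonals.
- The FP1 deviance test averages log-likelihoods across imputations rather
  than using a formal multiple-imputation likelihood-ratio combination.
- The alcohol imputation approximates a posterior parameter draw by a
  bootstrap refit.
- Health-economic magnitudes depend on placeholder parameters (above).
- The D-statistic interval is model-based, not bootstrap.
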