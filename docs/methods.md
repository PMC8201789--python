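# Methods

This note records the package's modelling conventions, the design
choices made where several defensible options existed, and what the
synthetic-data experiments do and do not demonstrate.

## Models and formulations

Three power–duration families are implemented in SI units (m/s, s, m):
the two-parameter hyperbola t(s) = d′/(s − CS), the three-parameter
hyperbola t(s) = d′(s_max − s)/[(s − CS)(s_max − CS)], and the
three-parameter exponential t(s) = τ ln[(s_max − CS)/(s − CS)] (natural
logarithm).  Each also has the algebraically equivalent distance
formulation d(s) = s·t(s).  Domain convention: speed at or below CS
raises (time is undefined or infinite there, and a returned infinity
would poison downstream sums); speed equal to s_max returns exactly 0,
a well-defined model value.  The speed-of-distance and time-of-distance
variants are not implemented: with error-free speed, the errors of time
and distance are perfectly correlated (endogeneity), and no standard
regression handles that case.

The exponential family's distance above CS is transient,
d′(t) = t(s_max − CS)e^(−t/τ), maximal at t = τ with
d′_max = τ(s_max − CS)/e.  Whenever families are compared on d′, the
exponential family contributes d′_max; the transient curve is exposed
separately.

## Weighted least squares

Speed is the controlled variable of an exhaustive trial; the dependent
variable is time for t(s) and distance for d(s).  Times to exhaustion
are heteroscedastic with variance taken proportional to the dependent
variable, so observations get inverse-variance weights ∝ 1/y, computed
from the *observed* dependent values (reproducible, and faithful to the
stated variance law; an iteratively reweighted variant that re-derives
weights from fitted values exists but is off by default).  Weights are
normalised to sum to n, making the objective invariant to the unit of
the dependent variable.

Minimisation uses scipy's bounded trust-region reflective algorithm, a
box-constrained Levenberg–Marquardt variant, inside
cs ∈ (0, min speed), d′ > 0, s_max > max speed, τ > 0 — the box keeps
every observation inside the model's speed domain during iteration.
Convergence tolerances default to 1e-10 (step, gradient and cost),
capped at 500 objective evaluations per start.  Starting values come
from the exact linear identity d = d′ + CS·t of the two-parameter
family (OLS of distance on time), plus s_max = 1.5× the fastest trial
speed (1.4× for the exponential family) and τ = the observed time at
the second-fastest speed.  If the default start fails, five ±20 %
jittered restarts (seeded) are tried and the best converged solution
kept.  A solution within 1e-7 (relative) of a finite bound is flagged
`active_bound` and excluded from cohort summaries; a four-point fit of
a three-parameter family has df = 1 and genuinely fragile intervals,
which is reported, not hidden.

Standard errors use the weighted Gauss–Newton covariance
s²(JᵀWJ)⁻¹ with s² = weighted RSS/(n − p); with df = 0 the estimates
are returned and interval metrics are marked unavailable.

## Fit quality

* 90 % CI: t-quantile(0.95, df) × SE.  This convention back-computes
  correctly from the reference cohort's published two-parameter CS
  interval (0.10/2.92 ≈ 0.034 ≈ 0.78 % of 4.39), which is the basis for
  adopting it.
* Combined %SEE: Σ 100·SE/|estimate| over fitted parameters.  For the
  exponential family the fitted set is (CS, τ, s_max); a variant
  substituting the derived d′_max (delta-method SE) is provided for
  cross-family comparisons.
* AIC = n ln(weighted RSS/n) + 2p, no small-sample correction.  The
  weighted RSS carries the squared units of the dependent variable, so
  AIC is comparable across families only within one formulation.  Its
  absolute level also depends on the weight normalisation, so only
  within-formulation differences are meaningful.
* Heteroscedasticity diagnostic: pairs (ŷᵢ, |√wᵢ eᵢ|) plus their
  Spearman rank correlation as a scalar index.  Caveat discovered in
  simulation: with only four support points and 2–3 parameters, the
  longest trial sits on the steep branch near CS and has leverage close
  to 1, so its residual is squeezed toward zero and the per-fit index
  reflects leverage, not the variance law (both weighted and unweighted
  medians come out negative).  On denser speed grids (≥16 points) the
  expected pattern emerges: unweighted fits show a positive
  residual-spread trend (median index ≈ +0.13) that 1/y weighting
  removes (≈ −0.09).  The diagnostic simulations therefore use the
  dense grid; the four-trial design is simply too small for a per-fit
  heteroscedasticity test to be informative.

## Aerobic mapping

The incremental protocol (2.78 m/s warm-up, +0.28 m/s every 2 min)
implies the line s = 2.78 + 0.14·t with t in minutes (time units
inferred from the protocol geometry).  A CS estimate maps to a test
time by inverting that line and to an oxygen-uptake value through the
participant's linear V̇O₂-vs-time regression, consumed as an
(intercept, slope) pair; CS above the attained peak speed is flagged as
extrapolation rather than rejected.  Peak speed credits the fractional
final stage: PS = s_V̇O₂max + α·Δs, α ∈ [0, 1).  Group summaries of
ratio quantities (%V̇O₂max, %s_V̇O₂max) are means of per-participant
ratios, not ratios of means.

## Cohort statistics

The long table holds one value per participant × family × formulation ×
outcome (CS, d′, s_max), with flagged fits excluded and counted.  The
mixed model is value ~ family * formulation + (1 | participant), REML.
Fixed-effect p values are Wald chi-square tests on each term's
coefficient block — the approximation method was an open choice and is
recorded in the result object's metadata; variance is decomposed as
R²marginal = var_fixed/total and R²conditional =
(var_fixed + var_random)/total with var_fixed the variance of the
fixed-effect predictions, and ICC = var_random/(var_random +
var_resid).  Pairwise family contrasts (run when the family term is
significant at 0.05) are paired t-tests on per-participant family
means, Holm-adjusted.  For s_max the family factor simply has two
levels.

Correlations between CS and fitness markers use natural-log transforms:
Pearson r with a Fisher-z 90 % CI, SEE% = 100(e^{s_res} − 1) from the
residual SD (df = n − 2) of the log-log regression, and
Δ% = 100(e^{mean LOO error} − 1).  The leave-one-out definition is
deliberate: the in-sample mean log residual is identically zero, so a
systematic-difference measure needs held-out predictions.

## Synthetic cohorts

The generator draws true parameters from truncated normals centred on
the reference cohort's group means (CS 4.4 ± 0.4 m/s, d′ 225 ± 55 m,
s_max 7.5 ± 0.8 m/s truncated above CS + 1, τ 250 ± 50 s), places peak
speed via a CS/PS ratio ~ N(0.85, 0.03) truncated to (0.7, 0.95), and
evaluates the generating family at 90/100/110/120 % of PS.  Draws are
rejected when a trial speed falls outside the model's speed domain
(error if that happens systematically), and a participant is redrawn
when the predicted slowest trial exceeds 30 min — the ratio
distribution otherwise has a near-singular tail (ratio just under 0.9
puts the 90 % trial hours from exhaustion) that no real
exhaustive-trial cohort would contain, since such runners would have
been screened out by the design.

Noise is multiplicative lognormal with mean 1.  The default law makes
Var[t_obs] ∝ t (multiplier variance `noise_scale²/t`), matching the
assumption behind the 1/y weights; `noise_scale = 2.0` gives a
coefficient of variation of ≈ 6.7 % on a 15-min trial and ≈ 20 % on a
100-s trial, a realistic reliability profile for times to exhaustion,
which are proportionally more variable at short durations.  A
constant-CV law and a noise-free mode are available.  All randomness
flows from one seeded generator: identical configs give bitwise
identical cohorts.

What the generator does *not* emulate: day-to-day within-participant
variability, V̇O₂ kinetics, pacing or motivation effects, or any
correlation between CS and d′ across runners (draws are independent).
Passing recovery tests therefore show that the estimation machinery is
calibrated under the assumed error law at the study's design — not that
the model is true of real runners.

## Problem sizes used in tests and the acceptance script

Simulation studies are sized for a laptop-class single CPU: CI
coverage and procedure agreement use 35 replicate 16-participant
cohorts (560 fits per formulation); the interval-width comparison 20
cohorts of full six-cell batteries; the mixed-model detection study 200
replicates; heteroscedasticity and noise-degradation studies 300–600
fits.  These sizes keep Monte-Carlo error well inside the asserted
bands (e.g. coverage SEM ≈ 1.3 % against a ±5 % band).

## Known limitations

* Four observations is the field's standard but a hard statistical
  floor: three-parameter fits have df = 1, intervals are wide, and an
  occasional draw converges onto a bound and is excluded (flagged and
  counted, ~1–2 % of three-parameter fits at default noise).
* The AIC constant is convention-dependent; only differences within a
  formulation are interpreted.
* Wald chi-square fixed-effect tests are mildly anti-conservative at 16
  participants compared with Satterthwaite or Kenward–Roger degrees of
  freedom; with the effect sizes of interest here the conclusion
  pattern is unaffected.
* The per-fit heteroscedasticity index is uninformative at n = 4 (see
  above); use the pooled profile or denser designs.
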