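# Methods

This note documents the statistical model behind `brevis`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Scoring

Each of the four cards carries exactly 25 targets. The performance time
`P = 25·t/(25 − omissions)` is the execution time a participant would have
needed at their observed pace to find all 25 targets; it equals `t` when
nothing is missed and is undefined when all 25 targets are omitted (scoring
raises an error naming the card — such a protocol cannot be scored).

The four indexes are SA = P1, OA = (P3+P4)/2 − (P1+P2)/2,
FA = (P2+P4)/2 − (P1+P3)/2 and Err = Σ(omissions + substitutions). Two
consequences of these definitions worth knowing:

* OA and FA are contrasts: adding a constant to all four card times leaves
  them unchanged and shifts SA by that constant.
* SA + OA + FA = P4 *identically* — the decomposition of the hardest card's
  time into baseline + layout cost + crowding cost is exact, with any
  layout×crowding interaction split evenly into OA and FA.

**Err composition.** The published definition ("sum of all errors") does not
enumerate error types. `brevis` counts omissions and substitutions and
excludes autocorrections: an autocorrected response is a self-corrected
procedure deviation (the instructions forbid going back), not a search
failure. Autocorrections are still recorded and reported.

Performance times are carried at full floating precision; rounding (half
away from zero, one decimal — the convention of the printed grids, which
round −0.4525 to −0.5) happens only at presentation and, deliberately, just
before table lookups, so that the printed band edges behave exactly as a
clinician reading the tables would expect.

## Published norms

The four correction equations, the tolerance limits, the equivalent-score
boundaries and the percentile grids of the normative study (550 healthy
Italian adults, ages 20–79) are embedded verbatim and exposed as a versioned
JSON norm file, so alternative norm sets plug into the same scoring surface.

One internal inconsistency of the published tables had to be resolved: the
OA equivalent-score table prints its ES-0 edge as 98.9 while the published
outer tolerance limit is 98.8. Since ES 0 and the pathological tolerance
class are by definition the same region (both are "beyond the outer
tolerance limit"), the embedded OA ES-0 edge is 98.8; all other cells are
as printed.

Demographics outside the normative ranges (age 20–79, education 1–21) are
accepted with an explicit extrapolation warning rather than refused —
clinical reality — except hard domain limits (age ≥ 86.9 makes the SA log
transform undefined; education 0 the inverse transform).

## Norming pipeline

* **Outlier filter.** Per card, threshold = Q3 + 3·IQR of the cohort's
  performance times (linearly interpolated quartiles — the default of
  mainstream statistical software; the convention is recorded in the output
  metadata). Any participant at or above a threshold on any card is dropped
  casewise. Thresholds are computed once, on the input cohort. A card with
  zero IQR cannot discriminate and is skipped with a warning.
* **Transform selection.** Candidate families are
  {identity, x², x³, 1/x, ln x, ln(c−x)} for age and
  {identity, 1/x, ln x} for education. Each candidate enters a bivariate
  OLS fit of the raw index; the winner minimises
  AICc = −2LL + 2k + 2k(k+1)/(n−k−1) with k counting intercept, slopes and
  residual variance. The reflected-log offset c is profiled over
  max(x)+0.1 … max(x)+25 in 0.1 steps. The offset is weakly identified:
  ln(c−x) for nearby c are almost affine transforms of one another over the
  adult age range, so the profile criterion is nearly flat in c. The
  published offset 86.9 is embedded verbatim for the published model and
  never re-derived.
* **Model selection.** The seven non-empty subsets of
  {age, education, gender} are ranked by AICc. A model nested in the
  AICc-best one within 2 AICc units (the conventional "substantial support"
  band) wins on parsimony; the chosen model must pass its overall F-test at
  α = 0.05, otherwise no correction is applied for that index.
* **Correction fit.** Transformed predictors and the index are centred at
  their cohort means; the sign-reversed OLS slopes plus those means form the
  correction equation. A correction is therefore identified only up to an
  additive constant — two pipelines centring on slightly different samples
  produce corrections offset by a constant that is absorbed in the adjusted
  scores' location and cancels in every classification.
* **Tolerance limits.** Normality is tested (Shapiro–Wilk, α = 0.05; an
  omnibus test above n = 5000). When rejected — the usual case for
  right-skewed time scores — the one-sided 95%-content/95%-confidence limits
  are order statistics: the outer rank is the smallest m with
  BinomCDF(m−1; n, 0.95) ≥ 0.95, the inner rank the smallest m with
  CDF ≥ 0.05. This is the unique simple rule reproducing the published pair
  (515, 532) at n = 550 (a symmetric 95%-confidence rule for both bounds
  would give 514). At small n the outer rank may exceed n; the limit is then
  reported as not computable rather than raising. The parametric branch uses
  the normal-theory one-sided tolerance factor from the noncentral-t
  distribution.
* **Equivalent scores and percentiles.** ES 0 begins at the outer tolerance
  limit; ES 4 at the median; the ES 1/2 and ES 2/3 edges are the order
  statistics at cumulative 0.80 and 0.65 — three equal 15%-probability bands
  between the 5% worse tail and the median, the convention that reproduces
  the relation between the published ES table and percentile grid.
  Percentile values are linearly interpolated empirical quantiles at
  cumulative 1 − p/100 (rank p = percentage of the sample performing
  worse). The exact rank convention of the original software is not fully
  documented; both conventions used here are parameterised and recorded.

## Synthetic cohorts

The generator emulates the normative study's conditions:

* demographics drawn from the study's gender × age-decade × education-band
  cell counts; ages uniform within decades; band→years mapping declared as
  0–5→5, 6–8→8, 9–13→uniform 9..13, >13→uniform 14..21 (the study reports
  bands, not years);
* continuous indexes by inverting the published corrections:
  raw = baseline − correction(demographics) + noise, with baselines set to
  the decade-size-weighted published index means and noise scaled by the
  published residual standard errors (16.01 / 23.38 / 18.11 / 8.83 s; the
  within-stratum SDs conflate demographic spread and residual noise, the
  RSE is the clean residual quantity). Noise is a shifted gamma (shape 4,
  zero mean, skewness 1) so the nonparametric tolerance branch — the
  published case — is exercised by default; a normal option exercises the
  parametric branch;
* Err as an overdispersed count: gamma-Poisson with demographic-dependent
  mean and variance matching the published residual scale — an emulation,
  not a claim about the study's error process;
* cards by inverting the index formulas, drawing per-card omissions
  (Poisson, default mean 1 per card — a realistic handful of misses per
  protocol against an error total near 16) and assigning the remaining
  errors as substitutions. If an omission draw exceeds the participant's
  error total after bounded redraws it is truncated to fit, so feasible
  inputs never abort. Scoring the generated cards reproduces the generated
  indexes exactly (Err identically, continuous indexes to ~1e-9).

Injected outliers (for exercising the filter) winsorise the clean
participants' card times at Q3 + 2·IQR and place the outliers' card-1 time
at Q3 + 12·IQR, so the 3×IQR filter on the combined cohort removes exactly
the injected records across seeds.

What passing synthetic tests show: the arithmetic, conventions and
statistical machinery are correct, corrections cancel the gradients they
model, and the pipeline recovers generating structure at realistic sample
sizes. What they cannot show: that real BReViS residuals follow a shifted
gamma, that real education–years mappings match the declared rules, or that
the published tolerance-limit *values* (which depend on the raw study data)
would be reproduced.

## Test problem sizes and numerical choices

Simulation-backed tests use n = 550 cohorts (the normative design), 50
replicate seeds for selection-consistency and coverage rates, and n = 5000
for the correction-cancellation check; transform-recovery runs use residual
noise at 25% of the published RSE (a strong-effect condition under which
transform families are statistically distinguishable) and the pipeline
round-trip at 10%. Coverage assertions use the 3.6σ lower band of
Binomial(50, 0.95) (≥ 43/50) so they fail for real defects, not sampling
luck. All randomness flows through explicit integer seeds; there is no
hidden global state.

## Known limitations

* The ES band construction between the 20th/35th percentile edges matches
  the published tables only approximately (the published SA ES-1/2 edge is
  74.8 against a printed 20th percentile of 74.0), reflecting an
  undocumented rank-convention nuance in the original software.
* Norms for children, neglect patients, or left/right omission asymmetry
  scoring are out of scope.
* The clinician-facing report rounds to the printed tables' resolution; the
  full-precision API is the reference for research use.
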