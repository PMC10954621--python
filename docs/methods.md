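# Methods

This note records the modelling assumptions, parameter choices and known
limitations behind `edscore`, at the level of detail a maintainer or
reviewer needs to judge what the package's results do and do not show.

## The scoring model

The score is a sum of nonnegative integer points over categorised triage
variables. Under the fitted logistic model

    logit P(death within 2 days) = β₀ + Σ_v Σ_c β_{v,c} · 1[x_v ∈ c]

points are an affine rescaling of the coefficients: negative β are clamped
to 0 (a category cannot "protect" below its variable's reference), the
vector is rescaled so the maximum achievable total equals 100 and rounded
half away from zero. The documented procedure also divides by the smallest
positive coefficient before rescaling; that step cancels algebraically
under the max-total normalisation, so the implementation computes points
directly from the clamped coefficients (numerically safer when the smallest
positive coefficient is nearly zero). The resulting table is invariant
under positive scaling of all coefficients, which the test suite asserts as
a property.

Rounding half away from zero is load-bearing: it is the convention that
reproduces every non-reference cell of the published overall scorecard from
the published per-site tables and weights (13 cells, verified exactly in
the acceptance suite).

Interval categories are left-closed/right-open: a value equal to a cut
point falls in the bin to its right, so age 60.0 is "60-80" and SpO2 95.0
is ">=95". The published table labels are ambiguous at boundaries; one
convention is fixed and documented here. The published temperature cutoff
is printed as 24 °C, which is physiologically impossible for the risk
direction shown (low temperature scores points); the fixtures record 36 °C
and carry the note in their metadata.

## Variable ranking and selection

Module 1 uses a random forest (500 trees, seeded, single-threaded for
reproducibility) with permutation importance measured on a 25% stratified
held-out fold of the development data, scoring AUROC loss over 5 shuffles.
Permutation importance on held-out data was chosen over impurity importance
because it is robust to the ordinal encoding of categorical variables (each
categorical is one integer-coded feature, so importance is per variable).
Ties are broken by variable-name order so rankings are stable.

The default candidate set is the 14 variables observable at triage (age,
sex, day-of-week, shift, KTAS, AVPU consciousness, arrival route, transport
mode, six vitals); comorbidity history can be added via the `candidates`
argument. The shipped multi-site pipeline then applies a clinical-review
substitution: the final scorecard uses a fixed 8-variable list (age, pulse,
respiration, temperature, SBP, DBP, SpO2, consciousness) regardless of the
per-site ranking, because administratively flavoured variables (e.g.
day-of-week) can rank highly without being clinically actionable, and a
fixed list keeps the per-site tables structurally identical — a
prerequisite for the weighted overall combination. The ranking and the
parsimony curve (validation AUROC for k = 1..k_max top-ranked variables,
smallest k within 0.5% of the best by default) are still computed and
exported, so the selection evidence is inspectable.

The parsimony curve is evaluated against the same held-out split later used
to report test AUROC. That mirrors the study design being replicated; when
model size is genuinely free, a further split or cross-validation inside
the development data would be cleaner.

## Class rebalancing

With ~0.5% prevalence, a 70% development split of a 30,000-visit cohort
holds only ~100 events. The rebalancing plan doubles the minority by SMOTE
interpolation (k = 5 nearest minority neighbours, Euclidean distance on
z-scored continuous features; categorical fields copied from the seed
record) and down-samples the majority without replacement to the enlarged
minority size, giving an exactly 1:1 development set. The alternative
reading — majority sampled to the *original* minority count — is available
as `majority_target="match-original"`. Rebalancing applies to the
development split only; all evaluation uses untouched data. A side effect
worth knowing: the logistic intercept (hence any probability calibration)
is meaningless after rebalancing; only the ranking of scores, and thus
AUROC, is preserved.

## Site weighting

w_i = sqrt(AUC_i)·N_i³ / Σ_j sqrt(AUC_j)·N_j³ makes weights scale-invariant
in N and dominated by cohort size (cubic) with a mild quality factor
(square root of AUROC). The package recomputes weights from whatever
(AUC, N) pairs it is given; the shipped fixture for the published overall
table stores the printed weights (0.472, 0.410, 0.116) verbatim, because
recomputing from the printed internal AUROCs (0.913/0.919/0.930) and cohort
sizes gives (0.475, 0.410, 0.115) — close but not identical, and the exact
inputs used originally are not identifiable.

## Validation

AUROC is computed in rank form and equals the Mann–Whitney concordance
probability with half-credit for ties; a brute-force O(n²) pairwise
enumeration serves as the oracle in tests. Confidence intervals are
percentile bootstrap over record indices (1000 replicates, 2.5/97.5
percentiles, seeded per grid cell so results are independent of evaluation
order). Single-class resamples are skipped with a logged count; more than
50% skipped raises, as the interval would be meaningless. Percentile
rather than BCa was chosen as the simplest defensible reading of an
unqualified "bootstrap CI"; at the cohort sizes used the difference is
well inside the interval width. Threshold metrics default to the
Youden-optimal threshold on the evaluated data (reported in the output);
note this optimism-biases sensitivity/specificity slightly relative to a
pre-registered threshold.

## Synthetic cohorts

The generator emulates three hospital ED populations from their published
class-conditional summaries: outcome drawn Bernoulli(prevalence from event
counts), then every predictor drawn independently given the class —
truncated normals for age and vitals (bounds: age 18–105, pulse 20–250,
SBP 40–260, DBP 20–160, respiration 4–60, SpO2 40–100, temperature
33–42 °C), categorical draws for the discrete variables, independent
Bernoulli flags for the 15 comorbidities. Prevalences use printed event
counts over printed totals; hospital C's count-derived rate (0.70%)
disagrees with its separately printed 0.65%, and the counts are used.

Conditional independence given the outcome is the simplest model consistent
with every published marginal summary, since the joint correlation
structure is unreported. Its consequences cut both ways: real vitals are
correlated (shock presents as low BP *and* high pulse), so the synthetic
discrimination task is easier — synthetic AUROCs of 0.95–0.98 against the
0.89–0.93 reported for real data are expected, and passing tests demonstrate
that the machinery recovers structure, not that the score would reach any
particular AUROC in deployment. Truncation also shifts moments away from
the nominal (mean, sd) where a bound is close — materially for age (lower
bound 18) and SpO2 (upper bound 100, about −1.1 points for survivors) —
so moment-recovery tests compare against the truncated distribution's
theoretical moments, which are what the generator actually targets; the
mildly truncated vitals are additionally checked against the nominal
parameters. Not modelled at all: inter-variable correlation, seasonality,
measurement missingness, repeat visits.

One integer seed drives a private `numpy` Generator per cohort; fixed
(profile, n, seed) reproduces a cohort byte for byte, and the pipeline
derives per-site and per-cell seeds from the single configured seed.

## Numerical and degenerate-input choices

- Logistic fitting: Newton's method first, BFGS fallback on singular
  Hessians; categories unobserved in the development data are excluded from
  the design and score 0 (they cannot be estimated); non-convergence or
  non-finite coefficients raise with advice to merge sparse categories.
- Quantile binning uses the 5th/20th/80th/95th percentiles and merges bins
  holding under 1% of the data; variables collapsing to one bin are flagged
  unusable and excluded rather than silently scored.
- Welch's t-test (unequal variances — class sizes differ by factor ~200)
  and Pearson chi-square without continuity correction for the
  demographics table; multi-category SMD uses the Mahalanobis form with a
  pseudo-inverse so empty categories do not blow up.
- A record missing a scorecard variable scores that variable as reference
  (0) with a logged warning — conservative for triage deployment, where a
  missing vital should not inflate risk; an unrecognised category value is
  an error naming the variable.
- The exclusion flow tallies each record at its first matching criterion in
  the order age < 18, death-on-arrival/left-without-being-seen, trauma.

## Problem sizes

Unit tests develop scores on cohorts of 6,000–20,000 synthetic visits; the
end-to-end recovery check uses 80,000 visits (three seeds), matching the
scale at which a ~0.5%-prevalence outcome yields a few hundred events and a
stable 8-variable fit. The acceptance script's study replica draws 30,000
visits per hospital — enough for every stage, including the 12-cell
bootstrap validation grid, to run at full fidelity while keeping the whole
script in the tens of seconds.

## Known limitations

- Published headline AUROCs cannot be reproduced without the original
  hospital data; the package asserts arithmetic identities (scorecard
  combination, prevalences, weights) exactly and everything else as
  properties on synthetic data.
- The score is a discrimination tool; no probability calibration is
  provided (and none would survive SMOTE, see above).
- The OMOP-style input path is a column-renaming shim, not an ETL; the
  common-data-model transformation proper is out of scope.
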