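# Methods

This note documents the models, assumptions, and numerical choices in
`asdsurv`. It is the package's own account of its science; every number
mentioned is computed by the test suite or the acceptance script, not
asserted here.

## The surveillance process being modelled

Active records-based ASD surveillance ascertains cases from existing
provider records rather than examining children. Sites request records
from community health, education, and service providers for children in
the cohort (age 8 in the analysis year, i.e. born eight years earlier)
carrying requested ICD codes or special-education exceptionalities;
trained staff review accessible charts and abstract developmental
evaluations, eligibility classifications, and cognitive tests, combining
each child's records across sources. A child is a case if the combined
record documents a qualified professional's ASD diagnostic statement, a
special-education autism classification/eligibility, or an ASD ICD code
(ICD-9 299.00–299.99; ICD-10 F84.* excluding F84.2 and its extensions).

Two observability mechanisms matter and are modelled explicitly:

- **Source availability.** A site without an education data source can
  never observe special-education indicators; children identified only
  at school are invisible there.
- **Chart accessibility.** A record that could not be physically
  reviewed still transmits its ICD and special-education codes but none
  of its narrative content (evaluations, cognitive tests). A diagnostic
  statement on an inaccessible chart therefore does not count toward the
  diagnostic-statement indicator — this mirrors the pandemic-era
  operating conditions of the 2018 surveillance year and produces
  underascertainment at low-accessibility sites.

One documented interpretation choice: the case definition's
special-education clause is satisfied by a *transmitted* eligibility
code even when the education chart itself was inaccessible, mirroring
the ICD clause; only the diagnostic-statement clause requires an
accessible evaluation.

## Synthetic data generator

The generator is first-class, tested code. Per site it draws:

- **Population.** `n_children` children with independent sex
  (`pct_male`) and race/ethnicity (`race_mix` over six categories
  including other/multiracial). Residency is uniform (all children
  resident); non-residency and wrong birth year are exercised directly
  in unit tests of the classifier.
- **Latent cases.** Bernoulli per child with sex-specific rates solving
  p_male = RR·p_female under the configured overall `true_prevalence`
  and male:female rate ratio RR.
- **Census tracts.** `tract_count` tracts with MHI drawn uniformly over
  `tract_mhi_range` (the field's income distributions are not modelled;
  uniformity suffices to exercise the tertile machinery). Children are
  assigned to tracts uniformly (a symmetric multinomial), except a
  `missing_tract_fraction` left ungeocoded; tract counts of 5–9-year-olds
  are stored as 5× the assigned 8-year-olds so the est = n/5 identity is
  exact. SES is therefore independent of case status by default; SES
  gradients are injected by tests when needed.
- **Identification.** Each true case independently draws one of the
  seven non-empty indicator combinations from the site's
  `identification_mixture`. Site presets derive their mixtures from the
  published per-site indicator marginals via a
  conditional-independence construction (independent indicators
  conditioned on at least one being present), which reproduces the
  marginals approximately.
- **Documents and ages.** Ages are generated directly in integer months
  (every reported age statistic is in months, so no calendar arithmetic
  is needed), from log-normal distributions parameterised by their
  median, truncated to [12, 107] by inverse-CDF sampling — right-skewed
  diagnosis ages with an age-8 observation ceiling. Diagnosis-age
  medians are configured per cognitive band; first-evaluation ages have
  their own distribution. A fixed 10% of diagnostic statements are
  recorded only as historically reported prior diagnoses inside a later
  evaluation. Suspected-before-confirmed and ruled-out evaluation
  sequences are inserted with the configured probabilities and
  internally consistent ordering (a "ruled out more recently" sequence
  places the rule-out strictly after the latest confirmation age;
  rule-out sequences are only generated for children with a diagnosis
  or eligibility to rule out).
- **Cognitive data.** A latent IQ band per case (`iq_band_probs`);
  observed as a test score within the band for `iq_available_fraction`
  of cases.
- **Noise.** Non-case children carry a requested-but-non-indicator code
  (a lone F84.2) at `false_trigger_rate`, exercising the Rett exclusion
  downstream.
- **Accessibility.** Sampled per record, not per child, so a child's
  sources can differ in accessibility.

Randomness: all draws come from `numpy.random.Generator` streams spawned
deterministically from a single seed via `SeedSequence([seed, stream])`
with one child-stream and one record-stream per site, so identical
(config, seed) pairs are byte-identical, and two configurations that
differ only in observability switches (e.g. `has_education_source`)
share the same latent population under the same seed — the basis of the
paired source-access experiments.

What the generator does **not** emulate: realistic clinical narratives,
joint distributions of identification type with race, sex, or SES
(independent unless configured), income geography, calendar-time service
pathways, or abstraction workload. Passing tests therefore demonstrate
the correctness and calibration of the pipeline under the stated
process, not the sociology of real referral patterns.

## Estimation layer

- **Prevalence.** x/n per 1,000 with the Wilson score interval at
  z = 1.959964 (the 97.5th normal percentile to six decimals rather than
  the textbook 1.96; the difference is below the one-decimal reporting
  resolution). The interval is the closed-form inversion of the score
  test; tests verify agreement with a numeric inversion oracle to 1e-9
  and near-nominal coverage by simulation.
- **RSE suppression.** RSE = √(p̂(1−p̂)/n)/p̂, infinite at x = 0. The
  reporting layer suppresses estimates with RSE > 0.30 (roughly,
  numerators below ~12) and every ratio built from a suppressed
  component, rendering them as an em dash.
- **Prevalence ratios.** Computed from unrounded prevalences (the
  published male:female ratio is only reproducible unrounded) with the
  log-normal (Katz) interval. The source reports do not name their ratio
  interval; the Katz interval was adopted and validated against the
  published network-total ratio bounds.
- **Chi-square.** Pearson, no continuity correction
  (`scipy.stats.chi2_contingency`), df = k−1 on 2×k tables.
- **Woolf homogeneity of ratios.** Weights w = 1/(1/x₁ − 1/n₁ + 1/x₂ −
  1/n₂); statistic Σw(ln R − ln R̄)² against χ²(strata−1). Strata with a
  zero numerator are excluded with a warning (their log ratio is
  undefined).
- **Cochran-Armitage trend.** Equally spaced scores over ordered SES
  tertiles; two-sided normal p; degenerate inputs (no cases / all
  cases) return p = 1. On two groups the squared statistic equals the
  Pearson chi-square, which the tests exploit as an identity check.
- **Permutation median test.** Statistic |median(x) − median(y)| with
  medians averaging the two central order statistics (half-month medians
  in the reports imply this convention). All C(n, n_x) label
  arrangements are enumerated when that count is ≤ 20,000 (exact p);
  otherwise a seeded Monte-Carlo with the add-one estimator
  (count+1)/(N+1), which cannot return p = 0.
- **Rounding.** Half-away-from-zero to one decimal, applied only at the
  reporting boundary; all internal arithmetic is unrounded.

## Denominators and SES tertiles

Denominator cells (site × sex × race/ethnicity) count the generated
children exactly. Children coded other/multiracial stay in the cells
(so site totals conserve) but are excluded from race-specific
numerators and denominators alike. Tract 8-year-old populations are
estimated as the 5–9 count divided by five, fractions preserved. MHI
tertiles are assigned over all sites combined: tracts sorted by MHI
(ties by tract id), cumulative estimated population tracked; a tract is
*low* if its cumulative interval ends by T/3, *high* if it starts at or
after 2T/3, else *medium*. Whole tracts are never split, so each
tertile is within one tract's population of T/3, and assignment is
invariant to input order. Tertile cuts weight by the estimated
8-year-old population (an assumption; the source describes only
"approximately equal-sized population groups"). SES-stratified
prevalence uses tract-sum denominators (possibly fractional); children
without a geocodable tract are excluded from SES strata but retained in
overall prevalence.

## Reporting and reproducibility

Tables are built as tidy numeric frames and rendered to
publication-style strings (`23.0 (22.3–23.6)`, suppressed cells as `—`)
only at the CSV boundary, so written CSVs re-parse into exactly the
rendered frames. A run manifest records the configuration hash, seed,
and package version; reruns with identical inputs produce identical
bytes. Figures are optional matplotlib methods on the results object;
CSV is the canonical output.

## Problem sizes used in the checks

The test suite exercises the generator at up to the full network scale
(220,281 children) for the calibration check (200 replicates), and uses
smaller populations (1,500–25,000 children) where the property under
test does not depend on scale: coverage and type-I-error simulations use
1,000–2,000 replicates, mixture-marginal recovery 100 replicates, and
the paired education-masking experiment 100 replicates of 5,000
children. These sizes were chosen so Monte-Carlo standard errors are
small relative to the tested tolerances (3 SE bands throughout).

## Known limitations

- The identification mixture is independent of demographics and SES, so
  the package cannot by itself reproduce published race-specific
  identification disparities; configuring per-site mixtures is the
  intended extension point.
- Preset `true_prevalence` values equal the published *ascertained*
  prevalences, and preset accessibility further attenuates observed
  diagnostic-statement shares; a preset run therefore lands near, not
  on, the published per-site identification shares.
- Suspected/ruled-out sequences are label-level only; no evaluation text
  or DSM-criteria scoring is modelled.
- The Woolf and Cochran-Armitage tests rely on large-sample chi-square /
  normal approximations; they are not exact for very small strata.
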