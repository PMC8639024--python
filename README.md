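# asdsurv

Records-based surveillance of autism spectrum disorder (ASD) among
8-year-old children, as a reusable Python pipeline: a seeded synthetic
generator of multi-source child records, the three-indicator surveillance
case definition, census-tract socioeconomic stratification, and the full
estimation layer behind multi-site prevalence reports.

It is written for epidemiologists and biostatisticians who want to study
how an active, records-based surveillance design behaves — how prevalence
estimates respond to source availability, chart accessibility, and
identification practices — without access to confidential child-level
surveillance data.

## The surveillance model

A surveillance site reviews health, education, and service-provider
records for every child born in the cohort year (age 8 in the analysis
year) who lived in the site's catchment area. A child **meets the ASD
case definition** if their combined records document any of:

1. a written ASD diagnostic statement by a qualified professional in a
   developmental evaluation (including reports of a previous diagnosis);
2. a special-education classification of autism (primary exceptionality
   or autism eligibility met); or
3. an ASD ICD billing code — ICD-9 in 299.00–299.99, or ICD-10 in the
   F84 family **except F84.2** (Rett syndrome).

Records flagged inaccessible (charts that could not be reviewed)
contribute only their transmitted ICD and special-education codes, so a
diagnostic statement on an unreviewable chart is never observed.

Prevalence is estimated per 1,000 children,

> p̂ = 1000 · x / n,  with the 95% Wilson score interval
> ( p̂ + z²/2n ± z·√(p̂(1−p̂)/n + z²/4n²) ) / (1 + z²/n),  z = 1.959964,

prevalence ratios carry log-normal (Katz) intervals
exp(ln R ± z·√(1/x₁ − 1/n₁ + 1/x₂ − 1/n₂)), and any estimate with
relative standard error √(p̂(1−p̂)/n)/p̂ above 30% is suppressed (rendered
as an em dash), along with every ratio built from it. Proportions are
compared with Pearson chi-square tests, prevalence ratios across sites
with the Woolf (Mantel-Haenszel) homogeneity test, prevalence trends
across census-tract median-household-income tertiles with the
Cochran-Armitage test, and differences in median ages with permutation
tests (exhaustive when the number of label arrangements is ≤ 20,000).

## Worked example

```python
from asdsurv import ASDSurveillance, network_preset

model = ASDSurveillance.from_config(network_preset(), seed=1)
results = model.fit()
print(results.summary())
```

```
ASD surveillance summary (children aged 8 years)
==================================================
Sites: 11    Population: 220,281
Children meeting the case definition: 4,934
Overall prevalence per 1,000: 22.4 (95% CI 21.8–23.0)
  i.e. one in 45 children
Male-to-female prevalence ratio: 4.3 (95% CI 4.0–4.6)
Identification: 69.0% diagnostic statement, 22.5% special-education only, 8.5% ICD code only
```

The eleven named site presets reproduce the published 2018 network's
population sizes, demographics, source availability, and chart
accessibility, so one seeded synthetic run lands close to the published
totals (23.0 per 1,000, one in 44, ratio 4.2). Per-site rows behave the
way the real sites did — e.g. the `missouri` preset (health sources only)
has the lowest prevalence and the highest ICD-only identification share:

```python
rendered = results.bundle.rendered()["table2"]
print(rendered[rendered.site.isin(["california", "missouri", "total"])])
```

```
      site n_asd population  prevalence_95ci male_prevalence_95ci female_prevalence_95ci male_female_ratio_95ci
california   593      15076 39.3 (36.3–42.6)     65.1 (59.8–70.8)        12.0 (9.8–14.8)          5.4 (4.3–6.8)
  missouri   403      24481 16.5 (14.9–18.1)     23.7 (21.2–26.5)         8.7 (7.2–10.5)          2.7 (2.2–3.4)
     total  4934     220281 22.4 (21.8–23.0)     35.8 (34.7–36.9)          8.4 (7.8–8.9)          4.3 (4.0–4.6)
```

`results.bundle` carries analogues of the full report: overall/sex
prevalence, race/ethnicity prevalence with pairwise ratios,
identification shares, cognitive (IQ) band availability and
distribution, first-evaluation and diagnosis-age tables, SES-tertile
prevalence with trend tests, and the seven-region identification Euler
counts. `results.to_csv(outdir)` writes every table; suppressed cells
appear as `—`.

The same pipeline is scriptable from the shell:

```bash
asdsurv all --preset california --seed 1 --outdir out/
asdsurv generate --preset georgia --seed 7 --outdir gen/
asdsurv ascertain --indir gen/ --outdir gen/
asdsurv report --indir gen/ --outdir gen/
```

## Layout

- `asdsurv.config` / `asdsurv.synthesize` — generator configuration,
  site presets, seeded population/record synthesis
- `asdsurv.ascertain` — record merging and the case definition
- `asdsurv.ses` — denominators, tract income tertiles
- `asdsurv.stats` — prevalence, intervals, suppression, and the named tests
- `asdsurv.report` / `asdsurv.model` / `asdsurv.pipeline` / `asdsurv.cli`
  — tables, the model/results front end, orchestration, and the CLI

See `docs/methods.md` for modelling assumptions and design choices.
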