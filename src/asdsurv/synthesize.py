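"""Seeded synthetic populations and multi-source child records.

The generator emulates the structure active records-based surveillance
assumes: a cohort of 8-year-olds per site with sex and race/ethnicity
mixes, a latent true-case process with a male:female rate ratio, census
tracts with uniform incomes and multinomial child counts, and per-case
records spread across health and education sources. True cases draw one
of the seven identification-type combinations; education-sourced
indicators are generated but never observable at sites without an
education data source, and inaccessible records transmit only their ICD
and special-education codes.

Everything is driven by ``numpy.random.Generator`` streams spawned
deterministically from a single seed, so identical (config, seed) pairs
produce byte-identical outputs.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ascertain import (
    IQ_BANDS,
    REGIONS,
    CognitiveAssessment,
    Evaluation,
    SourceRecord,
    SpedEligibility,
)
from .config import GeneratorConfig, SiteConfig
from .errors import ConsistencyError
from .ses import RACE_CATEGORIES, DenominatorTable, Tract

__all__ = ["generate_population", "generate_records", "CHILD_COLUMNS"]

CHILD_COLUMNS = [
    "child_id",
    "site",
    "sex",
    "race_ethnicity",
    "resident_in_year",
    "census_tract",
    "is_true_case",
]

#: ASD indicator billing codes the generator draws from.
_ASD_CODES = ("F84.0", "299.00", "F84.9", "299.80", "F84.5", "F84.8")
#: Requested-but-non-indicator code planted on false-trigger children.
_FALSE_TRIGGER_CODE = "F84.2"

#: Probability that a diagnostic statement is documented only as a
#: historically reported prior diagnosis inside a later evaluation.
_P_REPORTED_PRIOR = 0.10

_REGION_FLAGS = {
    "dx-only": (True, False, False),
    "sped-only": (False, True, False),
    "icd-only": (False, False, True),
    "dx+sped": (True, True, False),
    "dx+icd": (True, False, True),
    "sped+icd": (False, True, True),
    "all-three": (True, True, True),
}


def _site_rngs(config: GeneratorConfig, seed: Optional[int], stream: int):
    """One independent Generator per site, deterministic in (seed, stream)."""
    entropy = config.global_seed if seed is None else seed
    root = np.random.SeedSequence([int(entropy), stream])
    return [np.random.default_rng(ss) for ss in root.spawn(len(config.sites))]


def generate_population(
    config: GeneratorConfig, seed: Optional[int] = None
) -> tuple[pd.DataFrame, DenominatorTable, list]:
    """Generate children, denominators, and census tracts for a network.

    Returns a children DataFrame (one row per child), a
    :class:`DenominatorTable` whose cells count exactly the generated
    children, and the list of :class:`Tract` objects. Children missing a
    geocodable tract (per ``missing_tract_fraction``) have an empty
    ``census_tract``; tract child counts are the multinomial counts of
    geocoded children, stored as counts of 5–9-year-olds (5× the assigned
    8-year-olds) so the est_age_8 = n_age_5_9 / 5 identity is exact.
    """
    config.validate()
    frames = []
    tracts: list[Tract] = []
    for site, rng in zip(config.sites, _site_rngs(config, seed, stream=0)):
        n = site.n_children
        male = rng.random(n) < site.pct_male
        race_probs = np.array([site.race_mix[c] for c in RACE_CATEGORIES])
        race_idx = rng.choice(len(RACE_CATEGORIES), size=n, p=race_probs)
        p_male, p_female = site.sex_specific_prevalence()
        is_case = rng.random(n) < np.where(male, p_male, p_female)
        missing = rng.random(n) < site.missing_tract_fraction
        tract_idx = rng.integers(0, site.tract_count, size=n)
        mhi = rng.uniform(*site.tract_mhi_range, size=site.tract_count)
        tract_ids = [f"{site.site_name}-T{i:04d}" for i in range(site.tract_count)]
        assigned = np.where(missing, -1, tract_idx)
        counts = np.bincount(assigned[assigned >= 0], minlength=site.tract_count)
        child_tracts = np.array(tract_ids, dtype=object)[tract_idx]
        child_tracts[missing] = ""
        for i in range(site.tract_count):
            tracts.append(
                Tract(
                    tract_id=tract_ids[i],
                    site=site.site_name,
                    mhi_usd=float(round(mhi[i], 2)),
                    n_age_5_9=int(counts[i]) * 5,
                )
            )
        frames.append(
            pd.DataFrame(
                {
                    "child_id": [f"{site.site_name}-{i:06d}" for i in range(n)],
                    "site": site.site_name,
                    "sex": np.where(male, "male", "female"),
                    "race_ethnicity": np.array(RACE_CATEGORIES, dtype=object)[race_idx],
                    "resident_in_year": True,
                    "census_tract": child_tracts,
                    "is_true_case": is_case,
                }
            )
        )
    children = pd.concat(frames, ignore_index=True)[CHILD_COLUMNS]
    return children, DenominatorTable.from_children(children), tracts


def _case_records(
    site: SiteConfig,
    child_id: str,
    rng: np.random.Generator,
    region: str,
    band: str,
    iq_available: bool,
    conf_age: int,
    first_eval_age: int,
    suspected: bool,
    ruled_out: bool,
    ruled_out_more_recent: bool,
) -> list:
    """Build the observable records for one true case."""
    has_dx, has_sped, has_icd = _REGION_FLAGS[region]
    health = SourceRecord(
        child_id=child_id,
        site=site.site_name,
        source_type="health",
        accessible=bool(rng.random() < site.record_accessible_fraction),
    )
    education = None
    if has_sped and site.has_education_source:
        education = SourceRecord(
            child_id=child_id,
            site=site.site_name,
            source_type="education",
            accessible=bool(rng.random() < site.record_accessible_fraction),
            sped_eligibility=SpedEligibility(
                classification="autism-primary" if rng.random() < 0.5 else "autism-eligibility-met",
                age_months=int(np.clip(conf_age + rng.integers(-6, 19), 12, 107)),
            ),
        )

    if has_icd:
        code = _ASD_CODES[rng.integers(0, len(_ASD_CODES))]
        health.icd_codes.append((code, int(conf_age)))
    if has_dx:
        if rng.random() < _P_REPORTED_PRIOR:
            eval_age = int(min(107, conf_age + rng.integers(6, 19)))
            health.evaluations.append(
                Evaluation(
                    age_months=eval_age,
                    conclusion="asd-diagnosis",
                    by_qualified_professional=True,
                    reported_prior_diagnosis_age_months=int(conf_age),
                )
            )
        else:
            health.evaluations.append(
                Evaluation(age_months=int(conf_age), conclusion="asd-diagnosis")
            )

    # evaluations that accompany, rather than define, the indicators
    extra_evals = []
    if suspected:
        extra_evals.append(
            Evaluation(
                age_months=int(np.clip(min(first_eval_age, conf_age - 3), 12, 107)),
                conclusion="asd-suspected",
            )
        )
    elif first_eval_age < conf_age and (has_dx or has_sped):
        extra_evals.append(
            Evaluation(age_months=int(first_eval_age), conclusion="other")
        )
    if ruled_out and (has_dx or has_sped):
        if ruled_out_more_recent:
            age = int(min(107, conf_age + rng.integers(3, 25)))
            if age <= conf_age:  # confirmation at the observation ceiling
                age = 107
        else:
            age = int(max(12, conf_age - rng.integers(3, 25)))
        extra_evals.append(Evaluation(age_months=age, conclusion="asd-ruled-out"))

    cognitive = []
    if iq_available:
        lo, hi = {"<=70": (40, 70), "71-85": (71, 85), ">85": (86, 130)}[band]
        cognitive.append(
            CognitiveAssessment(
                age_months=int(rng.integers(48, 101)),
                kind="test-score",
                iq_score=int(rng.integers(lo, hi + 1)),
            )
        )

    # Attach narrative content to the health record when the child has any
    # health-side indicator; otherwise it lives on the education record.
    if has_icd or has_dx or education is None:
        health.evaluations.extend(extra_evals)
        health.cognitive.extend(cognitive)
    else:
        education.evaluations.extend(extra_evals)
        education.cognitive.extend(cognitive)

    records = []
    if health.icd_codes or health.evaluations or health.cognitive:
        records.append(health)
    if education is not None:
        records.append(education)
    return records


def generate_records(
    children: pd.DataFrame,
    config: GeneratorConfig,
    seed: Optional[int] = None,
) -> list:
    """Generate observable source records for a generated population.

    True cases draw an identification-type combination from the site's
    mixture and a latent cognitive band; indicator documents and ages are
    sampled from the configured distributions. Non-case children carry a
    requested-but-non-indicator code (a lone F84.2) at the site's
    false-trigger rate. Raises :class:`ConsistencyError` when the children
    do not match the configuration's sites.
    """
    config.validate()
    missing_cols = set(CHILD_COLUMNS) - set(children.columns)
    if missing_cols:
        raise ConsistencyError(f"children frame missing columns {sorted(missing_cols)}")
    site_names = {s.site_name for s in config.sites}
    extra = set(children["site"].unique()) - site_names
    if extra:
        raise ConsistencyError(f"children reference sites not in config: {sorted(extra)}")

    region_list = list(REGIONS)
    records: list[SourceRecord] = []
    for site, rng in zip(config.sites, _site_rngs(config, seed, stream=1)):
        sub = children[children["site"] == site.site_name]
        cases = sub[sub["is_true_case"]]
        n_cases = len(cases)
        if n_cases:
            weights = np.array([site.identification_mixture[r] for r in region_list])
            region_idx = rng.choice(len(region_list), size=n_cases, p=weights / weights.sum())
            band_probs = np.array([site.iq_band_probs[b] for b in IQ_BANDS])
            band_idx = rng.choice(len(IQ_BANDS), size=n_cases, p=band_probs / band_probs.sum())
            iq_avail = rng.random(n_cases) < site.iq_available_fraction
            conf_ages = np.empty(n_cases, dtype=int)
            for b, name in enumerate(IQ_BANDS):
                mask = band_idx == b
                if mask.any():
                    conf_ages[mask] = site.dx_age_months_distribution[name].sample(
                        rng, int(mask.sum())
                    )
            first_eval = site.first_eval_age_months_distribution.sample(rng, n_cases)
            suspected = rng.random(n_cases) < site.p_suspected_before_confirmed
            ruled_out = rng.random(n_cases) < site.p_ruled_out_ever
            p_recent = (
                site.p_ruled_out_more_recent / site.p_ruled_out_ever
                if site.p_ruled_out_ever > 0
                else 0.0
            )
            more_recent = ruled_out & (rng.random(n_cases) < p_recent)
            for i, child_id in enumerate(cases["child_id"].tolist()):
                records.extend(
                    _case_records(
                        site,
                        child_id,
                        rng,
                        region=region_list[region_idx[i]],
                        band=IQ_BANDS[band_idx[i]],
                        iq_available=bool(iq_avail[i]),
                        conf_age=int(conf_ages[i]),
                        first_eval_age=int(first_eval[i]),
                        suspected=bool(suspected[i]),
                        ruled_out=bool(ruled_out[i]),
                        ruled_out_more_recent=bool(more_recent[i]),
                    )
                )
        noncases = sub[~sub["is_true_case"]]
        if len(noncases) and site.false_trigger_rate > 0:
            trigger = rng.random(len(noncases)) < site.false_trigger_rate
            for child_id in noncases.loc[trigger, "child_id"].tolist():
                records.append(
                    SourceRecord(
                        child_id=child_id,
                        site=site.site_name,
                        source_type="health",
                        accessible=bool(rng.random() < site.record_accessible_fraction),
                        icd_codes=[(_FALSE_TRIGGER_CODE, int(rng.integers(18, 91)))],
                    )
                )
    return records
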