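"""Shared fixtures: small synthetic configurations and record builders."""

from __future__ import annotations

import dataclasses

import pytest

from asdsurv.ascertain import (
    Evaluation,
    SourceRecord,
    SpedEligibility,
)
from asdsurv.config import GeneratorConfig, SiteConfig, mixture_from_marginals


def make_site(**overrides) -> SiteConfig:
    """A small, fully-accessible single site; overrides tweak fields."""
    site = SiteConfig(site_name="testville", n_children=2_000, tract_count=6)
    return dataclasses.replace(site, **overrides)


def make_config(**site_overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(sites=[make_site(**site_overrides)])
    cfg.validate()
    return cfg


@pytest.fixture
def small_config() -> GeneratorConfig:
    return make_config()


@pytest.fixture
def rich_mixture() -> dict:
    """A mixture with substantial mass on every region."""
    return mixture_from_marginals(0.6, 0.6, 0.6)


def health_record(child_id="c1", site="testville", accessible=True, **kwargs) -> SourceRecord:
    return SourceRecord(
        child_id=child_id, site=site, source_type="health", accessible=accessible, **kwargs
    )


def education_record(
    child_id="c1", site="testville", accessible=True, classification="autism-primary", age=60
) -> SourceRecord:
    return SourceRecord(
        child_id=child_id,
        site=site,
        source_type="education",
        accessible=accessible,
        sped_eligibility=SpedEligibility(classification=classification, age_months=age),
    )


def dx_evaluation(age=48, qualified=True, prior=None) -> Evaluation:
    return Evaluation(
        age_months=age,
        conclusion="asd-diagnosis",
        by_qualified_professional=qualified,
        reported_prior_diagnosis_age_months=prior,
    )
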