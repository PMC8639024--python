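"""Reading and writing the pipeline's file formats.

All artefacts are plain text: children, denominators and tracts as CSV
with a header row; records either as CSV (one row per record-indicator
item) or nested JSON (one object per child); generator configuration as
YAML or JSON. Identifiers are stable strings, so a write/read round-trip
reproduces the in-memory objects exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .ascertain import (
    CognitiveAssessment,
    Evaluation,
    SourceRecord,
    SpedEligibility,
)
from .config import AgeDistribution, GeneratorConfig, SiteConfig
from .errors import ConfigurationError, DataError
from .ses import DenominatorTable, Tract
from .synthesize import CHILD_COLUMNS

__all__ = [
    "save_children", "load_children",
    "save_records_csv", "load_records_csv",
    "save_records_json", "load_records_json",
    "save_denominators", "load_denominators",
    "save_tracts", "load_tracts",
    "save_statuses",
    "config_to_dict", "config_from_dict",
    "load_generator_config", "save_generator_config",
]


# -- children ---------------------------------------------------------------

def save_children(children: pd.DataFrame, path) -> None:
    children.to_csv(path, index=False)


def load_children(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"census_tract": str}, keep_default_na=False)
    missing = set(CHILD_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"children file {path} missing columns {sorted(missing)}")
    for col in ("resident_in_year", "is_true_case"):
        df[col] = df[col].astype(str).str.lower().isin(("true", "1"))
    return df[CHILD_COLUMNS]


# -- records ----------------------------------------------------------------

_RECORD_COLUMNS = [
    "child_id", "site", "record_id", "source_type", "accessible", "item_type",
    "code", "age_months", "classification", "conclusion",
    "by_qualified_professional", "reported_prior_diagnosis_age_months",
    "kind", "iq_score", "stated_band",
]


def _record_rows(record: SourceRecord, record_id: str) -> list:
    base = {
        "child_id": record.child_id,
        "site": record.site,
        "record_id": record_id,
        "source_type": record.source_type,
        "accessible": record.accessible,
    }
    rows = []
    for code, age in record.icd_codes:
        rows.append({**base, "item_type": "icd", "code": code, "age_months": age})
    if record.sped_eligibility is not None:
        rows.append(
            {
                **base,
                "item_type": "sped",
                "classification": record.sped_eligibility.classification,
                "age_months": record.sped_eligibility.age_months,
            }
        )
    for ev in record.evaluations:
        rows.append(
            {
                **base,
                "item_type": "evaluation",
                "age_months": ev.age_months,
                "conclusion": ev.conclusion,
                "by_qualified_professional": ev.by_qualified_professional,
                "reported_prior_diagnosis_age_months": ev.reported_prior_diagnosis_age_months,
            }
        )
    for cg in record.cognitive:
        rows.append(
            {
                **base,
                "item_type": "cognitive",
                "age_months": cg.age_months,
                "kind": cg.kind,
                "iq_score": cg.iq_score,
                "stated_band": cg.stated_band,
            }
        )
    if not rows:  # an empty record still exists as an entity
        rows.append({**base, "item_type": "none"})
    return rows


def save_records_csv(records: Sequence[SourceRecord], path) -> None:
    rows = []
    for i, record in enumerate(records):
        rows.extend(_record_rows(record, f"{record.child_id}-r{i:06d}"))
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, index=False)


def _opt_int(value) -> Optional[int]:
    if value is None or value == "" or pd.isna(value):
        return None
    return int(float(value))


def load_records_csv(path) -> list:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    records: dict[str, SourceRecord] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        rid = row.record_id
        if rid not in records:
            records[rid] = SourceRecord(
                child_id=row.child_id,
                site=row.site,
                source_type=row.source_type,
                accessible=str(row.accessible).lower() in ("true", "1"),
            )
            order.append(rid)
        rec = records[rid]
        item = row.item_type
        if item == "icd":
            rec.icd_codes.append((row.code, _opt_int(row.age_months)))
        elif item == "sped":
            rec.sped_eligibility = SpedEligibility(
                classification=row.classification,
                age_months=_opt_int(row.age_months),
            )
        elif item == "evaluation":
            rec.evaluations.append(
                Evaluation(
                    age_months=_opt_int(row.age_months),
                    conclusion=row.conclusion,
                    by_qualified_professional=str(row.by_qualified_professional).lower()
                    in ("true", "1"),
                    reported_prior_diagnosis_age_months=_opt_int(
                        row.reported_prior_diagnosis_age_months
                    ),
                )
            )
        elif item == "cognitive":
            rec.cognitive.append(
                CognitiveAssessment(
                    age_months=_opt_int(row.age_months),
                    kind=row.kind,
                    iq_score=_opt_int(row.iq_score),
                    stated_band=row.stated_band or None,
                )
            )
        elif item != "none":
            raise DataError(f"unknown record item type {item!r} in {path}")
    return [records[rid] for rid in order]


def _record_to_dict(record: SourceRecord) -> dict:
    return {
        "source_type": record.source_type,
        "accessible": record.accessible,
        "icd_codes": [{"code": c, "age_months": a} for c, a in record.icd_codes],
        "sped_eligibility": (
            None
            if record.sped_eligibility is None
            else {
                "classification": record.sped_eligibility.classification,
                "age_months": record.sped_eligibility.age_months,
            }
        ),
        "evaluations": [
            {
                "age_months": ev.age_months,
                "conclusion": ev.conclusion,
                "by_qualified_professional": ev.by_qualified_professional,
                "reported_prior_diagnosis_age_months": ev.reported_prior_diagnosis_age_months,
            }
            for ev in record.evaluations
        ],
        "cognitive": [
            {
                "age_months": cg.age_months,
                "kind": cg.kind,
                "iq_score": cg.iq_score,
                "stated_band": cg.stated_band,
            }
            for cg in record.cognitive
        ],
    }


def save_records_json(records: Sequence[SourceRecord], path) -> None:
    """Nested JSON: one object per child carrying all their records."""
    children: dict[str, dict] = {}
    for record in records:
        entry = children.setdefault(
            record.child_id, {"child_id": record.child_id, "site": record.site, "records": []}
        )
        entry["records"].append(_record_to_dict(record))
    Path(path).write_text(json.dumps(list(children.values()), indent=1))


def load_records_json(path) -> list:
    data = json.loads(Path(path).read_text())
    records = []
    for child in data:
        for raw in child["records"]:
            records.append(
                SourceRecord(
                    child_id=child["child_id"],
                    site=child["site"],
                    source_type=raw["source_type"],
                    accessible=raw["accessible"],
                    icd_codes=[(c["code"], c["age_months"]) for c in raw["icd_codes"]],
                    sped_eligibility=(
                        None
                        if raw["sped_eligibility"] is None
                        else SpedEligibility(**raw["sped_eligibility"])
                    ),
                    evaluations=[Evaluation(**ev) for ev in raw["evaluations"]],
                    cognitive=[CognitiveAssessment(**cg) for cg in raw["cognitive"]],
                )
            )
    return records


# -- denominators / tracts / statuses ---------------------------------------

def save_denominators(denominators: DenominatorTable, path) -> None:
    denominators.cells.to_csv(path, index=False)


def load_denominators(path) -> DenominatorTable:
    return DenominatorTable(pd.read_csv(path))


def save_tracts(tracts: Sequence[Tract], path) -> None:
    pd.DataFrame(
        [
            {
                "tract_id": t.tract_id,
                "site": t.site,
                "mhi_usd": t.mhi_usd,
                "n_age_5_9": t.n_age_5_9,
                "tertile": t.tertile if t.tertile is not None else "",
            }
            for t in tracts
        ]
    ).to_csv(path, index=False)


def load_tracts(path) -> list:
    df = pd.read_csv(path, keep_default_na=False)
    return [
        Tract(
            tract_id=str(row.tract_id),
            site=row.site,
            mhi_usd=float(row.mhi_usd),
            n_age_5_9=float(row.n_age_5_9),
            tertile=(row.tertile or None) if "tertile" in df.columns else None,
        )
        for row in df.itertuples(index=False)
    ]


def save_statuses(statuses: pd.DataFrame, path) -> None:
    """Per-child case statuses, one row per record-bearing child."""
    statuses.to_csv(path, index=False)


# -- generator configuration ------------------------------------------------

def config_to_dict(config: GeneratorConfig) -> dict:
    def site_dict(site: SiteConfig) -> dict:
        return {
            "site_name": site.site_name,
            "n_children": site.n_children,
            "pct_male": site.pct_male,
            "race_mix": dict(site.race_mix),
            "true_prevalence": site.true_prevalence,
            "male_female_rate_ratio": site.male_female_rate_ratio,
            "has_education_source": site.has_education_source,
            "record_accessible_fraction": site.record_accessible_fraction,
            "tract_count": site.tract_count,
            "tract_mhi_range": list(site.tract_mhi_range),
            "missing_tract_fraction": site.missing_tract_fraction,
            "identification_mixture": dict(site.identification_mixture),
            "p_suspected_before_confirmed": site.p_suspected_before_confirmed,
            "p_ruled_out_ever": site.p_ruled_out_ever,
            "p_ruled_out_more_recent": site.p_ruled_out_more_recent,
            "iq_available_fraction": site.iq_available_fraction,
            "iq_band_probs": dict(site.iq_band_probs),
            "dx_age_months_distribution": {
                band: dist.to_dict()
                for band, dist in site.dx_age_months_distribution.items()
            },
            "first_eval_age_months_distribution": site.first_eval_age_months_distribution.to_dict(),
            "false_trigger_rate": site.false_trigger_rate,
        }

    return {
        "global_seed": config.global_seed,
        "analysis_year": config.analysis_year,
        "birth_year": config.birth_year,
        "sites": [site_dict(s) for s in config.sites],
    }


def config_from_dict(data: dict) -> GeneratorConfig:
    try:
        sites = []
        for raw in data["sites"]:
            raw = dict(raw)
            if "tract_mhi_range" in raw:
                raw["tract_mhi_range"] = tuple(raw["tract_mhi_range"])
            if "dx_age_months_distribution" in raw:
                raw["dx_age_months_distribution"] = {
                    band: AgeDistribution(**d)
                    for band, d in raw["dx_age_months_distribution"].items()
                }
            if "first_eval_age_months_distribution" in raw and isinstance(
                raw["first_eval_age_months_distribution"], dict
            ):
                raw["first_eval_age_months_distribution"] = AgeDistribution(
                    **raw["first_eval_age_months_distribution"]
                )
            sites.append(SiteConfig(**raw))
        config = GeneratorConfig(
            sites=sites,
            global_seed=data.get("global_seed", 0),
            analysis_year=data.get("analysis_year", 2018),
            birth_year=data.get("birth_year", 2010),
        )
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed generator config: {exc}") from exc
    config.validate()
    return config


def load_generator_config(path) -> GeneratorConfig:
    """Load a generator config from YAML or JSON (by extension)."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigurationError(f"config file {path} does not contain a mapping")
    return config_from_dict(data)


def save_generator_config(config: GeneratorConfig, path) -> None:
    data = config_to_dict(config)
    if str(path).endswith(".json"):
        Path(path).write_text(json.dumps(data, indent=1))
    else:
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
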