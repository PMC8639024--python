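"""Case ascertainment: merge multi-source records and apply the case definition.

A child aged 8 in the surveillance year (born in 2010) who lived in the
surveillance area meets the ASD case definition if their combined records
document any of three indicators:

1. a written ASD diagnostic statement from a qualified professional in a
   developmental evaluation (including reports of a previous diagnosis),
2. a special-education classification of autism (primary exceptionality or
   an evaluation concluding autism eligibility was met), or
3. an ASD ICD billing code: ICD-9 in 299.00–299.99, or ICD-10 in the F84
   family except F84.2 (Rett syndrome).

Records may be flagged inaccessible (e.g. a chart that could not be
reviewed); such records contribute only their transmitted ICD and
special-education codes — evaluation content and cognitive tests on them
are never observed. A child whose only indicator is a diagnostic statement
on an inaccessible record is therefore not ascertained.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import ConsistencyError, ValidationError

logger = logging.getLogger(__name__)

#: The seven non-empty combinations of the three identification types.
REGIONS = (
    "dx-only",
    "sped-only",
    "icd-only",
    "dx+sped",
    "dx+icd",
    "sped+icd",
    "all-three",
)

IQ_BANDS = ("<=70", "71-85", ">85")

SPED_AUTISM = ("autism-primary", "autism-eligibility-met")

_ICD9_RE = re.compile(r"299(\.\d{1,2})?$")
_ICD10_RE = re.compile(r"F84(\.\d{1,2})?$")
_ANY_CODE_RE = re.compile(r"[A-Z]?\d{2,3}(\.\d{1,2})?$")


@dataclass
class Evaluation:
    """One developmental evaluation abstracted from a record."""

    age_months: int
    conclusion: str  # asd-diagnosis | asd-suspected | asd-ruled-out | other
    by_qualified_professional: bool = True
    reported_prior_diagnosis_age_months: Optional[int] = None

    def __post_init__(self) -> None:
        prior = self.reported_prior_diagnosis_age_months
        if prior is not None and prior > self.age_months:
            raise ValidationError(
                "reported prior diagnosis age exceeds the evaluation's own age"
            )


@dataclass
class CognitiveAssessment:
    """A cognitive test score or an examiner's statement of cognitive level."""

    age_months: int
    kind: str  # test-score | examiner-statement
    iq_score: Optional[int] = None
    stated_band: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind == "test-score" and self.iq_score is None:
            raise ValidationError("test-score entries must carry an iq_score")
        if self.kind == "examiner-statement" and self.stated_band not in IQ_BANDS:
            raise ValidationError("examiner-statement entries must carry a stated_band")

    def band(self) -> str:
        if self.kind == "test-score":
            return iq_band(self.iq_score)
        return self.stated_band


def iq_band(score: int) -> str:
    """Map an IQ score to the reported bands (<=70, 71-85, >85)."""
    if score <= 70:
        return "<=70"
    if score <= 85:
        return "71-85"
    return ">85"


@dataclass
class SpedEligibility:
    classification: str  # autism-primary | autism-eligibility-met | other
    age_months: Optional[int] = None


@dataclass
class SourceRecord:
    """One provider record for one child from one source."""

    child_id: str
    site: str
    source_type: str  # health | education | service-program
    accessible: bool = True
    icd_codes: list = field(default_factory=list)  # [(code, age_months), ...]
    sped_eligibility: Optional[SpedEligibility] = None
    evaluations: list = field(default_factory=list)
    cognitive: list = field(default_factory=list)


@dataclass
class MergedRecord:
    """Union of a child's records; inaccessible content already filtered.

    ``evaluations`` and ``cognitive`` hold only content from accessible
    records; ``icd_codes`` and ``sped_entries`` include transmitted codes
    from inaccessible records too.
    """

    child_id: str
    site: str
    icd_codes: list
    sped_entries: list
    evaluations: list
    cognitive: list


@dataclass
class CaseStatus:
    """Per-child ascertainment result."""

    child_id: str
    has_dx_statement: bool
    has_sped: bool
    has_icd: bool
    is_case: bool
    region: str  # one of REGIONS or "none"
    earliest_dx_age_months: Optional[int]
    earliest_eval_age_months: Optional[int]
    suspected_ever: bool
    ruled_out_ever: bool
    ruled_out_more_recent: bool
    cognitive_band: Optional[str]


def is_asd_indicator_code(code: str) -> bool:
    """True iff the code is an ASD indicator under the case definition.

    ICD-9: any code in 299.00–299.99 ("299.0" is normalized to "299.00").
    ICD-10: any code in the F84 family except F84.2 and its extensions.
    Unparseable text is logged and treated as not an indicator; this
    function never raises.
    """
    if not code:
        return False
    text = str(code).strip().upper()
    if _ICD10_RE.fullmatch(text):
        return not (text == "F84.2" or text.startswith("F84.2"))
    if _ICD9_RE.fullmatch(text):
        if len(text) < 6 and "." in text:
            logger.info("normalizing short ICD-9 code %r", text)
        return True
    if not _ANY_CODE_RE.fullmatch(text):
        logger.warning("unparseable ICD code %r treated as non-indicator", code)
    return False


def merge_child_records(records: Sequence[SourceRecord]) -> MergedRecord:
    """Combine one child's records across sources.

    Raises :class:`ConsistencyError` on an empty list or mixed child ids.
    """
    if not records:
        raise ConsistencyError("cannot merge an empty record list")
    ids = {r.child_id for r in records}
    if len(ids) > 1:
        raise ConsistencyError(f"records mix child ids: {sorted(ids)}")
    icd, sped, evals, cog = [], [], [], []
    for rec in records:
        icd.extend(rec.icd_codes)
        if rec.sped_eligibility is not None:
            sped.append(rec.sped_eligibility)
        if rec.accessible:
            evals.extend(rec.evaluations)
            cog.extend(rec.cognitive)
    return MergedRecord(
        child_id=records[0].child_id,
        site=records[0].site,
        icd_codes=icd,
        sped_entries=sped,
        evaluations=evals,
        cognitive=cog,
    )


def _region(dx: bool, sped: bool, icd: bool) -> str:
    key = (dx, sped, icd)
    return {
        (True, False, False): "dx-only",
        (False, True, False): "sped-only",
        (False, False, True): "icd-only",
        (True, True, False): "dx+sped",
        (True, False, True): "dx+icd",
        (False, True, True): "sped+icd",
        (True, True, True): "all-three",
        (False, False, False): "none",
    }[key]


def diagnosis_history(
    merged: MergedRecord,
) -> tuple[Optional[int], bool, bool, bool]:
    """(earliest_dx_age, suspected_ever, ruled_out_ever, ruled_out_more_recent).

    The earliest diagnosis age is the minimum over direct diagnostic
    statements and reported prior-diagnosis ages. A more-recent rule-out
    requires the latest rule-out age to strictly exceed the latest age of
    any ASD diagnosis or special-education eligibility (equal months do
    not count: month resolution cannot order same-month events).
    """
    dx_ages: list[int] = []
    confirm_ages: list[int] = []
    suspected = False
    ruled_out_ages: list[int] = []
    for ev in merged.evaluations:
        if ev.conclusion == "asd-diagnosis" and ev.by_qualified_professional:
            dx_ages.append(ev.age_months)
            confirm_ages.append(ev.age_months)
        if ev.reported_prior_diagnosis_age_months is not None:
            dx_ages.append(ev.reported_prior_diagnosis_age_months)
            confirm_ages.append(ev.reported_prior_diagnosis_age_months)
        if ev.conclusion == "asd-suspected":
            suspected = True
        if ev.conclusion == "asd-ruled-out":
            ruled_out_ages.append(ev.age_months)
    for entry in merged.sped_entries:
        if entry.classification in SPED_AUTISM and entry.age_months is not None:
            confirm_ages.append(entry.age_months)
    earliest = min(dx_ages) if dx_ages else None
    ruled_out_ever = bool(ruled_out_ages)
    more_recent = False
    if ruled_out_ages:
        latest_confirm = max(confirm_ages) if confirm_ages else None
        more_recent = latest_confirm is None or max(ruled_out_ages) > latest_confirm
    return earliest, suspected, ruled_out_ever, more_recent


def earliest_evaluation_age(merged: MergedRecord) -> Optional[int]:
    """Age in months at the first known evaluation, or None if none exist.

    Includes historically reported prior-diagnosis ages, which document an
    earlier evaluation even when that evaluation itself was not collected.
    """
    ages = [ev.age_months for ev in merged.evaluations]
    ages += [
        ev.reported_prior_diagnosis_age_months
        for ev in merged.evaluations
        if ev.reported_prior_diagnosis_age_months is not None
    ]
    return min(ages) if ages else None


def classify_cognitive(merged: MergedRecord) -> Optional[str]:
    """Cognitive band from the most recent cognitive entry, or None.

    Ties at the same age are broken in favour of test scores over examiner
    statements, then by the higher score.
    """
    if not merged.cognitive:
        return None

    def sort_key(entry: CognitiveAssessment):
        kind_rank = 1 if entry.kind == "test-score" else 0
        score = entry.iq_score if entry.iq_score is not None else -1
        return (entry.age_months, kind_rank, score)

    return max(merged.cognitive, key=sort_key).band()


def classify_case(
    merged: MergedRecord,
    resident_in_year: bool = True,
    birth_year: int = 2010,
    surveillance_birth_year: int = 2010,
) -> CaseStatus:
    """Apply the three-indicator case definition to a merged record.

    Residency in the surveillance year and birth in the surveillance
    cohort year are hard preconditions: a child failing either is not a
    case regardless of indicators.
    """
    has_icd = any(is_asd_indicator_code(code) for code, _age in merged.icd_codes)
    has_sped = any(e.classification in SPED_AUTISM for e in merged.sped_entries)
    has_dx = any(
        (ev.conclusion == "asd-diagnosis" and ev.by_qualified_professional)
        or ev.reported_prior_diagnosis_age_months is not None
        for ev in merged.evaluations
    )
    eligible = resident_in_year and birth_year == surveillance_birth_year
    is_case = eligible and (has_icd or has_sped or has_dx)
    earliest_dx, suspected, ruled_out, more_recent = diagnosis_history(merged)
    if not has_dx:
        earliest_dx = None
    return CaseStatus(
        child_id=merged.child_id,
        has_dx_statement=has_dx,
        has_sped=has_sped,
        has_icd=has_icd,
        is_case=is_case,
        region=_region(has_dx, has_sped, has_icd) if is_case else "none",
        earliest_dx_age_months=earliest_dx,
        earliest_eval_age_months=earliest_evaluation_age(merged),
        suspected_ever=suspected,
        ruled_out_ever=ruled_out,
        ruled_out_more_recent=more_recent,
        cognitive_band=classify_cognitive(merged),
    )


@dataclass
class RegionSummary:
    """Counts over the seven identification regions plus headline shares.

    Shares are percentages of all cases: any diagnostic statement;
    special-education eligibility without a diagnostic statement; ICD code
    only; and at least two identification types. The first three partition
    the cases and sum to 100%.
    """

    counts: dict
    n_cases: int
    pct_any_dx: float
    pct_sped_no_dx: float
    pct_icd_only: float
    pct_two_or_more: float


def identification_regions(statuses: Iterable[CaseStatus]) -> RegionSummary:
    """Tabulate cases over the seven identification regions."""
    counts = {region: 0 for region in REGIONS}
    n = 0
    for status in statuses:
        if not status.is_case:
            raise ValidationError(f"child {status.child_id} is not a case")
        counts[status.region] += 1
        n += 1
    if n == 0:
        return RegionSummary(counts, 0, 0.0, 0.0, 0.0, 0.0)
    any_dx = sum(counts[r] for r in ("dx-only", "dx+sped", "dx+icd", "all-three"))
    sped_no_dx = counts["sped-only"] + counts["sped+icd"]
    icd_only = counts["icd-only"]
    multi = sum(counts[r] for r in ("dx+sped", "dx+icd", "sped+icd", "all-three"))
    return RegionSummary(
        counts=counts,
        n_cases=n,
        pct_any_dx=100.0 * any_dx / n,
        pct_sped_no_dx=100.0 * sped_no_dx / n,
        pct_icd_only=100.0 * icd_only / n,
        pct_two_or_more=100.0 * multi / n,
    )


def ascertain_population(
    children: pd.DataFrame,
    records: Sequence[SourceRecord],
    birth_year_column: str | None = None,
) -> pd.DataFrame:
    """Classify every record-bearing child; return one row per such child.

    ``children`` must carry child_id, site, sex, race_ethnicity,
    resident_in_year and census_tract columns. Children with no records
    are non-cases by construction and are omitted from the output (their
    contribution to the analysis is through the denominators).
    """
    by_child: dict[str, list[SourceRecord]] = {}
    for rec in records:
        by_child.setdefault(rec.child_id, []).append(rec)
    known = set(children["child_id"])
    unknown = set(by_child) - known
    if unknown:
        raise ConsistencyError(
            f"records reference children absent from the population: {sorted(unknown)[:5]}"
        )
    meta = children.set_index("child_id")
    rows = []
    for child_id in sorted(by_child):
        merged = merge_child_records(by_child[child_id])
        info = meta.loc[child_id]
        status = classify_case(
            merged,
            resident_in_year=bool(info["resident_in_year"]),
            birth_year=int(info.get("birth_year", 2010)) if birth_year_column is None else int(info[birth_year_column]),
        )
        rows.append(
            {
                "child_id": child_id,
                "site": info["site"],
                "sex": info["sex"],
                "race_ethnicity": info["race_ethnicity"],
                "census_tract": info["census_tract"],
                "has_dx_statement": status.has_dx_statement,
                "has_sped": status.has_sped,
                "has_icd": status.has_icd,
                "is_case": status.is_case,
                "region": status.region,
                "earliest_dx_age_months": status.earliest_dx_age_months,
                "earliest_eval_age_months": status.earliest_eval_age_months,
                "suspected_ever": status.suspected_ever,
                "ruled_out_ever": status.ruled_out_ever,
                "ruled_out_more_recent": status.ruled_out_more_recent,
                "cognitive_band": status.cognitive_band,
            }
        )
    columns = [
        "child_id",
        "site",
        "sex",
        "race_ethnicity",
        "census_tract",
        "has_dx_statement",
        "has_sped",
        "has_icd",
        "is_case",
        "region",
        "earliest_dx_age_months",
        "earliest_eval_age_months",
        "suspected_ever",
        "ruled_out_ever",
        "ruled_out_more_recent",
        "cognitive_band",
    ]
    flags = [
        "has_dx_statement",
        "has_sped",
        "has_icd",
        "is_case",
        "suspected_ever",
        "ruled_out_ever",
        "ruled_out_more_recent",
    ]
    return pd.DataFrame(rows, columns=columns).astype({f: bool for f in flags})
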