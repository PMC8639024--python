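"""Population denominators and census-tract socioeconomic-status machinery.

Denominators by site × sex × race/ethnicity play the role of bridged-race
postcensal population estimates. Census tracts carry a median household
income (MHI) and an estimated count of 8-year-olds obtained by dividing
the tract's count of children aged 5–9 by five; tracts from all sites
combined are split into three approximately equal-population MHI tertiles
which stratify the SES prevalence analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .errors import DataError, ValidationError

RACE_CATEGORIES = (
    "white-nh",
    "black-nh",
    "hispanic",
    "api-nh",
    "aian-nh",
    "other-multiracial",
)

#: Categories used in race-specific prevalence estimates; children coded as
#: other/multiracial are excluded from race-specific numerators and
#: denominators alike.
RACE_SPECIFIC = RACE_CATEGORIES[:-1]

TERTILES = ("low", "medium", "high")


def estimate_tract_denominator(n_age_5_9: float) -> float:
    """Estimated 8-year-old population of a tract: children aged 5–9 over 5."""
    if n_age_5_9 < 0:
        raise ValidationError(f"n_age_5_9 must be nonnegative, got {n_age_5_9}")
    return n_age_5_9 / 5.0


@dataclass
class Tract:
    """One census tract with income and estimated child population."""

    tract_id: str
    site: str
    mhi_usd: float
    n_age_5_9: float
    tertile: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mhi_usd < 0:
            raise ValidationError(f"tract {self.tract_id}: negative MHI")
        self.est_age_8 = estimate_tract_denominator(self.n_age_5_9)


def assign_tertiles(tracts: Sequence[Tract]) -> Sequence[Tract]:
    """Assign low/medium/high MHI tertiles over all sites combined.

    Tracts are ordered by MHI (ties by tract_id) and the cumulative
    estimated 8-year-old population is tracked. A tract is ``low`` when
    its cumulative interval ends at or below T/3, ``high`` when it starts
    at or above 2T/3, and ``medium`` otherwise, with T the total estimated
    population. Whole tracts are never split, so each tertile's population
    is within one tract of T/3. Assignment is independent of input order.
    """
    if len(tracts) < 3:
        raise ValidationError("need at least 3 tracts to form tertiles")
    total = sum(t.est_age_8 for t in tracts)
    if total <= 0:
        raise ValidationError("total estimated child population must be positive")
    ordered = sorted(tracts, key=lambda t: (t.mhi_usd, t.tract_id))
    eps = 1e-9 * total
    cum = 0.0
    for tract in ordered:
        lower = cum
        cum += tract.est_age_8
        if cum <= total / 3.0 + eps:
            tract.tertile = "low"
        elif lower >= 2.0 * total / 3.0 - eps:
            tract.tertile = "high"
        else:
            tract.tertile = "medium"
    return tracts


def child_ses_group(child, tracts: Iterable[Tract] | dict) -> Optional[str]:
    """SES tertile for one child, or None when the child has no tract.

    ``child`` is anything with a ``census_tract`` attribute or key (a
    Child row, a namedtuple, a dict). Children without a geocodable tract
    are excluded from SES-stratified analyses but retained in overall
    prevalence. A tract id that is not in the table is a data error.
    """
    tract_id = child["census_tract"] if isinstance(child, (dict, pd.Series)) else child.census_tract
    if tract_id is None or (isinstance(tract_id, float) and pd.isna(tract_id)) or tract_id == "":
        return None
    index = tracts if isinstance(tracts, dict) else {t.tract_id: t for t in tracts}
    if tract_id not in index:
        raise DataError(f"unknown census tract id {tract_id!r}")
    tertile = index[tract_id].tertile
    if tertile is None:
        raise ValidationError(f"tract {tract_id!r} has no tertile; run assign_tertiles first")
    return tertile


@dataclass
class DenominatorTable:
    """Population counts by site × sex × race/ethnicity.

    ``cells`` is a tidy frame with columns site, sex, race_ethnicity,
    count. Site totals include every race category; race-specific
    denominators exclude other/multiracial children.
    """

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"site", "sex", "race_ethnicity", "count"}
        missing = required - set(self.cells.columns)
        if missing:
            raise ValidationError(f"denominator table missing columns {sorted(missing)}")
        if (self.cells["count"] < 0).any():
            raise ValidationError("denominator counts must be nonnegative")

    @classmethod
    def from_children(cls, children: pd.DataFrame) -> "DenominatorTable":
        cells = (
            children.groupby(["site", "sex", "race_ethnicity"], observed=True)
            .size()
            .rename("count")
            .reset_index()
            .sort_values(["site", "sex", "race_ethnicity"], kind="mergesort")
            .reset_index(drop=True)
        )
        return cls(cells)

    def site_total(self, site: str) -> int:
        sub = self.cells[self.cells["site"] == site]
        if sub.empty:
            raise DataError(f"no denominator cells for site {site!r}")
        return int(sub["count"].sum())

    @property
    def network_total(self) -> int:
        return int(self.cells["count"].sum())

    @property
    def sites(self) -> list[str]:
        return sorted(self.cells["site"].unique())

    def sex_total(self, sex: str, site: str | None = None) -> int:
        sub = self.cells[self.cells["sex"] == sex]
        if site is not None:
            sub = sub[sub["site"] == site]
        return int(sub["count"].sum())

    def race_total(self, race: str, site: str | None = None) -> int:
        """Denominator for a race-specific estimate.

        Other/multiracial is not a valid race-specific stratum.
        """
        if race not in RACE_SPECIFIC:
            raise DataError(f"{race!r} is not a race-specific denominator category")
        sub = self.cells[self.cells["race_ethnicity"] == race]
        if site is not None:
            sub = sub[sub["site"] == site]
        return int(sub["count"].sum())
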