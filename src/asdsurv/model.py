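"""Model-style front end: ``ASDSurveillance(...).fit() -> SurveillanceResults``.

The model object holds the study inputs — the child population, their
multi-source records, the population denominators, and the census
tracts — and ``fit`` runs ascertainment and estimation, returning a
results object that carries the per-child case statuses, the headline
estimates with their uncertainties, every report table, and a
``summary()`` text view.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ascertain import ascertain_population
from .config import GeneratorConfig
from .errors import ValidationError
from .report import ReportBundle, build_bundle, DASH
from .ses import DenominatorTable, Tract
from .stats import (
    AnalysisConfig,
    DEFAULT_CONFIG,
    PrevalenceEstimate,
    RatioEstimate,
    one_in_n,
    round_half_away,
)


class ASDSurveillance:
    """Records-based ASD surveillance of one 8-year-old birth cohort.

    Parameters
    ----------
    children : DataFrame
        One row per child (child_id, site, sex, race_ethnicity,
        resident_in_year, census_tract).
    records : sequence of SourceRecord
        Provider records; children without records are non-cases.
    denominators : DenominatorTable
        Population counts by site × sex × race/ethnicity.
    tracts : sequence of Tract
        Census tracts with MHI and estimated child counts.
    """

    def __init__(
        self,
        children: pd.DataFrame,
        records: Sequence,
        denominators: DenominatorTable,
        tracts: Sequence[Tract],
        birth_year: int = 2010,
    ) -> None:
        self.children = children
        self.records = list(records)
        self.denominators = denominators
        self.tracts = list(tracts)
        self.birth_year = birth_year

    @classmethod
    def from_config(
        cls, config: GeneratorConfig, seed: Optional[int] = None
    ) -> "ASDSurveillance":
        """Build the model from a generator configuration (synthetic study)."""
        from .synthesize import generate_population, generate_records

        children, denominators, tracts = generate_population(config, seed)
        records = generate_records(children, config, seed)
        return cls(children, records, denominators, tracts, birth_year=config.birth_year)

    def fit(self, cfg: AnalysisConfig = DEFAULT_CONFIG) -> "SurveillanceResults":
        """Ascertain cases and compute every surveillance estimate."""
        statuses = ascertain_population(self.children, self.records)
        bundle = build_bundle(statuses, self.denominators, self.tracts, cfg)
        return SurveillanceResults(self, statuses, bundle, cfg)


class SurveillanceResults:
    """Fitted surveillance estimates with uncertainties and report tables."""

    def __init__(
        self,
        model: ASDSurveillance,
        statuses: pd.DataFrame,
        bundle: ReportBundle,
        cfg: AnalysisConfig,
    ) -> None:
        self.model = model
        self.statuses = statuses
        self.bundle = bundle
        self.cfg = cfg

    # -- headline quantities -------------------------------------------------

    @property
    def cases(self) -> pd.DataFrame:
        return self.statuses[self.statuses["is_case"]]

    @property
    def n_cases(self) -> int:
        return int(self.statuses["is_case"].sum())

    def _total_row(self, table: pd.DataFrame) -> pd.Series:
        return table[table["site"] == "total"].iloc[0]

    @property
    def overall_prevalence(self) -> PrevalenceEstimate:
        from .stats import prevalence

        return prevalence(self.n_cases, self.model.denominators.network_total, self.cfg)

    @property
    def male_female_ratio(self) -> Optional[RatioEstimate]:
        row = self._total_row(self.bundle.table2)
        if not np.isfinite(row["mf_ratio"]):
            return None
        return RatioEstimate(
            ratio=row["mf_ratio"],
            ci_low=row["mf_ratio_ci_low"],
            ci_high=row["mf_ratio_ci_high"],
            suppressed=bool(row["mf_ratio_suppressed"]),
        )

    def summary(self) -> str:
        """Plain-text summary of the headline surveillance estimates."""
        est = self.overall_prevalence
        lines = [
            "ASD surveillance summary (children aged 8 years)",
            "=" * 50,
            f"Sites: {len(self.model.denominators.sites)}"
            f"    Population: {self.model.denominators.network_total:,}",
            f"Children meeting the case definition: {self.n_cases:,}",
        ]
        if est.numerator > 0:
            lines.append(
                f"Overall prevalence per 1,000: "
                f"{round_half_away(est.per_1000):.1f} "
                f"(95% CI {round_half_away(est.ci_low_per_1000):.1f}–"
                f"{round_half_away(est.ci_high_per_1000):.1f})"
                + ("  [suppressed]" if est.suppressed else "")
            )
            lines.append(
                f"  i.e. one in {one_in_n(est.numerator, est.denominator)} children"
            )
        ratio = self.male_female_ratio
        if ratio is not None and not ratio.suppressed:
            lines.append(
                f"Male-to-female prevalence ratio: {round_half_away(ratio.ratio):.1f} "
                f"(95% CI {round_half_away(ratio.ci_low):.1f}–{round_half_away(ratio.ci_high):.1f})"
            )
        if self.n_cases:
            from .ascertain import identification_regions  # noqa: F401  (shares below)

            fig2 = self.bundle.fig2
            any_dx = fig2[fig2["region"].isin(["dx-only", "dx+sped", "dx+icd", "all-three"])]["n"].sum()
            sped_no_dx = fig2[fig2["region"].isin(["sped-only", "sped+icd"])]["n"].sum()
            icd_only = fig2[fig2["region"] == "icd-only"]["n"].sum()
            n = self.n_cases
            lines.append(
                "Identification: "
                f"{100 * any_dx / n:.1f}% diagnostic statement, "
                f"{100 * sped_no_dx / n:.1f}% special-education only, "
                f"{100 * icd_only / n:.1f}% ICD code only"
            )
        return "\n".join(lines)

    def to_csv(self, outdir, manifest: Optional[dict] = None) -> None:
        """Write every rendered report table to ``outdir`` as CSV."""
        self.bundle.write(outdir, manifest=manifest)

    # -- plotting ------------------------------------------------------------

    def plot_site_prevalence(self, ax=None):
        """Dot-and-interval plot of per-site prevalence (matplotlib)."""
        import matplotlib.pyplot as plt

        table = self.bundle.table2
        sites = table[table["site"] != "total"]
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.4 * max(len(sites), 4) + 1))
        y = np.arange(len(sites))
        prev = sites["prevalence"].to_numpy()
        ax.errorbar(
            prev,
            y,
            xerr=[
                prev - sites["ci_low"].to_numpy(),
                sites["ci_high"].to_numpy() - prev,
            ],
            fmt="o",
            capsize=3,
        )
        ax.set_yticks(y)
        ax.set_yticklabels(sites["site"])
        ax.set_xlabel("ASD prevalence per 1,000 children aged 8")
        total = self._total_row(table)
        ax.axvline(total["prevalence"], linestyle="--", linewidth=1)
        return ax

    def plot_ses_trend(self, ax=None):
        """Prevalence by MHI tertile per site (matplotlib)."""
        import matplotlib.pyplot as plt

        fig1 = self.bundle.fig1
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        x = np.arange(len(fig1))
        width = 0.25
        for k, tertile in enumerate(("low", "medium", "high")):
            ax.bar(x + (k - 1) * width, fig1[f"{tertile}_prevalence"], width, label=tertile)
        ax.set_xticks(x)
        ax.set_xticklabels(fig1["site"], rotation=45, ha="right")
        ax.set_ylabel("prevalence per 1,000")
        ax.legend(title="MHI tertile")
        return ax
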