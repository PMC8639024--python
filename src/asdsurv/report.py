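"""Build the surveillance report tables and figure datasets.

Each builder consumes the per-child ascertainment statuses together with
denominators/tracts and returns a tidy numeric DataFrame; ``render_*``
helpers turn these into publication-style string tables where prevalence
is printed per 1,000 to one decimal with its 95% CI and suppressed cells
(relative standard error > 30%) appear as an em dash. The numeric and
rendered forms are both kept on the :class:`ReportBundle`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .ascertain import identification_regions, CaseStatus, REGIONS
from .errors import DataError, ValidationError
from .ses import DenominatorTable, RACE_SPECIFIC, TERTILES, Tract, assign_tertiles
from .stats import (
    AnalysisConfig,
    DEFAULT_CONFIG,
    PrevalenceEstimate,
    cochran_armitage_trend,
    prevalence,
    prevalence_ratio,
    round_half_away,
)

logger = logging.getLogger(__name__)

DASH = "—"  # em dash rendered for suppressed cells

_RACE_LABELS = {
    "white-nh": "White, non-Hispanic",
    "black-nh": "Black, non-Hispanic",
    "hispanic": "Hispanic",
    "api-nh": "Asian/Pacific Islander",
}

_RATIO_PAIRS = [
    ("white-nh", "black-nh"),
    ("white-nh", "hispanic"),
    ("black-nh", "hispanic"),
    ("white-nh", "api-nh"),
    ("black-nh", "api-nh"),
    ("hispanic", "api-nh"),
]


def _fill_prev(row: dict, prefix: str, est: Optional[PrevalenceEstimate]) -> None:
    if est is None:
        row.update(
            {
                f"{prefix}prevalence": np.nan,
                f"{prefix}ci_low": np.nan,
                f"{prefix}ci_high": np.nan,
                f"{prefix}suppressed": True,
            }
        )
        return
    row.update(
        {
            f"{prefix}prevalence": est.per_1000,
            f"{prefix}ci_low": est.ci_low_per_1000,
            f"{prefix}ci_high": est.ci_high_per_1000,
            f"{prefix}suppressed": est.suppressed,
        }
    )


def _ratio_fields(row: dict, prefix: str, a, b, cfg) -> None:
    if b is None or a is None or b.numerator == 0:
        row.update(
            {
                f"{prefix}ratio": np.nan,
                f"{prefix}ratio_ci_low": np.nan,
                f"{prefix}ratio_ci_high": np.nan,
                f"{prefix}ratio_suppressed": True,
            }
        )
        return
    ratio = prevalence_ratio(a, b, cfg)
    row.update(
        {
            f"{prefix}ratio": ratio.ratio,
            f"{prefix}ratio_ci_low": ratio.ci_low,
            f"{prefix}ratio_ci_high": ratio.ci_high,
            f"{prefix}ratio_suppressed": ratio.suppressed,
        }
    )


def _cases(statuses: pd.DataFrame) -> pd.DataFrame:
    return statuses[statuses["is_case"]]


def _site_groups(denominators: DenominatorTable) -> list:
    """Per-site groups followed by the all-site total row."""
    return denominators.sites + ["total"]


def build_table2(
    statuses: pd.DataFrame,
    denominators: DenominatorTable,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Overall and sex-specific prevalence with the M:F prevalence ratio."""
    cases = _cases(statuses)
    rows = []
    for site in _site_groups(denominators):
        sub = cases if site == "total" else cases[cases["site"] == site]
        pop = denominators.network_total if site == "total" else denominators.site_total(site)
        if pop <= 0:
            raise DataError(f"no population denominator for site {site!r}")
        site_arg = None if site == "total" else site
        male_pop = denominators.sex_total("male", site_arg)
        female_pop = denominators.sex_total("female", site_arg)
        n_male = int((sub["sex"] == "male").sum())
        n_female = int((sub["sex"] == "female").sum())
        row = {"site": site, "n_asd": len(sub), "population": pop}
        _fill_prev(row, "", prevalence(len(sub), pop, cfg))
        male = prevalence(n_male, male_pop, cfg) if male_pop > 0 else None
        female = prevalence(n_female, female_pop, cfg) if female_pop > 0 else None
        row.update({"male_n": n_male, "male_population": male_pop})
        _fill_prev(row, "male_", male)
        row.update({"female_n": n_female, "female_population": female_pop})
        _fill_prev(row, "female_", female)
        _ratio_fields(row, "mf_", male, female, cfg)
        rows.append(row)
    return pd.DataFrame(rows)


def build_table3(
    statuses: pd.DataFrame,
    denominators: DenominatorTable,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Race/ethnicity-specific prevalence and pairwise prevalence ratios.

    Children coded other/multiracial are excluded from all race-specific
    numerators and denominators.
    """
    cases = _cases(statuses)
    rows = []
    for site in _site_groups(denominators):
        sub = cases if site == "total" else cases[cases["site"] == site]
        site_arg = None if site == "total" else site
        row = {"site": site}
        estimates = {}
        for race in RACE_SPECIFIC[:4]:  # white, black, hispanic, api
            pop = denominators.race_total(race, site_arg)
            n = int((sub["race_ethnicity"] == race).sum())
            est = prevalence(n, pop, cfg) if pop > 0 else None
            estimates[race] = est
            row[f"{race}_n"] = n
            row[f"{race}_population"] = pop
            _fill_prev(row, f"{race}_", est)
        for a, b in _RATIO_PAIRS:
            _ratio_fields(row, f"{a}_vs_{b}_", estimates[a], estimates[b], cfg)
        rows.append(row)
    return pd.DataFrame(rows)


def build_table4(statuses: pd.DataFrame) -> pd.DataFrame:
    """Identification-type shares and suspected/ruled-out history shares."""
    cases = _cases(statuses)
    rows = []
    sites = sorted(cases["site"].unique()) if len(cases) else []
    for site in sites + ["total"]:
        sub = cases if site == "total" else cases[cases["site"] == site]
        n = len(sub)
        row = {"site": site, "n_asd": n}
        for column, label in [
            ("has_icd", "pct_icd"),
            ("has_sped", "pct_sped"),
            ("has_dx_statement", "pct_dx"),
            ("suspected_ever", "pct_suspected"),
            ("ruled_out_ever", "pct_ruled_out_ever"),
            ("ruled_out_more_recent", "pct_ruled_out_more_recent"),
        ]:
            row[label] = 100.0 * sub[column].sum() / n if n else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_table5(statuses: pd.DataFrame) -> pd.DataFrame:
    """Availability and distribution of cognitive (IQ) data among cases."""
    cases = _cases(statuses)

    def block(label_kind: str, label: str, sub: pd.DataFrame) -> dict:
        n = len(sub)
        with_iq = sub[sub["cognitive_band"].notna()]
        k = len(with_iq)
        row = {
            "group_kind": label_kind,
            "group": label,
            "n_asd": n,
            "n_iq": k,
            "pct_iq": 100.0 * k / n if n else np.nan,
        }
        for band, label2 in [("<=70", "pct_le70"), ("71-85", "pct_71_85"), (">85", "pct_gt85")]:
            row[label2] = 100.0 * (with_iq["cognitive_band"] == band).sum() / k if k else np.nan
        return row

    rows = []
    for site in sorted(cases["site"].unique()):
        rows.append(block("site", site, cases[cases["site"] == site]))
    rows.append(block("site", "total", cases))
    for sex in ("female", "male"):
        rows.append(block("sex", sex, cases[cases["sex"] == sex]))
    for race in RACE_SPECIFIC[:3]:  # white, black, hispanic
        rows.append(block("race", race, cases[cases["race_ethnicity"] == race]))
    return pd.DataFrame(rows)


def _median_or_nan(values: pd.Series) -> float:
    vals = values.dropna()
    return float(np.median(vals)) if len(vals) else np.nan


def build_table6(statuses: pd.DataFrame) -> pd.DataFrame:
    """First-evaluation timing (share evaluated by 36 months, median age).

    Limited to children with a recorded earliest evaluation; the by-36-months
    boundary is inclusive. Cognitive-band splits compare IQ <=70 with IQ >70
    among children who also have cognitive data.
    """
    cases = _cases(statuses)
    rows = []
    sites = sorted(cases["site"].unique()) if len(cases) else []
    for site in sites + ["total"]:
        sub = cases if site == "total" else cases[cases["site"] == site]
        with_eval = sub[sub["earliest_eval_age_months"].notna()]
        row = {"site": site, "n_asd": len(sub), "n_eval": len(with_eval)}
        ages = with_eval["earliest_eval_age_months"]
        row["pct_by_36"] = 100.0 * (ages <= 36).sum() / len(ages) if len(ages) else np.nan
        row["median_eval_age"] = _median_or_nan(ages)
        for key, mask in [
            ("le70", with_eval["cognitive_band"] == "<=70"),
            ("gt70", with_eval["cognitive_band"].isin(["71-85", ">85"])),
        ]:
            band = with_eval[mask]
            ages_b = band["earliest_eval_age_months"]
            row[f"n_eval_{key}"] = len(band)
            row[f"pct_by_36_{key}"] = (
                100.0 * (ages_b <= 36).sum() / len(ages_b) if len(ages_b) else np.nan
            )
            row[f"median_eval_age_{key}"] = _median_or_nan(ages_b)
        rows.append(row)
    return pd.DataFrame(rows)


def build_table7(
    statuses: pd.DataFrame,
    denominators: DenominatorTable,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Documented-diagnosis counts, diagnosed-ASD prevalence, median dx age."""
    cases = _cases(statuses)
    rows = []
    for site in _site_groups(denominators):
        sub = cases if site == "total" else cases[cases["site"] == site]
        pop = denominators.network_total if site == "total" else denominators.site_total(site)
        dx = sub[sub["has_dx_statement"]]
        row = {"site": site, "n_asd": len(sub), "n_dx": len(dx), "population": pop}
        _fill_prev(row, "dx_", prevalence(len(dx), pop, cfg) if pop > 0 else None)
        row["median_dx_age"] = _median_or_nan(dx["earliest_dx_age_months"])
        for key, mask in [
            ("le70", dx["cognitive_band"] == "<=70"),
            ("gt70", dx["cognitive_band"].isin(["71-85", ">85"])),
        ]:
            band = dx[mask]
            row[f"n_dx_{key}"] = len(band)
            row[f"median_dx_age_{key}"] = _median_or_nan(band["earliest_dx_age_months"])
        rows.append(row)
    return pd.DataFrame(rows)


def build_fig1(
    statuses: pd.DataFrame,
    tracts: Sequence[Tract],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Prevalence by MHI tertile per site with the Cochran-Armitage trend p.

    Tertiles are assigned over all sites combined; denominators are tract
    sums of the estimated 8-year-old population, so children without a
    geocodable tract are excluded here (they still count in overall
    prevalence). Sites with fewer than 3 tracts are skipped.
    """
    if any(t.tertile is None for t in tracts):
        assign_tertiles(list(tracts))
    tract_tertile = {t.tract_id: t.tertile for t in tracts}
    cases = _cases(statuses)
    geocoded = cases[cases["census_tract"].astype(str) != ""]
    unknown = set(geocoded["census_tract"]) - set(tract_tertile)
    if unknown:
        raise DataError(f"cases reference unknown tracts: {sorted(unknown)[:5]}")
    case_tertile = geocoded["census_tract"].map(tract_tertile)

    sites = sorted({t.site for t in tracts})
    rows = []
    for site in sites + ["total"]:
        site_tracts = tracts if site == "total" else [t for t in tracts if t.site == site]
        if len(site_tracts) < 3:
            logger.warning("site %s has fewer than 3 tracts; skipping SES analysis", site)
            continue
        sub = case_tertile if site == "total" else case_tertile[geocoded["site"] == site]
        row = {"site": site}
        nums, dens = [], []
        for tertile in TERTILES:
            den = sum(t.est_age_8 for t in site_tracts if t.tertile == tertile)
            num = int((sub == tertile).sum())
            nums.append(num)
            dens.append(den)
            _fill_prev(row, f"{tertile}_", prevalence(num, den, cfg) if den > 0 else None)
            row[f"{tertile}_n"] = num
            row[f"{tertile}_population"] = den
        if all(d > 0 for d in dens):
            z, p = cochran_armitage_trend(nums, dens)
            row["trend_z"] = z
            row["trend_p"] = p
        else:
            row["trend_z"] = np.nan
            row["trend_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def build_fig2(statuses: pd.DataFrame) -> pd.DataFrame:
    """Counts and shares of the seven identification-type regions."""
    cases = _cases(statuses)
    status_objs = [
        CaseStatus(
            child_id=r.child_id,
            has_dx_statement=r.has_dx_statement,
            has_sped=r.has_sped,
            has_icd=r.has_icd,
            is_case=True,
            region=r.region,
            earliest_dx_age_months=None,
            earliest_eval_age_months=None,
            suspected_ever=False,
            ruled_out_ever=False,
            ruled_out_more_recent=False,
            cognitive_band=None,
        )
        for r in cases.itertuples()
    ]
    summary = identification_regions(status_objs)
    n = max(summary.n_cases, 1)
    return pd.DataFrame(
        [
            {"region": region, "n": summary.counts[region], "pct": 100.0 * summary.counts[region] / n}
            for region in REGIONS
        ]
    )


def build_fig3(
    statuses: pd.DataFrame,
    denominators: DenominatorTable,
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Prevalence per 1,000 based on each identification type separately."""
    cases = _cases(statuses)
    rows = []
    for site in _site_groups(denominators):
        sub = cases if site == "total" else cases[cases["site"] == site]
        pop = denominators.network_total if site == "total" else denominators.site_total(site)
        row = {"site": site, "population": pop}
        for column, label in [
            ("has_dx_statement", "dx"),
            ("has_sped", "sped"),
            ("has_icd", "icd"),
        ]:
            n = int(sub[column].sum())
            row[f"{label}_n"] = n
            _fill_prev(row, f"{label}_", prevalence(n, pop, cfg) if pop > 0 else None)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# rendering


def _fmt(value: float, ndigits: int = 1) -> str:
    if value is None or (isinstance(value, float) and not np.isfinite(value)):
        return DASH
    return f"{round_half_away(float(value), ndigits):.{ndigits}f}"


def _fmt_est(row: pd.Series, prefix: str) -> str:
    if bool(row.get(f"{prefix}suppressed", False)) or not np.isfinite(
        row.get(f"{prefix}prevalence", np.nan)
    ):
        return DASH
    return (
        f"{_fmt(row[f'{prefix}prevalence'])} "
        f"({_fmt(row[f'{prefix}ci_low'])}–{_fmt(row[f'{prefix}ci_high'])})"
    )


def _fmt_ratio(row: pd.Series, prefix: str) -> str:
    if bool(row.get(f"{prefix}ratio_suppressed", False)) or not np.isfinite(
        row.get(f"{prefix}ratio", np.nan)
    ):
        return DASH
    return (
        f"{_fmt(row[f'{prefix}ratio'])} "
        f"({_fmt(row[f'{prefix}ratio_ci_low'])}–{_fmt(row[f'{prefix}ratio_ci_high'])})"
    )


def render_table2(table2: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["site"] = table2["site"]
    out["n_asd"] = table2["n_asd"].map(str)
    out["population"] = table2["population"].map(str)
    out["prevalence_95ci"] = table2.apply(_fmt_est, axis=1, prefix="")
    out["male_prevalence_95ci"] = table2.apply(_fmt_est, axis=1, prefix="male_")
    out["female_prevalence_95ci"] = table2.apply(_fmt_est, axis=1, prefix="female_")
    out["male_female_ratio_95ci"] = table2.apply(_fmt_ratio, axis=1, prefix="mf_")
    return out


def render_table3(table3: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["site"] = table3["site"]
    for race in RACE_SPECIFIC[:4]:
        out[f"{race}_prevalence_95ci"] = table3.apply(_fmt_est, axis=1, prefix=f"{race}_")
    for a, b in _RATIO_PAIRS:
        out[f"{a}_vs_{b}"] = table3.apply(_fmt_ratio, axis=1, prefix=f"{a}_vs_{b}_")
    return out


def _render_pct_frame(df: pd.DataFrame, int_cols: Sequence[str]) -> pd.DataFrame:
    out = pd.DataFrame()
    for col in df.columns:
        if col in int_cols:
            out[col] = df[col].map(lambda v: DASH if pd.isna(v) else str(int(v)))
        elif df[col].dtype.kind in "fc":
            out[col] = df[col].map(_fmt)
        else:
            out[col] = df[col].map(str)
    return out


def render_fig1(fig1: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["site"] = fig1["site"]
    for tertile in TERTILES:
        out[f"{tertile}_prevalence_95ci"] = fig1.apply(_fmt_est, axis=1, prefix=f"{tertile}_")
    out["trend_p"] = fig1["trend_p"].map(lambda v: DASH if pd.isna(v) else f"{v:.4f}")
    return out


def render_table7(table7: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["site"] = table7["site"]
    out["n_asd"] = table7["n_asd"].map(str)
    out["n_dx"] = table7["n_dx"].map(str)
    out["dx_prevalence_95ci"] = table7.apply(_fmt_est, axis=1, prefix="dx_")
    for col in ("median_dx_age", "n_dx_le70", "median_dx_age_le70", "n_dx_gt70", "median_dx_age_gt70"):
        if col.startswith("n_"):
            out[col] = table7[col].map(str)
        else:
            out[col] = table7[col].map(_fmt)
    return out


def render_fig3(fig3: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame()
    out["site"] = fig3["site"]
    for label in ("dx", "sped", "icd"):
        out[f"{label}_prevalence_95ci"] = fig3.apply(_fmt_est, axis=1, prefix=f"{label}_")
    return out


@dataclass
class ReportBundle:
    """All report tables/figures in numeric and rendered form."""

    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame
    table5: pd.DataFrame
    table6: pd.DataFrame
    table7: pd.DataFrame
    fig1: pd.DataFrame
    fig2: pd.DataFrame
    fig3: pd.DataFrame

    def rendered(self) -> dict:
        return {
            "table2": render_table2(self.table2),
            "table3": render_table3(self.table3),
            "table4": _render_pct_frame(self.table4, int_cols=["n_asd"]),
            "table5": _render_pct_frame(self.table5, int_cols=["n_asd", "n_iq"]),
            "table6": _render_pct_frame(
                self.table6,
                int_cols=["n_asd", "n_eval", "n_eval_le70", "n_eval_gt70"],
            ),
            "table7": render_table7(self.table7),
            "fig1": render_fig1(self.fig1),
            "fig2": _render_pct_frame(self.fig2, int_cols=["n"]),
            "fig3": render_fig3(self.fig3),
        }

    def write(self, outdir: str | Path, manifest: Optional[dict] = None) -> None:
        """Write every rendered table as CSV (plus an optional manifest)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self.rendered().items():
            frame.to_csv(out / f"{name}.csv", index=False)
        if manifest is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def build_bundle(
    statuses: pd.DataFrame,
    denominators: DenominatorTable,
    tracts: Sequence[Tract],
    cfg: AnalysisConfig = DEFAULT_CONFIG,
) -> ReportBundle:
    return ReportBundle(
        table2=build_table2(statuses, denominators, cfg),
        table3=build_table3(statuses, denominators, cfg),
        table4=build_table4(statuses),
        table5=build_table5(statuses),
        table6=build_table6(statuses),
        table7=build_table7(statuses, denominators, cfg),
        fig1=build_fig1(statuses, tracts, cfg),
        fig2=build_fig2(statuses),
        fig3=build_fig3(statuses, denominators, cfg),
    )


def config_manifest(config_dict: dict, seed: Optional[int]) -> dict:
    """Reproducibility manifest: config hash, seed, package version."""
    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return {
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "package_version": _version,
    }
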