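"""Report tables, rendering, the model front end, and pipeline round-trips."""

import numpy as np
import pandas as pd
import pytest

from asdsurv import ASDSurveillance, run_pipeline, scenario_preset
from asdsurv.ascertain import ascertain_population
from asdsurv.config import network_preset
from asdsurv.report import (
    DASH,
    build_fig1,
    build_table2,
    build_table4,
)
from asdsurv.ses import DenominatorTable
from asdsurv.stats import AnalysisConfig, prevalence, round_half_away
from asdsurv.synthesize import generate_population, generate_records

from conftest import make_config

CFG = AnalysisConfig()


@pytest.fixture(scope="module")
def fitted():
    model = ASDSurveillance.from_config(make_config(n_children=8_000, true_prevalence=0.03), seed=13)
    return model.fit()


def _statuses_frame(rows):
    base = {
        "census_tract": "",
        "has_dx_statement": False,
        "has_sped": False,
        "has_icd": True,
        "is_case": True,
        "region": "icd-only",
        "earliest_dx_age_months": np.nan,
        "earliest_eval_age_months": np.nan,
        "suspected_ever": False,
        "ruled_out_ever": False,
        "ruled_out_more_recent": False,
        "cognitive_band": None,
    }
    return pd.DataFrame([{**base, **row} for row in rows])


def _denominators(cells):
    return DenominatorTable(pd.DataFrame(cells, columns=["site", "sex", "race_ethnicity", "count"]))


class TestTable2:
    def test_total_row_aggregates_site_rows(self, fitted):
        t2 = fitted.bundle.table2
        sites = t2[t2["site"] != "total"]
        total = t2[t2["site"] == "total"].iloc[0]
        assert sites["n_asd"].sum() == total["n_asd"]
        assert sites["population"].sum() == total["population"]

    def test_single_site_total_equals_site_row(self, fitted):
        t2 = fitted.bundle.table2
        site_row = t2.iloc[0]
        total = t2[t2["site"] == "total"].iloc[0]
        assert site_row["prevalence"] == total["prevalence"]

    def test_zero_female_cases_suppress_ratio(self):
        statuses = _statuses_frame(
            [{"child_id": "a", "site": "s", "sex": "male", "race_ethnicity": "white-nh"}]
        )
        denominators = _denominators(
            [("s", "male", "white-nh", 500), ("s", "female", "white-nh", 500)]
        )
        t2 = build_table2(statuses, denominators, CFG)
        row = t2.iloc[0]
        assert row["female_n"] == 0
        assert row["female_suppressed"]
        assert row["mf_ratio_suppressed"]


class TestTable4AndFig2:
    def test_shares_partition_to_100(self, fitted):
        t4 = fitted.bundle.table4
        fig2 = fitted.bundle.fig2
        n = fig2["n"].sum()
        assert n == int(fitted.statuses["is_case"].sum())
        any_dx = fig2[fig2["region"].isin(["dx-only", "dx+sped", "dx+icd", "all-three"])]["n"].sum()
        sped_no_dx = fig2[fig2["region"].isin(["sped-only", "sped+icd"])]["n"].sum()
        icd_only = fig2[fig2["region"] == "icd-only"]["n"].sum()
        assert any_dx + sped_no_dx + icd_only == n

    def test_fig2_and_table4_agree_on_indicator_shares(self, fitted):
        t4_total = fitted.bundle.table4.query("site == 'total'").iloc[0]
        cases = fitted.cases
        assert t4_total["pct_dx"] == pytest.approx(100 * cases["has_dx_statement"].mean())
        assert t4_total["pct_icd"] == pytest.approx(100 * cases["has_icd"].mean())

    def test_no_ruled_out_generation_gives_zero_columns(self):
        config = make_config(
            true_prevalence=0.05, p_ruled_out_ever=0.0, p_ruled_out_more_recent=0.0
        )
        children, denominators, tracts = generate_population(config, seed=2)
        statuses = ascertain_population(children, generate_records(children, config, seed=2))
        t4 = build_table4(statuses)
        assert (t4["pct_ruled_out_ever"] == 0).all()
        assert (t4["pct_ruled_out_more_recent"] == 0).all()

    def test_all_three_indicators_render_100_shares(self):
        statuses = _statuses_frame(
            [
                {
                    "child_id": "a",
                    "site": "s",
                    "sex": "male",
                    "race_ethnicity": "white-nh",
                    "has_dx_statement": True,
                    "has_sped": True,
                    "has_icd": True,
                    "region": "all-three",
                }
            ]
        )
        t4 = build_table4(statuses)
        row = t4.iloc[0]
        assert (row["pct_icd"], row["pct_sped"], row["pct_dx"]) == (100.0, 100.0, 100.0)


class TestTable7Consistency:
    def test_diagnosed_prevalence_recomputes_from_columns(self, fitted):
        t7 = fitted.bundle.table7
        for _, row in t7.iterrows():
            est = prevalence(int(row["n_dx"]), row["population"], CFG)
            assert row["dx_prevalence"] == pytest.approx(est.per_1000)


class TestFig1:
    def test_ses_gradient_detected_when_generated(self):
        # prevalence decreasing in MHI: engineered by post-hoc case assignment
        rng = np.random.default_rng(21)
        config = make_config(n_children=25_000, true_prevalence=0.0, tract_count=12)
        children, denominators, tracts = generate_population(config, seed=3)
        from asdsurv.ses import assign_tertiles

        assign_tertiles(tracts)
        tertile_of = {t.tract_id: t.tertile for t in tracts}
        p_by_tertile = {"low": 0.035, "medium": 0.023, "high": 0.012, None: 0.023}
        probs = children["census_tract"].map(
            lambda tid: p_by_tertile[tertile_of.get(tid)] if tid else 0.023
        )
        children = children.assign(is_true_case=rng.random(len(children)) < probs)
        statuses = ascertain_population(children, generate_records(children, config, seed=3))
        fig1 = build_fig1(statuses, tracts, CFG)
        row = fig1[fig1["site"] == "testville"].iloc[0]
        assert row["low_prevalence"] > row["high_prevalence"]
        assert row["trend_z"] < 0
        assert row["trend_p"] < 0.05

    def test_flat_generator_rarely_significant(self):
        hits = 0
        reps = 40
        config = make_config(n_children=6_000, true_prevalence=0.023, tract_count=9)
        for seed in range(reps):
            children, _, tracts = generate_population(config, seed=seed)
            for t in tracts:
                t.tertile = None
            statuses = ascertain_population(children, generate_records(children, config, seed=seed))
            fig1 = build_fig1(statuses, tracts, CFG)
            if fig1[fig1["site"] == "testville"].iloc[0]["trend_p"] < 0.05:
                hits += 1
        assert hits <= reps * 0.10 + 2  # ≥90% non-significant, MC slack

    def test_single_child_site_is_fully_suppressed(self):
        config = make_config(n_children=1, tract_count=3, missing_tract_fraction=0.0, true_prevalence=1.0)
        children, denominators, tracts = generate_population(config, seed=1)
        statuses = ascertain_population(children, generate_records(children, config, seed=1))
        fig1 = build_fig1(statuses, tracts, CFG)
        row = fig1[fig1["site"] == "testville"].iloc[0]
        for tertile in ("low", "medium", "high"):
            assert row[f"{tertile}_suppressed"]


class TestRenderingAndPipeline:
    def test_pipeline_reruns_byte_identically(self, tmp_path):
        config = make_config(n_children=3_000, true_prevalence=0.03)
        outs = []
        for name in ("a", "b"):
            out = tmp_path / name
            run_pipeline(config, out, seed=9, write_inputs=True)
            outs.append({p.name: p.read_bytes() for p in sorted(out.iterdir())})
        assert outs[0] == outs[1]
        assert "manifest.json" in outs[0]

    def test_written_csvs_round_trip(self, tmp_path, fitted):
        fitted.to_csv(tmp_path)
        for name, frame in fitted.bundle.rendered().items():
            back = pd.read_csv(tmp_path / f"{name}.csv", dtype=str, keep_default_na=False)
            assert back.equals(frame.astype(str)), name

    def test_suppressed_cells_render_as_dash(self):
        statuses = _statuses_frame(
            [{"child_id": "a", "site": "s", "sex": "male", "race_ethnicity": "white-nh"}]
        )
        denominators = _denominators(
            [("s", "male", "white-nh", 400), ("s", "female", "white-nh", 400)]
        )
        from asdsurv.report import render_table2

        rendered = render_table2(build_table2(statuses, denominators, CFG))
        assert (rendered["female_prevalence_95ci"] == DASH).all()
        assert (rendered["male_female_ratio_95ci"] == DASH).all()

    def test_empty_caseload_still_writes_headed_tables(self, tmp_path):
        config = make_config(true_prevalence=0.0, false_trigger_rate=0.0)
        run_pipeline(config, tmp_path, seed=1)
        t2 = pd.read_csv(tmp_path / "table2.csv", dtype=str, keep_default_na=False)
        assert list(t2.columns)[0] == "site"
        assert (t2["n_asd"] == "0").all()

    def test_missouri_preset_has_highest_icd_share_in_network_run(self):
        model = ASDSurveillance.from_config(network_preset(), seed=5)
        t4 = model.fit().bundle.table4
        sites = t4[t4["site"] != "total"]
        assert sites.loc[sites["pct_icd"].idxmax(), "site"] == "missouri"


class TestModelFrontEnd:
    def test_summary_reports_headline_numbers(self, fitted):
        text = fitted.summary()
        est = fitted.overall_prevalence
        assert f"{round_half_away(est.per_1000):.1f}" in text
        assert "one in" in text
        assert "Male-to-female" in text

    def test_results_expose_estimates(self, fitted):
        est = fitted.overall_prevalence
        assert est.numerator == fitted.n_cases
        assert est.ci_low_per_1000 < est.per_1000 < est.ci_high_per_1000
        ratio = fitted.male_female_ratio
        assert ratio is not None and ratio.ratio > 1

    def test_plotting_returns_axes(self, fitted):
        import matplotlib

        matplotlib.use("Agg")
        ax = fitted.plot_site_prevalence()
        assert ax.get_xlabel().startswith("ASD prevalence")
        ax2 = fitted.plot_ses_trend()
        assert ax2.get_ylabel() == "prevalence per 1,000"
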