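"""EDI/THQ/HI arithmetic, risk classification and Monte Carlo propagation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crustrisk import datasets
from crustrisk.core import ValidationError
from crustrisk.pipeline import make_survey_fixture
from crustrisk.risk import (
    ExposureGroup, MCSConfig, classify_risk, compute_edi, compute_thq,
    default_groups, deterministic_assessment, hazard_index, mcs_assessment,
)
from .conftest import make_table, mini_catalog

pos = st.floats(min_value=1e-6, max_value=1e6, allow_nan=False,
                allow_infinity=False)


class TestEdi:
    def test_children_point_estimate_for_tcep_mean(self):
        assert compute_edi(1.302, 11.85, 16.68) == pytest.approx(0.9249, abs=1e-4)

    def test_adult_point_estimate_for_tep_mean(self):
        assert compute_edi(1.089, 33.32, 57.03) == pytest.approx(0.6363, abs=1e-4)

    def test_zero_concentration_gives_zero(self):
        assert compute_edi(0.0, 11.85, 16.68) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(c=pos, ir=pos, bw=pos, k=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_c_and_ir_inverse_in_bw(self, c, ir, bw, k):
        base = compute_edi(c, ir, bw)
        assert compute_edi(k * c, ir, bw) == pytest.approx(k * base, rel=1e-9)
        assert compute_edi(c, k * ir, bw) == pytest.approx(k * base, rel=1e-9)
        assert compute_edi(c, ir, k * bw) == pytest.approx(base / k, rel=1e-9)

    def test_invalid_body_weight_rejected(self):
        with pytest.raises(ValidationError):
            compute_edi(1.0, 11.85, 0.0)


class TestThqHi:
    @pytest.mark.parametrize("edi,rfd,expected", [
        (0.581, 125, 0.00465), (0.388, 80, 0.00485), (0.0, 10, 0.0)])
    def test_published_ratio_cells(self, edi, rfd, expected):
        assert round(compute_thq(edi, rfd), 5) == pytest.approx(expected, abs=1e-5)

    def test_teens_thq_column_sums_to_0_046(self):
        thqs = [row["teens"][1] for row in datasets.RISK_TABLE_MEDIANS.values()]
        assert hazard_index(thqs) == pytest.approx(0.04632, abs=1e-5)
        assert round(hazard_index(thqs), 3) == 0.046

    def test_children_thq_column_sum(self):
        thqs = [row["children"][1] for row in datasets.RISK_TABLE_MEDIANS.values()]
        assert hazard_index(thqs) == pytest.approx(0.06034, abs=1e-5)

    def test_empty_collection_sums_to_zero(self):
        assert hazard_index([]) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1e3), max_size=20))
    def test_hi_additivity(self, thqs):
        split = len(thqs) // 2
        assert hazard_index(thqs) == pytest.approx(
            hazard_index(thqs[:split]) + hazard_index(thqs[split:]))

    def test_negative_thq_rejected(self):
        with pytest.raises(ValidationError):
            hazard_index([0.1, -0.2])


class TestClassification:
    @pytest.mark.parametrize("value,kind,expected", [
        (0.03067, "thq", "negligible"),
        (0.1, "thq", "low"),          # boundary inclusive: 0.1 <= THQ < 1
        (0.99, "thq", "low"),
        (1.0, "thq", "potential"),
        (0.999, "hi", "negligible"),
        (1.0, "hi", "potential"),     # boundary: HI >= 1
    ])
    def test_thresholds(self, value, kind, expected):
        assert classify_risk(value, kind) == expected

    def test_negative_value_rejected(self):
        with pytest.raises(ValidationError):
            classify_risk(-0.1)


class TestDeterministicAssessment:
    def test_published_means_children_hi(self):
        means, catalog, groups = make_survey_fixture()
        table = deterministic_assessment(means, catalog, groups)
        assert table.hi["children"] == pytest.approx(0.0795, abs=1e-4)
        assert table.classification == {g: "negligible" for g in
                                        ("children", "teens", "adults")}

    def test_hi_is_sum_of_thq_rows(self):
        means, catalog, groups = make_survey_fixture()
        table = deterministic_assessment(means, catalog, groups)
        for g in table.hi:
            assert table.hi[g] == pytest.approx(table.group_thqs(g).sum())

    def test_congeners_without_rfd_are_excluded_and_listed(self):
        means, catalog, _ = make_survey_fixture()
        table = deterministic_assessment(means, catalog)
        assert len(table.excluded_congeners) == 12
        assert "TiBP" in table.excluded_congeners
        assert set(table.rows["congener"]) == set(datasets.RFD)

    def test_constructed_boundary_thq_of_one(self):
        cat = mini_catalog(["TCEP"], cls="chlorinated", rfd={"TCEP": 22.0})
        g = ExposureGroup("adults", 33.32, 57.03)
        c = 22.0 * g.body_weight / g.intake_rate
        table = deterministic_assessment({"TCEP": c}, cat, [g])
        assert table.group_thqs("adults")["TCEP"] == pytest.approx(1.0)

    def test_doubling_concentrations_doubles_everything(self):
        means, catalog, groups = make_survey_fixture()
        base = deterministic_assessment(means, catalog, groups)
        double = deterministic_assessment(
            {k: 2 * v for k, v in means.items()}, catalog, groups)
        assert double.rows["edi"].to_numpy() == pytest.approx(
            2 * base.rows["edi"].to_numpy())
        for g in base.hi:
            assert double.hi[g] == pytest.approx(2 * base.hi[g])

    def test_raising_one_congener_mean_raises_every_hi(self):
        means, catalog, groups = make_survey_fixture()
        base = deterministic_assessment(means, catalog, groups)
        bumped = dict(means)
        bumped["TMP"] += 1.0
        after = deterministic_assessment(bumped, catalog, groups)
        for g in base.hi:
            assert after.hi[g] > base.hi[g]

    def test_empty_concentrations_rejected(self):
        _, catalog, _ = make_survey_fixture()
        with pytest.raises(ValidationError):
            deterministic_assessment({}, catalog)


def fixture_mcs_table():
    means, catalog, _ = make_survey_fixture()
    return make_table({"fixture": means}, catalog), catalog


class TestMonteCarlo:
    def test_degenerate_distributions_match_deterministic_exactly(self):
        table, catalog = fixture_mcs_table()
        means, _, groups = make_survey_fixture()
        det = deterministic_assessment(means, catalog, groups)
        mcs = mcs_assessment(table, catalog, groups,
                             MCSConfig(n_iter=100, c_strategy="fixed"))
        det_idx = det.rows.set_index(["group", "congener"])
        for _, row in mcs.thq_stats.iterrows():
            expected = det_idx.loc[(row["group"], row["congener"]), "thq"]
            for col in ("mean", "median", "p5", "p95"):
                assert row[col] == expected
        for _, row in mcs.hi_stats.iterrows():
            assert row["median"] == det.hi[row["group"]]

    def test_lognormal_median_below_mean_for_positive_congeners(self):
        table, catalog = fixture_mcs_table()
        mcs = mcs_assessment(table, catalog, config=MCSConfig(
            n_iter=4000, c_strategy="lognormal_mean_matched", c_gsd=2.2, seed=5))
        positive = mcs.edi_stats[mcs.edi_stats["mean"] > 0]
        assert (positive["median"] < positive["mean"]).all()

    def test_iteration_mean_converges_to_deterministic_edi(self):
        table, catalog = fixture_mcs_table()
        means, _, groups = make_survey_fixture()
        det = deterministic_assessment(means, catalog, groups)
        mcs = mcs_assessment(table, catalog, groups, MCSConfig(
            n_iter=10_000, c_strategy="lognormal_mean_matched", seed=2))
        det_idx = det.rows.set_index(["group", "congener"])
        for _, row in mcs.edi_stats.iterrows():
            expected = det_idx.loc[(row["group"], row["congener"]), "edi"]
            assert row["mean"] == pytest.approx(expected, rel=0.05)

    def test_same_seed_bit_identical(self):
        table, catalog = fixture_mcs_table()
        cfg = MCSConfig(n_iter=2000, seed=42)
        a = mcs_assessment(table, catalog, config=cfg)
        b = mcs_assessment(table, catalog, config=cfg)
        pd.testing.assert_frame_equal(a.edi_stats, b.edi_stats)
        pd.testing.assert_frame_equal(a.hi_stats, b.hi_stats)

    def test_percentiles_ordered(self):
        table, catalog = fixture_mcs_table()
        mcs = mcs_assessment(table, catalog, config=MCSConfig(
            n_iter=3000, seed=1, ir_cv=0.2, bw_cv=0.15))
        for frame in (mcs.edi_stats, mcs.thq_stats, mcs.hi_stats):
            assert (frame["p5"] <= frame["median"] + 1e-12).all()
            assert (frame["median"] <= frame["p95"] + 1e-12).all()

    def test_bootstrap_strategy_runs_and_centres_on_the_mean(self, catalog):
        rng = np.random.default_rng(33)
        values = {f"s{i}": {"TCEP": float(rng.lognormal(0, 1))}
                  for i in range(60)}
        table = make_table(values, catalog)
        mcs = mcs_assessment(table, catalog, config=MCSConfig(
            n_iter=2000, c_strategy="bootstrap", seed=3))
        observed = table.to_wide()["TCEP"].mean()
        row = mcs.edi_stats[(mcs.edi_stats["congener"] == "TCEP")
                            & (mcs.edi_stats["group"] == "adults")].iloc[0]
        g = [g for g in default_groups() if g.name == "adults"][0]
        expected = observed * g.intake_rate / g.body_weight
        assert row["mean"] == pytest.approx(expected, rel=0.05)
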