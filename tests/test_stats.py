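"""Cohort-statistics unit tests: t, CI, ANOVA, LSD, table emission."""

import numpy as np
import pandas as pd
import pytest

from meibomorph.reference import load_reference_tables, reproduce_summary_tables
from meibomorph.stats import (
    StatsError,
    SummaryStat,
    anova_from_summary,
    anova_raw,
    ci_from_summary,
    construct_groups_from_summary,
    emit_tables,
    independent_t,
    infer_n_from_summary,
    lsd_posthoc,
    paired_t,
    t_from_summary,
)


class TestPairedT:
    def test_hand_computed_example(self):
        r = paired_t([1.0, 1.0, 1.0, -1.0])
        assert r.mean == pytest.approx(0.5)
        assert r.sd == pytest.approx(1.0)
        assert r.t == pytest.approx(1.0)
        assert r.df == 3

    def test_zero_mean_symmetric_differences_give_t_zero_p_one(self):
        r = paired_t([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert r.t == 0.0
        assert r.p == pytest.approx(1.0)

    def test_ci_contains_mean_and_shrinks_with_se(self):
        r = paired_t(np.arange(30.0))
        assert r.ci[0] < r.mean < r.ci[1]
        r2 = paired_t(np.arange(30.0) * 0.01)
        assert (r2.ci[1] - r2.ci[0]) < (r.ci[1] - r.ci[0])

    def test_shift_invariance_of_paired_design(self):
        rng = np.random.default_rng(0)
        t_eye = rng.normal(5, 1, 20)
        c_eye = rng.normal(4, 1, 20)
        shift = rng.normal(0, 3, 20)  # same constant added to both eyes
        r1 = paired_t(t_eye - c_eye)
        r2 = paired_t((t_eye + shift) - (c_eye + shift))
        assert r1.t == pytest.approx(r2.t)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsError):
            paired_t([1.0])
        with pytest.raises(StatsError):
            paired_t([2.0, 2.0, 2.0])


class TestSummaryReconstruction:
    def test_t_from_printed_mean_and_se(self):
        # printed t values differ only through rounding of the inputs
        assert t_from_summary(0.634, 0.194) == pytest.approx(3.266, rel=0.005)
        assert t_from_summary(1.207, 0.257) == pytest.approx(4.691, rel=0.005)
        assert t_from_summary(0.0, 0.2) == 0.0

    def test_ci_from_printed_pair_summary(self):
        lo, hi = ci_from_summary(4.563, 0.589, df=35)
        assert lo == pytest.approx(3.367, abs=5e-4)
        assert hi == pytest.approx(5.759, abs=5e-4)

    def test_ci_from_printed_site_summary(self):
        lo, hi = ci_from_summary(1.983, 0.454 / 6, df=35)
        assert lo == pytest.approx(1.830, abs=1e-3)
        assert hi == pytest.approx(2.137, abs=1e-3)

    def test_ci_width_vanishes_with_se(self):
        lo, hi = ci_from_summary(2.0, 1e-12, df=35)
        assert lo == pytest.approx(2.0) and hi == pytest.approx(2.0)

    def test_infer_n_from_sd_se_ratio(self):
        assert infer_n_from_summary(3.536, 0.589)[0] == 36
        assert infer_n_from_summary(0.384, 0.064)[0] == 36
        assert infer_n_from_summary(1.0, 1.0)[0] == 1

    def test_summary_stat_consistency_check(self):
        s = SummaryStat(mean=1.0, sd=6.0, n=36)
        assert s.se == pytest.approx(1.0)
        assert s.df == 35
        with pytest.raises(StatsError):
            SummaryStat(mean=1.0, sd=6.0, se=2.0, n=36)

    def test_errors(self):
        with pytest.raises(StatsError):
            t_from_summary(1.0, 0.0)
        with pytest.raises(StatsError):
            ci_from_summary(1.0, 0.5, df=0)


class TestAnova:
    def test_summary_f_matches_printed_values(self):
        ref = load_reference_tables()
        for group, printed in (("treatment", 29.003), ("control", 3.011)):
            rows = ref["site_anova"][group]["rows"]
            res = anova_from_summary(
                [r["mean"] for r in rows], [r["sd"] for r in rows], 36
            )
            assert res.F == pytest.approx(printed, rel=0.005)
            assert res.df_between == 9
            assert res.df_within == 350

    def test_identical_group_means_give_f_zero(self):
        res = anova_from_summary([2.0, 2.0, 2.0], [0.5, 0.4, 0.6], 10)
        assert res.F == 0.0

    def test_raw_equals_summary_on_constructed_data(self):
        ref = load_reference_tables()
        rows = ref["site_anova"]["treatment"]["rows"]
        means = [r["mean"] for r in rows]
        sds = [r["sd"] for r in rows]
        groups = construct_groups_from_summary(means, sds, 36, seed=4)
        f_raw = anova_raw(groups).F
        f_sum = anova_from_summary(means, sds, 36).F
        assert abs(f_raw - f_sum) / f_sum < 1e-9

    def test_degenerate_raw_inputs_rejected(self):
        with pytest.raises(StatsError):
            anova_raw([[1.0, 1.0], [2.0, 2.0]])  # zero within-variance
        with pytest.raises(StatsError):
            anova_raw([[1.0, 2.0]])


class TestLsd:
    def test_identical_groups_give_empty_ordering(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = lsd_posthoc([g, g + 0.001, g - 0.001], labels=["a", "b", "c"])
        assert not res.significant[np.triu_indices(3, 1)].any()
        assert res.ordering == ""

    def test_two_separated_groups_order_by_mean(self):
        rng = np.random.default_rng(1)
        a = rng.normal(10, 1, 36)
        b = rng.normal(0, 1, 36)
        res = lsd_posthoc([a, b], labels=["A", "B"])
        assert res.ordering == "A > B"

    def test_three_tier_separation(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 0.5, 36) for m in (10, 10.1, 5, 5.1, 0)]
        res = lsd_posthoc(groups, labels=["a", "b", "c", "d", "e"])
        assert res.ordering == "a, b > c, d > e"


class TestIndependentT:
    def test_identical_groups_give_t_zero(self):
        g = [1.0, 2.0, 3.0]
        t, df, p = independent_t(g, g)
        assert t == 0.0 and df == 4

    def test_sign_follows_mean_order(self):
        rng = np.random.default_rng(3)
        a = 0.0 + rng.normal(0, 1e-3, 4)
        b = 1.0 + rng.normal(0, 1e-3, 4)
        t, _, p = independent_t(a, b)
        assert t < -100 and p < 1e-6

    def test_direct_formula_on_axial_length_style_summaries(self):
        # groups constructed to mean 0.14/0.42, sd 0.08/0.17, n=68: the
        # direct pooled formula gives about -12.3 (a printed -11.393 for
        # this configuration is not reconstructible from its summaries)
        a, b = construct_groups_from_summary([0.14, 0.42], [0.08, 0.17], 68, seed=0)
        t, df, _ = independent_t(a, b)
        sp = np.sqrt((0.08**2 + 0.17**2) / 2)
        expected = (0.14 - 0.42) / (sp * np.sqrt(2 / 68))
        assert t == pytest.approx(expected, rel=1e-9)
        assert t == pytest.approx(-12.29, abs=0.01)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(StatsError):
            independent_t([1.0, 1.0], [1.0, 1.0])


def _per_gland_frame(rng, n_subjects=12, effect=0.0):
    rows = []
    for s in range(n_subjects):
        base = rng.normal(2.0, 0.3, 10)
        for g in range(1, 11):
            for grp, shift in (("treatment", effect), ("control", 0.0)):
                rows.append(
                    {
                        "subject_id": f"S{s}", "group": grp, "gland_index": g,
                        "D": base[g - 1] + shift + rng.normal(0, 0.2),
                    }
                )
    return pd.DataFrame(rows)


class TestEmitTables:
    def test_emits_three_tables_with_expected_shape(self):
        df = _per_gland_frame(np.random.default_rng(0), effect=1.0)
        tables = emit_tables(df)
        assert set(tables) == {"paired", "treatment_sites", "control_sites"}
        assert len(tables["paired"]) == 10
        assert tables["paired"]["p"].between(0, 1).all()
        assert (tables["paired"]["ci_lo"] <= tables["paired"]["ci_hi"]).all()
        assert np.isfinite(tables["treatment_sites"].loc[0, "F"])

    def test_incomplete_subjects_are_excluded_with_warning(self):
        df = _per_gland_frame(np.random.default_rng(1), effect=0.5)
        df = df[~((df.subject_id == "S0") & (df.gland_index == 4) & (df.group == "treatment"))]
        with pytest.warns(UserWarning, match="S0"):
            tables = emit_tables(df)
        assert len(tables["paired"]) == 10

    def test_duplicated_identical_subjects_surface_zero_variance_per_gland(self):
        rng = np.random.default_rng(2)
        one = _per_gland_frame(rng, n_subjects=1, effect=1.0)
        two = pd.concat([one, one.assign(subject_id="S_copy")])
        with pytest.raises(StatsError, match="gland 1"):
            emit_tables(two)

    def test_fdr_option_adds_adjusted_column(self):
        df = _per_gland_frame(np.random.default_rng(3), effect=0.8)
        tables = emit_tables(df, fdr_correct=True)
        assert "p_bh" in tables["paired"]
        assert (tables["paired"]["p_bh"] >= tables["paired"]["p"] - 1e-12).all()


class TestReproduceSummaryTables:
    def test_all_rows_recompute_within_rounding(self):
        out = reproduce_summary_tables()
        paired = out["paired"]
        assert (paired["n_inferred"] == 36).all()
        # printed t and CI values derive from inputs rounded to 3 decimals;
        # rows with tiny means/SEs need the absolute term
        assert np.allclose(paired["t_recomputed"], paired["t_printed"], rtol=0.005, atol=0.01)
        assert np.allclose(paired["ci_lo_recomputed"], paired["ci_lo_printed"], atol=2e-3)
        assert np.allclose(paired["ci_hi_recomputed"], paired["ci_hi_printed"], atol=2e-3)
        anova = out["anova"]
        assert np.allclose(anova["F_recomputed"], anova["F_printed"], rtol=0.005)
        site = out["site_ci"]
        assert np.allclose(site["ci_lo_recomputed"], site["ci_lo_printed"], atol=2e-3)
        assert np.allclose(site["ci_hi_recomputed"], site["ci_hi_printed"], atol=2e-3)
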