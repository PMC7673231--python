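"""Arcsine transform, ANOVAs, correlations, demographic OLS."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf
from hypothesis import given, settings, strategies as st

from tonespace.cohort_stats import (
    DemographicRecord,
    arcsine_transform,
    glm_fit,
    pearson,
    rm_anova_oneway,
    two_way_anova,
)


class TestArcsine:
    @pytest.mark.parametrize(
        "p, expected", [(0.0, 0.0), (1.0, np.pi / 2), (0.5, np.pi / 4)]
    )
    def test_reference_values(self, p, expected):
        assert arcsine_transform(p) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            arcsine_transform(1.2)
        with pytest.raises(ValueError):
            arcsine_transform(-0.1)

    @settings(max_examples=100, deadline=None)
    @given(p=st.floats(0.0, 1.0))
    def test_strictly_increasing_and_invertible(self, p):
        y = arcsine_transform(p)
        assert np.sin(y) ** 2 == pytest.approx(p, abs=1e-12)
        if p < 1.0:
            assert arcsine_transform(min(1.0, p + 1e-6)) > y


def _factorial_scores(rng, n_per_cell, group_offset=0.0, method_offset=0.0,
                      noise=0.1):
    rows = []
    for grp, g_off in (("NH", group_offset), ("CI", 0.0)):
        for meth, m_off in (("2D", 0.0), ("3D", method_offset)):
            base = 0.5 + g_off + m_off
            vals = np.clip(rng.normal(base, noise, n_per_cell), 0, 1)
            rows += [
                dict(group=grp, method=meth, value=v) for v in vals
            ]
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_null_no_significant_effects(self):
        rng = np.random.default_rng(42)
        res = two_way_anova(_factorial_scores(rng, 50))
        assert all(p > 0.05 for p in res.p.values())

    def test_group_effect_detected_method_null(self):
        rng = np.random.default_rng(1)
        df = _factorial_scores(rng, 50, group_offset=0.3)
        res = two_way_anova(df, transform=False)
        assert res.p["group"] < 0.001
        assert res.p["method"] > 0.05

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        df = _factorial_scores(rng, 20, group_offset=0.1, method_offset=0.05)
        a = two_way_anova(df)
        b = two_way_anova(
            df.rename(columns={"group": "method", "method": "group"})
        )
        assert a.F["group"] == pytest.approx(b.F["method"])
        assert a.F["method"] == pytest.approx(b.F["group"])
        assert a.F["group:method"] == pytest.approx(b.F["group:method"])

    def test_empty_cell_rejected(self):
        rng = np.random.default_rng(3)
        df = _factorial_scores(rng, 10)
        df = df[~((df.group == "NH") & (df.method == "3D"))]
        with pytest.raises(ValueError, match="unbalanced"):
            two_way_anova(df)


def _rm_scores(rng, n_subjects, conditions, offsets=None, noise=0.05):
    offsets = offsets or {}
    rows = []
    for s in range(n_subjects):
        base = rng.uniform(0.3, 0.7)
        for cond in conditions:
            rows.append(
                dict(
                    subject_id=f"S{s}", condition=cond,
                    value=float(
                        np.clip(
                            base + offsets.get(cond, 0.0)
                            + rng.normal(0, noise), 0, 1,
                        )
                    ),
                )
            )
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_conditions_f_zero(self):
        rng = np.random.default_rng(0)
        df = _rm_scores(rng, 10, ["a", "b", "c"], noise=0.0)
        res = rm_anova_oneway(df)
        name = res.effects[0]
        assert res.F[name] == pytest.approx(0.0, abs=1e-9)

    def test_constant_shift_infinite_effect(self):
        rng = np.random.default_rng(1)
        df = _rm_scores(rng, 10, ["a", "b"], offsets={"b": 0.2}, noise=0.0)
        res = rm_anova_oneway(df, transform=False)
        name = res.effects[0]
        assert res.p[name] < 1e-12

    def test_depressed_contrast_flagged_by_posthoc(self):
        rng = np.random.default_rng(7)
        conds = ["1v2", "1v3", "1v4", "2v3", "2v4", "3v4"]
        df = _rm_scores(rng, 40, conds, offsets={"2v3": -0.2})
        res = rm_anova_oneway(df)
        name = res.effects[0]
        assert res.p[name] < 0.001
        post = res.posthoc
        rows_2v3 = post[(post["A"] == "2v3") | (post["B"] == "2v3")]
        assert len(rows_2v3) == 5
        assert (rows_2v3["p_corr"] < 0.05).all()
        means = df.groupby("condition")["value"].mean()
        assert means.idxmin() == "2v3"

    def test_incomplete_subjects_dropped(self):
        rng = np.random.default_rng(2)
        df = _rm_scores(rng, 6, ["a", "b", "c"])
        df = df.drop(df[(df.subject_id == "S0") & (df.condition == "c")].index)
        res = rm_anova_oneway(df)
        # S0 removed listwise: df2 of the effect reflects 5 subjects
        assert res.df[res.effects[0]][1] == pytest.approx(2 * 4)

    def test_single_condition_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            rm_anova_oneway(_rm_scores(rng, 5, ["a"]))


class TestPearson:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, p, _ = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_sampling_distribution(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(200)
        y = 0.9 * x + np.sqrt(1 - 0.9**2) * rng.standard_normal(200)
        r, p, _ = pearson(x, y)
        assert 0.85 <= r <= 0.94
        assert p < 1e-10

    def test_bonferroni_adjustment(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = 0.5 * x + rng.standard_normal(30)
        _, p, p_adj = pearson(x, y, n_family=12)
        assert p_adj == pytest.approx(min(1.0, 12 * p))

    def test_missing_pairs_deleted(self):
        x = np.array([1.0, 2, 3, np.nan, 5])
        y = np.array([2.0, 4, 6, 8, np.nan])
        r, _, _ = pearson(x, y)
        assert r == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        r, p, _ = pearson(np.ones(5), np.arange(5.0))
        assert np.isnan(r)


def _ci_records(n, rng):
    recs = []
    for i in range(n):
        a = float(rng.uniform(0.5, 8.0))
        d = float(rng.uniform(0.5, 9.0))
        recs.append(
            DemographicRecord(
                subject_id=f"CI{i}", group="CI", chronological_age=a + d,
                age_at_implantation=a, duration_of_use=d,
            )
        )
    return recs


class TestGlm:
    def test_planted_duration_effect_recovered(self):
        rng = np.random.default_rng(8)
        recs = _ci_records(200, rng)
        y = np.array(
            [0.05 * r.duration_of_use for r in recs]
        ) + rng.normal(0, 0.01, 200)
        res = glm_fit(y, recs)
        assert res.coefficients["duration_of_use"] == pytest.approx(
            0.05, rel=0.20
        )
        assert abs(res.coefficients["age_at_implantation"]) < 0.01
        assert res.p["duration_of_use"] < 1e-6

    def test_noise_free_linear_r2_one(self):
        rng = np.random.default_rng(9)
        recs = _ci_records(50, rng)
        y = np.array(
            [0.1 + 0.03 * r.age_at_implantation - 0.02 * r.duration_of_use
             for r in recs]
        )
        assert glm_fit(y, recs).r_squared == pytest.approx(1.0)

    def test_null_response_low_r2(self):
        rng = np.random.default_rng(10)
        recs = _ci_records(200, rng)
        y = rng.normal(0.5, 0.1, 200)
        assert glm_fit(y, recs).r_squared < 0.05

    def test_interaction_never_lowers_r2(self):
        rng = np.random.default_rng(11)
        recs = _ci_records(80, rng)
        y = rng.normal(0.5, 0.1, 80)
        full = glm_fit(y, recs).r_squared
        df = pd.DataFrame(
            {
                "y": y,
                "a": [r.age_at_implantation for r in recs],
                "d": [r.duration_of_use for r in recs],
            }
        )
        reduced = smf.ols("y ~ a + d", data=df).fit().rsquared
        assert full >= reduced - 1e-12

    def test_demographic_identity_enforced(self):
        with pytest.raises(ValueError, match="chronological"):
            DemographicRecord(
                subject_id="X", group="CI", chronological_age=10.0,
                age_at_implantation=3.0, duration_of_use=5.0,
            )
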