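"""g-computation engine: standardization, effect measures, subgroups."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gcomprisk import (
    NNT,
    ODDS_RATIO,
    RATE_DIFFERENCE,
    RATE_RATIO,
    RISK_DIFFERENCE,
    RISK_RATIO,
    AnalysisSpec,
    CounterfactualSet,
    build_cohort,
    marginal_contrast,
    measures_from_means,
    point_estimate,
    subgroup_split,
    validate_spec,
)
from conftest import newton_logistic


def _effects(table, spec, **kw):
    t, s = validate_spec(table, spec)
    return point_estimate(t, s, **kw), s


class TestClosedFormMeasures:
    def test_two_by_two_crude_measures(self, two_group_binary, binary_spec):
        pe, _ = _effects(two_group_binary, binary_spec)
        m = pe.effects["overall"][0].measures
        assert m[RISK_DIFFERENCE] == pytest.approx(0.10, abs=1e-9)
        assert m[RISK_RATIO] == pytest.approx(1.5, abs=1e-9)
        assert m[ODDS_RATIO] == pytest.approx((0.3 / 0.7) / (0.2 / 0.8), abs=1e-9)
        assert m[NNT] == pytest.approx(10.0, abs=1e-7)

    def test_two_group_rate_measures(self, two_group_rate):
        spec = AnalysisSpec(
            outcome_name="events", exposure_name="exposed", outcome_type="rate",
            offset_name="persondays", rate_multiplier=100.0,
        )
        pe, _ = _effects(two_group_rate, spec)
        m = pe.effects["overall"][0].measures
        assert m[RATE_DIFFERENCE] == pytest.approx(1.75, abs=1e-9)
        assert m[RATE_RATIO] == pytest.approx(2.4, abs=1e-9)

    def test_rate_ratio_invariant_difference_scales_with_multiplier(self, two_group_rate):
        base = dict(outcome_name="events", exposure_name="exposed",
                    outcome_type="rate", offset_name="persondays")
        m1 = _effects(two_group_rate, AnalysisSpec(**base, rate_multiplier=100.0))[0].effects["overall"][0].measures
        m2 = _effects(two_group_rate, AnalysisSpec(**base, rate_multiplier=1000.0))[0].effects["overall"][0].measures
        assert m2[RATE_RATIO] == pytest.approx(m1[RATE_RATIO], rel=1e-12)
        assert m2[RATE_DIFFERENCE] == pytest.approx(10 * m1[RATE_DIFFERENCE], rel=1e-12)

    def test_null_means_give_null_measures(self):
        cfs = CounterfactualSet(
            predictions=np.full((4, 2), 0.5), regimes=["0", "1"],
            marginal_means=np.array([0.5, 0.5]),
        )
        m = marginal_contrast(cfs, "binary")[0].measures
        assert m[RISK_DIFFERENCE] == 0 and m[RISK_RATIO] == 1 and m[ODDS_RATIO] == 1
        assert math.isinf(m[NNT])

    def test_zero_referent_mean_gives_nan_ratio(self):
        m = measures_from_means(np.array([0.0, 1.2]), ["0", "1"], "rate")[0].measures
        assert math.isnan(m[RATE_RATIO]) and m[RATE_DIFFERENCE] == pytest.approx(1.2)


class TestOracleEquivalence:
    def test_standardization_matches_newton_oracle(self, small_logistic):
        """Marginal means must equal the average of oracle-fitted
        counterfactual probabilities over all rows; measures to 1e-6."""
        spec = AnalysisSpec(outcome_name="y", exposure_name="a", covariate_names=["w"])
        pe, s = _effects(small_logistic, spec)
        df = small_logistic.data
        X = np.column_stack([np.ones(len(df)), df["a"], df["w"]]).astype(float)
        beta = newton_logistic(X, df["y"].to_numpy(float))

        def expit(v):
            return 1 / (1 + np.exp(-v))

        p1 = expit(beta[0] + beta[1] + beta[2] * df["w"]).mean()
        p0 = expit(beta[0] + beta[2] * df["w"]).mean()
        means = pe.counterfactuals["overall"].marginal_means
        assert means[1] == pytest.approx(p1, abs=1e-6)
        assert means[0] == pytest.approx(p0, abs=1e-6)
        m = pe.effects["overall"][0].measures
        assert m[RISK_DIFFERENCE] == pytest.approx(p1 - p0, abs=1e-6)
        assert m[RISK_RATIO] == pytest.approx(p1 / p0, abs=1e-6)
        assert m[ODDS_RATIO] == pytest.approx((p1 / (1 - p1)) / (p0 / (1 - p0)), abs=1e-6)

    def test_saturated_model_equals_direct_standardization(self):
        """With subgroup = W the model is saturated in (A, W): per-stratum
        g-computation equals stratum proportions and the combination equals
        classical direct standardization by cell counting, exactly."""
        rng = np.random.default_rng(21)
        n = 400
        w = rng.integers(0, 3, n)
        a = rng.binomial(1, 0.35 + 0.1 * (w == 2))
        y = rng.binomial(1, 0.2 + 0.15 * a + 0.1 * w / 2)
        df = pd.DataFrame({"a": a, "w": w, "y": y})
        t = build_cohort(df, {"w": "categorical"})
        spec = AnalysisSpec(outcome_name="y", exposure_name="a", subgroup_name="w")
        pe, s = _effects(t, spec)

        for lv in (0, 1, 2):
            sub = df[df["w"] == lv]
            for code, regime_idx in ((1, 1), (0, 0)):
                cell = sub[sub["a"] == code]["y"].mean()
                got = pe.counterfactuals[str(lv)].marginal_means[regime_idx]
                assert got == pytest.approx(cell, abs=1e-10)

        # total-population direct standardization from the same cell counts
        std = {code: sum(
            df[(df["w"] == lv) & (df["a"] == code)]["y"].mean() * (df["w"] == lv).mean()
            for lv in (0, 1, 2))
            for code in (0, 1)}
        combined = {code: sum(
            pe.counterfactuals[str(lv)].marginal_means[idx] * (df["w"] == lv).mean()
            for lv in (0, 1, 2))
            for idx, code in ((0, 0), (1, 1))}
        assert combined[1] == pytest.approx(std[1], abs=1e-10)
        assert combined[0] == pytest.approx(std[0], abs=1e-10)

    def test_subgroup_estimates_match_per_stratum_refits(self):
        """When the joint model is saturated in (exposure, subgroup), the
        interaction fit equals separate per-stratum fits exactly; with
        shared covariate coefficients the two would differ."""
        rng = np.random.default_rng(33)
        n = 600
        g = rng.integers(0, 2, n)
        a = rng.binomial(1, 0.4, n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.5 + 0.8 * a + 0.3 * g))))
        df = pd.DataFrame({"a": a, "g": g, "y": y})
        t = build_cohort(df, {"g": "categorical"})
        spec = AnalysisSpec(outcome_name="y", exposure_name="a", subgroup_name="g")
        pe, s = _effects(t, spec)
        tv, sv = validate_spec(t, spec)
        for lv, sub in subgroup_split(tv, sv).items():
            solo = point_estimate(
                *validate_spec(sub, AnalysisSpec(outcome_name="y", exposure_name="a"))
            )
            np.testing.assert_allclose(
                pe.counterfactuals[lv].marginal_means,
                solo.counterfactuals["overall"].marginal_means,
                atol=1e-7,
            )

    def test_exchangeable_subgroups_agree_under_null(self):
        rng = np.random.default_rng(44)
        n = 4000
        df = pd.DataFrame(
            {"a": rng.binomial(1, 0.5, n), "g": rng.integers(0, 2, n),
             "y": rng.binomial(1, 0.3, n)}
        )
        t = build_cohort(df, {"g": "categorical"})
        pe, _ = _effects(t, AnalysisSpec(outcome_name="y", exposure_name="a", subgroup_name="g"))
        rd0 = pe.effects["0"][0].measures[RISK_DIFFERENCE]
        rd1 = pe.effects["1"][0].measures[RISK_DIFFERENCE]
        assert abs(rd0 - rd1) < 0.06  # within Monte-Carlo error at n=2000/stratum


class TestProperties:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_collapsibility_ordering(self, seed):
        """Whenever RD > 0, the marginal OR is at least as far from the
        null as the marginal RR: OR >= RR >= 1."""
        rng = np.random.default_rng(seed)
        n = 200
        w = rng.normal(size=n)
        a = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, 1 / (1 + np.exp(-(-0.4 + 0.9 * a + 0.7 * w))))
        df = pd.DataFrame({"a": a, "w": w, "y": y})
        if y.min() == y.max() or len(set(a)) < 2:
            return
        t = build_cohort(df)
        pe, _ = _effects(t, AnalysisSpec(outcome_name="y", exposure_name="a",
                                         covariate_names=["w"]))
        m = pe.effects["overall"][0].measures
        if m[RISK_DIFFERENCE] > 1e-12:
            assert m[ODDS_RATIO] >= m[RISK_RATIO] - 1e-12
            assert m[RISK_RATIO] >= 1 - 1e-12

    def test_regime_permutation_flips_measures(self, two_group_binary):
        spec_fwd = AnalysisSpec(outcome_name="event", exposure_name="exposed")
        pe_f, _ = _effects(two_group_binary, spec_fwd)
        flipped = build_cohort(
            two_group_binary.data.assign(exposed=1 - two_group_binary.data["exposed"].astype(int))
        )
        pe_r, _ = _effects(flipped, spec_fwd)
        mf, mr = pe_f.effects["overall"][0].measures, pe_r.effects["overall"][0].measures
        assert mr[RISK_DIFFERENCE] == pytest.approx(-mf[RISK_DIFFERENCE], abs=1e-9)
        assert mr[RISK_RATIO] == pytest.approx(1 / mf[RISK_RATIO], rel=1e-9)
        assert mr[ODDS_RATIO] == pytest.approx(1 / mf[ODDS_RATIO], rel=1e-9)

    def test_categorical_exposure_gives_contrast_per_level(self):
        rng = np.random.default_rng(8)
        n = 300
        dose = rng.integers(0, 3, n)
        y = rng.binomial(1, 0.2 + 0.1 * dose)
        t = build_cohort(pd.DataFrame({"dose": dose, "y": y}), {"dose": "categorical"})
        pe, _ = _effects(t, AnalysisSpec(outcome_name="y", exposure_name="dose"))
        assert [e.contrast for e in pe.effects["overall"]] == ["1 vs 0", "2 vs 0"]

    def test_numeric_exposure_contrast_labels_raw_endpoints(self):
        df = pd.DataFrame({"age": [30.0, 40, 50, 60] * 10,
                           "y": ([0, 1, 0, 1] * 5 + [0, 0, 1, 1] * 5)})
        t = build_cohort(df)
        pe, _ = _effects(t, AnalysisSpec(outcome_name="y", exposure_name="age",
                                         exposure_scalar=10.0))
        assert pe.effects["overall"][0].contrast == "55 vs 45"
        assert pe.centering_value_used == pytest.approx(45.0)

    def test_single_level_exposure_rejected(self):
        df = pd.DataFrame({"a": [1, 1, 1, 1], "y": [0, 1, 0, 1]})
        t = build_cohort(df)
        with pytest.raises(Exception, match="level|constant"):
            _effects(t, AnalysisSpec(outcome_name="y", exposure_name="a"))
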