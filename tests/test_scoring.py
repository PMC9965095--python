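"""Phenotype scoring: dichotomization rules, stratified cutoffs, classification."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from frailtyscreen import ScoringConfig, derive_cutoffs, score_and_classify
from frailtyscreen.errors import CodingError, ConfigurationError, StratificationError
from frailtyscreen.scoring import (
    flag_exhaustion,
    flag_low_activity,
    flag_weight_loss,
    lower_quantile,
    mean_of_trials,
    upper_quantile,
)

from oracles import lower_quantile_oracle, upper_quantile_oracle


def tiny_cohort(grip, walk=None, sex="male", responses=None, bmi=None, height=None):
    """Hand-built cohort: trials equal to the wanted means, fixed covariates."""
    n = len(grip)
    walk = walk if walk is not None else [5.0] * n
    df = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(n)],
            "sex": sex if isinstance(sex, list) else [sex] * n,
            "age_group": ["60-69"] * n,
            "weight": [1.0] * n,
            "bmi": bmi if bmi is not None else [22.0] * n,
            "height": height if height is not None else [160.0] * n,
            "grip_trial1": grip,
            "grip_trial2": grip,
            "walk_trial1": walk,
            "walk_trial2": walk,
            "exhaustion_response": ["rarely (<1 day)"] * n,
            "weight_loss_response": ["no"] * n,
            "activity_frequency": ["every day"] * n,
            "residence": ["rural"] * n,
            "marital": ["in_wedlock"] * n,
            "education": ["none"] * n,
            "work": ["working"] * n,
            "smoking": ["no"] * n,
            "alcohol": ["no"] * n,
            "adl": ["no"] * n,
            "iadl": ["no"] * n,
        }
    )
    if responses:
        for col, vals in responses.items():
            df[col] = vals
    return df


@pytest.mark.parametrize(
    "func,value,expected",
    [
        (flag_exhaustion, "often (3-4 days)", 1),
        (flag_exhaustion, "most (5-7 days)", 1),
        (flag_exhaustion, "some (1-2 days)", 0),
        (flag_exhaustion, "rarely (<1 day)", 0),
        (flag_weight_loss, "yes", 1),
        (flag_weight_loss, "no", 0),
        (flag_low_activity, "hardly ever/never", 1),
        (flag_low_activity, "1-3/month", 1),
        (flag_low_activity, "1/week", 0),
        (flag_low_activity, ">1/week", 0),
        (flag_low_activity, "every day", 0),
    ],
)
def test_questionnaire_dichotomization(func, value, expected):
    assert func(value) == expected


@pytest.mark.parametrize("func", [flag_exhaustion, flag_weight_loss, flag_low_activity])
def test_questionnaire_missing_propagates_and_unknown_raises(func):
    assert math.isnan(func(np.nan))
    with pytest.raises(CodingError):
        func("whenever")


@pytest.mark.parametrize(
    "t1,t2,expected",
    [(30, 34, 32), (30, np.nan, 30), (np.nan, 34, 34)],
)
def test_mean_of_trials(t1, t2, expected):
    assert mean_of_trials(t1, t2) == expected


def test_mean_of_trials_both_missing_is_missing():
    assert math.isnan(mean_of_trials(np.nan, np.nan))


class TestDeriveCutoffs:
    def test_bottom_quintile_of_one_to_ten_is_two(self):
        cohort = tiny_cohort(grip=list(range(1, 11)), walk=[5.0] * 10)
        cuts = derive_cutoffs(cohort, ScoringConfig())
        grip = cuts[(cuts.measure == "grip") & (cuts.sex == "male")]
        assert set(grip.threshold) == {2.0}

    def test_slowest_quintile_of_walk_times(self):
        cohort = tiny_cohort(grip=[30.0] * 10, walk=list(range(2, 12)))
        cuts = derive_cutoffs(cohort, ScoringConfig())
        walk = cuts[(cuts.measure == "walk") & (cuts.sex == "male")]
        # largest value with at least 20% of times at or above it
        assert set(walk.threshold) == {10.0}

    def test_identical_values_degenerate_stratum(self):
        cohort = tiny_cohort(grip=[25.0] * 8)
        cfg = ScoringConfig()
        cuts = derive_cutoffs(cohort, cfg)
        grip = cuts[cuts.measure == "grip"]
        assert set(grip.threshold) == {25.0}
        flags = score_and_classify(cohort, cuts, cfg).flags
        assert flags["G"].mean() == 1.0  # everyone at the threshold is flagged

    def test_strata_are_local(self):
        """Cutoffs in one sex stratum ignore values in the other."""
        males = tiny_cohort(grip=list(range(1, 11)))
        females = tiny_cohort(grip=list(range(101, 111)), sex="female")
        females["id"] = [f"f{i}" for i in range(10)]
        both = pd.concat([males, females], ignore_index=True)
        cuts = derive_cutoffs(both, ScoringConfig())
        male_thr = cuts[(cuts.measure == "grip") & (cuts.sex == "male")].threshold
        female_thr = cuts[(cuts.measure == "grip") & (cuts.sex == "female")].threshold
        assert set(male_thr) == {2.0}
        assert set(female_thr) == {102.0}

    def test_empty_cohort_raises(self):
        with pytest.raises(StratificationError):
            derive_cutoffs(tiny_cohort(grip=[]), ScoringConfig())

    def test_survey_weighted_quantile_mode(self):
        # one heavy observation dominates the weighted quintile
        cohort = tiny_cohort(grip=[1.0, 2.0, 3.0, 4.0, 5.0])
        cohort["weight"] = [10.0, 1.0, 1.0, 1.0, 1.0]
        cfg = ScoringConfig(quantile_weighting="survey_weighted")
        cuts = derive_cutoffs(cohort, cfg)
        thr = cuts[(cuts.measure == "grip")].threshold.iloc[0]
        assert thr == 1.0


class TestQuantileConventions:
    @given(
        st.lists(st.integers(min_value=-50, max_value=50), min_size=1, max_size=25),
        st.floats(min_value=0.05, max_value=0.95),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_sort_and_scan_oracle(self, values, p):
        assert lower_quantile(np.array(values, float), p) == lower_quantile_oracle(values, p)
        assert upper_quantile(np.array(values, float), p) == upper_quantile_oracle(values, p)

    @given(st.integers(min_value=5, max_value=200), st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=200, deadline=None)
    def test_quintile_coverage_within_one_observation(self, n, seed):
        """In an all-distinct stratum the flagged fraction is within one
        observation of the nominal proportion, on both tails."""
        rng = np.random.default_rng(seed)
        vals = rng.permutation(np.arange(n, dtype=float) + rng.random())
        p = 0.20
        low = lower_quantile(vals, p)
        frac_low = np.mean(vals <= low)
        assert p <= frac_low <= p + 1 / n
        high = upper_quantile(vals, p)
        frac_high = np.mean(vals >= high)
        assert p <= frac_high <= p + 1 / n


class TestScoreAndClassify:
    def test_flag_combinations_and_threshold(self):
        # E,G,W set / E,G set / none set -> scores 3, 2, 0
        cohort = tiny_cohort(
            grip=[1.0, 1.0, 50.0, 40.0, 41.0, 42.0, 43.0],
            walk=[30.0, 5.0, 5.0, 5.0, 5.0, 5.0, 5.1],
            responses={
                "exhaustion_response": ["most (5-7 days)"] * 2 + ["rarely (<1 day)"] * 5
            },
        )
        cuts = pd.DataFrame(
            {
                "measure": ["grip", "walk"],
                "sex": ["male", "male"],
                "stratum": ["bmi_q1", "height_low"],
                "threshold": [2.0, 20.0],
                "n": [7, 7],
            }
        )
        scored = score_and_classify(cohort, cuts, ScoringConfig())
        out = scored.flags.set_index("id")
        assert out.loc["p0", ["E", "G", "W", "S", "frail"]].tolist() == [1, 1, 1, 3, 1]
        assert out.loc["p1", ["E", "G", "W", "S", "frail"]].tolist() == [1, 1, 0, 2, 0]
        assert out.loc["p2", ["S", "frail"]].tolist() == [0, 0]

    def test_tie_rule_at_grip_threshold(self):
        cohort = tiny_cohort(grip=[2.0, 30.0])
        cuts = pd.DataFrame(
            {
                "measure": ["grip", "walk"],
                "sex": ["male", "male"],
                "stratum": ["bmi_q1", "height_low"],
                "threshold": [2.0, 100.0],
                "n": [2, 2],
            }
        )
        at_or_below = score_and_classify(cohort, cuts, ScoringConfig()).flags
        assert at_or_below.set_index("id").loc["p0", "G"] == 1
        strict = score_and_classify(
            cohort, cuts, ScoringConfig(tie_rule="flag_strictly_below")
        ).flags
        assert strict.set_index("id").loc["p0", "G"] == 0

    def test_walk_maximum_always_flagged_under_slowest(self):
        cohort = tiny_cohort(grip=[30.0] * 6, walk=[4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        scored = score_and_classify(cohort, config=ScoringConfig())
        out = scored.flags.set_index("id")
        assert out.loc["p5", "W"] == 1

    def test_complete_case_drop_counted(self):
        cohort = tiny_cohort(grip=[10.0] * 6, walk=[4.0, 5.0, 6.0, 7.0, 8.0, 9.0])
        cohort.loc[0, "exhaustion_response"] = np.nan
        cohort.loc[1, ["grip_trial1", "grip_trial2"]] = np.nan
        scored = score_and_classify(cohort, config=ScoringConfig())
        assert scored.n_dropped == 2
        assert len(scored.flags) == 4
        assert set(scored.flags["id"]) == {"p2", "p3", "p4", "p5"}

    def test_single_trial_fallback_keeps_row(self):
        cohort = tiny_cohort(grip=[1.0, 10.0, 11.0, 12.0, 13.0])
        cohort.loc[0, "grip_trial2"] = np.nan
        scored = score_and_classify(cohort, config=ScoringConfig())
        assert scored.n_dropped == 0
        assert scored.flags.set_index("id").loc["p0", "G"] == 1

    def test_row_order_invariance(self, small_cohort):
        cfg = ScoringConfig()
        base = score_and_classify(small_cohort, config=cfg)
        shuffled = small_cohort.sample(frac=1.0, random_state=42).reset_index(drop=True)
        other = score_and_classify(shuffled, config=cfg)
        a = base.flags.sort_values("id").reset_index(drop=True)
        b = other.flags.sort_values("id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)
        ca = base.cutoffs.sort_values(["measure", "sex", "stratum"]).reset_index(drop=True)
        cb = other.cutoffs.sort_values(["measure", "sex", "stratum"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(ca, cb)

    def test_raising_frail_threshold_never_adds_frail(self, small_cohort):
        counts = []
        for thr in range(1, 6):
            cfg = ScoringConfig(frail_threshold=thr)
            counts.append(score_and_classify(small_cohort, config=cfg).flags["frail"].sum())
        assert counts == sorted(counts, reverse=True)

    def test_score_equals_flag_sum(self, scored_small):
        f = scored_small.flags
        assert (f["S"] == f[["E", "G", "W", "L", "P"]].sum(axis=1)).all()
        assert f["S"].between(0, 5).all()
        assert ((f["frail"] == 1) == (f["S"] >= 3)).all()


def test_invalid_scoring_config_rejected():
    with pytest.raises(ConfigurationError):
        ScoringConfig(frail_threshold=0)
    with pytest.raises(ConfigurationError):
        ScoringConfig(quintile_proportion=1.0)
    with pytest.raises(ConfigurationError):
        ScoringConfig(tie_rule="coin_flip")
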