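"""Standardization: stratum assignment, weighting, adjusted means, trends."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdcra.errors import (
    CollinearityError,
    DomainError,
    EmptyStratumError,
    TrendError,
)
from ckdcra.standardization import (
    ALL_STRATA,
    StratumKey,
    adjusted_means,
    assign_stratum,
    standardized_mean,
    standardized_prevalence,
    standardized_sample,
    trend_test,
    with_age_group,
)
from ckdcra.synthetic_data import default_config, generate_cohort


@pytest.mark.parametrize(
    "age, expected",
    [(18, "18-39"), (39, "18-39"), (40, "40-59"), (59, "40-59"),
     (60, "60-69"), (69, "60-69"), (70, "70+"), (95, "70+")],
)
def test_assign_stratum_boundaries(age, expected):
    assert assign_stratum(age, "male", "urban") == StratumKey(expected, "male", "urban")


def test_assign_stratum_rejects_minors():
    with pytest.raises(DomainError):
        assign_stratum(17, "male", "urban")


@given(st.integers(min_value=18, max_value=120))
@settings(max_examples=50, deadline=None)
def test_every_adult_age_maps_to_exactly_one_group(age):
    groups = [g for g in ALL_STRATA if assign_stratum(age, g.sex, g.residence)]
    key = assign_stratum(age, "female", "rural")
    assert key.age_group in ("18-39", "40-59", "60-69", "70+")


def _two_strata(make_survey):
    rows = []
    for _ in range(2):
        rows.append({"age": 30, "sbp": 120.0})
    for _ in range(2):
        rows.append({"age": 50, "sbp": 130.0})
    return make_survey(rows)


def test_standardized_mean_is_weighted_average(make_survey, make_census):
    survey = _two_strata(make_survey)
    census = make_census(
        {StratumKey("18-39", "male", "urban"): 1, StratumKey("40-59", "male", "urban"): 3}
    )
    mean, se = standardized_mean(survey, census, "sbp", 2011)
    assert mean == pytest.approx(0.25 * 120 + 0.75 * 130)


def test_self_weighting_census_recovers_crude_mean(make_survey, make_census):
    rows = [{"age": 30, "sbp": v} for v in (118.0, 122.0, 126.0)] + [
        {"age": 50, "sbp": v} for v in (128.0, 134.0)
    ]
    survey = make_survey(rows)
    census = make_census(
        {StratumKey("18-39", "male", "urban"): 3, StratumKey("40-59", "male", "urban"): 2}
    )
    mean, _ = standardized_mean(survey, census, "sbp", 2011)
    assert mean == pytest.approx(survey["sbp"].mean(), abs=1e-12)


def test_standardized_mean_matches_bruteforce(cohort, census):
    """Independent oracle: explicit per-stratum loop over census shares."""
    mean, _ = standardized_mean(cohort, census, "sbp", 2011)
    sub = with_age_group(cohort[cohort["wave"] == 2011].dropna(subset=["sbp"]))
    shares = census.set_index(["age_group", "sex", "residence"])["count"]
    shares = shares / shares.sum()
    acc = 0.0
    for s in ALL_STRATA:
        vals = sub[
            (sub["age_group"] == s.age_group)
            & (sub["sex"] == s.sex)
            & (sub["residence"] == s.residence)
        ]["sbp"]
        acc += shares[tuple(s)] * vals.mean()
    assert mean == pytest.approx(acc, abs=1e-10)


def test_empty_stratum_raises_and_names_it(make_survey, make_census):
    survey = _two_strata(make_survey)
    census = make_census(
        {
            StratumKey("18-39", "male", "urban"): 1,
            StratumKey("70+", "female", "rural"): 5,
            StratumKey("40-59", "male", "urban"): 3,
        }
    )
    with pytest.raises(EmptyStratumError, match="70\\+.*female.*rural"):
        standardized_mean(survey, census, "sbp", 2011)


def test_prevalence_all_never_smokers(make_survey, make_census):
    survey = make_survey([{"age": 30, "smoking": "never"} for _ in range(5)])
    census = make_census({StratumKey("18-39", "male", "urban"): 10})
    prev = standardized_prevalence(survey, census, "smoking", 2011)
    assert prev.loc["never", "fraction"] == pytest.approx(1.0)
    assert "current" not in prev.index or prev.loc["current", "fraction"] == 0.0


def test_prevalence_matches_bruteforce_and_sums_to_one(cohort, census):
    prev = standardized_prevalence(cohort, census, "smoking", 2011)
    assert prev["fraction"].sum() == pytest.approx(1.0, abs=1e-9)
    sub = with_age_group(cohort[cohort["wave"] == 2011])
    shares = census.set_index(["age_group", "sex", "residence"])["count"]
    shares = shares / shares.sum()
    acc = 0.0
    for s in ALL_STRATA:
        grp = sub[
            (sub["age_group"] == s.age_group)
            & (sub["sex"] == s.sex)
            & (sub["residence"] == s.residence)
        ]["smoking"]
        acc += shares[tuple(s)] * (grp == "current").mean()
    assert prev.loc["current", "fraction"] == pytest.approx(acc, abs=1e-12)


def test_standardized_sample_consistency(cohort, census):
    dist = standardized_sample(cohort, census, "sbp", 2011)
    mean, _ = standardized_mean(cohort, census, "sbp", 2011)
    assert dist.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert dist.mean() == pytest.approx(mean, abs=1e-12)
    # weighted variance against the brute-force formula
    xbar = dist.mean()
    brute = float(np.sum(dist.weights * (dist.values - xbar) ** 2))
    assert dist.var() == pytest.approx(brute, abs=1e-12)


def test_single_stratum_sample_has_uniform_weights(make_survey, make_census):
    survey = make_survey([{"age": 30, "sbp": 110.0 + i} for i in range(4)])
    census = make_census({StratumKey("18-39", "male", "urban"): 7})
    dist = standardized_sample(survey, census, "sbp", 2011)
    assert np.allclose(dist.weights, 0.25)


def test_row_permutation_invariance(cohort, census):
    shuffled = cohort.sample(frac=1.0, random_state=0).reset_index(drop=True)
    m1, s1 = standardized_mean(cohort, census, "bmi", 2011)
    m2, s2 = standardized_mean(shuffled, census, "bmi", 2011)
    assert m1 == pytest.approx(m2, abs=1e-12)
    assert s1 == pytest.approx(s2, abs=1e-12)


def test_equal_stratum_means_ignore_census_weights(make_survey, make_census):
    rows = [{"age": a, "sbp": 121.0} for a in (25, 45, 65, 75)]
    survey = make_survey(rows)
    for counts in ((1, 1, 1, 1), (10, 1, 5, 2)):
        census = make_census(
            {
                StratumKey("18-39", "male", "urban"): counts[0],
                StratumKey("40-59", "male", "urban"): counts[1],
                StratumKey("60-69", "male", "urban"): counts[2],
                StratumKey("70+", "male", "urban"): counts[3],
            }
        )
        mean, _ = standardized_mean(survey, census, "sbp", 2011)
        assert mean == pytest.approx(121.0, abs=1e-12)


# -- adjusted means ---------------------------------------------------------


def _flat_noise_free(n=400, seed=2):
    cfg = default_config(n_individuals=n, seed=seed)
    cfg.baseline_mean = {
        "sbp": {s: 120.0 for s in ALL_STRATA},
        "dbp": {s: 75.0 for s in ALL_STRATA},
        "bmi": {s: 22.0 for s in ALL_STRATA},
    }
    cfg.annual_slope = {
        "sbp": {s: 0.5 for s in ALL_STRATA},
        "dbp": {s: 0.2 for s in ALL_STRATA},
        "bmi": {s: 0.1 for s in ALL_STRATA},
    }
    cfg.within_sd = {f: 0.0 for f in cfg.within_sd}
    cfg.between_intercept_sd = {f: 0.0 for f in cfg.between_intercept_sd}
    cfg.between_slope_sd = {f: 0.0 for f in cfg.between_slope_sd}
    return cfg


def test_adjusted_means_equal_crude_without_confounding():
    survey = generate_cohort(_flat_noise_free())
    adj = adjusted_means(survey, "sbp")
    crude = survey.groupby("wave")["sbp"].mean()
    for wave in crude.index:
        assert adj.loc[wave, "mean"] == pytest.approx(crude[wave], abs=1e-8)


def test_adjusted_means_remove_configured_confounding():
    cfg = _flat_noise_free(n=4000, seed=21)
    cfg.within_sd = {"sbp": 2.0, "dbp": 2.0, "bmi": 0.5}
    cfg.annual_slope = {f: {s: 0.0 for s in ALL_STRATA} for f in cfg.annual_slope}
    cfg.education_effect = {"sbp": 4.0}
    cfg.education_drift = 0.5
    survey = generate_cohort(cfg)
    adj = adjusted_means(survey, "sbp")
    crude = survey.groupby("wave")["sbp"].mean()
    # the configured truth is flat across waves; adjustment removes the
    # compositional drift that education induces in the crude series
    spread_adj = adj["mean"].max() - adj["mean"].min()
    spread_crude = crude.max() - crude.min()
    assert spread_adj < spread_crude
    assert spread_adj < 0.3


def test_adjusted_means_require_two_waves(make_survey):
    survey = make_survey([{"age": 30, "sbp": 120.0, "wave": 2011} for _ in range(5)])
    with pytest.raises(TrendError):
        adjusted_means(survey, "sbp")


def test_collinear_covariates_are_named(cohort):
    dup = cohort.copy()
    dup["education_copy"] = dup["education"]
    with pytest.raises(CollinearityError, match="education"):
        adjusted_means(dup, "sbp", covariates=("education", "education_copy"))


# -- trend test -------------------------------------------------------------


def _linear_survey(make_survey, slope=0.5, waves=(1991, 1993, 1997, 2000), n_ids=6):
    rows = []
    for pid in range(1, n_ids + 1):
        for w in waves:
            rows.append(
                {
                    "id": pid,
                    "wave": w,
                    "age": 25 + pid + (w - waves[0]),
                    "sbp": 100.0 + slope * (w - waves[0]),
                }
            )
    return make_survey(rows)


def test_trend_recovers_exact_noise_free_slope(make_survey):
    survey = _linear_survey(make_survey, slope=0.5)
    res = trend_test(survey, "sbp")
    assert res.slope == pytest.approx(0.5, abs=1e-9)
    assert res.pvalue < 1e-6


def test_trend_slope_equivariance(cohort):
    base = trend_test(cohort, "sbp", covariates=("age",))
    shifted = cohort.copy()
    shifted["sbp"] = shifted["sbp"] + 0.3 * (shifted["wave"] - 2000)
    res = trend_test(shifted, "sbp", covariates=("age",))
    assert res.slope - base.slope == pytest.approx(0.3, abs=1e-8)


def test_trend_requires_three_waves(make_survey):
    survey = _linear_survey(make_survey, waves=(1991, 1993))
    with pytest.raises(TrendError):
        trend_test(survey, "sbp")


def test_male_smoking_trend_declines(cohort):
    res = trend_test(cohort, "smoking", {"sex": "male"})
    assert res.slope < 0
    assert res.pvalue < 0.001
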