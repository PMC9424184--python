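"""Attributable fractions and burden: closed forms, oracles, uncertainty."""
import numpy as np
import pytest
from scipy import integrate, stats

from ckdcra.attribution import (
    attributable_cases,
    attributable_series,
    burden_with_ci,
    counterfactual_mean_rr,
    _counterfactual_mean_rr_draws,
    paf_categorical,
    paf_continuous,
    total_cases,
)
from ckdcra.errors import DomainError
from ckdcra.risk_model import CategoryRisk, RiskFactorSpec, builtin_specs, rr_continuous
from ckdcra.standardization import StandardizedDistribution, StratumKey


def _dist(values, factor="sbp", wave=2011, weights=None):
    values = np.asarray(values, dtype=float)
    if weights is None:
        weights = np.full(values.size, 1.0 / values.size)
    return StandardizedDistribution(factor, wave, values, weights)


# -- categorical ------------------------------------------------------------


def test_paf_categorical_closed_form():
    assert paf_categorical([0.5, 0.5], [1.0, 3.0]) == pytest.approx(0.5)
    assert paf_categorical([0.2, 0.3, 0.5], [1.0, 1.0, 1.0]) == 0.0


@pytest.mark.parametrize(
    "prev, rrs, err",
    [
        ([0.6, 0.5], [1.0, 1.2], "sum"),
        ([-0.1, 1.1], [1.0, 1.2], "negative"),
        ([0.5, 0.5], [1.0, -2.0], "positive"),
        ([0.5, 0.5], [1.2, 1.3], "reference"),
    ],
)
def test_paf_categorical_input_validation(prev, rrs, err):
    with pytest.raises(DomainError, match=err):
        paf_categorical(prev, rrs)


def _simulated_paf(prev, rrs, n, rng, base=0.05):
    """Individual-level oracle: excess-case fraction in a simulated cohort."""
    cats = rng.choice(len(prev), size=n, p=prev)
    p_case = base * np.asarray(rrs)[cats]
    cases = rng.random(n) < p_case
    n_cases = cases.sum()
    paf_hat = (n_cases - base * n) / n_cases
    sd_cases = np.sqrt(np.sum(p_case * (1 - p_case)))
    se = base * n * sd_cases / n_cases**2  # delta method on (1 - C/X)
    return paf_hat, se


def test_paf_categorical_matches_simulation_oracle():
    prev, rrs = [0.735, 0.265], [1.0, 1.34]
    rng = np.random.default_rng(2024)
    paf_hat, se = _simulated_paf(prev, rrs, 2_000_000, rng)
    assert paf_categorical(prev, rrs) == pytest.approx(paf_hat, abs=3 * se)


def test_paf_categorical_monotone_in_rr_and_prevalence():
    base = paf_categorical([0.7, 0.3], [1.0, 1.3])
    assert paf_categorical([0.7, 0.3], [1.0, 1.5]) > base
    assert paf_categorical([0.6, 0.4], [1.0, 1.3]) > base


# -- continuous -------------------------------------------------------------


def _analytic_e2(spec, m):
    """Closed form for E[RR(x)] over the truncated TMRED normal on [0, m].

    With b = ln(rr)/u and z = (x - mu)/sd, the part above the TMRED mean is a
    lognormal partial expectation: exp(b^2 sd^2 / 2) * (Phi(zm - b sd) - Phi(-b sd)),
    and the part below contributes its probability mass (RR floored at 1).
    """
    mu, sd = spec.tmred_mean, spec.tmred_sd
    b = np.log(spec.rr) / spec.unit_increment
    z0, zm = (0.0 - mu) / sd, (m - mu) / sd
    zden = stats.norm.cdf(zm) - stats.norm.cdf(z0)
    below = (stats.norm.cdf(0.0) - stats.norm.cdf(z0)) / zden
    above = (
        np.exp(0.5 * b**2 * sd**2)
        * (stats.norm.cdf(zm - b * sd) - stats.norm.cdf(-b * sd))
        / zden
    )
    return below + above


@pytest.mark.parametrize("name", ["sbp", "dbp", "bmi"])
def test_counterfactual_integral_matches_closed_form(name):
    spec = builtin_specs()[name]
    m = spec.tmred_mean + 8 * spec.tmred_sd
    quad_val = counterfactual_mean_rr(spec, m)
    assert quad_val == pytest.approx(_analytic_e2(spec, m), abs=1e-9)
    grid_val = _counterfactual_mean_rr_draws(spec, m, np.array([spec.rr]))[0]
    assert grid_val == pytest.approx(quad_val, abs=1e-8)


def test_paf_continuous_point_mass_matches_monte_carlo_oracle():
    spec = builtin_specs()["sbp"]
    p1 = _dist([125.0])
    paf = paf_continuous(p1, spec)
    rng = np.random.default_rng(5)
    a, b = (0 - 115) / 6, (125 - 115) / 6
    draws = stats.truncnorm.rvs(a, b, loc=115, scale=6, size=1_000_000,
                                random_state=rng)
    rr_vals = rr_continuous(draws, spec)
    e2_mc, se_e2 = rr_vals.mean(), rr_vals.std(ddof=1) / 1000.0
    oracle = (1.08 - e2_mc) / 1.08
    assert paf == pytest.approx(oracle, abs=3 * se_e2 / 1.08)


def test_paf_continuous_null_when_p1_is_the_counterfactual():
    spec = builtin_specs()["sbp"]
    rng = np.random.default_rng(17)
    a = (0 - 115) / 6
    sample = stats.truncnorm.rvs(a, np.inf, loc=115, scale=6, size=200_000,
                                 random_state=rng)
    paf = paf_continuous(_dist(sample), spec)
    assert abs(paf) < 2e-3


def test_paf_continuous_point_mass_at_tmred_is_non_positive():
    spec = builtin_specs()["sbp"]
    paf = paf_continuous(_dist([115.0]), spec)
    assert paf <= 0.0


def test_paf_continuous_rejects_categorical_spec():
    with pytest.raises(TypeError):
        paf_continuous(_dist([1.0]), builtin_specs()["smoking"])


def test_discretization_limit_converges_to_continuous():
    """Binned categorical PAF with midpoint RRs converges to the integral form."""
    spec = builtin_specs()["sbp"]
    rng = np.random.default_rng(8)
    sample = rng.normal(125.0, 13.0, size=100_000)
    sample = sample[sample > 0]
    p1 = _dist(sample)
    continuous = paf_continuous(p1, spec)
    m = sample.max()
    k = 1000
    edges = np.linspace(0.0, m, k + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    rr_mid = rr_continuous(mids, spec)
    p1_bins = np.histogram(sample, bins=edges)[0] / sample.size
    a, b = (0 - 115) / 6, (m - 115) / 6
    cdf = stats.truncnorm.cdf((edges - 115) / 6, a, b)
    p2_bins = np.diff(cdf)
    e1 = float(p1_bins @ rr_mid)
    e2 = float(p2_bins @ rr_mid)
    binned = (e1 - e2) / e1
    assert binned == pytest.approx(continuous, abs=1e-3)


def test_e1_quadrature_on_smoothed_p1_agrees_with_empirical():
    spec = builtin_specs()["sbp"]
    rng = np.random.default_rng(9)
    sample = rng.normal(126.0, 12.0, size=20_000)
    p1 = _dist(sample)
    empirical = float(p1.weights @ rr_continuous(p1.values, spec))
    kde = stats.gaussian_kde(sample)
    smoothed, _ = integrate.quad(
        lambda x: rr_continuous(float(x), spec) * kde(x)[0],
        sample.min() - 20, sample.max() + 20, limit=200,
    )
    assert smoothed == pytest.approx(empirical, abs=1e-2)


def test_paf_continuous_monotone_under_upward_shift():
    spec = builtin_specs()["sbp"]
    rng = np.random.default_rng(10)
    sample = rng.normal(125.0, 12.0, size=20_000)
    low = paf_continuous(_dist(sample), spec)
    high = paf_continuous(_dist(sample + 5.0), spec)
    assert high > low


# -- case arithmetic --------------------------------------------------------


def test_total_cases_reproduces_published_total():
    total = total_cases(0.108, 846_662_309)
    assert total == pytest.approx(0.108 * 846_662_309)
    assert round(total / 1e6, 1) == 91.4
    assert total_cases(0.0, 1000) == 0.0
    assert total_cases(1.0, 1000) == 1000.0
    with pytest.raises(DomainError):
        total_cases(1.2, 1000)
    with pytest.raises(DomainError):
        total_cases(-0.1, 1000)


def test_attributable_cases_examples():
    total = total_cases(0.108, 846_662_309)
    assert attributable_cases(0.087, total) / 1e6 == pytest.approx(7.9, abs=0.1)
    assert attributable_cases(0.074, total) / 1e6 == pytest.approx(6.8, abs=0.1)
    assert attributable_cases(0.0, total) == 0.0
    with pytest.raises(DomainError):
        attributable_cases(1.0, total)


def test_attributable_series_is_linear_in_paf():
    total = 90e6
    series = attributable_series({1991: 0.10, 2011: 0.06}, total)
    diff = (
        series.loc[series["wave"] == 1991, "attributable_cases"].iloc[0]
        - series.loc[series["wave"] == 2011, "attributable_cases"].iloc[0]
    )
    assert diff == pytest.approx(0.04 * total)
    const = attributable_series({w: 0.08 for w in (1991, 2000, 2011)}, total)
    assert const["attributable_cases"].nunique() == 1


# -- Monte-Carlo uncertainty ------------------------------------------------


def _one_stratum_smoking_survey(make_survey, current_frac, n=400, rng=None):
    rng = rng or np.random.default_rng(0)
    states = np.where(rng.random(n) < current_frac, "current", "never")
    return make_survey(
        [{"id": i + 1, "age": 30, "smoking": s} for i, s in enumerate(states)]
    )


def test_burden_ci_degenerate_widths_collapse(make_survey, make_census):
    spec = RiskFactorSpec(
        name="smoking", kind="categorical", source="smoking",
        categories={
            "never": CategoryRisk(1.0, 1.0, 1.0, reference=True),
            "current": CategoryRisk(1.34, 1.34, 1.34),
            "former": CategoryRisk(1.27, 1.27, 1.27),
        },
    )
    survey = _one_stratum_smoking_survey(make_survey, 0.3)
    census = make_census({StratumKey("18-39", "male", "urban"): 100})
    paf_est, burden = burden_with_ci(
        survey, census, spec, 2011, (0.108, 0.108, 0.108), 1e8,
        n_draws=1000, seed=4,
    )
    assert paf_est.ci_low == pytest.approx(paf_est.paf, abs=1e-12)
    assert paf_est.ci_high == pytest.approx(paf_est.paf, abs=1e-12)
    assert burden.ci_low == pytest.approx(burden.attributable_cases, rel=1e-12)


def test_burden_ci_reproducible_under_fixed_seed(cohort, census, specs):
    kwargs = dict(n_draws=500, seed=42)
    a = burden_with_ci(cohort, census, specs["smoking"], 2011,
                       (0.108, 0.102, 0.113), 8.47e8, **kwargs)
    b = burden_with_ci(cohort, census, specs["smoking"], 2011,
                       (0.108, 0.102, 0.113), 8.47e8, **kwargs)
    assert a[0] == b[0]
    assert a[1] == b[1]


def test_burden_ci_covers_known_truth(make_survey, make_census, specs):
    """CI from RR + prevalence propagation covers the generative-truth PAF."""
    spec = builtin_specs()["smoking"]
    true_prev = {"never": 0.7, "former": 0.0, "current": 0.3}
    true_paf = paf_categorical(
        [0.7, 0.0, 0.3], [1.0, 1.27, 1.34]
    )
    census = make_census({StratumKey("18-39", "male", "urban"): 100})
    rng = np.random.default_rng(77)
    covered = 0
    n_rep = 120
    for rep in range(n_rep):
        survey = _one_stratum_smoking_survey(make_survey, 0.3, n=1200, rng=rng)
        paf_est, _ = burden_with_ci(
            survey, census, spec, 2011, (0.108, 0.102, 0.113), 1e8,
            n_draws=400, seed=rep,
        )
        covered += paf_est.ci_low <= true_paf <= paf_est.ci_high
    assert 0.9 <= covered / n_rep <= 1.0


def test_blood_factor_paf_uses_sex_thresholds(cohort, census, specs):
    from ckdcra.attribution import exposure_prevalences, paf_point

    prev = exposure_prevalences(cohort, census, specs["hdl"], 2009)
    assert prev["low"] + prev["normal"] == pytest.approx(1.0, abs=1e-9)
    assert 0.0 < prev["low"] < 0.5
    paf = paf_point(cohort, census, specs["hdl"], 2009)
    assert 0.0 < paf < 0.2
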