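"""Per-stratum random-effects exposure trends and 20-year projections.

The trend among individuals observed in at least three waves is estimated by
a two-stage random-effects (DerSimonian-Laird) procedure: an ordinary
least-squares slope per individual over that individual's waves, then an
inverse-variance-weighted mean slope with a method-of-moments
between-individual variance component.  For binary indicators (current
smoking) the per-individual residual variances are degenerate (most
trajectories are constant), so the stratum slope is the unweighted mean of
individual slopes with its empirical standard error.

Projections anchor at the last observed standardized mean (not the fitted
intercept) so the projected series continues the observed one, advance
linearly in calendar year, and do not age the population.  For continuous
factors the full standardized exposure distribution is location-shifted to
the projected mean (shape preserved) before the attributable fraction is
recomputed; smoking is projected on the prevalence scale with clipping to
[0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .attribution import (
    _paf_draws_categorical,
    _paf_draws_continuous,
    _prevalence_draws,
    attributable_cases,
    exposure_prevalences,
    paf_categorical,
    paf_continuous,
    total_cases,
)
from .errors import DomainError, ProjectionError
from .risk_model import RiskFactorSpec
from .standardization import (
    ALL_STRATA,
    StandardizedDistribution,
    StratumKey,
    census_weights,
    standardized_sample,
)
from .synthetic_data import entry_stratum_table

_VAR_FLOOR = 1e-12


@dataclass
class ProjectionModel:
    """Fitted per-stratum linear trend of one factor."""

    factor: str
    stratum: StratumKey | None
    slope: float
    se: float
    tau2: float  # between-individual slope variance component
    n_individuals: int

    def __post_init__(self) -> None:
        if self.se < 0 or self.tau2 < 0:
            raise DomainError("SE and between-variance must be non-negative")
        if self.n_individuals < 2:
            raise DomainError("a stratum trend needs at least 2 individuals")


def _individual_slopes(
    survey: pd.DataFrame, factor: str, min_waves: int
) -> pd.DataFrame:
    """Per-individual OLS slope and its sampling variance.

    Returns a frame indexed by id with columns slope, var, n; individuals with
    fewer than ``min_waves`` observed waves are excluded.
    """
    if factor == "smoking":
        sub = survey.dropna(subset=["smoking"]).copy()
        sub["_y"] = (sub["smoking"] == "current").astype(float)
    else:
        sub = survey.dropna(subset=[factor]).copy()
        sub["_y"] = sub[factor].astype(float)
    sub["_x"] = sub["wave"].astype(float)
    sub["_xx"] = sub["_x"] ** 2
    sub["_xy"] = sub["_x"] * sub["_y"]
    sub["_yy"] = sub["_y"] ** 2
    g = sub.groupby("id")
    agg = g.agg(
        n=("_x", "size"),
        sx=("_x", "sum"),
        sy=("_y", "sum"),
        sxx=("_xx", "sum"),
        sxy=("_xy", "sum"),
        syy=("_yy", "sum"),
    )
    agg = agg[agg["n"] >= min_waves]
    n = agg["n"].astype(float)
    sxx_c = agg["sxx"] - agg["sx"] ** 2 / n
    sxy_c = agg["sxy"] - agg["sx"] * agg["sy"] / n
    syy_c = agg["syy"] - agg["sy"] ** 2 / n
    ok = (sxx_c > 0).to_numpy()
    agg, n = agg[ok], n[ok].to_numpy()
    sxx_c, sxy_c, syy_c = (
        sxx_c[ok].to_numpy(), sxy_c[ok].to_numpy(), syy_c[ok].to_numpy()
    )
    slope = sxy_c / sxx_c
    sse = np.maximum(syy_c - slope * sxy_c, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(n > 2, sse / np.maximum(n - 2, 1) / sxx_c, np.nan)
    # individuals with exactly 2 points (if min_waves allows) get an
    # undefined residual variance; treat it as zero and let the floor apply
    var = np.where(np.isnan(var), 0.0, var)
    return pd.DataFrame(
        {"slope": slope, "var": var, "n": n.astype(int)}, index=agg.index
    )


def fit_stratum_trend(
    survey: pd.DataFrame,
    factor: str,
    stratum: StratumKey | None = None,
    min_waves: int = 3,
    weighting: str = "auto",
) -> ProjectionModel:
    """Two-stage random-effects trend among individuals with >= min_waves.

    Individuals are assigned to the stratum of their first observed wave.
    ``weighting`` is ``"ivw"`` (DerSimonian-Laird), ``"equal"`` (unweighted
    mean of slopes) or ``"auto"`` (equal for the binary smoking indicator,
    inverse-variance otherwise).
    """
    sub = survey
    if stratum is not None:
        entry = entry_stratum_table(survey)
        keep = entry[
            (entry["age_group"] == stratum.age_group)
            & (entry["sex"] == stratum.sex)
            & (entry["residence"] == stratum.residence)
        ].index
        sub = survey[survey["id"].isin(keep)]
    per = _individual_slopes(sub, factor, min_waves)
    k = len(per)
    if k < 2:
        label = tuple(stratum) if stratum is not None else "overall"
        raise ProjectionError(
            f"no eligible individuals (>= {min_waves} waves) for factor "
            f"{factor!r} in stratum {label}"
        )
    b = per["slope"].to_numpy()
    v = np.maximum(per["var"].to_numpy(), _VAR_FLOOR)
    if weighting == "auto":
        weighting = "equal" if factor == "smoking" else "ivw"
    if weighting == "equal":
        mean = float(b.mean())
        samp_var = float(b.var(ddof=1))
        tau2 = max(0.0, samp_var - float(np.mean(v)))
        se = float(np.sqrt(samp_var / k))
    elif weighting == "ivw":
        w = 1.0 / v
        bbar = float(np.sum(w * b) / np.sum(w))
        q = float(np.sum(w * (b - bbar) ** 2))
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
        w_star = 1.0 / (v + tau2)
        mean = float(np.sum(w_star * b) / np.sum(w_star))
        se = float(np.sqrt(1.0 / np.sum(w_star)))
    else:
        raise DomainError(f"unknown weighting {weighting!r}")
    return ProjectionModel(
        factor=factor, stratum=stratum, slope=mean, se=se, tau2=tau2,
        n_individuals=k,
    )


def project_mean(
    model: ProjectionModel,
    target_year: int,
    anchor_value: float,
    anchor_year: int,
    proportion: bool = False,
) -> float:
    """Linear projection from the anchored standardized mean.

    value = anchor + slope x (target_year - anchor_year); proportions are
    clipped to [0, 1].
    """
    if target_year < anchor_year:
        raise DomainError("target_year must be >= anchor year")
    value = anchor_value + model.slope * (target_year - anchor_year)
    if proportion:
        value = float(np.clip(value, 0.0, 1.0))
    return float(value)


def project_distribution(
    base: StandardizedDistribution, projected_mean: float
) -> StandardizedDistribution:
    """Location-shift the standardized distribution to the projected mean."""
    return base.shifted(projected_mean - base.mean())


def fit_all_strata(
    survey: pd.DataFrame, factor: str, min_waves: int = 3, weighting: str = "auto"
) -> dict[StratumKey, ProjectionModel]:
    """Fit the per-stratum trend in every joint stratum (error if any fails)."""
    return {
        s: fit_stratum_trend(survey, factor, s, min_waves, weighting)
        for s in ALL_STRATA
    }


def standardized_slope(
    models: Mapping[StratumKey, ProjectionModel], census: pd.DataFrame
) -> float:
    """Census-weighted combination of the stratum slopes."""
    weights = census_weights(census)
    return float(sum(weights[tuple(s)] * m.slope for s, m in models.items()))


def projected_burden(
    survey: pd.DataFrame,
    census: pd.DataFrame,
    specs: Mapping[str, RiskFactorSpec],
    years: Sequence[int],
    prevalence_ci: tuple[float, float, float],
    population: float,
    anchor_wave: int = 2011,
    min_waves: int = 3,
    n_draws: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Project exposures and attributable burden for the requested years.

    Per factor and year: extrapolate the standardized exposure (distribution
    shift for continuous factors, prevalence extrapolation for smoking),
    recompute the PAF, and multiply by the fixed anchor-year case total.
    Returns a long frame with exposure, PAF and case columns (CI via the same
    Monte-Carlo draws as :func:`ckdcra.attribution.burden_with_ci`).
    """
    total = total_cases(prevalence_ci[0], population)
    rows = []
    for fi, (name, spec) in enumerate(sorted(specs.items())):
        models = fit_all_strata(survey, name, min_waves=min_waves)
        slope = standardized_slope(models, census)
        overall = ProjectionModel(
            factor=name, stratum=None, slope=slope,
            se=0.0, tau2=0.0,
            n_individuals=sum(m.n_individuals for m in models.values()),
        )
        rng = np.random.default_rng([seed, fi])
        prev_draws = _prevalence_draws(prevalence_ci, rng, n_draws)
        if spec.kind == "continuous":
            base = standardized_sample(survey, census, spec.source, anchor_wave)
            anchor = base.mean()
        else:
            base_prev = exposure_prevalences(survey, census, spec, anchor_wave)
            anchor = base_prev["current"]
        for year in years:
            if spec.kind == "continuous":
                pm = project_mean(overall, year, anchor, anchor_wave)
                dist = project_distribution(base, pm)
                paf = paf_continuous(dist, spec)
                paf_draws = _paf_draws_continuous(
                    dist, spec, np.random.default_rng([seed, fi, year]), n_draws
                )
                exposure = pm
            else:
                cur = project_mean(overall, year, anchor, anchor_wave, proportion=True)
                former = min(base_prev.get("former", 0.0), 1.0 - cur)
                prev = {"never": 1.0 - cur - former, "former": former, "current": cur}
                prev = {c: prev[c] for c in spec.categories}
                # renormalize exactly (guards clipping round-off)
                s = sum(prev.values())
                prev = {c: p / s for c, p in prev.items()}
                rrs = {c: spec.categories[c].rr for c in spec.categories}
                paf = paf_categorical(prev, rrs)
                paf_draws = _paf_draws_categorical(
                    prev, spec, np.random.default_rng([seed, fi, year]), n_draws
                )
                exposure = cur
            cases = attributable_cases(paf, total)
            case_draws = paf_draws * prev_draws * population
            paf_lo, paf_hi = np.percentile(paf_draws, [2.5, 97.5])
            case_lo, case_hi = np.percentile(case_draws, [2.5, 97.5])
            rows.append(
                {
                    "factor": name,
                    "year": int(year),
                    "exposure": float(exposure),
                    "slope_per_year": slope,
                    "paf": float(paf),
                    "paf_ci_low": float(min(paf_lo, paf)),
                    "paf_ci_high": float(max(paf_hi, paf)),
                    "attributable_cases": float(cases),
                    "cases_ci_low": float(min(case_lo, cases)),
                    "cases_ci_high": float(max(case_hi, cases)),
                }
            )
    return pd.DataFrame(rows)
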