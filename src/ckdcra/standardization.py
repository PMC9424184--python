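"""Direct standardization of exposure distributions to census strata.

The reference population is stratified by the joint classification of age
group x sex x urban/rural residence (16 strata).  Standardized summaries
reweight stratum-specific sample statistics by the census population share of
each stratum, so that secular comparisons across survey waves are not
confounded by drift in the sample's demographic composition.

Covariate-adjusted wave means and the "P for trend" test are implemented as
fixed-effects least squares; the trend test treats calendar year as a numeric
(scored) regressor and uses cluster-robust standard errors by person id to
account for repeated measures within individuals.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DomainError,
    EmptyStratumError,
    TrendError,
)

AGE_GROUPS: tuple[str, ...] = ("18-39", "40-59", "60-69", "70+")
AGE_BREAKS: tuple[int, ...] = (18, 40, 60, 70)
SEXES: tuple[str, ...] = ("male", "female")
RESIDENCES: tuple[str, ...] = ("urban", "rural")

#: Default adjustment covariates for adjusted means / trend tests.
DEFAULT_COVARIATES: tuple[str, ...] = (
    "age",
    "sex",
    "residence",
    "education",
    "occupation",
    "province",
)


class StratumKey(NamedTuple):
    """One joint census stratum."""

    age_group: str
    sex: str
    residence: str


#: Canonical ordering of the 16 joint strata.
ALL_STRATA: tuple[StratumKey, ...] = tuple(
    StratumKey(g, s, r) for s in SEXES for g in AGE_GROUPS for r in RESIDENCES
)

_STRATUM_COLS = ["age_group", "sex", "residence"]


def age_group_of(age: float) -> str:
    """Map an adult age in years to its age group label."""
    if age < 18:
        raise DomainError(f"age {age} is below the adult threshold of 18")
    if age < 40:
        return AGE_GROUPS[0]
    if age < 60:
        return AGE_GROUPS[1]
    if age < 70:
        return AGE_GROUPS[2]
    return AGE_GROUPS[3]


def assign_stratum(age: float, sex: str, residence: str) -> StratumKey:
    """Deterministically assign one person-wave to its joint stratum."""
    if sex not in SEXES:
        raise DomainError(f"unknown sex {sex!r}; expected one of {SEXES}")
    if residence not in RESIDENCES:
        raise DomainError(
            f"unknown residence {residence!r}; expected one of {RESIDENCES}"
        )
    return StratumKey(age_group_of(age), sex, residence)


def with_age_group(survey: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the survey with an ``age_group`` column (age at wave)."""
    ages = np.asarray(survey["age"], dtype=float)
    if np.any(ages < 18):
        raise DomainError("survey contains rows with age < 18")
    cut = pd.cut(
        ages,
        bins=[18, 40, 60, 70, np.inf],
        right=False,
        labels=AGE_GROUPS,
    )
    out = survey.copy()
    out["age_group"] = cut.astype(str)
    return out


def census_weights(census: pd.DataFrame) -> pd.Series:
    """Population share per joint stratum; index (age_group, sex, residence).

    Strata must be unique with positive counts; a census restricted to a
    subset of strata defines weights over that subset only.
    """
    counts = census.set_index(_STRATUM_COLS)["count"]
    if counts.index.duplicated().any():
        raise DomainError("census table has duplicated strata")
    if (counts <= 0).any():
        raise DomainError("census table has non-positive population counts")
    return counts / counts.sum()


@dataclass
class StandardizedDistribution:
    """A census-standardized empirical exposure distribution P1(x).

    Each surveyed exposure value carries weight W_s / n_s, where W_s is the
    census share of its stratum and n_s the number of sampled values in that
    stratum, so the weights sum to one and the weighted mean equals the
    directly standardized mean exactly.
    """

    factor: str
    wave: int
    values: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.values.shape != self.weights.shape or self.values.ndim != 1:
            raise DomainError("values and weights must be 1-d arrays of equal length")
        if self.values.size == 0:
            raise DomainError("empty standardized distribution")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("non-finite exposure values")
        if np.any(self.weights < 0):
            raise DomainError("negative standardization weights")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise DomainError(f"weights sum to {total}, expected 1")

    def mean(self) -> float:
        return float(self.weights @ self.values)

    def var(self) -> float:
        m = self.mean()
        return float(self.weights @ (self.values - m) ** 2)

    def shifted(self, delta: float) -> "StandardizedDistribution":
        """Location-shift every value by ``delta``; weights unchanged."""
        return StandardizedDistribution(
            self.factor, self.wave, self.values + delta, self.weights
        )


@dataclass
class TrendResult:
    """Adjusted linear trend of one factor: slope per calendar year."""

    factor: str
    stratum: str
    slope: float
    se: float
    pvalue: float
    n_obs: int = 0
    n_individuals: int = 0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise DomainError("trend SE must be non-negative")
        if not (0.0 <= self.pvalue <= 1.0):
            raise DomainError("p-value outside [0, 1]")


def _wave_slice(survey: pd.DataFrame, factor: str, wave: int) -> pd.DataFrame:
    sub = survey[survey["wave"] == wave]
    if sub.empty:
        raise DomainError(f"wave {wave} not present in survey")
    sub = sub.dropna(subset=[factor])
    if sub.empty:
        raise DomainError(f"no non-missing {factor!r} values at wave {wave}")
    return with_age_group(sub)


def _stratum_stats(sub: pd.DataFrame, col: str) -> pd.DataFrame:
    g = sub.groupby(_STRATUM_COLS, observed=True)[col]
    return pd.DataFrame({"n": g.size(), "mean": g.mean(), "var": g.var(ddof=1)})


def _check_coverage(stats: pd.DataFrame, weights: pd.Series, factor, wave) -> None:
    empty = [s for s in weights.index if s not in stats.index]
    if empty:
        raise EmptyStratumError(empty, factor=factor, wave=wave)


def standardized_mean(
    survey: pd.DataFrame, census: pd.DataFrame, factor: str, wave: int
) -> tuple[float, float]:
    """Directly standardized mean and SE of ``factor`` at ``wave``.

    mean = sum_s W_s m_s with W_s the census stratum share and m_s the stratum
    sample mean; SE by the delta method with fixed weights,
    SE^2 = sum_s W_s^2 s_s^2 / n_s.
    """
    sub = _wave_slice(survey, factor, wave)
    weights = census_weights(census)
    stats = _stratum_stats(sub, factor)
    _check_coverage(stats, weights, factor, wave)
    stats = stats.reindex(weights.index)
    w = weights.to_numpy()
    mean = float(w @ stats["mean"].to_numpy())
    var_terms = stats["var"].fillna(0.0).to_numpy() / stats["n"].to_numpy()
    se = float(np.sqrt(np.sum(w**2 * var_terms)))
    return mean, se


def standardized_prevalence(
    survey: pd.DataFrame,
    census: pd.DataFrame,
    factor: str,
    wave: int,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Census-standardized category fractions of a categorical factor.

    Returns a frame indexed by category with columns ``fraction`` and ``se``;
    fractions sum to one.
    """
    sub = _wave_slice(survey, factor, wave)
    weights = census_weights(census)
    cats = list(categories) if categories is not None else sorted(sub[factor].unique())
    grouped = sub.groupby(_STRATUM_COLS, observed=True)[factor]
    n_s = grouped.size()
    _check_coverage(pd.DataFrame({"n": n_s}), weights, factor, wave)
    rows = {}
    for cat in cats:
        ind = (sub[factor] == cat).astype(float)
        stats = _stratum_stats(sub.assign(_ind=ind), "_ind")
        stats = stats.reindex(weights.index)
        w = weights.to_numpy()
        frac = float(w @ stats["mean"].to_numpy())
        var_terms = stats["var"].fillna(0.0).to_numpy() / stats["n"].to_numpy()
        rows[cat] = (frac, float(np.sqrt(np.sum(w**2 * var_terms))))
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["fraction", "se"])
    out.index.name = "category"
    return out


def standardized_sample(
    survey: pd.DataFrame, census: pd.DataFrame, factor: str, wave: int
) -> StandardizedDistribution:
    """The full standardized empirical distribution P1(x) of a factor."""
    sub = _wave_slice(survey, factor, wave)
    weights = census_weights(census)
    n_s = sub.groupby(_STRATUM_COLS, observed=True)[factor].size()
    _check_coverage(pd.DataFrame({"n": n_s}), weights, factor, wave)
    key = pd.MultiIndex.from_frame(sub[_STRATUM_COLS])
    per_obs = (weights / n_s).reindex(key).to_numpy()
    return StandardizedDistribution(
        factor, wave, sub[factor].to_numpy(dtype=float), per_obs
    )


# ---------------------------------------------------------------------------
# regression machinery (adjusted means, trend test)
# ---------------------------------------------------------------------------


def _covariate_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Dummy-coded covariate design (reference level dropped), numeric as-is."""
    parts = []
    for cov in covariates:
        col = df[cov]
        if pd.api.types.is_numeric_dtype(col):
            parts.append(col.astype(float).rename(cov))
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:
                parts.append(
                    (col.astype(str) == level).astype(float).rename(f"{cov}[{level}]")
                )
    if not parts:
        return pd.DataFrame(index=df.index)
    X = pd.concat(parts, axis=1)
    # within-subset constant columns carry no information
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def _check_rank(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the columns loading on the null space
        _, s, vt = np.linalg.svd(mat, full_matrices=False)
        null = vt[s < s.max() * 1e-10 * max(mat.shape)] if s.size else vt
        if null.size == 0:
            null = vt[-1:]
        loading = np.abs(null).max(axis=0)
        suspects = [c for c, l in zip(X.columns, loading) if l > 1e-6]
        raise CollinearityError(suspects or list(X.columns))


def adjusted_means(
    survey: pd.DataFrame,
    factor: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Covariate-adjusted (least-squares) mean of ``factor`` per wave.

    Fits y ~ C(wave) + covariates by OLS and evaluates the fitted mean for each
    wave at the overall covariate distribution of the analysis sample, so wave
    contrasts are not driven by compositional drift.  Returns a frame indexed
    by wave with columns ``mean`` and ``se``.
    """
    sub = survey.dropna(subset=[factor]).copy()
    waves = sorted(sub["wave"].unique())
    if len(waves) < 2:
        raise TrendError("adjusted means require at least 2 waves")
    wave_dummies = pd.concat(
        [
            (sub["wave"] == w).astype(float).rename(f"wave[{w}]")
            for w in waves[1:]
        ],
        axis=1,
    )
    Z = _covariate_design(sub, covariates)
    X = pd.concat(
        [pd.Series(1.0, index=sub.index, name="const"), wave_dummies, Z], axis=1
    )
    _check_rank(X)
    res = sm.OLS(sub[factor].astype(float), X).fit()
    cov = res.cov_params().to_numpy()
    z_bar = Z.mean().to_numpy() if Z.shape[1] else np.empty(0)
    rows = {}
    for w in waves:
        pattern = np.array([1.0 if f"wave[{v}]" == f"wave[{w}]" else 0.0 for v in waves[1:]])
        L = np.concatenate([[1.0], pattern, z_bar])
        mean = float(L @ res.params.to_numpy())
        se = float(np.sqrt(L @ cov @ L))
        rows[w] = (mean, se)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=["mean", "se"])
    out.index.name = "wave"
    return out


def _trend_response(sub: pd.DataFrame, factor: str) -> pd.Series:
    if factor == "smoking":
        # linear-probability model on the current-smoking indicator,
        # matching the percentage scale of the trajectory tables
        return (sub["smoking"] == "current").astype(float)
    return sub[factor].astype(float)


def trend_test(
    survey: pd.DataFrame,
    factor: str,
    stratum: StratumKey | Mapping[str, str] | None = None,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
) -> TrendResult:
    """Adjusted linear trend with calendar year as a scored regressor.

    Standard errors are cluster-robust by person id (repeated measures), with
    a t reference distribution on G-1 degrees of freedom.  ``stratum`` may be a
    :class:`StratumKey`, a mapping of column filters (e.g. ``{"sex": "male"}``)
    or ``None`` for the overall trend.
    """
    sub = survey if factor == "smoking" else survey.dropna(subset=[factor])
    sub = with_age_group(sub)
    label = "overall"
    if stratum is not None:
        filt = (
            dict(zip(_STRATUM_COLS, stratum))
            if isinstance(stratum, tuple)
            else dict(stratum)
        )
        for colname, value in filt.items():
            sub = sub[sub[colname] == value]
        label = ",".join(f"{k}={v}" for k, v in filt.items())
    if factor == "smoking":
        sub = sub.dropna(subset=["smoking"])
    if sub["wave"].nunique() < 3:
        raise TrendError(
            f"trend test for {factor!r} ({label}) needs >= 3 waves with data, "
            f"found {sub['wave'].nunique()}"
        )
    y = _trend_response(sub, factor)
    Z = _covariate_design(sub, covariates)
    X = pd.concat(
        [
            pd.Series(1.0, index=sub.index, name="const"),
            sub["wave"].astype(float).rename("year"),
            Z,
        ],
        axis=1,
    )
    _check_rank(X)
    res = sm.OLS(y, X).fit(
        cov_type="cluster", cov_kwds={"groups": sub["id"]}, use_t=True
    )
    slope = float(res.params["year"])
    se = float(res.bse["year"])
    if se == 0.0 or not np.isfinite(se):
        pvalue = 0.0 if slope != 0.0 else 1.0
        se = max(se, 0.0) if np.isfinite(se) else 0.0
    else:
        pvalue = float(res.pvalues["year"])
    return TrendResult(
        factor=factor,
        stratum=label,
        slope=slope,
        se=se,
        pvalue=pvalue,
        n_obs=int(len(sub)),
        n_individuals=int(sub["id"].nunique()),
    )
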