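"""Synthetic open-cohort survey data with CHNS-like statistical structure.

The real China Health and Nutrition Survey microdata require registration, so
every downstream stage here is exercised on a generated cohort that reproduces
the statistical features the analysis relies on:

* an open cohort over eight waves (1991-2011) with staggered entry and
  absorbing dropout, so a sizeable subset of individuals completes >= 3 waves;
* person-level exposure trajectories -- stratum baseline + calendar-period
  slope + person-specific random intercept/slope + per-wave noise -- for SBP,
  DBP and BMI;
* smoking as a per-stratum-per-wave multinomial over {never, former, current}
  with monotone individual transitions (quitting allowed, re-uptake not);
* a blood panel (TG, HDL-C, glucose) measured in a single wave only;
* a census reference table over the 16 joint age x sex x residence strata.

The default configuration is calibrated to the published 1991-2011 Chinese
adult trajectories: census-standardized means track 115->125 mm Hg (SBP),
74->79 mm Hg (DBP) and 21.67->23.92 kg/m^2 (BMI), and joint smoking
prevalences are raked to the published subgroup series (e.g. 66.7% of men
currently smoking in 1991, declining to 52.7% by 2011).

A design note on ageing: each person's trajectory carries the baseline of the
stratum they *entered* in, plus the calendar-period slope anchored at the
first study wave.  Ages still advance between waves (and standardization uses
age at wave), but individual trajectories contain no age-gradient jumps, so
fitted individual slopes estimate the period trend -- the quantity the
projection stage extrapolates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .standardization import (
    AGE_GROUPS,
    ALL_STRATA,
    RESIDENCES,
    SEXES,
    StratumKey,
)

WAVE_YEARS: tuple[int, ...] = (1991, 1993, 1997, 2000, 2004, 2006, 2009, 2011)
CONTINUOUS_FACTORS: tuple[str, ...] = ("sbp", "dbp", "bmi")
SMOKING_CATEGORIES: tuple[str, ...] = ("never", "former", "current")

#: Total adults in the 2010 Chinese Population Census.
CENSUS_TOTAL_2010: int = 846_662_309

#: Approximate adult marginal shares of the 2010 census used to build the
#: default joint reference table (joint cells are products of marginals).
CENSUS_AGE_SHARES: dict[str, float] = {
    "18-39": 0.44,
    "40-59": 0.365,
    "60-69": 0.11,
    "70+": 0.085,
}
CENSUS_MALE_SHARE: float = 0.51
CENSUS_URBAN_SHARE: float = 0.50

#: Age range (inclusive) sampled for entrants in each age group.
_AGE_RANGES: dict[str, tuple[int, int]] = {
    "18-39": (18, 39),
    "40-59": (40, 59),
    "60-69": (60, 69),
    "70+": (70, 84),
}

# ---------------------------------------------------------------------------
# published subgroup trajectories used as calibration targets
# ---------------------------------------------------------------------------
# Continuous factors: subgroup means at the first (1991) and last (2011) wave;
# keys are the marginal levels of sex, age group and residence.

_MARGINAL_1991 = {
    "sbp": {"male": 116, "female": 112, "18-39": 109, "40-59": 117,
            "60-69": 127, "70+": 133, "urban": 115, "rural": 113},
    "dbp": {"male": 76, "female": 73, "18-39": 72, "40-59": 76,
            "60-69": 79, "70+": 81, "urban": 74, "rural": 74},
    "bmi": {"male": 21.8, "female": 22.3, "18-39": 21.8, "40-59": 22.5,
            "60-69": 22.1, "70+": 21.4, "urban": 22.2, "rural": 21.9},
}
_MARGINAL_2011 = {
    "sbp": {"male": 124, "female": 119, "18-39": 116, "40-59": 123,
            "60-69": 129, "70+": 129, "urban": 121, "rural": 122},
    "dbp": {"male": 80, "female": 77, "18-39": 76, "40-59": 80,
            "60-69": 80, "70+": 77, "urban": 78, "rural": 79},
    "bmi": {"male": 24.0, "female": 23.6, "18-39": 23.1, "40-59": 24.2,
            "60-69": 23.3, "70+": 23.8, "urban": 23.7, "rural": 23.8},
}

#: Standardized overall anchors for the continuous factors (1991, 2011).
OVERALL_ANCHORS: dict[str, tuple[float, float]] = {
    "sbp": (115.0, 125.0),
    "dbp": (74.0, 79.0),
    "bmi": (21.67, 23.92),
}

#: Current-smoking percentage by subgroup and wave (rows follow WAVE_YEARS).
_SMOKING_MARGINALS: dict[str, tuple[float, ...]] = {
    "male": (66.7, 64.4, 58.4, 58.6, 56.0, 53.5, 54.6, 52.7),
    "female": (4.3, 4.4, 4.2, 4.5, 4.0, 3.5, 3.6, 2.9),
    "18-39": (31.9, 30.6, 29.7, 28.9, 27.8, 26.0, 27.7, 24.3),
    "40-59": (37.6, 36.7, 35.7, 33.6, 31.9, 30.2, 30.0, 29.5),
    "60-69": (35.5, 34.5, 29.0, 28.4, 28.2, 27.5, 28.2, 24.7),
    "70+": (25.5, 25.5, 20.5, 23.1, 21.7, 18.5, 20.9, 21.7),
    "urban": (32.7, 32.2, 29.9, 28.9, 28.1, 26.9, 26.6, 24.7),
    "rural": (34.2, 33.1, 31.8, 31.0, 29.6, 27.5, 29.0, 27.7),
}

_PROVINCES = tuple(f"province_{i}" for i in range(1, 10))
_OCCUPATIONS = tuple(f"occ_{i}" for i in range(1, 6))
_EDUCATION_LEVELS = ("primary", "middle", "high", "college")

SURVEY_COLUMNS = [
    "id", "wave", "age", "sex", "residence", "province", "education",
    "occupation", "sbp", "dbp", "bmi", "smoking", "tg", "hdl", "glucose",
]


def _census_marginal_shares() -> dict[str, float]:
    shares: dict[str, float] = dict(CENSUS_AGE_SHARES)
    shares["male"] = CENSUS_MALE_SHARE
    shares["female"] = 1.0 - CENSUS_MALE_SHARE
    shares["urban"] = CENSUS_URBAN_SHARE
    shares["rural"] = 1.0 - CENSUS_URBAN_SHARE
    return shares


def census_stratum_shares() -> dict[StratumKey, float]:
    """Joint census shares as products of the marginal shares."""
    m = _census_marginal_shares()
    return {
        s: m[s.age_group] * m[s.sex] * m[s.residence] for s in ALL_STRATA
    }


@dataclass
class CohortConfig:
    """Full parameterization of the synthetic open cohort.

    Continuous exposure model for person i of entry stratum s at calendar
    year t:  x = baseline_mean[f][s] + annual_slope[f][s] * (t - t0)
               + b0_i + b1_i * (t - t0) + eps,
    with t0 the first study wave, b0 ~ N(0, between_intercept_sd^2),
    b1 ~ N(0, between_slope_sd^2) and eps ~ N(0, within_sd^2).
    """

    wave_years: tuple[int, ...] = WAVE_YEARS
    n_individuals: int = 12000
    stratum_proportions: dict[StratumKey, float] = field(default_factory=dict)
    baseline_mean: dict[str, dict[StratumKey, float]] = field(default_factory=dict)
    annual_slope: dict[str, dict[StratumKey, float]] = field(default_factory=dict)
    within_sd: dict[str, float] = field(default_factory=dict)
    between_intercept_sd: dict[str, float] = field(default_factory=dict)
    between_slope_sd: dict[str, float] = field(default_factory=dict)
    # smoking_prevalence[stratum][wave] -> {never, former, current} fractions
    smoking_prevalence: dict[StratumKey, dict[int, dict[str, float]]] = field(
        default_factory=dict
    )
    blood_panel_wave: int = 2009
    blood_panel: dict = field(default_factory=dict)
    # participation: probability the first observed wave is each study wave,
    # plus a per-wave retention probability after entry (dropout is absorbing)
    entry_probabilities: dict[int, float] = field(default_factory=dict)
    retention: float = 0.85
    census_total: int = CENSUS_TOTAL_2010
    # optional confounding switches (off by default): education level shifts
    # across entry cohorts and adds a centered effect to each factor
    education_effect: dict[str, float] = field(default_factory=dict)
    education_drift: float = 0.0
    seed: int = 0

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        years = tuple(self.wave_years)
        if any(b <= a for a, b in zip(years, years[1:])):
            raise ConfigError("wave_years must be strictly increasing")
        if self.n_individuals <= 0:
            raise ConfigError("n_individuals must be positive")
        props = np.array(
            [self.stratum_proportions.get(s, 0.0) for s in ALL_STRATA]
        )
        if np.any(props < 0):
            raise ConfigError("stratum_proportions contains negative values")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"stratum_proportions sum to {props.sum():.12f}, expected 1"
            )
        for name, table in (
            ("within_sd", self.within_sd),
            ("between_intercept_sd", self.between_intercept_sd),
            ("between_slope_sd", self.between_slope_sd),
        ):
            for factor, sd in table.items():
                if sd < 0:
                    raise ConfigError(f"{name}[{factor!r}] is negative")
        for factor in CONTINUOUS_FACTORS:
            if factor not in self.baseline_mean:
                raise ConfigError(f"baseline_mean missing factor {factor!r}")
        for s, by_wave in self.smoking_prevalence.items():
            for w, cats in by_wave.items():
                total = sum(cats.get(c, 0.0) for c in SMOKING_CATEGORIES)
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(
                        f"smoking_prevalence[{s}][{w}] sums to {total:.12f}"
                    )
                if any(cats.get(c, 0.0) < 0 for c in SMOKING_CATEGORIES):
                    raise ConfigError(
                        f"smoking_prevalence[{s}][{w}] has negative fractions"
                    )
        if self.blood_panel_wave not in years:
            raise ConfigError(
                f"blood_panel_wave {self.blood_panel_wave} not in wave_years"
            )
        ep = np.array([self.entry_probabilities.get(w, 0.0) for w in years])
        if np.any(ep < 0) or abs(ep.sum() - 1.0) > 1e-9:
            raise ConfigError("entry_probabilities must be non-negative and sum to 1")
        if not (0.0 <= self.retention <= 1.0):
            raise ConfigError("retention must lie in [0, 1]")
        if self.census_total <= 0:
            raise ConfigError("census_total must be positive")

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def skey(s: StratumKey) -> str:
            return "|".join(s)

        return {
            "wave_years": list(self.wave_years),
            "n_individuals": self.n_individuals,
            "stratum_proportions": {
                skey(s): v for s, v in self.stratum_proportions.items()
            },
            "baseline_mean": {
                f: {skey(s): v for s, v in d.items()}
                for f, d in self.baseline_mean.items()
            },
            "annual_slope": {
                f: {skey(s): v for s, v in d.items()}
                for f, d in self.annual_slope.items()
            },
            "within_sd": dict(self.within_sd),
            "between_intercept_sd": dict(self.between_intercept_sd),
            "between_slope_sd": dict(self.between_slope_sd),
            "smoking_prevalence": {
                skey(s): {int(w): dict(c) for w, c in by_wave.items()}
                for s, by_wave in self.smoking_prevalence.items()
            },
            "blood_panel_wave": self.blood_panel_wave,
            "blood_panel": dict(self.blood_panel),
            "entry_probabilities": {
                int(w): v for w, v in self.entry_probabilities.items()
            },
            "retention": self.retention,
            "census_total": self.census_total,
            "education_effect": dict(self.education_effect),
            "education_drift": self.education_drift,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "CohortConfig":
        def sk(key: str) -> StratumKey:
            return StratumKey(*key.split("|"))

        return cls(
            wave_years=tuple(data["wave_years"]),
            n_individuals=int(data["n_individuals"]),
            stratum_proportions={
                sk(k): float(v) for k, v in data["stratum_proportions"].items()
            },
            baseline_mean={
                f: {sk(k): float(v) for k, v in d.items()}
                for f, d in data["baseline_mean"].items()
            },
            annual_slope={
                f: {sk(k): float(v) for k, v in d.items()}
                for f, d in data["annual_slope"].items()
            },
            within_sd={k: float(v) for k, v in data["within_sd"].items()},
            between_intercept_sd={
                k: float(v) for k, v in data["between_intercept_sd"].items()
            },
            between_slope_sd={
                k: float(v) for k, v in data["between_slope_sd"].items()
            },
            smoking_prevalence={
                sk(k): {
                    int(w): {c: float(x) for c, x in cats.items()}
                    for w, cats in by_wave.items()
                }
                for k, by_wave in data["smoking_prevalence"].items()
            },
            blood_panel_wave=int(data["blood_panel_wave"]),
            blood_panel=dict(data["blood_panel"]),
            entry_probabilities={
                int(w): float(v) for w, v in data["entry_probabilities"].items()
            },
            retention=float(data["retention"]),
            census_total=int(data["census_total"]),
            education_effect={
                k: float(v) for k, v in data.get("education_effect", {}).items()
            },
            education_drift=float(data.get("education_drift", 0.0)),
            seed=int(data["seed"]),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(text))

    # -- convenience: config-implied standardized summaries ----------------

    def implied_standardized_mean(self, factor: str, wave: int) -> float:
        """Census-weighted mean implied by the configured baselines/slopes."""
        shares = census_stratum_shares()
        t = wave - self.wave_years[0]
        return sum(
            w * (self.baseline_mean[factor][s] + self.annual_slope[factor][s] * t)
            for s, w in shares.items()
        )

    def implied_smoking_marginal(self, level: str, wave: int) -> float:
        """Census-weighted current-smoking fraction in one marginal subgroup."""
        shares = census_stratum_shares()
        sel = {s: w for s, w in shares.items() if level in s}
        total = sum(sel.values())
        return (
            sum(
                w * self.smoking_prevalence[s][wave]["current"]
                for s, w in sel.items()
            )
            / total
        )


# ---------------------------------------------------------------------------
# default (calibrated) configuration
# ---------------------------------------------------------------------------


def _additive_joint_means(factor: str, table: dict[str, float], anchor: float
                          ) -> dict[StratumKey, float]:
    """Joint stratum means: additive in the subgroup deviations, shifted so the
    census-weighted overall equals ``anchor`` exactly."""
    m = _census_marginal_shares()
    mean_sex = m["male"] * table["male"] + m["female"] * table["female"]
    mean_res = m["urban"] * table["urban"] + m["rural"] * table["rural"]
    raw = {
        s: table[s.age_group]
        + (table[s.sex] - mean_sex)
        + (table[s.residence] - mean_res)
        for s in ALL_STRATA
    }
    shares = census_stratum_shares()
    shift = anchor - sum(shares[s] * raw[s] for s in ALL_STRATA)
    return {s: raw[s] + shift for s in ALL_STRATA}


def _rake_smoking(wave_index: int) -> dict[StratumKey, float]:
    """Joint current-smoking prevalence raked (IPF) to the published subgroup
    series for one wave, under the census joint weights.

    The published sex, age and residence series are not mutually consistent
    under census weights (they were tabulated on the survey sample), so the
    age and residence target vectors are rescaled to the overall prevalence
    implied by the sex split; the sex marginals are then matched exactly.
    """
    m = _census_marginal_shares()
    shares = census_stratum_shares()
    targets = {
        level: _SMOKING_MARGINALS[level][wave_index] / 100.0
        for level in _SMOKING_MARGINALS
    }
    overall = m["male"] * targets["male"] + m["female"] * targets["female"]
    for levels in (AGE_GROUPS, RESIDENCES):
        implied = sum(m[l] * targets[l] for l in levels)
        for l in levels:
            targets[l] *= overall / implied
    q = {s: targets[s.sex] for s in ALL_STRATA}  # start from the sex split
    margins = (
        [("age_group", g) for g in AGE_GROUPS]
        + [("sex", x) for x in SEXES]
        + [("residence", r) for r in RESIDENCES]
    )
    for _ in range(200):
        max_rel = 0.0
        for dim, level in margins:
            members = [s for s in ALL_STRATA if getattr(s, dim) == level]
            w_tot = sum(shares[s] for s in members)
            current = sum(shares[s] * q[s] for s in members) / w_tot
            ratio = targets[level] / current
            max_rel = max(max_rel, abs(ratio - 1.0))
            for s in members:
                q[s] = min(0.98, max(1e-4, q[s] * ratio))
        if max_rel < 1e-10:
            break
    return q


def default_config(n_individuals: int = 12000, seed: int = 0) -> CohortConfig:
    """The calibrated default cohort configuration.

    Stratum baselines and slopes reproduce the published subgroup structure
    and the standardized overall series (SBP 115->125 mm Hg, DBP 74->79 mm Hg,
    BMI 21.67->23.92 kg/m^2 over 1991-2011); joint smoking prevalences are
    raked to the published subgroup percentages wave by wave.  Blood-panel
    threshold exceedances default to the fractions implied by the published
    attributable fractions (TG>1.7: 25%; glucose>5.6: 4%; low HDL-C: ~13%).
    """
    span = WAVE_YEARS[-1] - WAVE_YEARS[0]
    baseline: dict[str, dict[StratumKey, float]] = {}
    slope: dict[str, dict[StratumKey, float]] = {}
    for f in CONTINUOUS_FACTORS:
        lo, hi = OVERALL_ANCHORS[f]
        b1991 = _additive_joint_means(f, _MARGINAL_1991[f], lo)
        b2011 = _additive_joint_means(f, _MARGINAL_2011[f], hi)
        baseline[f] = b1991
        slope[f] = {s: (b2011[s] - b1991[s]) / span for s in ALL_STRATA}

    former_ratio = 0.20  # former smokers as a fraction of current, at entry
    smoking: dict[StratumKey, dict[int, dict[str, float]]] = {
        s: {} for s in ALL_STRATA
    }
    for wi, wave in enumerate(WAVE_YEARS):
        q = _rake_smoking(wi)
        for s in ALL_STRATA:
            cur = q[s]
            former = min(former_ratio * cur, 1.0 - cur)
            smoking[s][wave] = {
                "never": 1.0 - cur - former,
                "former": former,
                "current": cur,
            }

    entry = {w: 0.55 / (len(WAVE_YEARS) - 1) for w in WAVE_YEARS[1:]}
    entry[WAVE_YEARS[0]] = 1.0 - sum(entry.values())

    return CohortConfig(
        wave_years=WAVE_YEARS,
        n_individuals=n_individuals,
        stratum_proportions=census_stratum_shares(),
        baseline_mean=baseline,
        annual_slope=slope,
        within_sd={"sbp": 8.0, "dbp": 6.0, "bmi": 1.0},
        between_intercept_sd={"sbp": 10.0, "dbp": 7.0, "bmi": 2.8},
        between_slope_sd={"sbp": 0.15, "dbp": 0.10, "bmi": 0.04},
        smoking_prevalence=smoking,
        blood_panel_wave=2009,
        blood_panel={
            "tg_median": 1.2,
            "tg_log_sigma": 0.517,
            "glucose_median": 4.9,
            "glucose_log_sigma": 0.0763,
            "hdl_mean_male": 1.30,
            "hdl_mean_female": 1.40,
            "hdl_sd_male": 0.30,
            "hdl_sd_female": 0.28,
        },
        entry_probabilities=entry,
        retention=0.85,
        census_total=CENSUS_TOTAL_2010,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_census(config: CohortConfig | None = None) -> pd.DataFrame:
    """Census reference table over the 16 joint strata.

    Counts are products of the marginal shares scaled to the configured total
    (default 846,662,309 adults), with integer rounding absorbed by the first
    stratum so the total is exact.
    """
    total = config.census_total if config is not None else CENSUS_TOTAL_2010
    if total <= 0:
        raise ConfigError("census_total must be positive")
    shares = census_stratum_shares()
    rows = []
    counts = []
    for s in ALL_STRATA:
        counts.append(int(round(shares[s] * total)))
    counts[0] += total - sum(counts)
    for s, c in zip(ALL_STRATA, counts):
        rows.append({"age_group": s.age_group, "sex": s.sex,
                     "residence": s.residence, "count": c})
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the open-cohort survey table for one seeded configuration.

    The output is one row per person-wave (present individuals only), sorted
    by id then wave, and is byte-identical for identical configurations.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    waves = np.array(config.wave_years)
    n_waves = len(waves)
    t = (waves - waves[0]).astype(float)

    strata = list(ALL_STRATA)
    props = np.array([config.stratum_proportions.get(s, 0.0) for s in strata])
    stratum_idx = rng.choice(len(strata), size=n, p=props)

    entry_p = np.array([config.entry_probabilities.get(int(w), 0.0) for w in waves])
    entry_idx = rng.choice(n_waves, size=n, p=entry_p)

    # ages at entry, uniform over the entry stratum's range; advance by gaps
    lo = np.array([_AGE_RANGES[strata[i].age_group][0] for i in stratum_idx])
    hi = np.array([_AGE_RANGES[strata[i].age_group][1] for i in stratum_idx])
    entry_age = rng.integers(lo, hi + 1)

    # presence: at entry and then surviving each retention draw; dropout is
    # absorbing (an individual absent at one wave never returns)
    u = rng.random((n, n_waves))
    present = np.zeros((n, n_waves), dtype=bool)
    for w in range(n_waves):
        entering = entry_idx == w
        present[entering, w] = True
        if w > 0:
            cont = (entry_idx < w) & present[:, w - 1] & (u[:, w] < config.retention)
            present[cont, w] = True

    # continuous exposures
    values: dict[str, np.ndarray] = {}
    for f in CONTINUOUS_FACTORS:
        base = np.array([config.baseline_mean[f][s] for s in strata])[stratum_idx]
        slp = np.array([config.annual_slope[f][s] for s in strata])[stratum_idx]
        b0 = rng.normal(0.0, config.between_intercept_sd.get(f, 0.0), n)
        b1 = rng.normal(0.0, config.between_slope_sd.get(f, 0.0), n)
        eps = rng.normal(0.0, config.within_sd.get(f, 0.0), (n, n_waves))
        values[f] = (
            base[:, None]
            + slp[:, None] * t[None, :]
            + b0[:, None]
            + b1[:, None] * t[None, :]
            + eps
        )

    # smoking trajectories: initial category at entry from the entry stratum's
    # prevalence at the entry wave; thereafter current smokers persist with
    # probability min(1, p_t / p_{t-1}) and otherwise quit (become former)
    p_cur = np.zeros((n, n_waves))
    p_for = np.zeros((n, n_waves))
    for si, s in enumerate(strata):
        mask = stratum_idx == si
        for wi, wave in enumerate(waves):
            cats = config.smoking_prevalence[s][int(wave)]
            p_cur[mask, wi] = cats["current"]
            p_for[mask, wi] = cats["former"]
    smoke = np.empty((n, n_waves), dtype=object)
    u_init = rng.random(n)
    u_quit = rng.random((n, n_waves))
    pe_cur = p_cur[np.arange(n), entry_idx]
    pe_for = p_for[np.arange(n), entry_idx]
    init = np.where(
        u_init < pe_cur, "current", np.where(u_init < pe_cur + pe_for, "former", "never")
    )
    state = init.copy()
    for w in range(n_waves):
        fresh = entry_idx == w
        state[fresh] = init[fresh]
        if w > 0:
            ongoing = entry_idx < w
            with np.errstate(divide="ignore", invalid="ignore"):
                keep = np.where(p_cur[:, w - 1] > 0, p_cur[:, w] / p_cur[:, w - 1], 0.0)
            keep = np.clip(keep, 0.0, 1.0)
            quits = ongoing & (state == "current") & (u_quit[:, w] >= keep)
            state[quits] = "former"
        smoke[:, w] = state

    # blood panel (single wave)
    bp = config.blood_panel
    blood_wi = int(np.where(waves == config.blood_panel_wave)[0][0])
    tg = np.exp(
        rng.normal(np.log(bp.get("tg_median", 1.2)), bp.get("tg_log_sigma", 0.5), n)
    )
    glucose = np.exp(
        rng.normal(
            np.log(bp.get("glucose_median", 4.9)),
            bp.get("glucose_log_sigma", 0.08),
            n,
        )
    )
    sex_arr = np.array([strata[i].sex for i in stratum_idx])
    hdl_mean = np.where(
        sex_arr == "male", bp.get("hdl_mean_male", 1.30), bp.get("hdl_mean_female", 1.40)
    )
    hdl_sd = np.where(
        sex_arr == "male", bp.get("hdl_sd_male", 0.30), bp.get("hdl_sd_female", 0.28)
    )
    hdl = np.maximum(rng.normal(hdl_mean, hdl_sd), 0.3)

    # fixed person-level labels
    province = rng.choice(np.array(_PROVINCES, dtype=object), size=n)
    occupation = rng.choice(np.array(_OCCUPATIONS, dtype=object), size=n)
    # education: ordinal 0..3; under drift, later entrants are more educated
    drift = config.education_drift
    p_edu = np.clip(0.35 + drift * t[entry_idx] / max(t[-1], 1.0), 0.01, 0.99)
    edu_level = rng.binomial(3, p_edu)
    education = np.array(_EDUCATION_LEVELS, dtype=object)[edu_level]
    if config.education_effect:
        centered = edu_level - edu_level.mean()
        for f, beta in config.education_effect.items():
            values[f] = values[f] + beta * centered[:, None]

    # enforce physical row invariants
    values["dbp"] = np.minimum(values["dbp"], values["sbp"] - 1.0)
    values["bmi"] = np.maximum(values["bmi"], 12.0)

    ids, wave_pos = np.nonzero(present)
    frame = pd.DataFrame(
        {
            "id": ids + 1,
            "wave": waves[wave_pos],
            "age": entry_age[ids] + (t[wave_pos] - t[entry_idx[ids]]).astype(int),
            "sex": sex_arr[ids],
            "residence": np.array([strata[i].residence for i in stratum_idx])[ids],
            "province": province[ids],
            "education": education[ids],
            "occupation": occupation[ids],
            "sbp": values["sbp"][ids, wave_pos],
            "dbp": values["dbp"][ids, wave_pos],
            "bmi": values["bmi"][ids, wave_pos],
            "smoking": smoke[ids, wave_pos],
        }
    )
    is_blood = frame["wave"].to_numpy() == config.blood_panel_wave
    frame["tg"] = np.where(is_blood, tg[ids], np.nan)
    frame["hdl"] = np.where(is_blood, hdl[ids], np.nan)
    frame["glucose"] = np.where(is_blood, glucose[ids], np.nan)
    frame = frame.sort_values(["id", "wave"], kind="mergesort").reset_index(drop=True)
    return frame[SURVEY_COLUMNS]


def entry_stratum_table(survey: pd.DataFrame) -> pd.DataFrame:
    """Each individual's stratum at their first observed wave.

    Returns a frame indexed by id with columns age_group, sex, residence.
    """
    first = survey.sort_values(["id", "wave"]).groupby("id").first()
    from .standardization import with_age_group

    tagged = with_age_group(first.reset_index())
    return tagged.set_index("id")[["age_group", "sex", "residence"]]


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

_CSV_KWARGS = dict(index=False, float_format="%.10g", lineterminator="\n")


def write_survey(survey: pd.DataFrame, path) -> None:
    survey.to_csv(path, **_CSV_KWARGS)


def read_survey(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df[SURVEY_COLUMNS]


def write_census(census: pd.DataFrame, path) -> None:
    census.to_csv(path, **_CSV_KWARGS)


def read_census(path) -> pd.DataFrame:
    return pd.read_csv(path)
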