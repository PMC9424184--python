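"""Risk-factor registry: TMREDs, relative risks, and sampling rules.

Each modifiable risk factor carries either a log-linear dose-response per
exposure increment above a theoretical-minimum-risk exposure distribution
(TMRED; continuous factors) or per-category relative risks against a
reference category (categorical factors).  The seven built-in factors are the
standard comparative-risk-assessment set for chronic kidney disease in the
Chinese adult population:

=============  ============  =====================  ====================
factor         kind          TMRED / reference      RR (95% CI)
=============  ============  =====================  ====================
bmi            continuous    21 (1) kg/m^2          1.02 (1.01-1.03) per kg/m^2
sbp            continuous    115 (6) mm Hg          1.08 (1.04-1.11) per 10 mm Hg
dbp            continuous    75 (6) mm Hg           1.12 (1.04-1.20) per 10 mm Hg
smoking        categorical   never smoking          former 1.27 (1.19-1.35),
                                                    current 1.34 (1.23-1.47)
tg             categorical   TG <= 1.7 mmol/L       >1.7: 1.32 (1.15-1.51)
hdl            categorical   HDL-C above threshold  low: 1.24 (1.04-1.47)
                             (F 0.9 / M 1.1 mmol/L)
glucose        categorical   glucose <= 5.6 mmol/L  >5.6: 1.89 (1.51-2.37)
=============  ============  =====================  ====================

Relative risks below the TMRED mean are floored at 1: the TMRED is treated as
the minimum-risk level and no protective extrapolation is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DomainError

#: half-width of a 95% interval in standard-normal units
_Z95 = 1.96


@dataclass(frozen=True)
class CategoryRisk:
    """Relative risk of one exposure category with its 95% CI."""

    rr: float
    ci_low: float
    ci_high: float
    reference: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.rr <= self.ci_high):
            raise DomainError(
                f"category RR must satisfy 0 < low <= point <= high, "
                f"got ({self.ci_low}, {self.rr}, {self.ci_high})"
            )
        if self.reference and self.rr != 1.0:
            raise DomainError("reference category must have RR exactly 1")

    @property
    def log_sigma(self) -> float:
        return (np.log(self.ci_high) - np.log(self.ci_low)) / (2 * _Z95)


@dataclass(frozen=True)
class RiskFactorSpec:
    """One risk factor's TMRED and relative-risk parameterization."""

    name: str
    kind: str  # "continuous" | "categorical"
    source: str  # survey column carrying the raw exposure
    # continuous factors
    tmred_mean: float | None = None
    tmred_sd: float | None = None
    unit_increment: float | None = None
    rr: float | None = None
    rr_ci: tuple[float, float] | None = None
    # categorical factors
    categories: Mapping[str, CategoryRisk] = field(default_factory=dict)
    # threshold classification of a continuous measurement into categories;
    # a mapping gives sex-specific thresholds (low HDL-C)
    threshold: float | Mapping[str, float] | None = None
    harmful_direction: str | None = None  # "above" | "below"

    def __post_init__(self) -> None:
        if self.kind == "continuous":
            if self.tmred_sd is None or self.tmred_sd <= 0:
                raise DomainError(f"{self.name}: tmred_sd must be positive")
            if self.unit_increment is None or self.unit_increment <= 0:
                raise DomainError(f"{self.name}: unit_increment must be positive")
            lo, hi = self.rr_ci
            if not (0 < lo <= self.rr <= hi):
                raise DomainError(
                    f"{self.name}: RR CI must satisfy 0 < low <= point <= high"
                )
        elif self.kind == "categorical":
            refs = [c for c in self.categories.values() if c.reference]
            if len(refs) != 1:
                raise DomainError(
                    f"{self.name}: exactly one reference category required"
                )
        else:
            raise DomainError(f"unknown factor kind {self.kind!r}")

    @property
    def log_sigma(self) -> float:
        """Log-scale SD implied by the 95% CI of the per-unit RR."""
        lo, hi = self.rr_ci
        return (np.log(hi) - np.log(lo)) / (2 * _Z95)

    @property
    def reference_category(self) -> str:
        return next(k for k, c in self.categories.items() if c.reference)


def builtin_specs(two_category_smoking: bool = False) -> dict[str, RiskFactorSpec]:
    """The seven built-in risk-factor specifications, keyed by name.

    ``two_category_smoking=True`` drops the former-smoker category (current vs
    never only); the default three-category mode maps the ever-smoking RR to
    former smokers.
    """
    smoking_cats = {
        "never": CategoryRisk(1.0, 1.0, 1.0, reference=True),
        "current": CategoryRisk(1.34, 1.23, 1.47),
    }
    if not two_category_smoking:
        smoking_cats["former"] = CategoryRisk(1.27, 1.19, 1.35)
    specs = {
        "bmi": RiskFactorSpec(
            name="bmi", kind="continuous", source="bmi",
            tmred_mean=21.0, tmred_sd=1.0, unit_increment=1.0,
            rr=1.02, rr_ci=(1.01, 1.03),
        ),
        "sbp": RiskFactorSpec(
            name="sbp", kind="continuous", source="sbp",
            tmred_mean=115.0, tmred_sd=6.0, unit_increment=10.0,
            rr=1.08, rr_ci=(1.04, 1.11),
        ),
        "dbp": RiskFactorSpec(
            name="dbp", kind="continuous", source="dbp",
            tmred_mean=75.0, tmred_sd=6.0, unit_increment=10.0,
            rr=1.12, rr_ci=(1.04, 1.20),
        ),
        "smoking": RiskFactorSpec(
            name="smoking", kind="categorical", source="smoking",
            categories=smoking_cats,
        ),
        "tg": RiskFactorSpec(
            name="tg", kind="categorical", source="tg",
            categories={
                "normal": CategoryRisk(1.0, 1.0, 1.0, reference=True),
                "high": CategoryRisk(1.32, 1.15, 1.51),
            },
            threshold=1.7, harmful_direction="above",
        ),
        "hdl": RiskFactorSpec(
            name="hdl", kind="categorical", source="hdl",
            categories={
                "normal": CategoryRisk(1.0, 1.0, 1.0, reference=True),
                "low": CategoryRisk(1.24, 1.04, 1.47),
            },
            threshold={"female": 0.9, "male": 1.1}, harmful_direction="below",
        ),
        "glucose": RiskFactorSpec(
            name="glucose", kind="categorical", source="glucose",
            categories={
                "normal": CategoryRisk(1.0, 1.0, 1.0, reference=True),
                "high": CategoryRisk(1.89, 1.51, 2.37),
            },
            threshold=5.6, harmful_direction="above",
        ),
    }
    return specs


def rr_continuous(x, spec: RiskFactorSpec):
    """Relative risk at exposure level(s) ``x`` under a continuous spec.

    RR(x) = rr ** ((x - tmred_mean) / unit_increment) for x above the TMRED
    mean, floored at 1 below it (no protective extrapolation).  Accepts
    scalars or arrays.
    """
    if spec.kind != "continuous":
        raise TypeError(f"{spec.name} is categorical; use rr_category")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise DomainError("non-finite exposure value")
    z = np.maximum((x - spec.tmred_mean) / spec.unit_increment, 0.0)
    out = np.power(spec.rr, z)
    return float(out) if out.ndim == 0 else out


def rr_category(category: str, spec: RiskFactorSpec) -> float:
    """Relative risk of one category (1 for the reference)."""
    if spec.kind != "categorical":
        raise TypeError(f"{spec.name} is continuous; use rr_continuous")
    try:
        return spec.categories[category].rr
    except KeyError:
        raise DomainError(
            f"unknown category {category!r} for factor {spec.name!r}; "
            f"known: {sorted(spec.categories)}"
        ) from None


def classify_exposure(values, spec: RiskFactorSpec, sex=None) -> np.ndarray:
    """Classify raw continuous measurements into a categorical spec's classes.

    For sex-specific thresholds (low HDL-C: female < 0.9, male < 1.1 mmol/L)
    ``sex`` must be given, aligned with ``values``.
    """
    if spec.kind != "categorical" or spec.threshold is None:
        raise TypeError(f"{spec.name} has no threshold classification")
    values = np.asarray(values, dtype=float)
    if isinstance(spec.threshold, Mapping):
        if sex is None:
            raise DomainError(f"{spec.name}: sex required for classification")
        sex = np.asarray(sex, dtype=object)
        thr = np.array([spec.threshold[s] for s in sex], dtype=float)
    else:
        thr = np.full(values.shape, float(spec.threshold))
    harmful = next(k for k in spec.categories if k != spec.reference_category)
    if spec.harmful_direction == "above":
        exposed = values > thr
    else:
        exposed = values < thr
    return np.where(exposed, harmful, spec.reference_category)


def rr_draw(spec: RiskFactorSpec, rng: np.random.Generator, n: int = 1):
    """Sample relative risks from lognormal distributions matched to the CIs.

    log(RR) ~ Normal(log rr_point, sigma) with sigma = (log hi - log lo)/3.92.
    Continuous specs return an array of per-increment RRs of shape (n,);
    categorical specs return a dict of category -> array (reference all 1).
    """
    if spec.kind == "continuous":
        return np.exp(rng.normal(np.log(spec.rr), spec.log_sigma, size=n))
    draws = {}
    for cat, risk in spec.categories.items():
        if risk.reference or risk.log_sigma == 0.0:
            draws[cat] = np.full(n, risk.rr)
        else:
            draws[cat] = np.exp(rng.normal(np.log(risk.rr), risk.log_sigma, size=n))
    return draws
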