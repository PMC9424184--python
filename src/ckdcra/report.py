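"""End-to-end pipeline: simulate/load, standardize, attribute, project, report.

Outputs are delimited text tables (comma-separated, header row, UTF-8, empty
cells for missing values) plus a JSON run manifest carrying the seed, the
full configuration, and SHA-256 digests of every written table, so a rerun
with the same configuration is byte-identical and verifiable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import attribution, projection, standardization
from .errors import ConfigError
from .risk_model import builtin_specs
from .synthetic_data import (
    CohortConfig,
    default_config,
    generate_census,
    generate_cohort,
    read_census,
    read_survey,
)

log = logging.getLogger("ckdcra")

#: Factors with longitudinal measurements (trajectories and projection).
LONGITUDINAL_FACTORS = ("sbp", "dbp", "bmi", "smoking")
#: Blood-panel factors measured in a single wave and carried forward.
BLOOD_FACTORS = ("tg", "hdl", "glucose")

_CSV_KWARGS = dict(index=False, float_format="%.10g", lineterminator="\n")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    survey_path: str | None = None
    census_path: str | None = None
    cohort: CohortConfig | None = None
    prevalence: tuple[float, float, float] = (0.108, 0.102, 0.113)
    population: float | None = None  # default: census total
    n_draws: int = 2000
    seed: int = 0
    out_dir: str = "results"
    anchor_wave: int = 2011
    projection_years: tuple[int, ...] = tuple(range(2013, 2032, 2))
    two_category_smoking: bool = False

    def validate(self) -> None:
        p, lo, hi = self.prevalence
        if not (0 < lo <= p <= hi < 1):
            raise ConfigError("prevalence CI must bracket the point in (0, 1)")
        if self.n_draws < 1:
            raise ConfigError("n_draws must be >= 1")
        if self.population is not None and self.population <= 0:
            raise ConfigError("population must be positive")

    def to_dict(self) -> dict:
        return {
            "survey_path": self.survey_path,
            "census_path": self.census_path,
            "cohort": self.cohort.to_dict() if self.cohort else None,
            "prevalence": list(self.prevalence),
            "population": self.population,
            "n_draws": self.n_draws,
            "seed": self.seed,
            "out_dir": str(self.out_dir),
            "anchor_wave": self.anchor_wave,
            "projection_years": list(self.projection_years),
            "two_category_smoking": self.two_category_smoking,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        cohort = data.get("cohort")
        return cls(
            survey_path=data.get("survey_path"),
            census_path=data.get("census_path"),
            cohort=CohortConfig.from_dict(cohort) if cohort else None,
            prevalence=tuple(data.get("prevalence", (0.108, 0.102, 0.113))),
            population=data.get("population"),
            n_draws=int(data.get("n_draws", 2000)),
            seed=int(data.get("seed", 0)),
            out_dir=data.get("out_dir", "results"),
            anchor_wave=int(data.get("anchor_wave", 2011)),
            projection_years=tuple(
                data.get("projection_years", range(2013, 2032, 2))
            ),
            two_category_smoking=bool(data.get("two_category_smoking", False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_inputs(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    if config.survey_path:
        survey = read_survey(config.survey_path)
        census = (
            read_census(config.census_path)
            if config.census_path
            else generate_census()
        )
        return survey, census
    cohort = config.cohort or default_config(seed=config.seed)
    return generate_cohort(cohort), generate_census(cohort)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _timed(stage: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", stage, dt)
            else:
                log.error("stage %s: failed after %.2fs: %s", stage, dt, exc)
            return False

    return _Timer()


def trajectory_table(
    survey: pd.DataFrame, census: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardized per-wave exposure series and overall trend tests."""
    waves = sorted(survey["wave"].unique())
    rows = []
    trend_rows = []
    for factor in LONGITUDINAL_FACTORS:
        for wave in waves:
            if factor == "smoking":
                prev = standardization.standardized_prevalence(
                    survey, census, "smoking", wave
                )
                est = float(prev.loc["current", "fraction"])
                se = float(prev.loc["current", "se"])
            else:
                est, se = standardization.standardized_mean(
                    survey, census, factor, wave
                )
            rows.append({"factor": factor, "wave": wave, "estimate": est, "se": se})
        tr = standardization.trend_test(survey, factor)
        trend_rows.append(
            {
                "factor": factor,
                "stratum": tr.stratum,
                "slope_per_year": tr.slope,
                "se": tr.se,
                "p_for_trend": tr.pvalue,
                "n_obs": tr.n_obs,
                "n_individuals": tr.n_individuals,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(trend_rows)


def attribution_table(
    survey: pd.DataFrame,
    census: pd.DataFrame,
    config: RunConfig,
    population: float,
) -> pd.DataFrame:
    """PAF and attributable burden per factor at the anchor year.

    Blood-panel factors are evaluated at their measurement wave and carried
    forward to the anchor year.  Case counts are reported unrounded and in
    display-rounded millions; factors are reported separately and never
    summed (attributable cases of correlated factors overlap).
    """
    specs = builtin_specs(two_category_smoking=config.two_category_smoking)
    blood_wave = int(
        survey.loc[survey["tg"].notna(), "wave"].iloc[0]
        if survey["tg"].notna().any()
        else config.anchor_wave
    )
    rows = []
    for fi, name in enumerate(LONGITUDINAL_FACTORS + BLOOD_FACTORS):
        spec = specs[name]
        wave = blood_wave if name in BLOOD_FACTORS else config.anchor_wave
        paf_est, burden = attribution.burden_with_ci(
            survey, census, spec, wave, config.prevalence, population,
            n_draws=config.n_draws, seed=config.seed * 1000 + fi,
        )
        rows.append(
            {
                "factor": name,
                "exposure_wave": wave,
                "burden_year": config.anchor_wave,
                "paf": paf_est.paf,
                "paf_ci_low": paf_est.ci_low,
                "paf_ci_high": paf_est.ci_high,
                "paf_pct_display": round(100 * paf_est.paf, 1),
                "total_cases": burden.total_cases,
                "attributable_cases": burden.attributable_cases,
                "cases_ci_low": burden.ci_low,
                "cases_ci_high": burden.ci_high,
                "cases_million_display": round(burden.attributable_cases / 1e6, 1),
            }
        )
    return pd.DataFrame(rows)


def wave_paf_table(
    survey: pd.DataFrame,
    census: pd.DataFrame,
    config: RunConfig,
    population: float,
) -> pd.DataFrame:
    """Per-wave PAFs of the longitudinal factors, with the anchor-year case
    total applied to every wave."""
    specs = builtin_specs(two_category_smoking=config.two_category_smoking)
    total = attribution.total_cases(config.prevalence[0], population)
    waves = sorted(survey["wave"].unique())
    frames = []
    for name in LONGITUDINAL_FACTORS:
        pafs = {
            w: attribution.paf_point(survey, census, specs[name], w) for w in waves
        }
        series = attribution.attributable_series(pafs, total)
        series.insert(0, "factor", name)
        frames.append(series)
    return pd.concat(frames, ignore_index=True)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Writes trajectories.csv, trends.csv, attribution.csv, attribution_by_wave
    .csv, projection.csv, survey.csv, census.csv and manifest.json under
    ``config.out_dir``; returns the tables and the manifest in memory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with _timed("inputs"):
        survey, census = _load_inputs(config)
        population = (
            config.population
            if config.population is not None
            else float(census["count"].sum())
        )
    with _timed("trajectories"):
        traj, trends = trajectory_table(survey, census)
    with _timed("attribution"):
        attr = attribution_table(survey, census, config, population)
        by_wave = wave_paf_table(survey, census, config, population)
    with _timed("projection"):
        specs = builtin_specs(two_category_smoking=config.two_category_smoking)
        proj_specs = {f: specs[f] for f in LONGITUDINAL_FACTORS}
        years = (config.anchor_wave,) + tuple(config.projection_years)
        proj = projection.projected_burden(
            survey, census, proj_specs, years, config.prevalence, population,
            anchor_wave=config.anchor_wave, n_draws=config.n_draws,
            seed=config.seed,
        )
        for _, row in proj.iterrows():
            if row["paf"] <= 0:
                log.warning(
                    "non-positive PAF for %s in %d", row["factor"], row["year"]
                )

    tables = {
        "survey.csv": survey,
        "census.csv": census,
        "trajectories.csv": traj,
        "trends.csv": trends,
        "attribution.csv": attr,
        "attribution_by_wave.csv": by_wave,
        "projection.csv": proj,
    }
    digests = {}
    for fname, frame in tables.items():
        path = out / fname
        frame.to_csv(path, **_CSV_KWARGS)
        digests[fname] = _sha256(path)

    try:
        pkg_version = version("ckdcra")
    except PackageNotFoundError:  # running from a source tree
        pkg_version = "unknown"
    manifest = {
        "package": "ckdcra",
        "version": pkg_version,
        "seed": config.seed,
        "config": config.to_dict(),
        "population": population,
        "outputs": digests,
        "n_survey_rows": int(len(survey)),
        "n_individuals": int(survey["id"].nunique()),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    manifest["manifest_path"] = str(manifest_path)
    return {"tables": tables, "manifest": manifest, "out_dir": str(out)}
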