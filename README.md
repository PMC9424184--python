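# ckdcra

Comparative risk assessment (CRA) of modifiable risk factors for the chronic
kidney disease (CKD) burden in the Chinese adult population: standardized
exposure trajectories over a 1991–2011 open-cohort survey, population-
attributable fractions (PAFs) against theoretical-minimum-risk
counterfactuals, attributable case counts with Monte-Carlo confidence
intervals, and 20-year projections.

The package is aimed at epidemiologists and biostatisticians who want a
tested, reproducible implementation of the GBD-style CRA machinery for a
longitudinal survey — or who need a calibrated synthetic cohort to exercise
such a pipeline without access to restricted microdata.

## The model

For a categorical exposure with population fractions `Pᵢ` and relative risks
`RRᵢ` (reference category `RR = 1`):

    PAF = Σᵢ Pᵢ(RRᵢ − 1) / (Σᵢ Pᵢ(RRᵢ − 1) + 1)

For a continuous exposure with population distribution `P₁(x)`, counterfactual
TMRED distribution `P₂(x)` and maximum observed level `m`:

    PAF = (∫₀ᵐ RR(x)P₁(x)dx − ∫₀ᵐ RR(x)P₂(x)dx) / ∫₀ᵐ RR(x)P₁(x)dx

with a log-linear dose-response `RR(x) = rr^((x − tmred)/unit)` floored at 1
below the TMRED mean. Attributable cases are `PAF × (prevalence × census
population)`. Seven factors are built in (TMRED, RR per unit or category):
BMI 21 (1) kg/m², 1.02/kg/m²; SBP 115 (6) mm Hg, 1.08/10 mm Hg; DBP 75 (6)
mm Hg, 1.12/10 mm Hg; smoking (never reference; former 1.27, current 1.34);
TG > 1.7 mmol/L, 1.32; low HDL-C (< 0.9 F / < 1.1 M mmol/L), 1.24; glucose
> 5.6 mmol/L, 1.89.

Exposure distributions are directly standardized to the 2010 census over the
16 joint age × sex × residence strata; secular trends are tested with
calendar year as a scored regressor (cluster-robust by person); projections
fit per-stratum two-stage random-effects slopes among individuals with ≥ 3
surveys and carry the 2011 standardized distribution forward. The methods
note in `docs/methods.md` documents every modelling choice.

## Worked example

```python
import ckdcra

cfg = ckdcra.default_config(n_individuals=20000, seed=1)
survey = ckdcra.generate_cohort(cfg)          # open cohort, 8 waves 1991-2011
census = ckdcra.generate_census(cfg)          # 16 strata, 846,662,309 adults
population = float(census["count"].sum())

total = ckdcra.total_cases(0.108, population)
sbp91, se91 = ckdcra.standardized_mean(survey, census, "sbp", 1991)
sbp11, se11 = ckdcra.standardized_mean(survey, census, "sbp", 2011)
trend = ckdcra.trend_test(survey, "smoking", {"sex": "male"})

spec = ckdcra.builtin_specs()["sbp"]
paf, burden = ckdcra.burden_with_ci(
    survey, census, spec, 2011, (0.108, 0.102, 0.113), population,
    n_draws=2000, seed=1)
proj = ckdcra.projected_burden(
    survey, census, {"sbp": spec}, [2031], (0.108, 0.102, 0.113), population,
    n_draws=2000, seed=1)
```

which prints (formatted):

```
total CKD cases 2011: 91.4 million
standardized SBP: 114.9 (SE 0.14) in 1991 -> 123.0 (SE 0.15) in 2011
male current smoking: slope -0.70 pp/year, p = 1.9e-49
high SBP in 2011: PAF 6.3% (3.7-9.1), 5.8 million cases (3.3-8.3)
projected SBP 2031: 133.1 mm Hg, PAF 12.3%, 11.2 million cases
```

Reading: at a CKD prevalence of 10.8%, the 2010 adult census implies 91.4
million cases. On the calibrated synthetic cohort the standardized SBP mean
rises ~8 mm Hg over 1991–2011 while male current smoking falls ~0.7
percentage points per year; 6.3% of 2011 CKD cases (5.8 million) are
attributable to SBP above its theoretical minimum of 115 mm Hg, and the
fitted individual-level trends project the standardized SBP mean to
133 mm Hg by 2031 with a correspondingly larger attributable burden.

## Command line

A `ckdcra` console script exposes the stages individually: `simulate`
(synthetic survey + census), `standardize`, `trends`, `attribute`, `project`
and `report` (the full pipeline: trajectory, attribution and projection
tables plus a JSON manifest with seeds and SHA-256 output digests; reruns at
a fixed seed are byte-identical). `ckdcra report --validate` checks a YAML
run configuration without running it.

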