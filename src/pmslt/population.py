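"""Synthetic parameter bundles for the life-table model.

The model is parameterised for a closed adult population stratified by sex
(male/female), ethnicity (Māori/non-Māori) and single year of age at the 2011
baseline.  Real national input schedules (mortality, morbidity, BMI, disease
epidemiology, costs) are not distributed, so this module generates an
internally consistent synthetic stand-in with the same structure and the
qualitative features the analysis relies on:

* Gompertz all-cause mortality rising with age, higher for men, and higher
  for Māori than non-Māori by a configurable gap factor;
* mean BMI higher for Māori than non-Māori;
* 14 BMI-related diseases (coronary heart disease, stroke, type 2 diabetes,
  osteoarthritis and ten cancers) with age-increasing incidence, case
  fatality, remission for cancers only, log-linear relative risks per BMI
  unit that attenuate with age, and per-phase treatment costs (first year of
  illness, subsequent years, last six months of life).

Everything is deterministic given ``(seed, config)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

SEXES = ("male", "female")
ETHNICITIES = ("maori", "non_maori")
AGE_MIN = 18

__all__ = [
    "SEXES",
    "ETHNICITIES",
    "AGE_MIN",
    "DISEASES",
    "CANCERS",
    "GeneratorConfig",
    "ParameterBundle",
    "generate_bundle",
    "validate_bundle",
]


@dataclass(frozen=True)
class DiseaseDef:
    """Static template for one disease used by the generator.

    Rates are at age 18 with exponential age slopes (per year); ``rr`` is the
    relative risk per 1 kg/m² of BMI before age attenuation.
    """

    name: str
    is_cancer: bool
    rr: float
    disability_weight: float
    inc18: float
    inc_slope: float
    cf18: float
    cf_slope: float
    remission: float
    cost_first: float
    cost_subsequent: float
    cost_last6m: float
    female_factor: float = 1.0
    male_factor: float = 1.0


# Magnitudes are plausible for a high-income adult population; they are not a
# fit to any national dataset.
DISEASE_DEFS: tuple[DiseaseDef, ...] = (
    DiseaseDef("coronary_heart_disease", False, 1.08, 0.08, 1.0e-4, 0.075, 0.050, 0.015, 0.0, 15_000, 2_500, 25_000, 0.7, 1.3),
    DiseaseDef("stroke", False, 1.06, 0.25, 5.0e-5, 0.080, 0.080, 0.015, 0.0, 25_000, 4_000, 22_000, 0.9, 1.1),
    DiseaseDef("type_2_diabetes", False, 1.20, 0.07, 5.0e-4, 0.045, 0.012, 0.012, 0.0, 4_000, 2_000, 15_000),
    DiseaseDef("osteoarthritis", False, 1.06, 0.12, 1.0e-3, 0.030, 0.0, 0.0, 0.0, 6_000, 900, 0.0, 1.2, 0.8),
    DiseaseDef("endometrial_cancer", True, 1.12, 0.18, 8.0e-6, 0.075, 0.08, 0.0, 0.10, 35_000, 4_000, 30_000, 1.0, 0.0),
    DiseaseDef("kidney_cancer", True, 1.07, 0.20, 4.0e-6, 0.080, 0.15, 0.0, 0.10, 40_000, 5_000, 32_000, 0.7, 1.3),
    DiseaseDef("liver_cancer", True, 1.07, 0.25, 2.0e-6, 0.085, 0.45, 0.0, 0.06, 45_000, 6_000, 35_000, 0.6, 1.4),
    DiseaseDef("esophageal_cancer", True, 1.10, 0.25, 2.0e-6, 0.085, 0.40, 0.0, 0.06, 45_000, 6_000, 35_000, 0.5, 1.5),
    DiseaseDef("pancreatic_cancer", True, 1.05, 0.28, 3.0e-6, 0.090, 0.50, 0.0, 0.05, 50_000, 6_000, 35_000),
    DiseaseDef("thyroid_cancer", True, 1.04, 0.12, 5.0e-6, 0.045, 0.03, 0.0, 0.15, 30_000, 3_000, 25_000, 1.5, 0.5),
    DiseaseDef("colorectal_cancer", True, 1.03, 0.20, 6.0e-6, 0.085, 0.15, 0.0, 0.10, 45_000, 5_000, 32_000),
    DiseaseDef("breast_cancer", True, 1.03, 0.18, 3.0e-5, 0.050, 0.08, 0.0, 0.12, 40_000, 4_500, 30_000, 1.0, 0.01),
    DiseaseDef("ovarian_cancer", True, 1.03, 0.22, 5.0e-6, 0.070, 0.25, 0.0, 0.08, 45_000, 5_500, 33_000, 1.0, 0.0),
    DiseaseDef("gallbladder_cancer", True, 1.06, 0.24, 1.5e-6, 0.085, 0.35, 0.0, 0.06, 42_000, 5_000, 33_000, 1.3, 0.7),
)

DISEASES: tuple[str, ...] = tuple(d.name for d in DISEASE_DEFS)
CANCERS: frozenset[str] = frozenset(d.name for d in DISEASE_DEFS if d.is_cancer)

# Age above which BMI relative risks have fully attenuated to 1, and the age
# up to which they apply in full.
RR_FULL_AGE = 45
RR_NULL_AGE = 95


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic generator.

    The defaults define the study conditions: a ~3.4 M adult population with a
    Māori share of ~13.5%, a Māori:non-Māori all-cause mortality ratio of 1.5,
    a +1.5 kg/m² Māori BMI gap, and 73% of adults with BMI ≥ 25 in every
    stratum (per-stratum overrides are allowed downstream).
    """

    total_population: float = 3_400_000.0
    maori_share: float = 0.135
    maori_mortality_gap: float = 1.5
    maori_pyld_gap: float = 1.15
    maori_bmi_gap: float = 1.5
    male_mortality_factor: float = 1.4
    gompertz_rate18: float = 2.0e-4
    gompertz_slope: float = 0.10
    overweight_prop: float = 0.73
    cost_scale: float = 1.0
    baseline_year: int = 2011
    closure_age: int = 110

    def validate(self) -> None:
        if self.maori_mortality_gap <= 0:
            raise ConfigurationError("maori_mortality_gap must be > 0")
        if self.maori_pyld_gap <= 0:
            raise ConfigurationError("maori_pyld_gap must be > 0")
        if not 0 < self.maori_share < 1:
            raise ConfigurationError("maori_share must be in (0, 1)")
        if not 0 < self.overweight_prop < 1:
            raise ConfigurationError("overweight_prop must be in (0, 1)")
        if self.gompertz_rate18 <= 0:
            raise ConfigurationError("gompertz_rate18 must be > 0")
        if self.gompertz_slope <= 0:
            raise ConfigurationError("gompertz_slope must be > 0")
        if self.cost_scale < 0:
            raise ConfigurationError("cost_scale must be >= 0")
        if self.total_population <= 0:
            raise ConfigurationError("total_population must be > 0")
        if self.closure_age <= AGE_MIN:
            raise ConfigurationError("closure_age must exceed 18")


_SCHEDULE_FILES = {
    "demography": "demography.csv",
    "bmi": "bmi.csv",
    "disease_rates": "disease_rates.csv",
    "disease_attrs": "disease_attrs.csv",
    "relative_risks": "relative_risks.csv",
    "unrelated_cost": "unrelated_cost.csv",
}


@dataclass
class ParameterBundle:
    """Complete input set for one model run.

    Tables (all plain :class:`pandas.DataFrame`):

    demography
        sex, ethnicity, age, population, mortality, pyld
    bmi
        sex, ethnicity, age, mean, sd, overweight_prop
    disease_rates
        disease, sex, ethnicity, age, incidence, case_fatality, remission
    disease_attrs
        disease, is_cancer, disability_weight, rr_per_unit,
        cost_first_year, cost_subsequent_year, cost_last_6m, lag_min, lag_max
    relative_risks
        disease, age, rr  (age-attenuated RR per 1 kg/m²)
    unrelated_cost
        sex, age, cost  (annual unrelated health-system cost per person)
    """

    demography: pd.DataFrame
    bmi: pd.DataFrame
    disease_rates: pd.DataFrame
    disease_attrs: pd.DataFrame
    relative_risks: pd.DataFrame
    unrelated_cost: pd.DataFrame
    baseline_year: int = 2011
    closure_age: int = 110

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, self.closure_age + 1)

    @property
    def diseases(self) -> list[str]:
        return list(self.disease_attrs["disease"])

    def copy(self) -> "ParameterBundle":
        return ParameterBundle(
            demography=self.demography.copy(),
            bmi=self.bmi.copy(),
            disease_rates=self.disease_rates.copy(),
            disease_attrs=self.disease_attrs.copy(),
            relative_risks=self.relative_risks.copy(),
            unrelated_cost=self.unrelated_cost.copy(),
            baseline_year=self.baseline_year,
            closure_age=self.closure_age,
        )

    # ------------------------------------------------------------------ IO

    def to_dir(self, path: str | Path) -> None:
        """Write the bundle as a directory of CSVs plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for attr, fname in _SCHEDULE_FILES.items():
            getattr(self, attr).to_csv(path / fname, index=False)
        manifest = {
            "format": "pmslt-parameter-bundle",
            "version": 1,
            "baseline_year": self.baseline_year,
            "closure_age": self.closure_age,
            "files": _SCHEDULE_FILES,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "ParameterBundle":
        """Load a bundle written by :meth:`to_dir`, validating on read."""
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        tables = {
            attr: pd.read_csv(path / fname)
            for attr, fname in manifest["files"].items()
        }
        bundle = cls(
            baseline_year=int(manifest["baseline_year"]),
            closure_age=int(manifest["closure_age"]),
            **tables,
        )
        violations = validate_bundle(bundle)
        if violations:
            raise ConfigurationError(
                "bundle failed validation on read: " + "; ".join(violations[:5])
            )
        return bundle


def _age_attenuation(ages: np.ndarray) -> np.ndarray:
    """Linear taper of the log-RR slope: full below 45, zero from 95 up."""
    return np.clip((RR_NULL_AGE - ages) / (RR_NULL_AGE - RR_FULL_AGE), 0.0, 1.0)


def generate_bundle(seed: int, config: GeneratorConfig | None = None) -> ParameterBundle:
    """Generate a synthetic :class:`ParameterBundle`.

    Deterministic: the same ``(seed, config)`` reproduces the bundle
    bit-for-bit.  The seed drives mild stratum-level jitter; the broad shapes
    come from the config.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    ages = np.arange(AGE_MIN, config.closure_age + 1)
    n_age = ages.size
    atten = _age_attenuation(ages)

    # Stratum-level multiplicative jitter, drawn in a fixed order.  Mortality
    # jitter is per sex only, so the Māori/non-Māori ratio stays exactly the
    # configured gap and Gompertz monotonicity is preserved.
    mort_jitter = {sex: rng.uniform(0.95, 1.05) for sex in SEXES}
    inc_jitter = {
        (d.name, sex, eth): rng.uniform(0.92, 1.08)
        for d in DISEASE_DEFS
        for sex in SEXES
        for eth in ETHNICITIES
    }

    # --- demography -------------------------------------------------------
    demo_rows = []
    # Age pyramid: exponential decline with a soft old-age roll-off.
    for eth in ETHNICITIES:
        decay = 0.030 if eth == "maori" else 0.012
        shape = np.exp(-decay * (ages - AGE_MIN))
        shape = shape * np.exp(-(np.clip(ages - 70, 0, None) / 12.0) ** 2)
        share = config.maori_share if eth == "maori" else 1 - config.maori_share
        for sex in SEXES:
            sex_share = 0.49 if sex == "male" else 0.51
            counts = shape / shape.sum() * config.total_population * share * sex_share
            m = (
                config.gompertz_rate18
                * (config.male_mortality_factor if sex == "male" else 1.0)
                * mort_jitter[sex]
                * np.exp(config.gompertz_slope * (ages - AGE_MIN))
            )
            if eth == "maori":
                m = m * config.maori_mortality_gap
            pyld = 0.02 + 0.0022 * (ages - AGE_MIN)
            if eth == "maori":
                pyld = pyld * config.maori_pyld_gap
            pyld = np.clip(pyld, 0.0, 0.95)
            demo_rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "ethnicity": eth,
                        "age": ages,
                        "population": counts,
                        "mortality": m,
                        "pyld": pyld,
                    }
                )
            )
    demography = pd.concat(demo_rows, ignore_index=True)

    # --- BMI ---------------------------------------------------------------
    bmi_rows = []
    base_mean = 26.0 + 3.0 * (1.0 - np.exp(-(ages - AGE_MIN) / 25.0))
    base_mean = base_mean - 0.02 * np.clip(ages - 70, 0, None)
    for sex in SEXES:
        for eth in ETHNICITIES:
            mean = base_mean + (config.maori_bmi_gap if eth == "maori" else 0.0)
            mean = mean + (0.3 if sex == "male" else 0.0)
            bmi_rows.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "ethnicity": eth,
                        "age": ages,
                        "mean": mean,
                        "sd": np.full(n_age, 4.2),
                        "overweight_prop": np.full(n_age, config.overweight_prop),
                    }
                )
            )
    bmi = pd.concat(bmi_rows, ignore_index=True)

    # --- diseases ----------------------------------------------------------
    rate_rows = []
    attr_rows = []
    rr_rows = []
    for d in DISEASE_DEFS:
        attr_rows.append(
            {
                "disease": d.name,
                "is_cancer": d.is_cancer,
                "disability_weight": d.disability_weight,
                "rr_per_unit": d.rr,
                "cost_first_year": d.cost_first * config.cost_scale,
                "cost_subsequent_year": d.cost_subsequent * config.cost_scale,
                "cost_last_6m": d.cost_last6m * config.cost_scale,
                "lag_min": 10 if d.is_cancer else 0,
                "lag_max": 30 if d.is_cancer else 5,
            }
        )
        rr_rows.append(
            pd.DataFrame(
                {
                    "disease": d.name,
                    "age": ages,
                    "rr": np.exp(np.log(d.rr) * atten),
                }
            )
        )
        cf = np.clip(d.cf18 * np.exp(d.cf_slope * (ages - AGE_MIN)), 0.0, 1.5)
        for sex in SEXES:
            sex_factor = d.male_factor if sex == "male" else d.female_factor
            for eth in ETHNICITIES:
                inc = (
                    d.inc18
                    * sex_factor
                    * inc_jitter[(d.name, sex, eth)]
                    * np.exp(d.inc_slope * (ages - AGE_MIN))
                )
                inc = np.clip(inc, 0.0, 0.15)
                rate_rows.append(
                    pd.DataFrame(
                        {
                            "disease": d.name,
                            "sex": sex,
                            "ethnicity": eth,
                            "age": ages,
                            "incidence": inc,
                            "case_fatality": cf,
                            "remission": np.full(n_age, d.remission),
                        }
                    )
                )
    disease_rates = pd.concat(rate_rows, ignore_index=True)
    disease_attrs = pd.DataFrame(attr_rows)
    relative_risks = pd.concat(rr_rows, ignore_index=True)

    # --- unrelated annual health-system cost -------------------------------
    unrel_rows = []
    for sex in SEXES:
        base = 1_300.0 if sex == "male" else 1_400.0
        unrel_rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "age": ages,
                    "cost": base * np.exp(0.028 * (ages - AGE_MIN)) * config.cost_scale,
                }
            )
        )
    unrelated_cost = pd.concat(unrel_rows, ignore_index=True)

    return ParameterBundle(
        demography=demography,
        bmi=bmi,
        disease_rates=disease_rates,
        disease_attrs=disease_attrs,
        relative_risks=relative_risks,
        unrelated_cost=unrelated_cost,
        baseline_year=config.baseline_year,
        closure_age=config.closure_age,
    )


def validate_bundle(bundle: ParameterBundle) -> list[str]:
    """Check every structural invariant; return a list of violation messages.

    An empty list means the bundle is valid.  Each message names the
    offending stratum, disease and field.
    """
    v: list[str] = []
    ages = bundle.ages

    expected_strata = {
        (sex, eth, age) for sex in SEXES for eth in ETHNICITIES for age in ages
    }

    demo = bundle.demography
    got = set(zip(demo["sex"], demo["ethnicity"], demo["age"]))
    missing = expected_strata - got
    if missing:
        v.append(f"demography: {len(missing)} strata missing (e.g. {sorted(missing)[0]})")
    for _, row in demo.iterrows():
        where = f"sex={row['sex']} ethnicity={row['ethnicity']} age={row['age']}"
        if row["population"] < 0:
            v.append(f"demography.population < 0 at {where}")
        if not row["mortality"] > 0:
            v.append(f"demography.mortality <= 0 at {where}")
        if not 0 <= row["pyld"] < 1:
            v.append(f"demography.pyld outside [0, 1) at {where}")

    b = bundle.bmi
    got = set(zip(b["sex"], b["ethnicity"], b["age"]))
    missing = expected_strata - got
    if missing:
        v.append(f"bmi: {len(missing)} strata missing (e.g. {sorted(missing)[0]})")
    bad = b[(b["mean"] < 18) | (b["mean"] > 45)]
    for _, row in bad.iterrows():
        v.append(
            f"bmi.mean outside [18, 45] at sex={row['sex']} "
            f"ethnicity={row['ethnicity']} age={row['age']}"
        )
    bad = b[b["sd"] <= 0]
    for _, row in bad.iterrows():
        v.append(f"bmi.sd <= 0 at sex={row['sex']} ethnicity={row['ethnicity']} age={row['age']}")
    bad = b[(b["overweight_prop"] <= 0) | (b["overweight_prop"] >= 1)]
    for _, row in bad.iterrows():
        v.append(
            f"bmi.overweight_prop outside (0, 1) at sex={row['sex']} "
            f"ethnicity={row['ethnicity']} age={row['age']}"
        )

    names = list(bundle.disease_attrs["disease"])
    if sorted(names) != sorted(DISEASES):
        v.append(
            "disease_attrs: expected the 14 BMI-related diseases exactly once, got "
            + ", ".join(sorted(names))
        )
    for _, row in bundle.disease_attrs.iterrows():
        d = row["disease"]
        if not 0 <= row["disability_weight"] < 1:
            v.append(f"{d}.disability_weight outside [0, 1)")
        if row["rr_per_unit"] < 1:
            v.append(f"{d}.rr_per_unit < 1")
        for c in ("cost_first_year", "cost_subsequent_year", "cost_last_6m"):
            if row[c] < 0:
                v.append(f"{d}.{c} < 0")
        if not 0 <= row["lag_min"] <= row["lag_max"]:
            v.append(f"{d}: lag window invalid (min={row['lag_min']}, max={row['lag_max']})")

    dr = bundle.disease_rates
    for dname, grp in dr.groupby("disease", sort=False):
        got = set(zip(grp["sex"], grp["ethnicity"], grp["age"]))
        missing = expected_strata - got
        if missing:
            v.append(f"disease_rates[{dname}]: {len(missing)} strata missing")
        for col in ("incidence", "case_fatality", "remission"):
            nbad = int((grp[col] < 0).sum())
            if nbad:
                v.append(f"disease_rates[{dname}].{col} < 0 at {nbad} strata")
        if dname not in CANCERS and (grp["remission"] > 0).any():
            v.append(f"disease_rates[{dname}].remission > 0 but {dname} is not a cancer")

    rr = bundle.relative_risks
    nbad = int((rr["rr"] < 1).sum())
    if nbad:
        v.append(f"relative_risks.rr < 1 at {nbad} rows")

    uc = bundle.unrelated_cost
    nbad = int((uc["cost"] < 0).sum())
    if nbad:
        v.append(f"unrelated_cost.cost < 0 at {nbad} rows")

    return v
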