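"""Probabilistic sensitivity analysis, scenario suite, equity, reporting.

Monte Carlo uncertainty propagation samples the six intervention parameters
independently from their assigned families (beta for the three cascade
proportions, normal for the pooled BMI effect, log-normal for the monthly
regain rate, gamma for the campaign cost), plus the lag-window endpoints,
and reruns the paired simulation per draw.  Dispersion follows the stated
convention: the effect's SD comes from its 95% CI, all other SDs are a
stated percentage of the central value (5% for smartphone ownership, 20%
for the high-uncertainty inputs).

The scenario suite covers: enhanced campaign recognition (68%), a 50% larger
effect, full long-duration adherence, regain delayed by 1 or 5 years or
eliminated, the legacy (pre-update) effect size, and 0%/6% discount rates.
The equity adjustment removes the ethnic gap in background life expectancy
by giving Māori strata the same-age-sex non-Māori mortality and pYLD
schedules, so health gains are no longer discounted by shorter remaining
lifespans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, ReportingError
from .lifetable import NZD_TO_USD, InterventionSpec, Model, RunResult
from .pathway import EffectSpec, weighted_effect_size
from .pif import LagSpec
from .population import ParameterBundle

__all__ = [
    "ParameterDistribution",
    "default_distributions",
    "sample_parameters",
    "SCENARIOS",
    "scenario_spec",
    "run_scenario",
    "run_monte_carlo",
    "UncertaintyResult",
    "equity_adjust",
    "percent_difference",
    "classify_cost_effectiveness",
    "subgroup_table",
    "scenario_table",
    "CE_THRESHOLD_NZD",
]

#: Willingness-to-pay threshold, ≈ GDP per capita (NZ$ per QALY).
CE_THRESHOLD_NZD = 45_000.0

#: Mean height (m) used to convert a weight effect (kg) to a BMI effect
#: (kg/m²) for the legacy-effect scenario.
LEGACY_MEAN_HEIGHT_M = 1.69


@dataclass(frozen=True)
class ParameterDistribution:
    """One sampled input: family, central value, and dispersion.

    ``sd_pct`` expresses the SD as a percentage of the central value; for
    the normal family an explicit 95% CI may be given instead, implying
    SD = (upper − lower) / (2 × 1.96).
    """

    name: str
    family: str  # beta | normal | lognormal | gamma
    central: float
    sd_pct: float | None = None
    ci95: tuple[float, float] | None = None

    @property
    def sd(self) -> float:
        if self.ci95 is not None:
            lo, hi = self.ci95
            return (hi - lo) / (2.0 * 1.96)
        if self.sd_pct is None:
            return 0.0
        return abs(self.central) * self.sd_pct / 100.0

    def sample(self, rng: np.random.Generator) -> float:
        s = self.sd
        if s == 0.0:
            return self.central
        m = self.central
        if self.family == "beta":
            if not 0.0 < m < 1.0:
                raise ConfigurationError(f"{self.name}: beta central {m} outside (0, 1)")
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:
                raise ConfigurationError(
                    f"{self.name}: SD {s} too large for a beta distribution with mean {m}"
                )
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        if self.family == "normal":
            return float(rng.normal(m, s))
        if self.family == "lognormal":
            if m <= 0:
                raise ConfigurationError(f"{self.name}: lognormal central {m} must be > 0")
            sigma2 = np.log1p((s / m) ** 2)
            mu = np.log(m) - sigma2 / 2.0
            return float(rng.lognormal(mu, np.sqrt(sigma2)))
        if self.family == "gamma":
            if m <= 0:
                raise ConfigurationError(f"{self.name}: gamma central {m} must be > 0")
            shape = (m / s) ** 2
            return float(rng.gamma(shape, s**2 / m))
        raise ConfigurationError(f"{self.name}: unknown family {self.family!r}")


def default_distributions(
    spec: InterventionSpec | None = None, dispersion_scale: float = 1.0
) -> list[ParameterDistribution]:
    """The six intervention-parameter distributions around a spec's centrals.

    ``dispersion_scale`` scales every SD (0 collapses all draws onto the
    central values, which is how Monte Carlo convergence is verified).
    """
    spec = spec or InterventionSpec()
    effect = spec.resolved_effect()
    # 95% CI of the pooled weighted effect, scaled with the effect itself.
    scale = effect / weighted_effect_size(EffectSpec()) if effect != 0 else 1.0
    ci = (-0.858 * scale, 0.051 * scale) if scale > 0 else None
    dists = [
        ParameterDistribution("p_smartphone", "beta", spec.p_smartphone, sd_pct=5.0),
        ParameterDistribution("p_recognition", "beta", spec.p_recognition, sd_pct=20.0),
        ParameterDistribution("p_uptake", "beta", spec.p_uptake, sd_pct=20.0),
        ParameterDistribution("effect", "normal", effect, ci95=ci, sd_pct=None if ci else 20.0),
        ParameterDistribution(
            "regain_rate", "lognormal", spec.effect_spec.regain_rate, sd_pct=20.0
        ),
        ParameterDistribution("intervention_cost", "gamma", spec.cost, sd_pct=20.0),
    ]
    if dispersion_scale != 1.0:
        scaled = []
        for d in dists:
            if d.ci95 is not None:
                mid = d.central
                lo, hi = d.ci95
                scaled.append(
                    ParameterDistribution(
                        d.name,
                        d.family,
                        d.central,
                        ci95=(mid + (lo - mid) * dispersion_scale, mid + (hi - mid) * dispersion_scale),
                    )
                )
            else:
                scaled.append(
                    ParameterDistribution(
                        d.name, d.family, d.central,
                        sd_pct=(d.sd_pct or 0.0) * dispersion_scale,
                    )
                )
        dists = scaled
    return dists


def _draw_rng(seed: int, draw_index: int) -> np.random.Generator:
    """Substream for one draw: reproducible in isolation from (seed, draw)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(draw_index))))


def sample_parameters(
    distributions: list[ParameterDistribution], seed: int, draw_index: int
) -> dict[str, float]:
    """Sample one parameter set; independent across parameters and draws."""
    rng = _draw_rng(seed, draw_index)
    return {d.name: d.sample(rng) for d in distributions}


def _sample_lag(rng: np.random.Generator, base: LagSpec, dispersion_scale: float) -> LagSpec:
    """Per-draw lag-window endpoints: normal with SD 20% of central, rounded
    to non-negative integers, min clipped below max."""
    sd_lo = 0.2 * base.lag_min * dispersion_scale
    sd_hi = 0.2 * base.lag_max * dispersion_scale
    lo = max(0, round(rng.normal(base.lag_min, sd_lo))) if sd_lo > 0 else base.lag_min
    hi = max(0, round(rng.normal(base.lag_max, sd_hi))) if sd_hi > 0 else base.lag_max
    return LagSpec(min(lo, hi), max(lo, hi))


# --------------------------------------------------------------------------
# scenarios
# --------------------------------------------------------------------------

#: Scenario id -> overrides of the base-case intervention/discount settings.
SCENARIOS: dict[str, dict] = {
    "base": {},
    "s1_recognition68": {"p_recognition": 0.68},
    "s2_effect_x1.5": {"effect_scale": 1.5},
    "s3_full_adherence": {"effect": -0.609},
    "s4a_delay1": {"regain_delay": 1.0},
    "s4b_delay5": {"regain_delay": 5.0},
    "s4c_no_regain": {"no_regain": True},
    "s5_legacy_effect": {"effect": -0.430 / LEGACY_MEAN_HEIGHT_M**2},
    "s6a_disc0": {"discount_rate": 0.0},
    "s6b_disc6": {"discount_rate": 0.06},
}


def scenario_spec(
    scenario_id: str, base: InterventionSpec | None = None
) -> tuple[InterventionSpec, float]:
    """Resolve a scenario id to (InterventionSpec, discount rate)."""
    if scenario_id not in SCENARIOS:
        raise DomainError(
            f"unknown scenario {scenario_id!r}; valid ids: {', '.join(SCENARIOS)}"
        )
    overrides = dict(SCENARIOS[scenario_id])
    discount = overrides.pop("discount_rate", 0.03)
    spec = base or InterventionSpec()
    effect_changes = {
        k: overrides.pop(k) for k in ("regain_delay", "no_regain") if k in overrides
    }
    if effect_changes:
        spec = spec.with_(effect_spec=spec.effect_spec.with_(**effect_changes))
    if overrides:
        spec = spec.with_(**overrides)
    return spec, discount


def run_scenario(
    bundle: ParameterBundle | Model, scenario_id: str = "base", equity: bool = False
) -> RunResult:
    """Expected-value run (all parameters at central values) for one scenario."""
    spec, discount = scenario_spec(scenario_id)
    model = _as_model(bundle, equity)
    return model.run(spec, discount)


def _as_model(bundle: ParameterBundle | Model, equity: bool) -> Model:
    if isinstance(bundle, Model):
        if equity:
            raise DomainError("pass a ParameterBundle when equity adjustment is requested")
        return bundle
    return Model(equity_adjust(bundle) if equity else bundle)


# --------------------------------------------------------------------------
# Monte Carlo
# --------------------------------------------------------------------------

_MC_QUANTITIES = (
    ("qalys", {}),
    ("qalys_maori", {"ethnicity": "maori"}),
    ("qalys_non_maori", {"ethnicity": "non_maori"}),
    ("qalys_male", {"sex": "male"}),
    ("qalys_female", {"sex": "female"}),
    ("net_cost", {}),
    ("net_cost_maori", {"ethnicity": "maori"}),
    ("net_cost_non_maori", {"ethnicity": "non_maori"}),
    ("net_cost_male", {"sex": "male"}),
    ("net_cost_female", {"sex": "female"}),
)


@dataclass
class UncertaintyResult:
    """Draw-level outputs with mean and 95% uncertainty interval summaries."""

    draws: pd.DataFrame
    n_draws: int
    seed: int
    scenario: str

    def mean(self, quantity: str) -> float:
        return float(self.draws[quantity].mean())

    def interval(self, quantity: str, level: float = 0.95) -> tuple[float, float]:
        """Empirical percentile uncertainty interval across the draws."""
        tail = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.draws[quantity].to_numpy(), [tail, 1.0 - tail])
        return float(lo), float(hi)

    def summary(self) -> pd.DataFrame:
        rows = []
        for q in self.draws.columns:
            lo, hi = self.interval(q)
            rows.append({"quantity": q, "mean": self.mean(q), "ui_low": lo, "ui_high": hi})
        return pd.DataFrame(rows).set_index("quantity")


def run_monte_carlo(
    bundle: ParameterBundle | Model,
    scenario_id: str = "base",
    n_draws: int = 2000,
    seed: int = 0,
    equity: bool = False,
    dispersion_scale: float = 1.0,
    horizon: int | None = None,
) -> UncertaintyResult:
    """Probabilistic sensitivity analysis for one scenario.

    Each draw samples the intervention parameters and the lag-window
    endpoints independently from their distributions and reruns the paired
    simulation.  Deterministic given ``seed``; draw ``d`` uses the
    substream ``(seed, d)`` and is reproducible in isolation.
    """
    model = _as_model(bundle, equity)
    base_spec, discount = scenario_spec(scenario_id)
    dists = default_distributions(base_spec, dispersion_scale)
    base_lags = {
        "cvd_metabolic": LagSpec(0, 5),
        "cancer": LagSpec(10, 30),
    }
    records = []
    for d in range(n_draws):
        # One substream per draw; the six parameters are sampled first (in
        # the order of `dists`, matching sample_parameters), then the lag
        # windows, so draw d is reproducible in isolation.
        rng = _draw_rng(seed, d)
        params = {dist.name: dist.sample(rng) for dist in dists}
        lags = {
            key: _sample_lag(rng, base, dispersion_scale)
            for key, base in base_lags.items()
        }
        spec = base_spec.with_(
            p_smartphone=params["p_smartphone"],
            p_recognition=params["p_recognition"],
            p_uptake=params["p_uptake"],
            effect=params["effect"],
            effect_scale=1.0,
            effect_spec=base_spec.effect_spec.with_(regain_rate=params["regain_rate"]),
            cost=params["intervention_cost"],
            lag_overrides=lags,
        )
        try:
            result = model.run(spec, discount)
        except Exception as exc:  # pragma: no cover - diagnostic path
            raise RuntimeError(
                f"draw {d} failed with parameters {params!r}: {exc}"
            ) from exc
        rec = {}
        for name, sel in _MC_QUANTITIES:
            if name.startswith("qalys"):
                rec[name] = result.qaly_gain(horizon=horizon, **sel)
            else:
                rec[name] = result.net_cost(horizon=horizon, **sel)
        records.append(rec)
    return UncertaintyResult(
        draws=pd.DataFrame.from_records(records),
        n_draws=n_draws,
        seed=seed,
        scenario=scenario_id,
    )


# --------------------------------------------------------------------------
# equity adjustment
# --------------------------------------------------------------------------


def equity_adjust(bundle: ParameterBundle) -> ParameterBundle:
    """Remove the ethnic gap in background life expectancy.

    Māori strata receive the same-age-same-sex non-Māori all-cause mortality
    and pYLD schedules (in both arms); Māori BMI, disease relative risks and
    the uptake cascade are unchanged.  Returns a new bundle.
    """
    out = bundle.copy()
    demo = out.demography
    for sex in demo["sex"].unique():
        ref = (
            demo[(demo["sex"] == sex) & (demo["ethnicity"] == "non_maori")]
            .set_index("age")[["mortality", "pyld"]]
        )
        mask = (demo["sex"] == sex) & (demo["ethnicity"] == "maori")
        ages = demo.loc[mask, "age"]
        demo.loc[mask, "mortality"] = ref.loc[ages, "mortality"].to_numpy()
        demo.loc[mask, "pyld"] = ref.loc[ages, "pyld"].to_numpy()
    return out


# --------------------------------------------------------------------------
# reporting
# --------------------------------------------------------------------------


def percent_difference(scenario_value: float, base_value: float) -> int:
    """100 × (scenario − base) / base, rounded to the nearest integer."""
    if base_value == 0:
        raise DomainError("cannot compute a percent difference against a zero base")
    return int(round(100.0 * (scenario_value - base_value) / base_value))


def classify_cost_effectiveness(
    net_cost: float, qalys: float, threshold: float = CE_THRESHOLD_NZD
) -> str:
    """cost_saving | cost_effective | not_cost_effective | dominated."""
    if net_cost < 0:
        return "cost_saving"
    if qalys <= 0:
        return "dominated"
    return "cost_effective" if net_cost / qalys <= threshold else "not_cost_effective"


_AGE_BANDS = ((25, 44), (45, 64), (65, 200))


def _denominator(bundle: ParameterBundle, sex=None, ethnicity=None, age_band=None, target=False):
    demo = bundle.demography
    mask = np.ones(len(demo), dtype=bool)
    if sex is not None:
        mask &= (demo["sex"] == sex).to_numpy()
    if ethnicity is not None:
        mask &= (demo["ethnicity"] == ethnicity).to_numpy()
    if age_band is not None:
        lo, hi = age_band
        mask &= ((demo["age"] >= lo) & (demo["age"] <= hi)).to_numpy()
    pop = demo.loc[mask, "population"].sum()
    if pop <= 0:
        raise ReportingError(
            f"no population denominator for sex={sex} ethnicity={ethnicity} age_band={age_band}"
        )
    if target:
        bmi = bundle.bmi
        bmask = np.ones(len(bmi), dtype=bool)
        if sex is not None:
            bmask &= (bmi["sex"] == sex).to_numpy()
        if ethnicity is not None:
            bmask &= (bmi["ethnicity"] == ethnicity).to_numpy()
        merged = demo.loc[mask].merge(
            bmi.loc[bmask, ["sex", "ethnicity", "age", "overweight_prop"]],
            on=["sex", "ethnicity", "age"],
        )
        pop = (merged["population"] * merged["overweight_prop"]).sum()
    return float(pop)


def subgroup_table(
    result: RunResult,
    bundle: ParameterBundle,
    horizon: int | None = None,
    uncertainty: UncertaintyResult | None = None,
) -> pd.DataFrame:
    """Health gains and net costs by sex, ethnicity and baseline age band.

    Per-1000 rates use the 2011 baseline population of each subgroup.
    Uncertainty intervals, when a Monte Carlo result is supplied, are
    attached only to the aggregate rows (overall, by ethnicity, by sex);
    the finest cells report expected values.
    """
    rows = []

    def add_row(label, sex=None, ethnicity=None, age_band=None, ui_key=None):
        q = result.qaly_gain(sex=sex, ethnicity=ethnicity, age_band=age_band, horizon=horizon)
        c = result.net_cost(sex=sex, ethnicity=ethnicity, age_band=age_band, horizon=horizon)
        pop = _denominator(bundle, sex, ethnicity, age_band)
        row = {
            "group": label,
            "qalys": q,
            "qalys_per_1000": 1000.0 * q / pop,
            "net_cost_nzd": c,
            "net_cost_usd": c * NZD_TO_USD,
        }
        if uncertainty is not None and ui_key is not None:
            row["qalys_ui_low"], row["qalys_ui_high"] = uncertainty.interval(ui_key)
            row["cost_ui_low"], row["cost_ui_high"] = uncertainty.interval(
                ui_key.replace("qalys", "net_cost")
            )
        rows.append(row)

    add_row("all", ui_key="qalys")
    add_row("non_maori", ethnicity="non_maori", ui_key="qalys_non_maori")
    add_row("maori", ethnicity="maori", ui_key="qalys_maori")
    for sex in ("male", "female"):
        add_row(sex, sex=sex, ui_key=f"qalys_{sex}")
        for eth in ("non_maori", "maori"):
            for lo, hi in _AGE_BANDS:
                band = f"{lo}-{hi}" if hi < 200 else f">={lo}"
                add_row(f"{sex}/{eth}/{band}", sex=sex, ethnicity=eth, age_band=(lo, hi))
    return pd.DataFrame(rows).set_index("group")


def target_population_rates(result: RunResult, bundle: ParameterBundle) -> dict[str, float]:
    """Lifetime QALYs gained per 1000 of the overweight/obese target population."""
    out = {}
    for label, eth in (("all", None), ("non_maori", "non_maori"), ("maori", "maori")):
        q = result.qaly_gain(ethnicity=eth)
        pop = _denominator(bundle, ethnicity=eth, target=True)
        out[label] = 1000.0 * q / pop
    return out


def scenario_table(
    bundle: ParameterBundle | Model, scenario_ids: list[str] | None = None
) -> pd.DataFrame:
    """Expected-value scenario suite with percent differences from base."""
    model = _as_model(bundle, equity=False)
    ids = scenario_ids or list(SCENARIOS)
    if "base" not in ids:
        ids = ["base"] + ids
    results = {sid: run_scenario(model, sid) for sid in ids}
    base_q = results["base"].qaly_gain()
    base_c = results["base"].net_cost()
    rows = []
    for sid in ids:
        q = results[sid].qaly_gain()
        c = results[sid].net_cost()
        rows.append(
            {
                "scenario": sid,
                "qalys": q,
                "qalys_pct_diff": 0 if sid == "base" else percent_difference(q, base_q),
                "net_cost_nzd": c,
                "net_cost_usd": c * NZD_TO_USD,
                "cost_pct_diff": 0 if sid == "base" else percent_difference(c, base_c),
                "classification": classify_cost_effectiveness(c, q),
            }
        )
    return pd.DataFrame(rows).set_index("scenario")
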