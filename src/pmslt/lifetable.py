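"""Proportional multistate life table engine.

The model follows each 2011 baseline cohort (sex × ethnicity × single year of
age 18–110) until the closure age.  A main life table carries all-cause
mortality and prevalent morbidity (pYLD); parallel to it run 14 disease life
tables, each a three-compartment system — susceptible S, prevalent cases C,
cumulative disease deaths D — driven by incidence, case fatality and (for
cancers) remission at annual time steps.

The business-as-usual (BAU) arm runs with unmodified rates.  The intervention
arm multiplies disease incidence by (1 − PIF); the resulting differences in
disease-death flows and prevalence feed back into the main table as lower
all-cause mortality and lower pYLD.  Outputs are discounted quality-adjusted
life years (QALYs) and health-system costs per cohort and calendar year.

Numerical scheme: annual cycles; rates convert to probabilities by
exponential survival (1 − e^(−rate)); cases incident within a cycle are
exposed to case fatality and remission for half a cycle on average; the main
table uses half-cycle-corrected life-years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError, NumericalStabilityError
from .pathway import EffectSpec, bmi_effect_trajectory, weighted_effect_size
from .pif import LagSpec, apply_lag
from .population import AGE_MIN, ETHNICITIES, SEXES, ParameterBundle

logger = logging.getLogger("pmslt")

#: NZ$ -> US$ conversion used for reporting only.
NZD_TO_USD = 0.673

__all__ = [
    "DiseaseState",
    "InterventionSpec",
    "RunResult",
    "Model",
    "step_disease",
    "run_disease_lifetable",
    "link_mortality_morbidity",
    "run_main_lifetable",
    "compute_costs",
    "discount_series",
    "life_expectancy",
    "NZD_TO_USD",
]


# --------------------------------------------------------------------------
# elemental disease-table step
# --------------------------------------------------------------------------


def _step_flows(S, C, incidence, case_fatality, remission):
    """One annual cycle's flows: (new cases, disease deaths, remissions).

    Incident cases accrue uniformly through the year, so they face half a
    cycle of exposure to case fatality and remission; exits from C split
    proportionally between death and remission.
    """
    new = S * -np.expm1(-incidence)
    fr = case_fatality + remission
    exits = C * -np.expm1(-fr) + new * -np.expm1(-fr / 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac_fatal = np.where(fr > 0, case_fatality / np.where(fr > 0, fr, 1.0), 0.0)
    deaths = exits * frac_fatal
    return new, deaths, exits - deaths


@dataclass(frozen=True)
class DiseaseState:
    """Disease-table compartments as proportions of the original cohort."""

    susceptible: float = 1.0
    prevalent: float = 0.0
    dead: float = 0.0
    incident: float = 0.0

    @property
    def total(self) -> float:
        return self.susceptible + self.prevalent + self.dead


def step_disease(
    state: DiseaseState,
    incidence: float,
    case_fatality: float,
    remission: float,
    pif: float = 0.0,
) -> DiseaseState:
    """Advance one disease table by one annual cycle.

    Effective incidence is ``incidence × (1 − pif)``; new cases flow S→C,
    disease deaths C→D at the case-fatality rate, remissions C→S.
    """
    if incidence < 0 or case_fatality < 0 or remission < 0:
        raise DomainError("incidence, case_fatality and remission must be >= 0")
    if pif > 1:
        raise DomainError(f"pif={pif} must be <= 1")
    new, deaths, remit = _step_flows(
        state.susceptible, state.prevalent, incidence * (1.0 - pif), case_fatality, remission
    )
    out = DiseaseState(
        susceptible=state.susceptible - new + remit,
        prevalent=state.prevalent + new - deaths - remit,
        dead=state.dead + deaths,
        incident=new,
    )
    if min(out.susceptible, out.prevalent, out.dead) < -1e-12:
        raise NumericalStabilityError(
            "annual step produced a negative compartment; rates are too large "
            "for a one-year cycle — use sub-annual stepping"
        )
    return out


# --------------------------------------------------------------------------
# standalone single-stratum operations (the building blocks the vectorised
# engine mirrors; kept simple and loop-based for inspectability)
# --------------------------------------------------------------------------


def run_disease_lifetable(
    bundle: ParameterBundle,
    pifs: np.ndarray,
    sex: str,
    ethnicity: str,
    age0: int,
    disease: str,
) -> tuple[list[DiseaseState], list[DiseaseState]]:
    """Simulate one disease table for one cohort, both arms.

    ``pifs`` gives the intervention arm's per-year PIF (the BAU arm uses
    zero everywhere).  Returns (bau_states, intervention_states), one
    :class:`DiseaseState` per simulated year.
    """
    rates = bundle.disease_rates
    sel = rates[
        (rates["disease"] == disease)
        & (rates["sex"] == sex)
        & (rates["ethnicity"] == ethnicity)
    ].sort_values("age")
    if sel.empty:
        raise DomainError(f"no rates for disease={disease} sex={sex} ethnicity={ethnicity}")
    inc = sel["incidence"].to_numpy()
    cf = sel["case_fatality"].to_numpy()
    rem = sel["remission"].to_numpy()
    ages = sel["age"].to_numpy()
    n_years = len(pifs)
    bau: list[DiseaseState] = []
    itv: list[DiseaseState] = []
    sb = si = DiseaseState()
    for t in range(n_years):
        ai = int(np.clip(np.searchsorted(ages, min(age0 + t, bundle.closure_age)), 0, len(ages) - 1))
        try:
            sb = step_disease(sb, inc[ai], cf[ai], rem[ai], 0.0)
            si = step_disease(si, inc[ai], cf[ai], rem[ai], float(pifs[t]))
        except (DomainError, NumericalStabilityError) as exc:
            raise type(exc)(
                f"{exc} (disease={disease}, sex={sex}, ethnicity={ethnicity}, "
                f"age0={age0}, year={t})"
            ) from exc
        bau.append(sb)
        itv.append(si)
    return bau, itv


def link_mortality_morbidity(
    mortality: np.ndarray,
    pyld: np.ndarray,
    bau_deaths: np.ndarray,
    intervention_deaths: np.ndarray,
    bau_prevalence: np.ndarray,
    intervention_prevalence: np.ndarray,
    disability_weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Feed disease-table differences back into the main life table.

    Arrays are stacked per disease along axis 0 (death flows and prevalence
    per year); ``mortality``/``pyld`` are the BAU main-table schedules.
    Returns the intervention arm's adjusted all-cause mortality and pYLD,
    clipped to valid ranges (clipping is logged: it signals implausible
    inputs).
    """
    dw = np.asarray(disability_weights, dtype=float)
    dw = dw.reshape((dw.shape[0],) + (1,) * (np.asarray(bau_deaths).ndim - 1))
    m_adj = mortality - (np.asarray(bau_deaths) - np.asarray(intervention_deaths)).sum(axis=0)
    p_adj = pyld - ((np.asarray(bau_prevalence) - np.asarray(intervention_prevalence)) * dw).sum(axis=0)
    if np.any(m_adj < 0):
        logger.warning(
            "adjusted all-cause mortality < 0 at %d points; clipped to 0",
            int(np.sum(m_adj < 0)),
        )
        m_adj = np.clip(m_adj, 0.0, None)
    if np.any(p_adj < 0) or np.any(p_adj >= 1):
        logger.warning("adjusted pYLD outside [0, 1); clipped")
        p_adj = np.clip(p_adj, 0.0, 1.0 - 1e-12)
    return m_adj, p_adj


def run_main_lifetable(
    mortality: np.ndarray, pyld: np.ndarray, age0: int, closure_age: int = 110
) -> dict[str, np.ndarray]:
    """Main life table for one cohort.

    Annual survival is ``exp(−m)``; survivorship is forced to zero beyond
    the closure age; life-years use the half-cycle average of start/end
    survivors; QALYs are life-years × (1 − pYLD).
    """
    mortality = np.asarray(mortality, dtype=float)
    pyld = np.asarray(pyld, dtype=float)
    n = mortality.shape[-1]
    alive_next = (age0 + np.arange(1, n + 1)) <= closure_age
    surv_mult = np.exp(-mortality) * alive_next
    l = np.concatenate([[1.0], np.cumprod(surv_mult)])
    ly = 0.5 * (l[:-1] + l[1:])
    return {
        "survivors": l,
        "life_years": ly,
        "qalys": ly * (1.0 - pyld),
    }


def compute_costs(
    incident: np.ndarray,
    prevalent: np.ndarray,
    deaths: np.ndarray,
    life_years: np.ndarray,
    cost_first: float,
    cost_subsequent: float,
    cost_last6m: float,
    unrelated: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Per-year health-system cost for one cohort and one disease.

    Disease costs follow the timing of health events: the first year of
    illness, subsequent years, and the last six months of life (disease
    deaths).  Disease-state proportions are weighted by the cohort's alive
    person-years; unrelated annual costs accrue to everyone alive.
    """
    disease = (
        incident * cost_first
        + np.clip(prevalent - incident, 0.0, None) * cost_subsequent
        + deaths * cost_last6m
    )
    return life_years * (disease + np.asarray(unrelated, dtype=float))


def discount_series(values: np.ndarray, rate: float) -> float:
    """Present value at the baseline year: Σ v(t) / (1 + rate)^t."""
    if rate < 0:
        raise DomainError(f"discount rate {rate} must be >= 0")
    values = np.asarray(values, dtype=float)
    t = np.arange(values.shape[-1])
    return float(np.sum(values / (1.0 + rate) ** t, axis=-1))


def life_expectancy(bundle: ParameterBundle, sex: str, ethnicity: str, age: int = 18) -> float:
    """Remaining BAU life expectancy (undiscounted life-years) at ``age``."""
    demo = bundle.demography
    sel = demo[(demo["sex"] == sex) & (demo["ethnicity"] == ethnicity) & (demo["age"] >= age)]
    sel = sel.sort_values("age")
    table = run_main_lifetable(
        sel["mortality"].to_numpy(), np.zeros(len(sel)), age, bundle.closure_age
    )
    return float(table["life_years"].sum())


# --------------------------------------------------------------------------
# intervention specification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class InterventionSpec:
    """Everything that defines one intervention arm.

    ``p_overweight=None`` takes the per-stratum overweight/obesity
    proportion from the bundle; a float overrides it uniformly.
    ``effect=None`` computes the duration-weighted pooled effect from
    ``effect_spec``; ``effect_scale`` multiplies the resolved effect
    (scenario lever).  ``lag_overrides`` replaces the default lag windows
    per disease class ("cvd_metabolic" / "cancer"), e.g. for per-draw lag
    uncertainty.
    """

    p_smartphone: float = 0.81
    p_recognition: float = 0.45
    p_uptake: float = 0.14
    p_overweight: float | None = None
    effect: float | None = None
    effect_scale: float = 1.0
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    cost: float = 2_883_000.0
    lag_overrides: dict[str, LagSpec] | None = None

    def __post_init__(self) -> None:
        for name in ("p_smartphone", "p_recognition", "p_uptake"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{name}={value} outside [0, 1]")
        if self.p_overweight is not None and not 0.0 <= self.p_overweight <= 1.0:
            raise DomainError(f"p_overweight={self.p_overweight} outside [0, 1]")
        if self.cost < 0:
            raise DomainError("intervention cost must be >= 0")

    def resolved_effect(self) -> float:
        base = self.effect if self.effect is not None else weighted_effect_size(self.effect_spec)
        return base * self.effect_scale

    def with_(self, **changes) -> "InterventionSpec":
        return replace(self, **changes)


# --------------------------------------------------------------------------
# run result
# --------------------------------------------------------------------------


@dataclass
class RunResult:
    """Paired BAU/intervention outputs, person-scaled, per cohort and year.

    Cohorts are indexed by (sex, ethnicity, baseline age); arrays have shape
    ``(n_cohorts, n_years)`` and are already multiplied by cohort population
    counts, so sums are population totals.  ``cost_*`` excludes the
    intervention's implementation cost, which is booked separately
    (year 0, undiscounted, intervention arm only).
    """

    sex: np.ndarray
    ethnicity: np.ndarray
    age0: np.ndarray
    population: np.ndarray
    qaly_bau: np.ndarray
    qaly_int: np.ndarray
    cost_bau: np.ndarray
    cost_int: np.ndarray
    baseline_year: int
    discount_rate: float
    intervention_cost: float

    @property
    def n_years(self) -> int:
        return self.qaly_bau.shape[1]

    def _mask(self, sex=None, ethnicity=None, age_band=None) -> np.ndarray:
        mask = np.ones(self.population.shape, dtype=bool)
        if sex is not None:
            mask &= self.sex == sex
        if ethnicity is not None:
            mask &= self.ethnicity == ethnicity
        if age_band is not None:
            lo, hi = age_band
            mask &= (self.age0 >= lo) & (self.age0 <= hi)
        return mask

    def _discounted_delta(
        self, a_int, a_bau, mask, horizon=None, discount_rate=None
    ) -> float:
        rate = self.discount_rate if discount_rate is None else discount_rate
        if rate < 0:
            raise DomainError("discount rate must be >= 0")
        n = self.n_years if horizon is None else min(horizon, self.n_years)
        factors = 1.0 / (1.0 + rate) ** np.arange(n)
        delta = (a_int[mask, :n] - a_bau[mask, :n]).sum(axis=0)
        return float(np.sum(delta * factors))

    def qaly_gain(
        self, sex=None, ethnicity=None, age_band=None, horizon=None, discount_rate=None
    ) -> float:
        """Discounted QALYs gained by the intervention over BAU."""
        mask = self._mask(sex, ethnicity, age_band)
        return self._discounted_delta(
            self.qaly_int, self.qaly_bau, mask, horizon, discount_rate
        )

    def cost_offset(
        self, sex=None, ethnicity=None, age_band=None, horizon=None, discount_rate=None
    ) -> float:
        """Discounted downstream cost change (excl. intervention cost)."""
        mask = self._mask(sex, ethnicity, age_band)
        return self._discounted_delta(
            self.cost_int, self.cost_bau, mask, horizon, discount_rate
        )

    def net_cost(
        self, sex=None, ethnicity=None, age_band=None, horizon=None, discount_rate=None
    ) -> float:
        """Intervention cost plus discounted cost offsets.

        The one-off campaign cost falls in year 0 (undiscounted); for
        subgroup selections it is apportioned by population share.
        """
        mask = self._mask(sex, ethnicity, age_band)
        share = self.population[mask].sum() / self.population.sum()
        return self.intervention_cost * share + self._discounted_delta(
            self.cost_int, self.cost_bau, mask, horizon, discount_rate
        )

    def summary(self) -> dict:
        """Headline quantities at the 10-year, 20-year and lifetime horizons."""
        out = {}
        for label, horizon in (("10y", 10), ("20y", 20), ("lifetime", None)):
            q = self.qaly_gain(horizon=horizon)
            c = self.net_cost(horizon=horizon)
            out[label] = {
                "qalys_gained": q,
                "net_cost_nzd": c,
                "net_cost_usd": c * NZD_TO_USD,
            }
        out["discount_rate"] = self.discount_rate
        return out

    def to_frame(self) -> pd.DataFrame:
        """Per-cohort-year export (undiscounted deltas)."""
        n_c, n_y = self.qaly_bau.shape
        years = self.baseline_year + np.arange(n_y)
        return pd.DataFrame(
            {
                "sex": np.repeat(self.sex, n_y),
                "ethnicity": np.repeat(self.ethnicity, n_y),
                "age0": np.repeat(self.age0, n_y),
                "year": np.tile(years, n_c),
                "qaly_gain": (self.qaly_int - self.qaly_bau).ravel(),
                "cost_offset": (self.cost_int - self.cost_bau).ravel(),
            }
        )


# --------------------------------------------------------------------------
# vectorised paired-cohort engine
# --------------------------------------------------------------------------


class Model:
    """Compiled form of a parameter bundle, with the BAU arm precomputed.

    Building a ``Model`` flattens all (sex × ethnicity × baseline-age)
    cohorts into one axis and materialises per-cohort-per-year rate
    matrices, then runs the BAU arm once.  ``run`` then simulates only the
    intervention arm, which makes Monte Carlo loops cheap.
    """

    def __init__(self, bundle: ParameterBundle):
        self.bundle = bundle
        ages = bundle.ages
        n_age = ages.size
        self.n_years = n_age
        groups = [(sex, eth) for sex in SEXES for eth in ETHNICITIES]

        t = np.arange(self.n_years)
        age_idx = np.minimum(np.arange(n_age)[:, None] + t[None, :], n_age - 1)

        demo = bundle.demography
        uc = bundle.unrelated_cost
        dr = bundle.disease_rates
        rr = bundle.relative_risks
        attrs = bundle.disease_attrs
        self.diseases = list(attrs["disease"])
        n_dis = len(self.diseases)

        sex_l, eth_l, pop_l, mort_l, pyld_l, unrel_l, pow_l = [], [], [], [], [], [], []
        inc_blocks = {d: [] for d in self.diseases}
        cf_blocks = {d: [] for d in self.diseases}
        rem_blocks = {d: [] for d in self.diseases}

        bmi = bundle.bmi
        for sex, eth in groups:
            dsel = demo[(demo["sex"] == sex) & (demo["ethnicity"] == eth)].sort_values("age")
            if len(dsel) != n_age:
                raise DomainError(f"demography incomplete for {sex}/{eth}")
            sex_l.append(np.full(n_age, sex, dtype=object))
            eth_l.append(np.full(n_age, eth, dtype=object))
            pop_l.append(dsel["population"].to_numpy())
            mort_l.append(dsel["mortality"].to_numpy()[age_idx])
            pyld_l.append(dsel["pyld"].to_numpy()[age_idx])
            usel = uc[uc["sex"] == sex].sort_values("age")
            unrel_l.append(usel["cost"].to_numpy()[age_idx])
            bsel = bmi[(bmi["sex"] == sex) & (bmi["ethnicity"] == eth)].sort_values("age")
            pow_l.append(bsel["overweight_prop"].to_numpy())
            for d in self.diseases:
                rsel = dr[
                    (dr["disease"] == d) & (dr["sex"] == sex) & (dr["ethnicity"] == eth)
                ].sort_values("age")
                inc_blocks[d].append(rsel["incidence"].to_numpy()[age_idx])
                cf_blocks[d].append(rsel["case_fatality"].to_numpy()[age_idx])
                rem_blocks[d].append(rsel["remission"].to_numpy()[age_idx])

        self.sex = np.concatenate(sex_l)
        self.ethnicity = np.concatenate(eth_l)
        self.age0 = np.tile(ages, len(groups))
        self.population = np.concatenate(pop_l)
        self.mort = np.vstack(mort_l)
        self.pyld = np.vstack(pyld_l)
        self.unrel = np.vstack(unrel_l)
        self.p_overweight = np.concatenate(pow_l)
        n_coh = self.population.size

        self.inc = np.stack([np.vstack(inc_blocks[d]) for d in self.diseases])
        self.cf = np.stack([np.vstack(cf_blocks[d]) for d in self.diseases])
        self.rem = np.stack([np.vstack(rem_blocks[d]) for d in self.diseases])

        # log-RR per BMI unit, by disease and attained age (same across strata)
        beta_age = np.empty((n_dis, n_age))
        for k, d in enumerate(self.diseases):
            rsel = rr[rr["disease"] == d].sort_values("age")
            beta_age[k] = np.log(rsel["rr"].to_numpy())
        # tile across the four sex×ethnicity groups along the cohort axis
        self.beta = np.tile(beta_age[:, age_idx], (1, len(groups), 1))

        self.dw = attrs["disability_weight"].to_numpy()
        self.cost_first = attrs["cost_first_year"].to_numpy()
        self.cost_sub = attrs["cost_subsequent_year"].to_numpy()
        self.cost_l6m = attrs["cost_last_6m"].to_numpy()
        self.is_cancer = attrs["is_cancer"].to_numpy().astype(bool)
        self.default_lags = [
            LagSpec(int(lo), int(hi))
            for lo, hi in zip(attrs["lag_min"], attrs["lag_max"])
        ]

        self.alive_next = (self.age0[:, None] + t[None, :] + 1) <= bundle.closure_age

        # BAU arm, computed once
        self.new_bau, self.deaths_bau, self.prev_bau = self._simulate_diseases(None)
        self.qaly_bau_pc, self.cost_bau_pc = self._finish_arm(
            self.deaths_bau, self.prev_bau, self.new_bau, bau=True
        )

    # -- internals ---------------------------------------------------------

    def _simulate_diseases(self, pif: np.ndarray | None):
        n_dis, n_coh, n_y = self.inc.shape
        S = np.ones((n_dis, n_coh))
        C = np.zeros((n_dis, n_coh))
        new = np.empty((n_dis, n_coh, n_y))
        deaths = np.empty_like(new)
        prev = np.empty_like(new)
        for t in range(n_y):
            i = self.inc[:, :, t]
            if pif is not None:
                i = i * (1.0 - pif[:, :, t])
            nw, dth, rmt = _step_flows(S, C, i, self.cf[:, :, t], self.rem[:, :, t])
            S = S - nw + rmt
            C = C + nw - dth - rmt
            new[:, :, t] = nw
            deaths[:, :, t] = dth
            prev[:, :, t] = C
        return new, deaths, prev

    def _finish_arm(self, deaths, prev, new, bau: bool):
        if bau:
            m, py = self.mort, self.pyld
        else:
            m, py = link_mortality_morbidity(
                self.mort, self.pyld, self.deaths_bau, deaths, self.prev_bau, prev, self.dw
            )
        surv_mult = np.exp(-m) * self.alive_next
        l = np.concatenate(
            [np.ones((surv_mult.shape[0], 1)), np.cumprod(surv_mult, axis=1)], axis=1
        )
        ly = 0.5 * (l[:, :-1] + l[:, 1:])
        qaly = ly * (1.0 - py)
        disease_cost = (
            new * self.cost_first[:, None, None]
            + np.clip(prev - new, 0.0, None) * self.cost_sub[:, None, None]
            + deaths * self.cost_l6m[:, None, None]
        ).sum(axis=0)
        cost = ly * (disease_cost + self.unrel)
        return qaly, cost

    def _pif_series(self, spec: InterventionSpec) -> np.ndarray:
        effect = spec.resolved_effect()
        if effect <= 0:
            delta = bmi_effect_trajectory(effect, spec.effect_spec, self.n_years)
        else:
            # A sampled effect may fall on the harmful side of its CI; the
            # same regain dynamics then pull the BMI increase back to zero.
            delta = -bmi_effect_trajectory(-effect, spec.effect_spec, self.n_years)
        p_ow = (
            self.p_overweight
            if spec.p_overweight is None
            else np.full_like(self.p_overweight, spec.p_overweight)
        )
        p_elig = p_ow * spec.p_smartphone * spec.p_recognition * spec.p_uptake
        raw = p_elig[None, :, None] * -np.expm1(self.beta * delta[None, None, :])
        out = np.empty_like(raw)
        for k in range(raw.shape[0]):
            lag = self.default_lags[k]
            if spec.lag_overrides:
                key = "cancer" if self.is_cancer[k] else "cvd_metabolic"
                lag = spec.lag_overrides.get(key, lag)
            out[k] = apply_lag(raw[k], lag)
        return out

    # -- public ------------------------------------------------------------

    def run(self, spec: InterventionSpec, discount_rate: float = 0.03) -> RunResult:
        """Simulate the intervention arm and pair it with the cached BAU arm."""
        if discount_rate < 0:
            raise DomainError("discount rate must be >= 0")
        pif = self._pif_series(spec)
        new_i, deaths_i, prev_i = self._simulate_diseases(pif)
        qaly_int_pc, cost_int_pc = self._finish_arm(deaths_i, prev_i, new_i, bau=False)
        pop = self.population[:, None]
        return RunResult(
            sex=self.sex,
            ethnicity=self.ethnicity,
            age0=self.age0,
            population=self.population,
            qaly_bau=self.qaly_bau_pc * pop,
            qaly_int=qaly_int_pc * pop,
            cost_bau=self.cost_bau_pc * pop,
            cost_int=cost_int_pc * pop,
            baseline_year=self.bundle.baseline_year,
            discount_rate=discount_rate,
            intervention_cost=spec.cost,
        )


def run_paired(
    bundle: ParameterBundle,
    spec: InterventionSpec | None = None,
    discount_rate: float = 0.03,
) -> RunResult:
    """Convenience wrapper: build a :class:`Model` and run one intervention."""
    return Model(bundle).run(spec or InterventionSpec(), discount_rate)
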