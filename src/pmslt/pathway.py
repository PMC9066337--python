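"""Intervention uptake cascade and BMI effect trajectory.

A one-off, one-year mass-media campaign promotes weight-loss smartphone apps.
The reach of the campaign is a sequential cascade of independent proportions:

    adults with BMI >= 25  ->  smartphone owners  ->  campaign recognition
        ->  download-and-use

whose product is the fraction of the adult population that actually uses an
app and loses weight.  App effectiveness is a duration-weighted pooled BMI
change (users adhering <= 3 months vs > 3 months), and the achieved BMI
reduction erodes over time through weight regain at a fixed rate per month.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DomainError

__all__ = [
    "UptakeCascade",
    "EffectSpec",
    "eligible_fraction",
    "weighted_effect_size",
    "bmi_effect_trajectory",
]


@dataclass(frozen=True)
class UptakeCascade:
    """Sequential proportions of the adult population reached by the campaign.

    Defaults are the base-case values: 73% of adults with overweight/obesity,
    81% smartphone ownership, 45% campaign recognition, 14% downloading and
    using the promoted app.
    """

    p_overweight: float = 0.73
    p_smartphone: float = 0.81
    p_recognition: float = 0.45
    p_uptake: float = 0.14

    def __post_init__(self) -> None:
        for name in ("p_overweight", "p_smartphone", "p_recognition", "p_uptake"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise DomainError(f"{name}={value} outside [0, 1]")

    def intermediates(self) -> tuple[float, float, float]:
        """Running products after each cascade stage.

        Returns (after smartphone ownership, after recognition, final).
        With base-case inputs these are 0.591, 0.266 and 0.037.
        """
        a = self.p_overweight * self.p_smartphone
        b = a * self.p_recognition
        return a, b, b * self.p_uptake


def eligible_fraction(cascade: UptakeCascade) -> float:
    """Final fraction of the adult population that uses the app.

    The product of all four cascade proportions; base case ≈ 3.7%.
    """
    return cascade.intermediates()[2]


@dataclass(frozen=True)
class EffectSpec:
    """Pooled app effect on BMI and post-intervention regain dynamics.

    ``e_short``/``e_long`` are the pooled BMI changes (kg/m²) for users who
    adhere for <= 3 months and > 3 months; ``p_short``/``p_long`` the
    corresponding user proportions.  ``regain_rate`` is the monthly BMI
    regain (kg/m² per month) that erodes the achieved reduction, starting
    ``regain_delay`` years after the intervention year (``no_regain``
    suppresses erosion entirely).
    """

    e_short: float = -0.219
    e_long: float = -0.609
    p_short: float = 0.53
    p_long: float = 0.47
    regain_rate: float = 0.03
    regain_delay: float = 0.0
    no_regain: bool = False

    def __post_init__(self) -> None:
        if self.regain_rate < 0:
            raise DomainError(f"regain_rate={self.regain_rate} must be >= 0")
        if self.regain_delay < 0:
            raise DomainError(f"regain_delay={self.regain_delay} must be >= 0")

    def with_(self, **changes) -> "EffectSpec":
        return replace(self, **changes)


def weighted_effect_size(spec: EffectSpec) -> float:
    """Duration-weighted pooled BMI change, kg/m².

    E = e_short * p_short + e_long * p_long; with the default pooled effects
    this is -0.402 kg/m² (reported rounded as -0.400).
    """
    if abs(spec.p_short + spec.p_long - 1.0) > 1e-9:
        raise DomainError(
            f"p_short + p_long = {spec.p_short + spec.p_long!r} must equal 1"
        )
    return spec.e_short * spec.p_short + spec.e_long * spec.p_long


def bmi_effect_trajectory(
    effect: float, spec: EffectSpec, horizon: int
) -> np.ndarray:
    """Population-average BMI change δ(t) for eligible users, year by year.

    δ(0) equals ``effect`` (the pooled trial effect is achieved within the
    intervention year).  From ``regain_delay`` years on, the reduction erodes
    linearly at ``regain_rate`` × 12 kg/m² per year, clipped at zero; with
    ``no_regain`` the full effect persists for the whole horizon.

    Returns an array of length ``horizon`` with values in [effect, 0].
    """
    if effect > 0:
        raise DomainError(f"effect={effect} must be <= 0 (BMI must not increase)")
    if horizon < 1:
        raise DomainError(f"horizon={horizon} must be >= 1")
    t = np.arange(horizon, dtype=float)
    if spec.no_regain:
        return np.full(horizon, effect)
    erosion = np.maximum(0.0, t - spec.regain_delay) * spec.regain_rate * 12.0
    return np.clip(effect + erosion, effect, 0.0)
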