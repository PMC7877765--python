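"""Model parameters, policy and climate scenarios, and schedule helpers.

All monetary quantities are in US dollars; food prices are stored in $/kg
(0.40 $/kg = 40 cents/kg, the initial local and global price). Yields and
diets are in kg of cereal equivalents per year.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Any

import yaml

log = logging.getLogger(__name__)

# Farming styles. Orphan and agroecology are peasant sub-styles; the
# entrepreneurial style is market- and credit-dependent.
ORPHAN = "orphan"
AGRO = "agroecology"
ENTRE = "entrepreneurial"

STYLES = (ORPHAN, AGRO, ENTRE)


class ConfigError(ValueError):
    """Raised for unknown scenario names or out-of-range overrides."""


@dataclass
class Params:
    """All scalar model parameters with their default values.

    Defaults describe a community in which the average orphan farmer sits
    close to the income threshold for developing their farm: 1 ha yields
    ~1000 kg/yr, of which 700 kg feeds the family and ~110 kg feeds the
    labour effort, leaving ~$77/yr of marketable surplus at 40 c/kg.
    """

    # World size and horizon
    grid_side: int = 21
    n_households: int = 250
    years: int = 50

    # Plot productivity
    base_plot_yield_mean: float = 1000.0        # kg/yr under orphan farming
    base_plot_yield_halfwidth: float = 0.20     # uniform +/- fraction
    agro_multiple_mean: float = 4.0
    agro_multiple_sd: float = 1.5
    agro_multiple_bounds: tuple[float, float] = (2.0, 7.0)
    agro_transition_years: int = 3
    plot_yield_cap: float = 10_000.0            # kg/ha, any style

    # Slow yield increments on optimised peasant plots (rate per year)
    orphan_yield_increment_peasant: float = 0.015
    orphan_yield_increment_other: float = 0.010
    agro_yield_increment_peasant: float = 0.030
    agro_yield_increment_other: float = 0.015

    # Diet and labour
    basic_diet_kg: float = 700.0                # kg/yr per 4-person household
    labour_full_kcal: float = 5100.0            # kcal/day at full effort
    labour_extra_kcal: float = 2900.0           # kcal/day above basic diet
    labour_days_full: int = 150                 # 10-h days per FTE-year
    cereal_kcal_per_kg: float = 4015.0          # 200 kg -> 2200 kcal/day/yr
    agro_labour_multiple: float = 2.0           # labour-diet & input intensity
    family_workers: float = 2.0                 # FTE per household

    # Climate response
    warming_loss_per_degC: float = 0.04
    agro_warming_loss_reduction: float = 0.10   # agro rate = 0.04 * 0.9
    agro_drought_loss_reduction: float = 0.20   # agro loss *= 0.8
    base_drought_risk: float = 0.05             # per year, year 0
    farm_drought_noise_halfwidth: float = 0.25  # per-farm multiplicative

    # Yield realization noise
    yield_noise_halfwidth: float = 0.15

    # Abandonment
    abandonment_diet_fraction: float = 0.5

    # Prices ($/kg unless noted)
    initial_local_price: float = 0.40
    initial_global_price: float = 0.40
    oscillator_amplitude: float = 0.015         # $/kg (1.5 cents)
    oscillator_period: float = 10.0             # years
    price_floor: float = 0.01                   # $/kg (1 cent)

    # Input prices
    wage_markup: float = 1.8                    # x cost of a basic diet
    wage_drift: float = 0.02                    # per year
    necessary_input_share: float = 0.15         # of wage, per ha at full prod
    fertilizer_price_multiple: float = 10.0     # x local food price per kg
    fertilizer_drift: float = 0.01              # per year
    fertilizer_max_kg: float = 500.0            # per ha for max productivity
    fertilizer_max_multiple: float = 10.0       # x base yield at max fert

    # Capital goods
    animal_capacity_ha: float = 5.0             # ha/worker with animal team
    tractor_capacity_ha: float = 16.0           # ha/worker with tractor
    animal_price_years: float = 30.0            # years of orphan net income
    tractor_price_years: float = 150.0
    land_price_tonnes: float = 30.0             # tonnes of cereal per ha

    # Credit (annual rates; terms in years)
    interest_short: float = 0.20
    interest_mid: float = 0.15
    interest_long: float = 0.10
    loan_term_short: int = 1
    loan_term_mid: int = 5                      # midpoint of the 3-6 yr band
    loan_term_long: int = 8

    # Expansion rules
    agro_max_ha: int = 10
    agro_max_animal_teams: int = 2
    entre_land_per_year: int = 1
    agro_expansion_min_years_per_ha: int = 3

    # Behavioural constants
    price_expectation_noise: float = 0.05       # uniform +/- on expectations
    entre_ask_markup: float = 1.2               # over unit cash cost

    # Sensitivity-analysis overrides (None = main-model behaviour)
    fixed_yield_ratio: float | None = None      # agro:entre max-yield ratio
    agro_climate_sensitivity: float | None = None  # in {0.9, 1.0, 1.1}

    def validate(self) -> None:
        positive = (
            "grid_side", "n_households", "years", "base_plot_yield_mean",
            "plot_yield_cap", "basic_diet_kg", "cereal_kcal_per_kg",
            "initial_local_price", "initial_global_price", "wage_markup",
            "fertilizer_price_multiple", "fertilizer_max_kg",
            "animal_capacity_ha", "tractor_capacity_ha",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        fractions = (
            "base_plot_yield_halfwidth", "warming_loss_per_degC",
            "agro_warming_loss_reduction", "agro_drought_loss_reduction",
            "base_drought_risk", "yield_noise_halfwidth",
            "abandonment_diet_fraction", "necessary_input_share",
            "wage_drift", "fertilizer_drift", "price_expectation_noise",
        )
        for name in fractions:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} must lie in [0, 1]")
        lo, hi = self.agro_multiple_bounds
        if not (1.0 < lo <= hi <= self.fertilizer_max_multiple):
            raise ConfigError(
                "agro_multiple_bounds must lie within (1, fertilizer_max_multiple]"
            )
        if self.fixed_yield_ratio is not None and not 0 < self.fixed_yield_ratio <= 1:
            raise ConfigError("fixed_yield_ratio must lie in (0, 1]")
        if self.agro_climate_sensitivity is not None and self.agro_climate_sensitivity <= 0:
            raise ConfigError("agro_climate_sensitivity must be positive")

    @property
    def labour_diet_kg_per_fte(self) -> float:
        """kg of cereal equivalents feeding one FTE-year of full effort."""
        return self.labour_extra_kcal * self.labour_days_full / self.cereal_kcal_per_kg


@dataclass
class PolicyScenario:
    """Agricultural policy: which farming style is favoured, and how."""

    name: str
    prop_pref_agro: float
    transmission: float
    fertilizer_subsidy: float = 0.0
    interest_halved: bool = False
    eroding: bool = False

    @property
    def peasant_increments(self) -> bool:
        """Peasant policy raises the annual yield-increment rates."""
        return self.name == "peasant"

    def validate(self) -> None:
        if not 0.0 <= self.prop_pref_agro <= 1.0:
            raise ConfigError(f"prop_pref_agro={self.prop_pref_agro} not in [0, 1]")
        if not 0.0 <= self.transmission <= 1.0:
            raise ConfigError(f"transmission={self.transmission} not in [0, 1]")
        if not 0.0 <= self.fertilizer_subsidy <= 1.0:
            raise ConfigError(f"fertilizer_subsidy={self.fertilizer_subsidy} not in [0, 1]")


@dataclass
class ClimateScenario:
    """Climate severity: warming trend, drought risk growth and losses.

    Warming is linear in time; drought risk interpolates linearly from the
    base 5 %/yr at year 0 up to ``multiplier`` times that at year 50. The
    global food-price trend declines most slowly under high climate change.
    """

    name: str
    warming_total_degC: float
    drought_risk_multiplier_at_50yr: float
    local_drought_loss_mean: float
    local_drought_loss_max: float
    global_trend_decline: float                 # fraction per year
    global_drought_bump: tuple[float, float]    # uniform range

    def validate(self) -> None:
        if self.warming_total_degC < 0:
            raise ConfigError("warming_total_degC must be non-negative")
        if not 0 < self.local_drought_loss_mean <= self.local_drought_loss_max <= 1:
            raise ConfigError("drought loss mean/max must satisfy 0 < mean <= max <= 1")


POLICIES: dict[str, PolicyScenario] = {
    "entrepreneurial": PolicyScenario(
        "entrepreneurial", prop_pref_agro=0.25, transmission=0.75,
        fertilizer_subsidy=0.5, interest_halved=True,
    ),
    "entrepreneurial_eroding": PolicyScenario(
        "entrepreneurial_eroding", prop_pref_agro=0.25, transmission=0.75,
        fertilizer_subsidy=0.5, interest_halved=True, eroding=True,
    ),
    "peasant": PolicyScenario(
        "peasant", prop_pref_agro=0.75, transmission=0.25,
    ),
    "none": PolicyScenario(
        "none", prop_pref_agro=0.5, transmission=0.5,
    ),
}

CLIMATES: dict[str, ClimateScenario] = {
    "no": ClimateScenario(
        "no", warming_total_degC=0.0, drought_risk_multiplier_at_50yr=1.0,
        local_drought_loss_mean=0.075, local_drought_loss_max=0.20,
        global_trend_decline=0.015, global_drought_bump=(0.05, 0.075),
    ),
    "low": ClimateScenario(
        "low", warming_total_degC=1.0, drought_risk_multiplier_at_50yr=1.5,
        local_drought_loss_mean=0.10, local_drought_loss_max=0.25,
        global_trend_decline=0.0125, global_drought_bump=(0.075, 0.125),
    ),
    "high": ClimateScenario(
        "high", warming_total_degC=2.0, drought_risk_multiplier_at_50yr=2.0,
        local_drought_loss_mean=0.15, local_drought_loss_max=0.30,
        global_trend_decline=0.010, global_drought_bump=(0.10, 0.175),
    ),
}


def build_scenario(
    policy_name: str,
    climate_name: str,
    overrides: dict[str, Any] | None = None,
) -> tuple[Params, PolicyScenario, ClimateScenario]:
    """Resolve a fully-validated configuration.

    ``overrides`` may touch any declared field of :class:`Params`,
    :class:`PolicyScenario` or :class:`ClimateScenario` (matched by field
    name, policy/climate taking precedence over params for shared names).
    Unknown keys or out-of-range values raise :class:`ConfigError` naming
    the offending field.
    """
    if policy_name not in POLICIES:
        raise ConfigError(
            f"unknown policy {policy_name!r}; expected one of {sorted(POLICIES)}"
        )
    if climate_name not in CLIMATES:
        raise ConfigError(
            f"unknown climate {climate_name!r}; expected one of {sorted(CLIMATES)}"
        )
    params = Params()
    policy = dataclasses.replace(POLICIES[policy_name])
    climate = dataclasses.replace(CLIMATES[climate_name])

    param_fields = {f.name for f in dc_fields(Params)}
    policy_fields = {f.name for f in dc_fields(PolicyScenario)} - {"name"}
    climate_fields = {f.name for f in dc_fields(ClimateScenario)} - {"name"}

    for key, value in (overrides or {}).items():
        if key in policy_fields:
            setattr(policy, key, value)
        elif key in climate_fields:
            setattr(climate, key, value)
        elif key in param_fields:
            setattr(params, key, value)
        else:
            raise ConfigError(f"unknown configuration field {key!r}")

    params.validate()
    policy.validate()
    climate.validate()
    return params, policy, climate


_erosion_clamp_logged: set[tuple[float, float, int]] = set()


def eroded_value(initial: float, final: float, year: int, horizon: int) -> float:
    """Linear interpolation between ``initial`` at year 0 and ``final`` at
    ``year == horizon``; years beyond the horizon clamp to ``final``.

    Used for the eroding-policy schedules (fertilizer subsidy falling
    1 %-point/yr from 50 %; halved interest rates returning linearly to
    their full values over 50 years).
    """
    if year < 0:
        raise ConfigError("year must be non-negative")
    if year > horizon:
        key = (initial, final, horizon)
        if key not in _erosion_clamp_logged:
            log.warning("eroded_value: year %d beyond horizon %d, clamping", year, horizon)
            _erosion_clamp_logged.add(key)
        return final
    if horizon == 0:
        return final
    return initial + (final - initial) * year / horizon


# ---------------------------------------------------------------------------
# Flat-file serialization: one document of named scalar fields.

def scenario_to_dict(
    params: Params, policy: PolicyScenario, climate: ClimateScenario
) -> dict[str, Any]:
    doc: dict[str, Any] = {"policy": policy.name, "climate": climate.name}
    for f in dc_fields(Params):
        v = getattr(params, f.name)
        doc[f.name] = list(v) if isinstance(v, tuple) else v
    for f in dc_fields(PolicyScenario):
        if f.name != "name":
            doc[f.name] = getattr(policy, f.name)
    for f in dc_fields(ClimateScenario):
        if f.name != "name":
            v = getattr(climate, f.name)
            doc[f.name] = list(v) if isinstance(v, tuple) else v
    return doc


def scenario_to_yaml(
    params: Params, policy: PolicyScenario, climate: ClimateScenario
) -> str:
    return yaml.safe_dump(scenario_to_dict(params, policy, climate), sort_keys=True)


def scenario_from_yaml(text: str) -> tuple[Params, PolicyScenario, ClimateScenario]:
    doc = yaml.safe_load(text)
    policy_name = doc.pop("policy")
    climate_name = doc.pop("climate")
    tuple_fields = {"agro_multiple_bounds", "global_drought_bump"}
    overrides = {
        k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
        for k, v in doc.items()
    }
    return build_scenario(policy_name, climate_name, overrides)
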