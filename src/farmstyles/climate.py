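"""Warming, drought risk and drought events for the local area and the
global price process.

Warming rises linearly to the scenario total over 50 years. Drought risk
starts at 5 %/yr and interpolates linearly to ``multiplier`` times that at
year 50. Local and global drought events are independent draws at the same
risk. A local drought draws one community-wide mean loss; each farm then
experiences that loss with multiplicative noise, reduced for agroecology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from farmstyles.config import AGRO, ClimateScenario, Params

HORIZON = 50  # years over which scenario trends are defined


@dataclass
class ClimateState:
    scenario: ClimateScenario
    year: int = 0
    warming: float = 0.0
    local_drought_risk: float = 0.05
    local_drought: bool = False
    local_drought_loss: float = 0.0   # community-wide mean loss this year
    global_drought: bool = False
    global_drought_bump: float = 0.0


def drought_risk(scenario: ClimateScenario, params: Params, year: int) -> float:
    mult = scenario.drought_risk_multiplier_at_50yr
    return params.base_drought_risk * (1.0 + (mult - 1.0) * min(year, HORIZON) / HORIZON)


def step_climate(state: ClimateState, params: Params,
                 rng: np.random.Generator) -> ClimateState:
    """Advance one year: update warming and risk, draw drought events.

    The community drought loss is drawn Uniform[0, 2*mean] truncated at the
    scenario maximum, so its expectation equals the scenario mean loss.
    """
    sc = state.scenario
    year = state.year + 1
    warming = sc.warming_total_degC * min(year, HORIZON) / HORIZON
    risk = drought_risk(sc, params, year)

    local = bool(rng.random() < risk)
    loss = 0.0
    if local:
        hi = min(2.0 * sc.local_drought_loss_mean, sc.local_drought_loss_max)
        loss = rng.uniform(0.0, hi)

    glob = bool(rng.random() < risk)
    bump = 0.0
    if glob:
        bump = rng.uniform(*sc.global_drought_bump)

    return ClimateState(
        scenario=sc, year=year, warming=warming, local_drought_risk=risk,
        local_drought=local, local_drought_loss=loss,
        global_drought=glob, global_drought_bump=bump,
    )


def _agro_rate_multiplier(params: Params, default_reduction: float) -> float:
    """Agroecology climate-loss rate relative to other styles.

    Defaults: warming losses 10% lower, drought losses 20% lower. In
    sensitivity mode a single relative sensitivity (0.9 / 1.0 / 1.1)
    replaces both reductions.
    """
    if params.agro_climate_sensitivity is not None:
        return params.agro_climate_sensitivity
    return 1.0 - default_reduction


def warming_loss_factor(warming: float, style: str, params: Params) -> float:
    """Multiplicative yield factor for the current warming level."""
    rate = params.warming_loss_per_degC
    if style == AGRO:
        rate *= _agro_rate_multiplier(params, params.agro_warming_loss_reduction)
    return max(0.0, 1.0 - rate * warming)


def drought_loss_factor(state: ClimateState, style: str, params: Params,
                        rng: np.random.Generator) -> float:
    """Per-farm multiplicative yield factor for this year's drought.

    The community mean loss is perturbed per farm by a multiplicative
    Uniform[1-w, 1+w] (w = 0.25), clamped to [0, scenario max], then
    reduced for agroecology.
    """
    if not state.local_drought:
        return 1.0
    w = params.farm_drought_noise_halfwidth
    loss = state.local_drought_loss * rng.uniform(1.0 - w, 1.0 + w)
    loss = min(max(loss, 0.0), state.scenario.local_drought_loss_max)
    if style == AGRO:
        loss *= _agro_rate_multiplier(params, params.agro_drought_loss_reduction)
    return min(1.0, max(0.0, 1.0 - loss))
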