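"""Farming households and their annual decisions.

Each household (four people, two full-time-equivalent family workers)
starts as an orphan (subsistence) farm on one 1-ha plot and may develop
into its preferred style:

* agroecology (peasant): a 3-year, savings-financed transition per plot
  that raises the plot's maximum yield by its agroecology multiple;
  family labour only, no credit; expansion up to 10 ha and two teams of
  working animals, savings-only.
* entrepreneurial: purchased fertilizer (up to a 10x yield), hired wage
  labour, credit; expands land, animals and tractors whenever income plus
  savings cover at least half the cost.

Peasants maximise returns to labour (labour is never costed; the labour
diet is provided in kind); entrepreneurs optimise with every input costed,
family labour included. Both face diminishing returns: producing a
fraction q of the attainable maximum requires the fraction q^2 of each
variable input (labour effort, necessary inputs, fertilizer).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from farmstyles.config import AGRO, ENTRE, ORPHAN, Params
from farmstyles.climate import ClimateState, drought_loss_factor, warming_loss_factor
from farmstyles.landscape import (
    Landscape,
    Plot,
    agro_target_yield,
    entre_max_yield,
    release_plot,
    start_transition,
)
from farmstyles.market import (
    Loan,
    MarketState,
    annual_debt_service,
    scheduled_debt_service,
)

log = logging.getLogger(__name__)

# Rationing preferences: 'production' households ration the family diet
# (down to the 50% floor) to pay input bills and build development
# savings; 'nutrition' households protect the diet and sell assets or
# defer inputs instead. Saving styles: 'hoard' households keep all cash;
# 'spend' households keep only a goal-oriented reserve (conversion cost,
# then the next hectare plus working capital) and consume the rest, and
# buy food up to a full diet in shortfall years where hoarders stop at
# the floor.
RATION_PRODUCTION = "production"
RATION_NUTRITION = "nutrition"
SAVE_HOARD = "hoard"
SAVE_SPEND = "spend"


@dataclass(slots=True)
class Plan:
    """One household's production plan for the year."""

    q: float = 0.0                 # fraction of attainable maximum
    q_unconstrained: float = 0.0   # optimum before goal escalation
    attainable: float = 0.0        # kg at q = 1
    target: float = 0.0            # kg
    area: int = 0                  # ha farmed
    fte_full: float = 0.0          # FTE at q = 1
    fte_used: float = 0.0
    hired_fte: float = 0.0
    labour_diet_kg: float = 0.0
    ni_cost: float = 0.0           # necessary inputs, $
    fert_kg: float = 0.0
    fert_cost: float = 0.0         # total fertilizer bill, $
    fert_cash: float = 0.0         # paid from savings
    fert_loan: float = 0.0         # short-term credit
    wage_cost: float = 0.0         # hired labour, $
    debt_due: float = 0.0          # annuities scheduled this year
    optimized: bool = True         # produced at the unconstrained optimum


@dataclass(slots=True)
class Household:
    id: int
    preference: str                      # AGRO or ENTRE
    plot_ids: list[int]
    rationing_pref: str = RATION_PRODUCTION
    saving_style: str = SAVE_HOARD
    style: str = ORPHAN
    savings: float = 0.0
    loans: list[Loan] = field(default_factory=list)
    animal_teams: int = 0
    tractors: int = 0
    active: bool = True
    converted: bool = False
    conversion_prepaid_years: int = 0    # transition years already paid for
    last_production: float = 0.0
    last_net_income: float = 0.0
    income_smooth: float = 0.0   # exponentially smoothed net income
    diet_fraction: float = 1.0
    gross_value: float = 0.0
    purchased_inputs_nonlabour: float = 0.0
    plan: Plan = field(default_factory=Plan)
    ledger: dict[str, float] = field(default_factory=dict)
    new_loans: list[Loan] = field(default_factory=list)
    abandon_reason: str = ""

    def plots(self, land: Landscape) -> list[Plot]:
        return [land.plots[i] for i in self.plot_ids]

    @property
    def area(self) -> int:
        return len(self.plot_ids)

    def asset_value(self, market: MarketState) -> float:
        return (self.animal_teams * market.animal_price
                + self.tractors * market.tractor_price
                + self.area * market.land_price)


# ---------------------------------------------------------------------------
# Capacity and input requirements

def peasant_capacity_ha(h: Household, params: Params) -> float:
    """Area manageable with family labour and owned animal teams."""
    workers = params.family_workers
    teams = min(h.animal_teams, int(workers))
    return teams * params.animal_capacity_ha + (workers - teams) * 1.0


def fte_at_full(h: Household, area: float, params: Params) -> float:
    """FTE needed to farm ``area`` ha at full effort, best equipment first."""
    rem = float(area)
    fte = 0.0
    for _ in range(h.tractors):
        if rem <= 0:
            break
        cover = min(params.tractor_capacity_ha, rem)
        fte += cover / params.tractor_capacity_ha
        rem -= cover
    for _ in range(h.animal_teams):
        if rem <= 0:
            break
        cover = min(params.animal_capacity_ha, rem)
        fte += cover / params.animal_capacity_ha
        rem -= cover
    fte += max(rem, 0.0)
    return fte


def _cost_intensity(h: Household) -> tuple[float, float]:
    """(labour-diet multiplier, necessary-input multiplier in units of the
    per-ha full-production rate) for the household's current way of farming.

    Every household needs the standard per-ha rate (clothing, tool
    repair, building maintenance); agroecology needs twice that (input
    needs rise with labour). During the initially prepaid conversion
    years an agroecology farm's extras are already covered.
    """
    if h.style == ORPHAN:
        return 1.0, 1.0
    if h.style == AGRO:
        if h.conversion_prepaid_years > 0:
            return 1.0, 1.0
        return 2.0, 2.0
    return 1.0, 1.0  # entrepreneurial


def attainable_max(h: Household, land: Landscape, params: Params) -> tuple[float, int, float]:
    """(kg at q=1, ha used, FTE at q=1) for the household's farm.

    Peasants are limited by family labour capacity (best plots first);
    entrepreneurs hire labour, so only land limits them. Entrepreneurial
    potential is the fertilizer-driven 10x of base yield, capped at
    10 t/ha; peasant potential is the plots' current maximum yields.
    """
    plots = h.plots(land)
    if h.style == ENTRE:
        total = sum(entre_max_yield(p, params) for p in plots)
        area = len(plots)
        return total, area, fte_at_full(h, area, params)
    if len(plots) == 1:
        return plots[0].current_max_yield, 1, fte_at_full(h, 1, params)
    cap = int(peasant_capacity_ha(h, params))
    usable = sorted(plots, key=lambda p: -p.current_max_yield)[:cap]
    total = sum(p.current_max_yield for p in usable)
    area = len(usable)
    return total, area, fte_at_full(h, area, params)


def input_requirements(q: float, h: Household, area: int, fte_full: float,
                       market: MarketState, params: Params) -> Plan:
    """Inputs needed to produce the fraction q of the attainable maximum.

    Diminishing returns: each variable channel needs the fraction x = q^2
    of its full-production quantity.
    """
    x = q * q
    ld_mult, ni_mult = _cost_intensity(h)
    plan = Plan(q=q, area=area, fte_full=fte_full)
    if h.style == ENTRE:
        plan.fte_used = x * fte_full
    else:
        # peasant labour intensification doubles the work under
        # agroecology, bounded by what the family can supply
        plan.fte_used = min(x * fte_full * ld_mult, params.family_workers)
    plan.labour_diet_kg = (x * fte_full * params.labour_diet_kg_per_fte * ld_mult
                           if h.style != ENTRE else 0.0)
    plan.ni_cost = x * area * market.ni_per_ha_full * ni_mult
    if h.style == ENTRE:
        plan.fert_kg = x * params.fertilizer_max_kg * area
        plan.fert_cost = plan.fert_kg * market.fertilizer_price
        plan.hired_fte = max(0.0, plan.fte_used - params.family_workers)
        plan.wage_cost = plan.hired_fte * market.wage
    return plan


# ---------------------------------------------------------------------------
# Price expectations

def expected_price(h: Household, market: MarketState, params: Params,
                   rng: np.random.Generator, transmission: float = 0.0) -> float:
    """Next year's price: current price plus a one-year trend, with +/-5%
    noise for unmodelled factors.

    Style-specific considerations: peasants (autonomy, local orientation)
    extrapolate the local price's own five-year trend; entrepreneurs
    (market orientation) project the transmission-adjusted trend of the
    global price onto the local price.
    """
    if h.style == ENTRE:
        base = market.local_price * (1.0 + transmission * global_price_trend(market))
    else:
        # autonomy-oriented sellers anchor on the going price; weighting
        # the local trend as well would have the majority seller class
        # chasing its own extrapolation, which destabilises an ask-driven
        # market with no demand side
        base = market.local_price
    w = params.price_expectation_noise
    p = base * rng.uniform(1.0 - w, 1.0 + w)
    return max(p, params.price_floor)


def global_price_trend(market: MarketState) -> float:
    """Mean annual relative change of the global price over the last
    five years."""
    hist = market.global_price_history[-6:]
    if len(hist) >= 2 and hist[0] > 0:
        return (hist[-1] / hist[0]) ** (1.0 / (len(hist) - 1)) - 1.0
    return 0.0


# ---------------------------------------------------------------------------
# Production optimization

_GRID_STEP = 0.01


def _snap(q: float) -> float:
    """Nearest grid value in [0, 1] at 0.01 resolution."""
    return min(1.0, max(0.0, round(q * 100) / 100.0))


def _grid_argmax_concave(a: float, b: float) -> float:
    """Grid point in {0, 0.01, ..., 1} maximising a*q - b*q^2.

    Equivalent to an exhaustive scan of the 101-point grid (ties break
    to the smaller q, as an exhaustive first-maximum scan would).
    """
    if b <= 0.0:
        return 1.0 if a > 0.0 else 0.0
    q_cont = a / (2.0 * b)
    if q_cont >= 1.0:
        return 1.0
    if q_cont <= 0.0:
        return 0.0
    lo = math.floor(q_cont * 100) / 100.0
    hi = min(1.0, lo + _GRID_STEP)
    f_lo = a * lo - b * lo * lo
    f_hi = a * hi - b * hi * hi
    return lo if f_lo >= f_hi else hi


def _largest_grid_root(a: float, b: float, c: float) -> float | None:
    """Largest grid q in [0, 1] with a*q - b*q^2 + c >= 0 (b > 0), or
    None if no grid point qualifies."""
    disc = a * a + 4.0 * b * c
    if disc < 0.0:
        return None
    q_hi = (a + math.sqrt(disc)) / (2.0 * b)
    if q_hi < 0.0:
        return None
    q = min(1.0, math.floor(q_hi * 100) / 100.0)
    while q >= 0.0 and a * q - b * q * q + c < -1e-9:
        q -= _GRID_STEP
    return max(q, 0.0) if q >= -1e-9 else None


def optimize_target(h: Household, p_exp: float, land: Landscape,
                    market: MarketState, params: Params) -> Plan:
    """Choose the production fraction q on a 0.01-resolution grid.

    Peasants maximise the value of output net of the in-kind labour diet
    and cash necessary inputs (labour itself is not costed); if the
    optimum would not raise net income per hectare above last year's,
    they escalate production (autonomy goal). Entrepreneurs maximise
    profit with all inputs costed, family labour at the going wage; if
    profit at the optimum falls short of their expansion goal (the cash
    half of the next hectare) they escalate to the largest
    non-loss-making q.

    The objectives are concave quadratics in q, so the grid optimum is
    found by evaluating the grid neighbours of the continuous optimum;
    this matches an exhaustive scan of the grid exactly.
    """
    attainable, area, fte_full = attainable_max(h, land, params)
    if attainable <= 0 or area == 0:
        plan = Plan(area=area, fte_full=fte_full)
        plan.debt_due = scheduled_debt_service(h.loans)
        return plan

    ld_mult, ni_mult = _cost_intensity(h)
    ni_full = area * market.ni_per_ha_full * ni_mult
    debt_due = scheduled_debt_service(h.loans)

    if h.style != ENTRE:
        ld_full_kg = fte_full * params.labour_diet_kg_per_fte * ld_mult
        # returns-to-labour objective: output value minus in-kind labour
        # diet and cash input costs, labour not costed
        a = p_exp * attainable
        b = p_exp * ld_full_kg + ni_full
        q_opt = _grid_argmax_concave(a, b)
        q = q_opt
        if h.last_net_income > 0 and h.area > 0:
            # autonomy goal: net income per ha not below last year's
            goal = h.last_net_income
            diet_val = p_exp * params.basic_diet_kg
            while q < 1.0 - 1e-9 and a * q - b * q * q - diet_val < goal:
                q = min(1.0, q + _GRID_STEP)
        # pre-production rationing: input commitments should be fundable
        # from savings plus harvest value net of the diet the household
        # intends to protect (the full basic diet for nutrition-first
        # households, the 50% floor for production-first ones); if no
        # output level is fundable they plan the optimum anyway and let
        # the input bill slide
        if ni_full > 0:
            if h.rationing_pref == "production":
                protected_kg = params.abandonment_diet_fraction * params.basic_diet_kg
            else:
                protected_kg = params.basic_diet_kg

            def fundable(qv: float) -> bool:
                sellable = max(0.0, attainable * qv - protected_kg
                               - ld_full_kg * qv * qv)
                return ni_full * qv * qv <= h.savings + p_exp * sellable + 1e-9

            if not fundable(q):
                # feasible region of this concave condition is an interval
                # from 0; find its upper end
                qa = _largest_grid_root(
                    p_exp * attainable,
                    ni_full + p_exp * ld_full_kg,
                    h.savings - p_exp * protected_kg)
                if ni_full > 0 and h.savings > 0:
                    q_sav = math.floor(math.sqrt(h.savings / ni_full) * 100) / 100.0
                else:
                    q_sav = 0.0
                cand = max(qa if qa is not None else 0.0, min(q_sav, 1.0))
                while cand > 0.0 and not fundable(cand):
                    cand -= _GRID_STEP
                if 0.0 < cand < q:
                    q = cand
            # but never plan below feeding the family: growing one's own
            # food needs no cash, only the input bill can slide
            disc = attainable * attainable - 4.0 * ld_full_kg * params.basic_diet_kg
            if ld_full_kg > 0 and disc >= 0:
                q_feed = (attainable - math.sqrt(disc)) / (2.0 * ld_full_kg)
                q_feed = math.ceil(q_feed * 100) / 100.0
            else:
                q_feed = params.basic_diet_kg / attainable if attainable > 0 else 1.0
                q_feed = math.ceil(q_feed * 100) / 100.0
            if q_feed <= 1.0:
                q = max(q, min(q_feed, q_opt))
        q = _snap(q)
        plan = input_requirements(q, h, area, fte_full, market, params)
        plan.q_unconstrained = q_opt
        plan.optimized = q >= q_opt - 1e-9
    else:
        fert_full = params.fertilizer_max_kg * area * market.fertilizer_price
        wage_full = fte_full * market.wage  # family labour costed too
        cost_full = fert_full + wage_full + ni_full
        a = p_exp * attainable
        q_opt = _grid_argmax_concave(a, cost_full)
        q = q_opt
        # the expansion goal: income enough to fund the cash half of the
        # next hectare (growth is the point of the entrepreneurial style)
        goal = 0.5 * market.land_price
        profit_opt = a * q_opt - cost_full * q_opt * q_opt - debt_due
        if profit_opt < goal and cost_full > 0:
            # expansion goal unmet: produce as much as possible without a loss
            q_escal = _largest_grid_root(a, cost_full, -debt_due)
            if q_escal is not None:
                q = max(q, q_escal)
        q = _snap(q)
        plan = input_requirements(q, h, area, fte_full, market, params)
        plan.q_unconstrained = q_opt
        plan.optimized = True
    plan.attainable = attainable
    plan.target = plan.q * attainable
    plan.debt_due = debt_due
    return plan


def entre_projected_loss(h: Household, plan: Plan, p_exp: float) -> float:
    """Expected cash result of the plan (negative = cash loss), family
    labour not counted as a cash cost."""
    revenue = p_exp * plan.target
    cash_costs = plan.fert_cost + plan.ni_cost + plan.wage_cost + plan.debt_due
    return revenue - cash_costs


# ---------------------------------------------------------------------------
# Production and asking price

def realize_production(plan: Plan, style: str, climate: ClimateState,
                       params: Params, rng: np.random.Generator) -> float:
    """Actual yield: target times warming and drought loss factors and
    +/-15% random variation, floored at zero."""
    if plan.target <= 0:
        return 0.0
    f = warming_loss_factor(climate.warming, style, params)
    f *= drought_loss_factor(climate, style, params, rng)
    w = params.yield_noise_halfwidth
    f *= rng.uniform(1.0 - w, 1.0 + w)
    return max(0.0, plan.target * f)


def asking_price(h: Household, production: float, p_exp: float,
                 params: Params) -> float:
    """Ask the larger of the expected price and a goal-driven floor.

    Peasants ask at least the price that would maintain last year's net
    income from this year's marketable surplus (the autonomy goal).
    Entrepreneurs ask at least 20% over their variable cash cost per kg
    (a return-on-investment floor); fixed debt service is carried by the
    margin, since a full-cost-recovery floor would let asks feed on
    themselves and foreclose the oversupply crises this supply-side
    market is capable of.
    """
    if production <= 0:
        return p_exp
    plan = h.plan
    if h.style == ENTRE:
        cash = plan.fert_cost + plan.ni_cost + plan.wage_cost
        floor = cash / production * params.entre_ask_markup
    else:
        # the peasant autonomy goal: hold on to the income level the farm
        # has been achieving. Both sides are taken at their typical (not
        # single-harvest) values so one good or bad year does not swing
        # the ask many-fold, and the (wage-indexed) input bill is not
        # recovered through the ask — that would feed a wage-price spiral
        planned_surplus = plan.target - params.basic_diet_kg - plan.labour_diet_kg
        if planned_surplus > 0 and h.income_smooth > 0:
            floor = h.income_smooth / planned_surplus
        else:
            floor = 0.0
    return max(floor, p_exp)
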