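"""Prices and credit: the exogenous global food price, local price
formation, derived input prices, and loan amortization.

The global price is a falling, oscillating trend (corporate agriculture as
an exogenous forcing term) that jumps up in drought years. The local price
is the production-weighted average of household asking prices, adjusted by
the scenario's global-to-local transmission elasticity. All input prices
derive from the food price (Table-of-prices logic): the low-skilled wage is
180% of a basic diet's cost, necessary inputs are 15% of a wage per ha,
fertilizer is 10x the food price per kg, land costs 30 t of cereal per ha,
and working animals / tractors cost 30 / 150 years of an average orphan
farm's net income.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from farmstyles.config import (
    ClimateScenario,
    Params,
    PolicyScenario,
    eroded_value,
)
from farmstyles.climate import ClimateState, HORIZON

log = logging.getLogger(__name__)


@dataclass(slots=True)
class Loan:
    principal: float
    rate: float
    term: int
    remaining_term: int = -1
    balance: float = -1.0

    def __post_init__(self) -> None:
        if self.remaining_term < 0:
            self.remaining_term = self.term
        if self.balance < 0:
            self.balance = self.principal

    @property
    def annuity(self) -> float:
        return annuity_payment(self.principal, self.rate, self.term)


def annuity_payment(principal: float, rate: float, term: int) -> float:
    """Level annual payment amortizing ``principal`` over ``term`` years."""
    if term <= 0:
        raise ValueError("loan term must be positive")
    if rate == 0.0:
        return principal / term
    return principal * rate / (1.0 - (1.0 + rate) ** -term)


def annual_debt_service(loans: list[Loan]) -> tuple[float, float, list[Loan]]:
    """Pay one annuity on every loan.

    Returns (total due, interest portion, surviving loans); fully-paid
    loans are dropped.
    """
    due = 0.0
    interest_total = 0.0
    surviving: list[Loan] = []
    for loan in loans:
        pay = loan.annuity
        interest = loan.balance * loan.rate
        principal_part = pay - interest
        loan.balance = max(0.0, loan.balance - principal_part)
        loan.remaining_term -= 1
        due += pay
        interest_total += interest
        if loan.remaining_term > 0 and loan.balance > 1e-9:
            surviving.append(loan)
    return due, interest_total, surviving


def scheduled_debt_service(loans: list[Loan]) -> float:
    """Total annuity due this year without mutating the loans."""
    if not loans:
        return 0.0
    return sum(loan.annuity for loan in loans)


def total_debt(loans: list[Loan]) -> float:
    return sum(loan.balance for loan in loans)


@dataclass
class MarketState:
    local_price: float                  # $/kg
    global_price: float                 # $/kg
    local_price_history: list[float] = field(default_factory=list)
    global_price_history: list[float] = field(default_factory=list)
    global_trend: float = 0.0           # trend level before the oscillator
    global_change_pct: float = 0.0      # year-on-year % change
    wage: float = 0.0                   # $/FTE-year
    ni_per_ha_full: float = 0.0         # necessary inputs $/ha at full prod
    fertilizer_price: float = 0.0       # $/kg, after subsidy
    land_price: float = 0.0             # $/ha
    animal_price: float = 0.0
    tractor_price: float = 0.0
    interest: dict[str, float] = field(default_factory=dict)
    fertilizer_subsidy: float = 0.0
    _floor_logged: bool = False

    @property
    def mean_price_5yr(self) -> float:
        h = self.local_price_history[-5:]
        return sum(h) / len(h) if h else self.local_price


def init_market(params: Params) -> MarketState:
    m = MarketState(local_price=params.initial_local_price,
                    global_price=params.initial_global_price,
                    global_trend=params.initial_global_price)
    m.local_price_history.append(m.local_price)
    m.global_price_history.append(m.global_price)
    return m


def orphan_net_income(price: float, params: Params) -> float:
    """Net income of the average orphan farm at a given food price:
    gross surplus after the family diet and the labour diet.

    At 40 c/kg this is (1000 - 700 - ~108) kg x $0.40 ~= $77/yr, the
    reference quantity used to price working animals and tractors.
    """
    surplus = (params.base_plot_yield_mean - params.basic_diet_kg
               - params.labour_diet_kg_per_fte)
    return max(0.0, surplus * price)


def step_global_price(market: MarketState, climate: ClimateState,
                      scenario: ClimateScenario, params: Params,
                      rng: np.random.Generator) -> None:
    """Advance the exogenous global price by one year.

    The trend declines by a random annual rate (mean = scenario rate,
    sd = rate, truncated to [-2*rate, 4*rate] so occasional rises occur),
    jumps by the drought bump in global-drought years, and carries an
    additive sinusoid of 1.5 cents amplitude and 10-year period.
    """
    rate = scenario.global_trend_decline
    if rate > 0:
        while True:
            d = rng.normal(rate, rate)
            if -2 * rate <= d <= 4 * rate:
                break
    else:
        d = 0.0
    trend = market.global_trend * (1.0 - d)
    if climate.global_drought:
        trend *= 1.0 + climate.global_drought_bump
    market.global_trend = max(trend, params.price_floor)

    osc = params.oscillator_amplitude * math.sin(
        2 * math.pi * climate.year / params.oscillator_period)
    new_price = market.global_trend + osc
    if new_price < params.price_floor:
        if not market._floor_logged:
            log.warning("global price hit the %.0f-cent floor", params.price_floor * 100)
            market._floor_logged = True
        new_price = params.price_floor

    prev = market.global_price
    market.global_price = new_price
    market.global_change_pct = 100.0 * (new_price - prev) / prev
    market.global_price_history.append(new_price)


def form_local_price(asks: list[float], productions: list[float],
                     global_change_pct: float, transmission: float,
                     last_price: float, price_floor: float = 0.01) -> float:
    """Production-weighted average of asking prices, adjusted for the
    global price change via the transmission elasticity.

    A +5% global change with transmission 0.5 raises the local price by
    2.5%. With zero total production the last price carries forward.
    """
    total = sum(productions)
    if total <= 0.0:
        log.debug("no marketed production; carrying local price forward")
        base = last_price
    else:
        base = sum(a * p for a, p in zip(asks, productions)) / total
    price = base * (1.0 + transmission * global_change_pct / 100.0)
    return max(price, price_floor)


def update_input_prices(market: MarketState, params: Params,
                        policy: PolicyScenario, year: int) -> None:
    """Recompute wage, input, land and asset prices and credit terms.

    Wage and capital goods track the 5-year mean local food price;
    fertilizer tracks the current local price. Entrepreneurial policies
    halve interest rates and subsidise fertilizer 50%; under the eroding
    variant both supports return linearly to baseline over 50 years.
    """
    p5 = market.mean_price_5yr
    market.wage = (params.wage_markup * params.basic_diet_kg * p5
                   * (1.0 + params.wage_drift) ** year)
    market.ni_per_ha_full = params.necessary_input_share * market.wage

    if policy.fertilizer_subsidy > 0 and policy.eroding:
        subsidy = eroded_value(policy.fertilizer_subsidy, 0.0, year, HORIZON)
    else:
        subsidy = policy.fertilizer_subsidy
    market.fertilizer_subsidy = subsidy
    market.fertilizer_price = (params.fertilizer_price_multiple
                               * market.local_price
                               * (1.0 + params.fertilizer_drift) ** year
                               * (1.0 - subsidy))

    market.land_price = params.land_price_tonnes * 1000.0 * p5
    oni = orphan_net_income(p5, params)
    market.animal_price = params.animal_price_years * oni
    market.tractor_price = params.tractor_price_years * oni

    base_rates = {"short": params.interest_short, "mid": params.interest_mid,
                  "long": params.interest_long}
    if policy.interest_halved:
        if policy.eroding:
            market.interest = {
                k: eroded_value(v / 2.0, v, year, HORIZON)
                for k, v in base_rates.items()
            }
        else:
            market.interest = {k: v / 2.0 for k, v in base_rates.items()}
    else:
        market.interest = base_rates
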