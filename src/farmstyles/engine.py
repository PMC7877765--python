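"""The annual simulation cycle, single runs and Monte-Carlo batches.

Each year executes, in order: climate step, global price step, orphan
conversions, farm expansions, price expectations and production
optimization (with entrepreneurial viability checks and fertilizer
purchase), production realization, asking prices, local price formation,
year-end accounting with the distress cascade, slow yield increments and
transition progress, and finally a metrics snapshot.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from farmstyles.config import (
    AGRO,
    ENTRE,
    ORPHAN,
    ClimateScenario,
    Params,
    PolicyScenario,
    build_scenario,
)
from farmstyles import metrics as metrics_mod
from farmstyles.climate import ClimateState, step_climate
from farmstyles.decisions import (
    _sell_one_asset,
    abandon,
    account_and_ration,
    decide_conversion,
    decide_expansion_agro,
    decide_expansion_entre,
    entre_preproduction_check,
)
from farmstyles.households import (
    Household,
    RATION_NUTRITION,
    RATION_PRODUCTION,
    SAVE_HOARD,
    SAVE_SPEND,
    asking_price,
    entre_projected_loss,
    expected_price,
    optimize_target,
    realize_production,
)
from farmstyles.landscape import (
    Landscape,
    advance_transition,
    apply_yield_increment,
    init_landscape,
    place_households,
)
from farmstyles.market import (
    Loan,
    MarketState,
    form_local_price,
    init_market,
    step_global_price,
    update_input_prices,
)

log = logging.getLogger(__name__)

OUTPUT_COLUMNS = [
    "year", "total_production_t", "local_price_c", "global_price_c",
    "n_converted", "n_abandoned", "orphan_nutrition", "labour_fte",
    "income_gini", "mean_net_income", "mean_net_income_5yr",
    "income_slope_orphan", "income_slope_agroecology",
    "income_slope_entrepreneurial", "mean_rlp", "households_feedable",
    "warming", "local_drought", "community_loss", "global_drought",
    "wage", "fertilizer_price", "land_price",
]


class LedgerError(RuntimeError):
    """A household's money ledger failed to close."""


class World:
    """One simulated community under a resolved scenario."""

    def __init__(self, params: Params, policy: PolicyScenario,
                 climate_scenario: ClimateScenario, seed: int,
                 check_ledger: bool = False):
        self.params = params
        self.policy = policy
        self.climate_scenario = climate_scenario
        self.check_ledger = check_ledger
        ss = np.random.SeedSequence(seed)
        s_main, s_shuffle = ss.spawn(2)
        self.rng = np.random.default_rng(s_main)
        self.shuffle_rng = np.random.default_rng(s_shuffle)

        self.land = init_landscape(params, self.rng)
        plot_ids = place_households(self.land, params.n_households, self.rng)
        self.market = init_market(params)
        update_input_prices(self.market, params, policy, 0)
        self.households: list[Household] = []
        for hid, pid in enumerate(plot_ids):
            pref = AGRO if self.rng.random() < policy.prop_pref_agro else ENTRE
            ration = (RATION_PRODUCTION if self.rng.random() < 0.5
                      else RATION_NUTRITION)
            save = SAVE_HOARD if self.rng.random() < 0.5 else SAVE_SPEND
            h = Household(id=hid, preference=pref, plot_ids=[pid],
                          rationing_pref=ration, saving_style=save)
            # initialization: every household at its maximum yield, no savings
            h.last_production = self.land.plots[pid].base_max_yield
            h.income_smooth = max(
                0.0,
                (h.last_production - params.basic_diet_kg
                 - params.labour_diet_kg_per_fte) * params.initial_local_price
                - self.market.ni_per_ha_full)
            h.new_loans = []
            self.households.append(h)

        self.climate = ClimateState(scenario=climate_scenario,
                                    local_drought_risk=params.base_drought_risk)
        self.year = 0
        self._income_by_style: dict[str, list[float]] = {
            ORPHAN: [], AGRO: [], ENTRE: []}
        self._mean_income_series: list[float] = []
        self.rows: list[dict] = []

    # -- annual cycle ------------------------------------------------------

    def step_year(self) -> None:
        params, policy, market, land = (self.params, self.policy,
                                        self.market, self.land)
        self.year += 1
        self.climate = step_climate(self.climate, params, self.rng)
        step_global_price(market, self.climate, self.climate_scenario,
                          params, self.rng)
        update_input_prices(market, params, policy, self.year)

        active = [h for h in self.households if h.active]
        order = list(active)
        self.shuffle_rng.shuffle(order)
        if self.check_ledger:
            start_savings = {h.id: h.savings for h in order}
        for h in order:
            h.ledger = {}

        # conversions, then expansions
        for h in order:
            if h.active and h.style == ORPHAN:
                decide_conversion(h, land, market, params)
        for h in order:
            if not h.active:
                continue
            if h.style == AGRO:
                decide_expansion_agro(h, land, market, params)
            elif h.style == ENTRE:
                decide_expansion_entre(h, land, market, params)

        # expectations, optimization, input purchase
        expectations: dict[int, float] = {}
        for h in order:
            if not h.active:
                continue
            if h.style == ENTRE:
                entre_preproduction_check(h, land, market, params)
                if not h.active:
                    continue
            p_exp = expected_price(h, market, params, self.rng,
                                   transmission=policy.transmission)
            plan = optimize_target(h, p_exp, land, market, params)
            if h.style == ENTRE:
                # loss-making optimum that savings cannot absorb: sell
                # assets one by one and re-optimize
                while (entre_projected_loss(h, plan, p_exp) < 0
                       and h.savings + entre_projected_loss(h, plan, p_exp) < 0):
                    raised = _sell_one_asset(h, land, market)
                    if raised <= 0:
                        break
                    h.savings += raised
                    h.ledger["asset_sales"] = h.ledger.get("asset_sales", 0.0) + raised
                    plan = optimize_target(h, p_exp, land, market, params)
                loss = entre_projected_loss(h, plan, p_exp)
                if loss < 0 and h.savings + loss < 0:
                    abandon(h, land, "debt")
                    continue
                # fertilizer: cash first, short-term credit for the rest
                plan.fert_cash = min(h.savings, plan.fert_cost)
                plan.fert_loan = plan.fert_cost - plan.fert_cash
                h.savings -= plan.fert_cash
                h.ledger["fert_cash"] = plan.fert_cash
                if plan.fert_loan > 1e-9:
                    h.new_loans.append(Loan(principal=plan.fert_loan,
                                            rate=market.interest["short"],
                                            term=params.loan_term_short))
            h.plan = plan
            expectations[h.id] = p_exp

        # production
        productions: dict[int, float] = {}
        for h in order:
            if not h.active:
                continue
            productions[h.id] = realize_production(
                h.plan, h.style, self.climate, params, self.rng)

        # asking prices and local price formation
        asks, weights = [], []
        for h in order:
            if not h.active:
                continue
            prod = productions[h.id]
            own_use = params.basic_diet_kg + h.plan.labour_diet_kg
            surplus = prod - own_use
            if surplus > 0:
                # weight by marketed surplus: the aggregate price reflects
                # what each seller actually brings to market
                asks.append(asking_price(h, prod, expectations[h.id], params))
                weights.append(surplus)
        new_price = form_local_price(
            asks, weights, market.global_change_pct, policy.transmission,
            market.local_price, params.price_floor)
        market.local_price = new_price
        market.local_price_history.append(new_price)

        # accounting and distress
        for h in order:
            if not h.active:
                continue
            account_and_ration(h, productions.get(h.id, 0.0), land,
                               market, params)
            h.loans.extend(h.new_loans)
            h.new_loans = []
            if self.check_ledger and h.active:
                self._verify_ledger(h, start_savings[h.id])

        # yield increments and transition progress
        for h in order:
            if not h.active:
                continue
            plots = h.plots(land)
            if h.style != ENTRE and h.plan.optimized:
                for plot in plots:
                    apply_yield_increment(plot, h.style, policy, params)
            for plot in plots:
                if plot.in_transition:
                    advance_transition(plot, params)
            if h.style == AGRO and not h.converted:
                if any(p.transitioned for p in plots):
                    h.converted = True
            if h.conversion_prepaid_years > 0:
                h.conversion_prepaid_years -= 1

        self._snapshot(productions)

    def _verify_ledger(self, h: Household, start: float) -> None:
        led = h.ledger
        expect = (start
                  + led.get("revenue", 0.0)
                  + led.get("asset_sales", 0.0)
                  - led.get("conversion_cost", 0.0)
                  - led.get("asset_purchases", 0.0)
                  - led.get("fert_cash", 0.0)
                  - led.get("debt_paid", 0.0)
                  - led.get("cash_costs", 0.0)
                  - led.get("food_bought", 0.0)
                  - led.get("consumption", 0.0))
        if abs(expect - h.savings) > 1e-6 * max(1.0, abs(expect)):
            raise LedgerError(
                f"household {h.id} ledger mismatch: savings {h.savings:.6f} "
                f"vs expected {expect:.6f}; ledger={led}")

    # -- outputs -----------------------------------------------------------

    def _snapshot(self, productions: dict[int, float]) -> None:
        params = self.params
        active = [h for h in self.households if h.active]
        total_kg = sum(productions.get(h.id, 0.0) for h in active)

        incomes = [h.last_net_income for h in active]
        mean_income = float(np.mean(incomes)) if incomes else float("nan")
        self._mean_income_series.append(mean_income)
        for style in (ORPHAN, AGRO, ENTRE):
            vals = [h.last_net_income for h in active if h.style == style]
            self._income_by_style[style].append(
                float(np.mean(vals)) if vals else float("nan"))

        rlps = [metrics_mod.real_land_productivity(
                    h.last_net_income, h.area, h.gross_value,
                    h.purchased_inputs_nonlabour)
                for h in active if h.area > 0]
        recent = [v for v in self._mean_income_series[-5:] if not np.isnan(v)]

        self.rows.append({
            "year": self.year,
            "total_production_t": total_kg / 1000.0,
            "local_price_c": self.market.local_price * 100.0,
            "global_price_c": self.market.global_price * 100.0,
            "n_converted": sum(1 for h in self.households if h.converted),
            "n_abandoned": sum(1 for h in self.households if not h.active),
            "orphan_nutrition": metrics_mod.orphan_nutrition(self.households),
            "labour_fte": metrics_mod.labour_fte(self.households),
            "income_gini": metrics_mod.gini(incomes) if incomes else float("nan"),
            "mean_net_income": mean_income,
            "mean_net_income_5yr": float(np.mean(recent)) if recent else float("nan"),
            "income_slope_orphan": metrics_mod.income_slope(
                self._income_by_style[ORPHAN]),
            "income_slope_agroecology": metrics_mod.income_slope(
                self._income_by_style[AGRO]),
            "income_slope_entrepreneurial": metrics_mod.income_slope(
                self._income_by_style[ENTRE]),
            "mean_rlp": float(np.mean(rlps)) if rlps else float("nan"),
            "households_feedable": metrics_mod.households_feedable(
                total_kg, params.basic_diet_kg),
            "warming": self.climate.warming,
            "local_drought": int(self.climate.local_drought),
            "community_loss": self.climate.local_drought_loss,
            "global_drought": int(self.climate.global_drought),
            "wage": self.market.wage,
            "fertilizer_price": self.market.fertilizer_price,
            "land_price": self.market.land_price,
        })

    def run(self, years: int | None = None) -> pd.DataFrame:
        for _ in range(years if years is not None else self.params.years):
            self.step_year()
        return self.outputs()

    def outputs(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=OUTPUT_COLUMNS)
        return df.set_index("year")


def run_simulation(policy: str = "none", climate: str = "no",
                   overrides: dict | None = None, seed: int = 0,
                   years: int | None = None,
                   check_ledger: bool = False) -> pd.DataFrame:
    """Run one simulation; deterministic given (configuration, seed)."""
    params, pol, clim = build_scenario(policy, climate, overrides)
    world = World(params, pol, clim, seed, check_ledger=check_ledger)
    return world.run(years)


def run_batch(policy: str = "none", climate: str = "no",
              overrides: dict | None = None, n_runs: int = 250,
              base_seed: int = 0, years: int | None = None,
              progress: bool = False) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Across-run mean and SD of every outcome per year.

    Replicates are independent; run i uses seed ``base_seed + i``.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    frames = []
    iterator = range(n_runs)
    if progress:
        from tqdm import tqdm  # pragma: no cover
        iterator = tqdm(iterator)  # pragma: no cover
    for i in iterator:
        frames.append(run_simulation(policy, climate, overrides,
                                     seed=base_seed + i, years=years))
    stacked = pd.concat(frames, keys=range(n_runs))
    mean = stacked.groupby(level=1).mean()
    sd = stacked.groupby(level=1).std(ddof=1) if n_runs > 1 else mean * 0.0
    return mean, sd
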