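"""Conversion, expansion, accounting and distress handling.

These are the discrete, rule-based parts of the annual household cycle;
the continuous production optimization lives in
:mod:`farmstyles.households`.
"""

from __future__ import annotations

import logging

from farmstyles.config import AGRO, ENTRE, ORPHAN, Params
from farmstyles.households import (
    Household,
    Plan,
    RATION_NUTRITION,
    RATION_PRODUCTION,
    SAVE_SPEND,
    _cost_intensity,
    peasant_capacity_ha,
)
from farmstyles.landscape import (
    Landscape,
    best_contiguous_plot,
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


def transition_cost_per_ha(market: MarketState, params: Params) -> float:
    """Savings needed to carry one plot through the 3-year agroecology
    transition: the extra labour diet (labour doubles) plus the
    agroecology-level necessary inputs, for each transition year."""
    extra_ld_kg = (params.agro_labour_multiple - 1.0) * params.labour_diet_kg_per_fte
    extra_ni = (params.agro_labour_multiple - 1.0) * market.ni_per_ha_full
    return params.agro_transition_years * (
        extra_ld_kg * market.local_price + extra_ni)


def decide_conversion(h: Household, land: Landscape, market: MarketState,
                      params: Params) -> bool:
    """Orphan households convert to their preferred style when resources
    allow. Agroecology needs savings covering the full transition cost
    (no credit); entrepreneurial needs income-after-family-diet plus
    savings to cover a low-skilled wage, which grants credit eligibility.
    """
    if h.style != ORPHAN or not h.active:
        return False
    p = market.local_price
    if h.preference == ENTRE:
        income_after_diet = max(0.0, h.last_production - params.basic_diet_kg) * p
        if income_after_diet + h.savings >= market.wage:
            h.style = ENTRE
            h.converted = True
            for plot in h.plots(land):
                # entrepreneurial potential is the fertilizer channel on
                # the plot's base yield; peasant increments do not carry
                plot.current_max_yield = plot.base_max_yield
                plot.in_transition = False
                plot.transitioned = False
            return True
    else:
        cost = transition_cost_per_ha(market, params) * h.area
        if h.savings >= cost and cost > 0:
            h.savings -= cost
            h.ledger["conversion_cost"] = h.ledger.get("conversion_cost", 0.0) + cost
            h.style = AGRO
            h.conversion_prepaid_years = params.agro_transition_years
            for plot in h.plots(land):
                start_transition(plot)
            return True
    return False


def decide_expansion_agro(h: Household, land: Landscape, market: MarketState,
                          params: Params) -> None:
    """Savings-only growth up to 10 ha and two animal teams; new land only
    once every existing plot has been transitioned (so at most 1 ha per
    3 years), choosing the best contiguous unoccupied plot."""
    plots = h.plots(land)
    if any(p.in_transition for p in plots):
        return
    # capacity first: more area than family labour can work needs animals
    if (h.area > peasant_capacity_ha(h, params)
            and h.animal_teams < params.agro_max_animal_teams
            and h.savings >= market.animal_price):
        h.savings -= market.animal_price
        h.animal_teams += 1
        h.ledger["asset_purchases"] = h.ledger.get("asset_purchases", 0.0) + market.animal_price
    if h.area >= params.agro_max_ha:
        return
    plot = best_contiguous_plot(land, h.plot_ids, AGRO, params)
    if plot is None:
        log.debug("household %d: no contiguous plot available", h.id)
        return
    need_team = ((h.area + 1) > peasant_capacity_ha(h, params)
                 and h.animal_teams < params.agro_max_animal_teams)
    cost = market.land_price + (market.animal_price if need_team else 0.0)
    if (h.area + 1) > peasant_capacity_ha(h, params) and not need_team \
            and h.animal_teams >= params.agro_max_animal_teams:
        return  # no way to work the extra land
    if h.savings >= cost:
        h.savings -= cost
        h.ledger["asset_purchases"] = h.ledger.get("asset_purchases", 0.0) + cost
        plot.owner = h.id
        h.plot_ids.append(plot.idx)
        start_transition(plot)
        if need_team:
            h.animal_teams += 1


def _entre_take_loan(h: Household, amount: float, rate: float, term: int) -> None:
    if amount > 1e-9:
        h.new_loans.append(Loan(principal=amount, rate=rate, term=term))
        h.ledger["loans_taken"] = h.ledger.get("loans_taken", 0.0) + amount


def decide_expansion_entre(h: Household, land: Landscape, market: MarketState,
                           params: Params) -> None:
    """Buy land (at most 1 ha/yr), then equipment, whenever income plus
    savings cover at least half the cost; credit covers the balance
    (long-term for land, mid-term for animals and tractors)."""
    income = max(0.0, h.last_net_income)

    plot = best_contiguous_plot(land, h.plot_ids, ENTRE, params)
    if plot is not None and h.savings + income >= 0.5 * market.land_price:
        # a half down payment; credit covers the balance, and the rest of
        # the cash stays as working capital
        cash = min(h.savings, 0.5 * market.land_price)
        h.savings -= cash
        h.ledger["asset_purchases"] = h.ledger.get("asset_purchases", 0.0) + cash
        _entre_take_loan(h, market.land_price - cash,
                         market.interest["long"], params.loan_term_long)
        plot.owner = h.id
        h.plot_ids.append(plot.idx)

    uncovered = (h.area - params.tractor_capacity_ha * h.tractors
                 - params.animal_capacity_ha * h.animal_teams)
    want = None
    if uncovered >= 8 and market.tractor_price > 0:
        want, price, term = "tractor", market.tractor_price, params.loan_term_mid
    elif uncovered >= 3 and market.animal_price > 0:
        want, price, term = "animals", market.animal_price, params.loan_term_mid
    if want and h.savings + income >= 0.5 * price:
        cash = min(h.savings, 0.5 * price)
        h.savings -= cash
        h.ledger["asset_purchases"] = h.ledger.get("asset_purchases", 0.0) + cash
        _entre_take_loan(h, price - cash, market.interest["mid"], term)
        if want == "tractor":
            h.tractors += 1
        else:
            h.animal_teams += 1


def _sell_one_asset(h: Household, land: Landscape, market: MarketState) -> float:
    """Sell the next asset in distress order (animals, tractor, land
    last, never the final plot). Returns the proceeds (0 = nothing left)."""
    if h.animal_teams > 0:
        h.animal_teams -= 1
        return market.animal_price
    if h.tractors > 0:
        h.tractors -= 1
        return market.tractor_price
    if h.area > 1:
        plots = h.plots(land)
        worst = min(plots, key=lambda p: p.current_max_yield)
        h.plot_ids.remove(worst.idx)
        release_plot(worst)
        return market.land_price
    return 0.0


def sell_assets_for(h: Household, need: float, land: Landscape,
                    market: MarketState) -> float:
    """Liquidate assets until ``need`` dollars are raised (or nothing is
    left); returns the total proceeds."""
    raised = 0.0
    while raised < need:
        got = _sell_one_asset(h, land, market)
        if got <= 0:
            break
        raised += got
    if raised:
        h.ledger["asset_sales"] = h.ledger.get("asset_sales", 0.0) + raised
    return raised


def abandon(h: Household, land: Landscape, reason: str) -> None:
    """Leave farming for good: plots revert to the unoccupied pool and
    outstanding loans default. Abandonment is absorbing."""
    for plot in h.plots(land):
        release_plot(plot)
    h.plot_ids = []
    h.loans = []
    h.new_loans = []
    h.active = False
    h.diet_fraction = 0.0
    h.abandon_reason = reason


def entre_preproduction_check(h: Household, land: Landscape,
                              market: MarketState, params: Params) -> None:
    """Entrepreneurs first check that income plus savings can meet debt
    obligations and half a basic diet; failing that they sell assets,
    and failing that they abandon."""
    p = market.local_price
    need = scheduled_debt_service(h.loans)
    if h.last_production < params.abandonment_diet_fraction * params.basic_diet_kg:
        # the family cannot be fed from the farm: food must be bought too
        need += params.abandonment_diet_fraction * params.basic_diet_kg * p
    # judged on the farm's typical earnings, not one harvest's luck
    have = h.savings + max(0.0, h.income_smooth)
    if have >= need:
        return
    raised = sell_assets_for(h, need - have, land, market)
    h.savings += raised
    if h.savings + max(0.0, h.last_net_income) < need:
        abandon(h, land, "debt")


def account_and_ration(h: Household, production: float, land: Landscape,
                       market: MarketState, params: Params) -> None:
    """Year-end accounting: consumption in kind, revenue, debt service,
    cash costs, diet purchases, and the distress cascade (ration by
    preference, sell assets, abandon).

    Savings can never go negative: any shortfall routes through grain
    rationing, asset sales, and finally abandonment.
    """
    p = market.local_price
    plan = h.plan
    led = h.ledger

    # in-kind consumption: family diet first, then the labour diet
    fam_kg = min(production, params.basic_diet_kg)
    ld_kg = min(max(0.0, production - fam_kg), plan.labour_diet_kg)
    surplus_kg = production - fam_kg - ld_kg
    revenue = surplus_kg * p

    debt_paid, interest_paid, surviving = annual_debt_service(h.loans)
    h.loans = surviving

    cash = h.savings + revenue
    floor_kg = params.abandonment_diet_fraction * params.basic_diet_kg

    def ration_diet(amount: float) -> float:
        # tightening the belt to pay the input bill in full does not
        # stop the farm from optimizing production
        nonlocal fam_kg, revenue, cash
        sellable = max(0.0, fam_kg - floor_kg)
        sell = min(sellable, amount / p) if p > 0 else 0.0
        fam_kg -= sell
        revenue += sell * p
        cash += sell * p
        return sell * p

    def liquidate(amount: float) -> float:
        nonlocal cash
        raised = sell_assets_for(h, amount, land, market)
        cash += raised
        return raised

    ni_paid = plan.ni_cost
    if h.style == ENTRE:
        # wage and debt obligations are hard: failing them after asset
        # sales means leaving farming
        outflows = plan.ni_cost + plan.wage_cost + debt_paid
        if outflows - cash > 1e-9:
            steps = ((ration_diet, liquidate)
                     if h.rationing_pref == RATION_PRODUCTION
                     else (liquidate, ration_diet))
            for step in steps:
                short = outflows - cash
                if short > 1e-9:
                    step(short)
            if outflows - cash > 1e-9:
                abandon(h, land, "debt")
                return
        cash -= outflows
    else:
        # peasants owe nobody: necessary inputs get paid by rationing
        # (production-preferring households only) and otherwise default
        # (deferred maintenance: the farm cannot optimize, so it gains
        # no yield increment this year)
        if plan.ni_cost - cash > 1e-9 and h.rationing_pref == RATION_PRODUCTION:
            ration_diet(plan.ni_cost - cash)
        ni_paid = min(plan.ni_cost, max(0.0, cash))
        if ni_paid < plan.ni_cost - 1e-9:
            plan.optimized = False
        cash -= ni_paid

    # diet top-up from the market
    bought_kg = 0.0
    deficit_kg = params.basic_diet_kg - fam_kg
    if deficit_kg > 1e-9 and p > 0:
        _, ni_mult = _cost_intensity(h)
        reserve = h.area * market.ni_per_ha_full * ni_mult
        if h.saving_style == SAVE_SPEND:
            target_kg = params.basic_diet_kg
        else:
            target_kg = params.abandonment_diet_fraction * params.basic_diet_kg
        want_kg = max(0.0, target_kg - fam_kg)
        afford_kg = max(0.0, cash - reserve) / p
        bought_kg = min(want_kg, afford_kg)
        # survival overrides the hoarding reserve
        floor_kg = params.abandonment_diet_fraction * params.basic_diet_kg
        if fam_kg + bought_kg < floor_kg:
            bought_kg = min(max(0.0, floor_kg - fam_kg), cash / p)
        if fam_kg + bought_kg < floor_kg:
            raised = sell_assets_for(
                h, (floor_kg - fam_kg - bought_kg) * p - (cash - bought_kg * p),
                land, market)
            cash += raised
            bought_kg = min(max(0.0, floor_kg - fam_kg), cash / p)
        cash -= bought_kg * p
        led["food_bought"] = led.get("food_bought", 0.0) + bought_kg * p

    # goal rationing: production-preferring orphans still short of their
    # conversion goal tighten the belt (down to 75% of a basic diet) and
    # put the grain money toward developing the farm
    if (h.style == ORPHAN and h.rationing_pref == RATION_PRODUCTION
            and bought_kg == 0 and p > 0):
        if h.preference == "agroecology":
            goal = transition_cost_per_ha(market, params) * h.area
        else:
            goal = market.wage
        gap = goal - h.savings
        if gap > 0:
            allow_kg = max(0.0, fam_kg - 0.75 * params.basic_diet_kg)
            sell = min(allow_kg, gap / p)
            fam_kg -= sell
            revenue += sell * p
            cash += sell * p
            led["revenue_rationed"] = led.get("revenue_rationed", 0.0) + sell * p

    h.diet_fraction = min(1.0, (fam_kg + bought_kg) / params.basic_diet_kg)
    if h.diet_fraction < params.abandonment_diet_fraction - 1e-9:
        abandon(h, land, "hunger")
        return

    # saving style: spend-style households consume cash beyond a
    # goal-oriented reserve (what conversion requires for orphans, one
    # year of operating costs for developed farms); hoard-style keep all
    if h.saving_style == SAVE_SPEND:
        if h.style == ORPHAN:
            # the conversion goal, with headroom for input-cost growth
            if h.preference == "agroecology":
                reserve = 1.2 * transition_cost_per_ha(market, params) * h.area
            else:
                reserve = 1.2 * market.wage
        elif h.style == "agroecology" and h.area < params.agro_max_ha:
            # the autonomy goal continues: save toward the next hectare
            # (plus working animals when family labour is outgrown)
            reserve = 1.2 * market.land_price + plan.ni_cost
            if (h.area + 1 > peasant_capacity_ha(h, params)
                    and h.animal_teams < params.agro_max_animal_teams):
                reserve += market.animal_price
        elif h.style == ENTRE:
            # working capital plus the cash half of the next hectare
            # (expansion is the point of the entrepreneurial style)
            reserve = (plan.ni_cost + plan.fert_cost + plan.debt_due
                       + 0.6 * market.land_price)
        else:
            # a working-capital year: purchased inputs plus debt service
            reserve = plan.ni_cost + plan.fert_cost + plan.debt_due
        excess = cash - reserve
        if excess > 0:
            cash -= excess
            led["consumption"] = led.get("consumption", 0.0) + excess

    h.savings = cash

    # income and endogeneity bookkeeping
    gvp = production * p
    h.gross_value = gvp
    h.purchased_inputs_nonlabour = ni_paid + plan.fert_cost
    diet_value = (params.basic_diet_kg + plan.labour_diet_kg) * p
    h.last_net_income = (gvp - diet_value - ni_paid - plan.fert_cost
                         - plan.wage_cost - interest_paid)
    h.income_smooth = 0.7 * h.income_smooth + 0.3 * h.last_net_income
    h.last_production = production

    led["revenue"] = led.get("revenue", 0.0) + revenue
    led["debt_paid"] = led.get("debt_paid", 0.0) + debt_paid
    led["cash_costs"] = led.get("cash_costs", 0.0) + ni_paid + plan.wage_cost
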