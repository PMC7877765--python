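"""Tracked outcomes: production, prices, conversions, abandonment,
nutrition, labour, income inequality, incomes and real land productivity.
"""

from __future__ import annotations

import numpy as np


def gini(incomes) -> float:
    """Gini coefficient G = sum_ij |x_i - x_j| / (2 n^2 xbar), in [0, 1].

    Incomes may be negative (farm losses); the vector is then shifted by
    its minimum so G stays within [0, 1]. Returns 0 for an all-equal or
    all-zero vector; NaN for an empty one.
    """
    x = np.asarray(list(incomes), dtype=float)
    if x.size == 0:
        return float("nan")
    if x.min() < 0:
        x = x - x.min()
    mean = x.mean()
    if mean == 0:
        return 0.0
    # O(n log n) form of the pairwise-difference sum
    xs = np.sort(x)
    n = xs.size
    i = np.arange(1, n + 1)
    return float((2.0 * np.sum(i * xs) - (n + 1) * xs.sum()) / (n * n * mean))


def income_slope(series, window: int = 10) -> float:
    """OLS slope ($/yr) of income on year over the trailing window.

    Uses whatever shorter span is available early in a run; fewer than
    two points give 0.
    """
    y = np.asarray(list(series), dtype=float)[-window:]
    y = y[~np.isnan(y)]
    if y.size < 2:
        return 0.0
    t = np.arange(y.size, dtype=float)
    return float(np.polyfit(t, y, 1)[0])


def endogeneity(gross_value: float, purchased_nonlabour: float) -> float:
    """Share of gross value product created on the farm itself:
    (GVP - purchased inputs excluding labour) / GVP, clamped to [0, 1]."""
    if gross_value <= 0:
        return 0.0
    return min(1.0, max(0.0, (gross_value - purchased_nonlabour) / gross_value))


def real_land_productivity(net_income: float, farm_size_ha: float,
                           gross_value: float,
                           purchased_nonlabour: float) -> float:
    """Net income per hectare scaled by endogeneity ($/ha).

    An environmentally-sensitive intensity measure: value transferred
    into yield from purchased inputs does not count as land productivity.
    """
    if farm_size_ha <= 0 or gross_value <= 0:
        return 0.0
    return (net_income / farm_size_ha) * endogeneity(gross_value, purchased_nonlabour)


def orphan_nutrition(households) -> float:
    """Mean diet fraction across active orphan households (NaN if none)."""
    fracs = [h.diet_fraction for h in households
             if h.active and h.style == "orphan"]
    if not fracs:
        return float("nan")
    return float(np.mean(fracs))


def labour_fte(households) -> float:
    """Total FTE actually employed in production this year, family
    workers and wage earners alike."""
    return float(sum(h.plan.fte_used for h in households if h.active))


def households_feedable(total_production_kg: float,
                        basic_diet_kg: float = 700.0) -> int:
    """How many households the community's production could feed a basic
    diet: floor(total kg / 700 kg)."""
    if total_production_kg < 0:
        raise ValueError("total production must be non-negative")
    return int(total_production_kg // basic_diet_kg)
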