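"""The rural landscape: a square grid of 1-ha arable plots.

Each plot carries a base productive potential (kg/yr under orphan
farming, uniform on 1000 +/- 20%) and a plot-specific agroecology yield
multiple (truncated normal, mean 4, SD 1.5, on [2, 7]). Ownership,
agroecology transition state and the slowly evolving current maximum
yield live here too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from farmstyles.config import AGRO, ENTRE, ORPHAN, ConfigError, Params, PolicyScenario


@dataclass(slots=True)
class Plot:
    idx: int
    row: int
    col: int
    base_max_yield: float
    agro_multiple: float
    owner: int | None = None
    in_transition: bool = False
    transitioned: bool = False
    transition_progress: int = 0
    current_max_yield: float = 0.0

    def __post_init__(self) -> None:
        if self.current_max_yield == 0.0:
            self.current_max_yield = self.base_max_yield


class Landscape:
    """Fixed-size grid of plots with 4-neighbour (von Neumann) adjacency."""

    def __init__(self, plots: list[Plot], side: int):
        self.plots = plots
        self.side = side

    def __len__(self) -> int:
        return len(self.plots)

    def neighbors(self, idx: int) -> list[Plot]:
        side = self.side
        r, c = divmod(idx, side)
        out = []
        if r > 0:
            out.append(self.plots[idx - side])
        if r < side - 1:
            out.append(self.plots[idx + side])
        if c > 0:
            out.append(self.plots[idx - 1])
        if c < side - 1:
            out.append(self.plots[idx + 1])
        return out

    def unoccupied(self) -> list[Plot]:
        return [p for p in self.plots if p.owner is None]


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    # Rejection sampling: exact at this scale.
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v


def init_landscape(params: Params, rng: np.random.Generator) -> Landscape:
    """Create the grid with independently sampled plot potentials."""
    side = params.grid_side
    lo = params.base_plot_yield_mean * (1 - params.base_plot_yield_halfwidth)
    hi = params.base_plot_yield_mean * (1 + params.base_plot_yield_halfwidth)
    mlo, mhi = params.agro_multiple_bounds
    plots = []
    for idx in range(side * side):
        r, c = divmod(idx, side)
        base = rng.uniform(lo, hi)
        mult = _truncated_normal(rng, params.agro_multiple_mean,
                                 params.agro_multiple_sd, mlo, mhi)
        plots.append(Plot(idx=idx, row=r, col=c, base_max_yield=base,
                          agro_multiple=mult))
    return Landscape(plots, side)


def place_households(landscape: Landscape, n: int,
                     rng: np.random.Generator) -> list[int]:
    """Assign households 0..n-1 to n distinct randomly chosen plots.

    Returns the plot index assigned to each household.
    """
    if n > len(landscape):
        raise ConfigError(f"cannot place {n} households on {len(landscape)} plots")
    chosen = rng.choice(len(landscape), size=n, replace=False)
    for hid, idx in enumerate(chosen):
        landscape.plots[int(idx)].owner = hid
    return [int(i) for i in chosen]


def agro_target_yield(plot: Plot, params: Params) -> float:
    """Maximum yield of a plot once fully transitioned to agroecology.

    In sensitivity mode a fixed agroecology:entrepreneurial yield ratio r
    replaces the plot's own multiple: the target becomes r times the
    entrepreneurial maximum (10 x base), with no increments over time.
    """
    if params.fixed_yield_ratio is not None:
        target = params.fixed_yield_ratio * params.fertilizer_max_multiple * plot.base_max_yield
    else:
        target = plot.base_max_yield * plot.agro_multiple
    return min(target, params.plot_yield_cap)


def entre_max_yield(plot: Plot, params: Params) -> float:
    """Maximum yield of a plot under entrepreneurial farming (full fertilizer)."""
    return min(plot.base_max_yield * params.fertilizer_max_multiple,
               params.plot_yield_cap)


def best_contiguous_plot(landscape: Landscape, owned: list[int],
                         style: str, params: Params) -> Plot | None:
    """The unoccupied plot adjacent to a holding with the highest potential.

    Potential is the agroecology target yield for agroecology buyers, the
    base maximum for others. Ties break to the lowest (row, col) for
    determinism.
    """
    candidates: dict[int, Plot] = {}
    for idx in owned:
        for nb in landscape.neighbors(idx):
            if nb.owner is None:
                candidates[nb.idx] = nb
    if not candidates:
        return None

    def potential(p: Plot) -> float:
        if style == AGRO:
            return agro_target_yield(p, params)
        return p.base_max_yield

    return max(candidates.values(), key=lambda p: (potential(p), -p.row, -p.col))


def start_transition(plot: Plot) -> None:
    plot.in_transition = True
    plot.transitioned = False
    plot.transition_progress = 0


def advance_transition(plot: Plot, params: Params) -> None:
    """Advance an in-transition plot by one year.

    Productivity rises linearly from the base yield to the full
    agroecology target over the transition period.
    """
    if not plot.in_transition:
        return
    plot.transition_progress += 1
    target = agro_target_yield(plot, params)
    frac = plot.transition_progress / params.agro_transition_years
    plot.current_max_yield = plot.base_max_yield + frac * (target - plot.base_max_yield)
    if plot.transition_progress >= params.agro_transition_years:
        plot.in_transition = False
        plot.transitioned = True
        plot.current_max_yield = target


def apply_yield_increment(plot: Plot, style: str, policy: PolicyScenario,
                          params: Params) -> None:
    """Slow annual gain on optimised peasant plots (capped at 10 t/ha).

    Entrepreneurial plots gain nothing; transitioned agroecology plots in
    sensitivity mode (fixed yield ratio) gain nothing. Increments apply
    only to fully transitioned or orphan plots, not during transition.
    """
    if style == ENTRE or plot.in_transition:
        return
    if style == ORPHAN:
        rate = (params.orphan_yield_increment_peasant if policy.peasant_increments
                else params.orphan_yield_increment_other)
    elif plot.transitioned:
        if params.fixed_yield_ratio is not None:
            return
        rate = (params.agro_yield_increment_peasant if policy.peasant_increments
                else params.agro_yield_increment_other)
    else:
        return
    plot.current_max_yield = min(plot.current_max_yield * (1 + rate),
                                 params.plot_yield_cap)


def release_plot(plot: Plot) -> None:
    """Return a plot to the unoccupied pool (abandonment or land sale)."""
    plot.owner = None
    plot.in_transition = False
    plot.transition_progress = 0
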