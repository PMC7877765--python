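import numpy as np
import pytest

from farmstyles.config import AGRO, ENTRE, ORPHAN, ConfigError, build_scenario
from farmstyles.landscape import (
    Landscape,
    Plot,
    advance_transition,
    agro_target_yield,
    apply_yield_increment,
    best_contiguous_plot,
    init_landscape,
    place_households,
    start_transition,
)


@pytest.fixture
def landscape(params, rng):
    return init_landscape(params, rng)


class TestInit:
    def test_grid_size(self, landscape):
        assert len(landscape) == 441

    def test_base_yields_uniform_about_mean(self, landscape):
        yields = np.array([p.base_max_yield for p in landscape.plots])
        assert yields.min() >= 800 and yields.max() <= 1200
        # mean of U[800,1200]: SE = 400/sqrt(12)/sqrt(441)
        se = 400 / np.sqrt(12) / np.sqrt(441)
        assert abs(yields.mean() - 1000) < 3 * se

    def test_agro_multiples_truncated(self, landscape):
        mults = np.array([p.agro_multiple for p in landscape.plots])
        assert mults.min() >= 2.0 and mults.max() <= 7.0
        assert 3.3 < mults.mean() < 4.7

    def test_no_initial_owners(self, landscape):
        assert all(p.owner is None for p in landscape.plots)


class TestPlacement:
    def test_250_households_leave_191_plots_free(self, landscape, rng):
        place_households(landscape, 250, rng)
        free = sum(1 for p in landscape.plots if p.owner is None)
        assert free == 191
        assert free / len(landscape) == pytest.approx(0.43, abs=0.01)

    def test_owners_distinct(self, landscape, rng):
        place_households(landscape, 250, rng)
        owners = [p.owner for p in landscape.plots if p.owner is not None]
        assert len(owners) == len(set(owners)) == 250

    def test_overfull_world_rejected(self, landscape, rng):
        with pytest.raises(ConfigError):
            place_households(landscape, 442, rng)


def tiny_landscape(values):
    """3x3 landscape with given base yields (row-major), multiples 4."""
    plots = [Plot(idx=i, row=i // 3, col=i % 3, base_max_yield=v,
                  agro_multiple=4.0) for i, v in enumerate(values)]
    return Landscape(plots, side=3)


class TestBestContiguousPlot:
    def test_none_when_surrounded(self, params):
        land = tiny_landscape([1000] * 9)
        for p in land.plots:
            p.owner = 1
        land.plots[4].owner = 0
        assert best_contiguous_plot(land, [4], ORPHAN, params) is None

    def test_argmax_over_adjacent(self, params):
        land = tiny_landscape([1000, 900, 1000,
                               1100, 1000, 900,
                               1000, 1000, 1000])
        land.plots[4].owner = 0  # centre; neighbours 1 (900), 3 (1100), 5, 7
        best = best_contiguous_plot(land, [4], ENTRE, params)
        assert best.idx == 3 and best.base_max_yield == 1100

    def test_tie_breaks_to_lowest_row_col(self, params):
        land = tiny_landscape([1000] * 9)
        land.plots[4].owner = 0
        best = best_contiguous_plot(land, [4], ORPHAN, params)
        assert best.idx == 1  # (0,1) beats (1,0), (1,2), (2,1)

    def test_agro_buyer_weighs_agro_potential(self, params):
        land = tiny_landscape([1000] * 9)
        land.plots[1].agro_multiple = 7.0
        land.plots[3].base_max_yield = 1100
        land.plots[4].owner = 0
        best = best_contiguous_plot(land, [4], AGRO, params)
        assert best.idx == 1  # 7000 potential beats 1100*4


class TestTransition:
    def test_full_transition_reaches_multiple(self, params):
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4)
        start_transition(plot)
        for _ in range(3):
            advance_transition(plot, params)
        assert plot.transitioned
        assert plot.current_max_yield == pytest.approx(4000)

    def test_yield_interpolates_during_transition(self, params):
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4)
        start_transition(plot)
        assert plot.current_max_yield == pytest.approx(1000)
        advance_transition(plot, params)
        assert plot.current_max_yield == pytest.approx(2000)
        advance_transition(plot, params)
        assert plot.current_max_yield == pytest.approx(3000)

    def test_cap_applies(self, params):
        plot = Plot(idx=0, row=0, col=0, base_max_yield=2000, agro_multiple=7)
        start_transition(plot)
        for _ in range(3):
            advance_transition(plot, params)
        assert plot.current_max_yield == pytest.approx(10_000)

    def test_sensitivity_ratio_overrides_multiple(self):
        p, _, _ = build_scenario("peasant", "no", {"fixed_yield_ratio": 0.25})
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4)
        assert agro_target_yield(plot, p) == pytest.approx(2500)


class TestYieldIncrements:
    def test_orphan_under_peasant_policy(self):
        params, policy, _ = build_scenario("peasant", "no")
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4)
        apply_yield_increment(plot, ORPHAN, policy, params)
        assert plot.current_max_yield == pytest.approx(1015)

    def test_agroecology_under_none_policy(self):
        params, policy, _ = build_scenario("none", "no")
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4,
                    transitioned=True, current_max_yield=4000)
        apply_yield_increment(plot, AGRO, policy, params)
        assert plot.current_max_yield == pytest.approx(4060)

    def test_cap_holds(self, params):
        _, policy, _ = build_scenario("none", "no")
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=7,
                    transitioned=True, current_max_yield=10_000)
        apply_yield_increment(plot, AGRO, policy, params)
        assert plot.current_max_yield == 10_000

    def test_entrepreneurial_plots_unchanged(self, params):
        _, policy, _ = build_scenario("none", "no")
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4)
        apply_yield_increment(plot, ENTRE, policy, params)
        assert plot.current_max_yield == pytest.approx(1000)

    def test_in_transition_plots_gain_nothing(self, params):
        _, policy, _ = build_scenario("peasant", "no")
        plot = Plot(idx=0, row=0, col=0, base_max_yield=1000, agro_multiple=4)
        start_transition(plot)
        apply_yield_increment(plot, AGRO, policy, params)
        assert plot.current_max_yield == pytest.approx(1000)
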