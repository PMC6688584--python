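import math

import numpy as np
import pandas as pd
import pytest

from commitval.control import ControlSurface, GridSpec
from commitval.decision import (
    EOSurface,
    decision_value,
    evaluate_pass,
    evaluate_passes,
    expected_outcome,
    find_alternative,
    kick_smoothing,
)
from commitval.field import FieldConfig
from commitval.synthetic import SimConfig, make_fixture, simulate_match
from commitval.tracking import FieldFormation, PlayerState


class _ConstEquity:
    """Equity stub returning fixed values per direction."""

    def __init__(self, e_a=2.0, e_o=2.0):
        self.e_a, self.e_o = e_a, e_o

    def evaluate(self, x, y, direction=1):
        value = self.e_a if direction == 1 else self.e_o
        return np.full(np.broadcast(np.asarray(x), np.asarray(y)).shape, value)


def _fake_surface(grid, p_a, p_b, p_c, p_d):
    """ControlSurface with prescribed outcome fields (for EO arithmetic)."""
    dom = np.asarray(p_b, dtype=float)
    inf_a = np.divide(p_a, np.where(dom == 0, 1, dom))
    inf_o = np.divide(p_c, np.where(1 - dom == 0, 1, 1 - dom))
    return ControlSurface(
        grid=grid,
        attacking_team="A",
        ball_origin=(0.0, 0.0),
        influence_attacking=np.asarray(inf_a, dtype=float),
        influence_opponent=np.asarray(inf_o, dtype=float),
        dominance_attacking=dom,
        mark_prob_attacking=np.asarray(p_a, dtype=float),
        mark_prob_opponent=np.asarray(p_c, dtype=float),
    )


class TestExpectedOutcome:
    def test_pure_mark_outcome(self):
        grid = GridSpec(0, 0, 0, 0)
        ones = np.ones((1, 1))
        zeros = np.zeros((1, 1))
        # p_A = 1 needs dom = 1 and inf_a = 1; then p_B = dom = 1 as well,
        # so isolate the p_A term with e_o = e_a and p_C = p_D = 0
        surface = _fake_surface(grid, ones, zeros, zeros, zeros)
        surface.dominance_attacking = zeros  # p_B = 0, p_D = 1
        surface.mark_prob_opponent = zeros
        eo = expected_outcome(surface, _ConstEquity(e_a=2.0, e_o=0.0))
        assert eo[0, 0] == pytest.approx(2.0)

    def test_symmetric_cancellation(self):
        grid = GridSpec(0, 1, 0, 1)
        half = np.full((2, 2), 0.5)
        p = np.full((2, 2), 0.2)
        surface = _fake_surface(grid, p, half, p, 1 - half)
        eo = expected_outcome(surface, _ConstEquity(e_a=1.7, e_o=1.7))
        np.testing.assert_allclose(eo, 0.0, atol=1e-12)

    def test_termwise_recomputation(self, rng):
        grid = GridSpec(0, 4, 0, 4)
        shape = grid.shape
        p_a = rng.uniform(0, 1, shape)
        dom = rng.uniform(0, 1, shape)
        p_c = rng.uniform(0, 1, shape)
        surface = _fake_surface(grid, p_a, dom, p_c, 1 - dom)
        e_a, e_o = 1.3, -0.7
        eo = expected_outcome(surface, _ConstEquity(e_a=e_a, e_o=e_o))
        expected = (p_a + dom) * e_a - (p_c + (1 - dom)) * e_o
        np.testing.assert_allclose(eo, expected, atol=1e-12)

    def test_linear_in_equity_scaling(self, planted_fixture):
        fx = planted_fixture
        ev1 = evaluate_pass(
            fx.formation, fx.kicker_id, fx.receiver_location, fx.model, fx.equity,
            receiver_id=fx.receiver_id, field=fx.field,
        )
        scaled = type(fx.equity)(
            field=fx.equity.field, max_value=fx.equity.max_value * 3.0,
            decay_length=fx.equity.decay_length, angle_weight=fx.equity.angle_weight,
        )
        ev3 = evaluate_pass(
            fx.formation, fx.kicker_id, fx.receiver_location, fx.model, scaled,
            receiver_id=fx.receiver_id, field=fx.field,
        )
        assert ev3.decision.eo == pytest.approx(3.0 * ev1.decision.eo, rel=1e-9)
        assert ev3.dv == pytest.approx(ev1.dv, abs=1e-9)


class TestKickSmoothing:
    def test_constant_field_fixed_point(self):
        grid = GridSpec(-30, 30, -30, 30)
        raw = np.full(grid.shape, 4.2)
        smoothed = kick_smoothing(raw, grid, (0.0, 0.0))
        np.testing.assert_allclose(smoothed, 4.2, atol=1e-12)

    def test_short_kick_identity(self, rng):
        grid = GridSpec(-15, 15, -15, 15)
        raw = rng.normal(0, 1, grid.shape)
        smoothed = kick_smoothing(raw, grid, (0.0, 0.0))
        X, Y = grid.cells()
        close = np.hypot(X, Y) < 20.0  # radius < 1 m below 20 m distance
        np.testing.assert_allclose(smoothed[close], raw[close], atol=1e-12)

    def test_radius_is_five_percent_of_distance(self, rng):
        # at exactly 20 m the radius reaches one cell and smoothing begins
        grid = GridSpec(-30, 30, -30, 30)
        raw = rng.normal(0, 1, grid.shape)
        smoothed = kick_smoothing(raw, grid, (0.0, 0.0))
        ix, iy = grid.nearest_index(20.0, 0.0)
        neighborhood = [
            raw[ix, iy], raw[ix - 1, iy], raw[ix + 1, iy],
            raw[ix, iy - 1], raw[ix, iy + 1],
        ]
        assert smoothed[ix, iy] != raw[ix, iy]
        assert min(neighborhood) <= smoothed[ix, iy] <= max(neighborhood)

    def test_contraction(self, rng):
        grid = GridSpec(-40, 40, -40, 40)
        raw = rng.normal(0, 2, grid.shape)
        smoothed = kick_smoothing(raw, grid, (-35.0, -35.0))
        assert smoothed.min() >= raw.min() - 1e-12
        assert smoothed.max() <= raw.max() + 1e-12


class TestDecisionValue:
    def test_optimal_is_one(self):
        assert decision_value(2.0, 2.0) == (1.0, True)

    def test_clamped_at_minus_one(self):
        dv, defined = decision_value(-5.0, 2.0)
        assert dv == -1.0 and defined

    def test_half(self):
        assert decision_value(1.0, 2.0)[0] == pytest.approx(0.5)

    def test_nonpositive_optimum_undefined(self):
        dv, defined = decision_value(1.0, 0.0)
        assert not defined and math.isnan(dv)
        dv, defined = decision_value(1.0, -2.0)
        assert not defined and math.isnan(dv)


class TestFindAlternative:
    def _surface(self, values, grid):
        return EOSurface(
            grid=grid, raw=values, smoothed=values, kicker_location=(0.0, 0.0),
            valid=np.ones(grid.shape, bool), in_range=np.ones(grid.shape, bool),
        )

    def _formation(self, positions):
        states = {
            pid: PlayerState(pid, team, x, y, 1.0, 0.0)
            for pid, team, x, y in positions
        }
        return FieldFormation(time=0.0, states=states, ball_position=(0.0, 0.0))

    def test_single_in_range_teammate(self):
        grid = GridSpec(-70, 70, -70, 70)
        values = np.zeros(grid.shape)
        formation = self._formation(
            [("k", "A", 0.0, 0.0), ("t1", "A", 10.0, 0.0), ("o1", "B", -5.0, 0.0)]
        )
        alt = find_alternative(self._surface(values, grid), formation, "k")
        assert alt.player_id == "t1"

    def test_out_of_range_excluded_even_if_best(self):
        grid = GridSpec(-70, 70, -70, 70)
        values = np.zeros(grid.shape)
        ix, iy = grid.nearest_index(61.0, 0.0)
        values[ix, iy] = 100.0
        formation = self._formation(
            [("k", "A", 0.0, 0.0), ("far", "A", 61.0, 0.0), ("near", "A", 10.0, 0.0)]
        )
        alt = find_alternative(self._surface(values, grid), formation, "k")
        assert alt.player_id == "near"

    def test_no_teammate_in_range(self):
        grid = GridSpec(-70, 70, -70, 70)
        formation = self._formation([("k", "A", 0.0, 0.0), ("far", "A", 65.0, 0.0)])
        assert (
            find_alternative(self._surface(np.zeros(grid.shape), grid), formation, "k")
            is None
        )

    def test_matches_brute_force(self, rng):
        grid = GridSpec(-70, 70, -70, 70)
        values = rng.normal(0, 1, grid.shape)
        positions = [("k", "A", 0.0, 0.0)]
        for i in range(12):
            positions.append((f"t{i:02d}", "A", rng.uniform(-65, 65), rng.uniform(-65, 65)))
        formation = self._formation(positions)
        surface = self._surface(values, grid)
        alt = find_alternative(surface, formation, "k")
        best = None
        for pid, team, x, y in positions[1:]:
            if math.hypot(x, y) > 60.0:
                continue
            ix, iy = grid.nearest_index(x, y)
            if best is None or values[ix, iy] > best[1]:
                best = (pid, values[ix, iy])
        if best is None:
            assert alt is None
        else:
            assert alt.eo == pytest.approx(best[1])

    def test_tie_broken_by_lowest_id(self):
        grid = GridSpec(-70, 70, -70, 70)
        values = np.zeros(grid.shape)
        formation = self._formation(
            [("k", "A", 0.0, 0.0), ("z", "A", 10.0, 0.0), ("b", "A", -10.0, 0.0)]
        )
        alt = find_alternative(self._surface(values, grid), formation, "k")
        assert alt.player_id == "b"


class TestEvaluatePass:
    def test_planted_optimum_recovered(self, planted_fixture):
        fx = planted_fixture
        ev = evaluate_pass(
            fx.formation, fx.kicker_id, fx.receiver_location, fx.model, fx.equity,
            receiver_id=fx.receiver_id, field=fx.field,
        )
        assert ev.alternative.player_id == fx.expected["alternative_id"]
        assert ev.dv == pytest.approx(fx.expected["dv"])
        assert ev.dv_defined

    def test_pass_to_alternative_location_dv_one(self, planted_fixture):
        fx = planted_fixture
        ev = evaluate_pass(
            fx.formation, fx.kicker_id, fx.receiver_location, fx.model, fx.equity,
            receiver_id=fx.receiver_id, field=fx.field,
        )
        assert ev.decision.eo == pytest.approx(ev.alternative.eo)
        assert ev.decision.distance == pytest.approx(40.0)

    def test_ball_flight_time_used(self, planted_fixture):
        # 37 m kick at 18.5 m/s -> 2.0 s time-to-point at the target cell
        fx = planted_fixture
        ev = evaluate_pass(
            fx.formation, fx.kicker_id, (37.0, 0.0), fx.model, fx.equity,
            field=fx.field,
        )
        assert ev.decision.distance == pytest.approx(37.0)

    def test_dv_upper_bound(self, planted_fixture):
        """DV <= 1 whenever the optimum is positive and the decision targets
        a teammate cell (the alternative search is exhaustive)."""
        fx = planted_fixture
        for target in [(40.0, 0.0), (-30.0, 0.0)]:
            ev = evaluate_pass(
                fx.formation, fx.kicker_id, target, fx.model, fx.equity,
                field=fx.field,
            )
            if ev.dv_defined:
                assert ev.dv <= 1.0 + 1e-12


class TestEvaluatePasses:
    def test_synthetic_chains_evaluated(self, toy_model):
        res = simulate_match(
            SimConfig(seed=21, n_plays=12, pass_fraction=1.0, players_per_team=8)
        )
        from commitval.equity import SurrogateEquity

        evaluations, diag = evaluate_passes(
            res.tracking_frame(), res.transactions, toy_model, SurrogateEquity(),
            match_id="m1",
        )
        assert diag.n_evaluated == len(evaluations)
        # every planted mark->kick->mark chain is either evaluated or
        # accounted for by a diagnostic
        assert diag.n_evaluated + diag.no_alternative == len(res.passes)
        assert (evaluations["dist_alt"] <= 60.0 + 1e-9).all()
        defined = evaluations[evaluations["dv_defined"]]
        assert (defined["dv"] <= 1.0 + 1e-9).all()
        assert (defined["dv"] >= -1.0 - 1e-9).all()

    def test_kick_not_from_mark_skipped(self, toy_model):
        res = simulate_match(
            SimConfig(seed=21, n_plays=8, pass_fraction=0.0, players_per_team=8)
        )
        from commitval.equity import SurrogateEquity

        evaluations, diag = evaluate_passes(
            res.tracking_frame(), res.transactions, toy_model, SurrogateEquity()
        )
        assert len(evaluations) == 0
        assert diag.no_preceding_mark == diag.n_kicks
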