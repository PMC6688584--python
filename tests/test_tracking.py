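import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commitval.synthetic import SimConfig, make_fixture, simulate_match
from commitval.tracking import (
    KICK,
    SPOIL,
    ParseError,
    PlayerState,
    PlayerTrack,
    SchemaError,
    angle_between,
    build_tracks,
    consolidate,
    heading_angle,
    read_tracking,
    read_transactions,
    to_relative,
    write_tracking,
    write_transactions,
)


def _tracking_df(rows):
    return pd.DataFrame(rows, columns=["timestamp", "player_id", "team_id", "x", "y"])


class TestReadTracking:
    def test_three_row_roundtrip(self, tmp_path):
        df = _tracking_df(
            [
                (0.0, "p1", "A", 1.0, 2.0),
                (0.1, "p1", "A", 1.1, 2.0),
                (0.2, "p1", "A", 1.2, 2.0),
            ]
        )
        path = tmp_path / "t.csv"
        write_tracking(df, path)
        out = read_tracking(path)
        assert len(out) == 3
        assert list(out["timestamp"]) == [0.0, 0.1, 0.2]

    def test_empty_file_with_header(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("timestamp,player_id,team_id,x,y\n")
        assert len(read_tracking(path)) == 0

    def test_missing_column_raises_schema_error(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("timestamp,player_id,x,y\n0.0,p1,1,2\n")
        with pytest.raises(SchemaError, match="team_id"):
            read_tracking(path)

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "timestamp,player_id,team_id,x,y\n0.0,p1,A,1.0,2.0\n0.1,p1,A,oops,2.0\n"
        )
        with pytest.raises(ParseError, match="line 3"):
            read_tracking(path)

    def test_generator_output_row_count(self, tmp_path):
        res = simulate_match(SimConfig(seed=1, n_plays=4))
        path = tmp_path / "t.csv"
        write_tracking(res.tracking_frame(), path)
        out = read_tracking(path)
        n_frames, n_players, _ = res.positions.shape
        assert len(out) == n_frames * n_players

    def test_roundtrip_bit_exact(self, tmp_path):
        res = simulate_match(SimConfig(seed=1, n_plays=3))
        p0 = tmp_path / "raw.csv"
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_tracking(res.tracking_frame(), p0)
        write_tracking(read_tracking(p0), p1)
        write_tracking(read_tracking(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestReadTransactions:
    def test_bad_event_type(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("timestamp,event_type,player_id,x,y\n10,tackle,p1,0,0\n")
        with pytest.raises(SchemaError, match="tackle"):
            read_transactions(path)

    def test_fractional_timestamp_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("timestamp,event_type,player_id,x,y\n10.4,kick,p1,0,0\n")
        with pytest.raises(ParseError, match="whole second"):
            read_transactions(path)

    def test_roundtrip_bit_exact(self, tmp_path):
        res = simulate_match(SimConfig(seed=1, n_plays=5))
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_transactions(res.transactions, p1)
        write_transactions(read_transactions(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestVelocity:
    def _track(self, points):
        ts = [p[0] for p in points]
        return PlayerTrack("p", ts, [p[1] for p in points], [p[2] for p in points])

    def test_three_four_five(self):
        tr = self._track([(9.0, 0.0, 0.0), (10.0, 3.0, 4.0)])
        assert tr.velocity_at(10.0) == pytest.approx(5.0)

    def test_stationary(self):
        tr = self._track([(9.0, 1.0, 1.0), (10.0, 1.0, 1.0)])
        assert tr.velocity_at(10.0) == 0.0

    def test_missing_prior_frame_undefined(self):
        tr = self._track([(10.0, 0.0, 0.0)])
        assert tr.velocity_at(10.0) is None

    def test_constant_velocity_recovered(self):
        v = 3.7
        ts = np.round(np.arange(0, 5, 0.1), 1)
        tr = PlayerTrack("p", ts, v * ts, np.zeros_like(ts))
        assert tr.velocity_at(4.0) == pytest.approx(v, abs=1e-9)

    def test_velocity_invariant_under_rigid_motion(self, rng):
        ts = np.round(np.arange(0, 3, 0.1), 1)
        xs = rng.normal(0, 5, ts.size).cumsum() * 0.05
        ys = rng.normal(0, 5, ts.size).cumsum() * 0.05
        theta = rng.uniform(0, 2 * math.pi)
        c, s = math.cos(theta), math.sin(theta)
        xr = c * xs - s * ys + 12.0
        yr = s * xs + c * ys - 7.0
        t1 = PlayerTrack("p", ts, xs, ys)
        t2 = PlayerTrack("p", ts, xr, yr)
        assert t1.velocity_at(2.0) == pytest.approx(t2.velocity_at(2.0), abs=1e-9)


class TestDirection:
    def test_axis_directions(self):
        assert heading_angle(0.0, 1.0) == pytest.approx(0.0)
        assert heading_angle(1.0, 0.0) == pytest.approx(math.pi / 2)
        assert heading_angle(0.0, -1.0) == pytest.approx(math.pi)

    def test_zero_displacement_carries_previous(self):
        tr = PlayerTrack(
            "p", [0.0, 0.1, 0.2], [0.0, 1.0, 1.0], [0.0, 0.0, 0.0]
        )
        direction, defined = tr.direction_at(0.2)
        assert defined
        assert direction == pytest.approx(math.pi / 2)

    def test_never_moved_is_undefined(self):
        tr = PlayerTrack("p", [0.0, 0.1], [2.0, 2.0], [3.0, 3.0])
        direction, defined = tr.direction_at(0.1)
        assert not defined
        assert direction == 0.0


class TestAngleBetween:
    def test_collinear(self):
        assert angle_between((0, 0), (0, 1), (0, 2)) == pytest.approx(0.0)

    def test_right_turn(self):
        assert angle_between((0, 0), (0, 1), (1, 1)) == pytest.approx(math.pi / 2)

    def test_reversal(self):
        assert angle_between((0, 0), (0, 1), (0, 0)) == pytest.approx(math.pi)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            angle_between((0, 0), (0, 0), (1, 1))


class TestToRelative:
    def test_identity_frame(self):
        st_ = PlayerState("p", "A", 0.0, 0.0, 1.0, 0.0)
        assert to_relative(st_, (3.0, 4.0)) == pytest.approx((3.0, 4.0))

    def test_pure_rotation(self):
        st_ = PlayerState("p", "A", 0.0, 0.0, 1.0, math.pi / 2)
        rel = to_relative(st_, (5.0, 0.0))
        assert rel[0] == pytest.approx(0.0, abs=1e-12)
        assert rel[1] == pytest.approx(5.0)

    def test_isometry(self, rng):
        for _ in range(25):
            px, py = rng.normal(0, 30, 2)
            lx, ly = rng.normal(0, 30, 2)
            st_ = PlayerState("p", "A", px, py, 1.0, rng.uniform(0, 2 * math.pi))
            rel = to_relative(st_, (lx, ly))
            assert math.hypot(*rel) == pytest.approx(
                math.hypot(lx - px, ly - py), abs=1e-9
            )

    @settings(max_examples=40, deadline=None)
    @given(
        theta=st.floats(0, 2 * math.pi - 1e-9),
        phi=st.floats(0, 2 * math.pi - 1e-9),
        px=st.floats(-50, 50),
        py=st.floats(-50, 50),
        lx=st.floats(-50, 50),
        ly=st.floats(-50, 50),
    )
    def test_rotation_invariance(self, theta, phi, px, py, lx, ly):
        """Rigidly rotating the whole field leaves relative coordinates fixed."""
        c, s = math.cos(phi), math.sin(phi)

        def rot(x, y):
            return (c * x - s * y, s * x + c * y)

        st0 = PlayerState("p", "A", px, py, 1.0, theta)
        rel0 = to_relative(st0, (lx, ly))
        # rotating by phi counter-clockwise reduces the clockwise-from-+y
        # heading by phi
        prx, pry = rot(px, py)
        lrx, lry = rot(lx, ly)
        st1 = PlayerState("p", "A", prx, pry, 1.0, (theta - phi) % (2 * math.pi))
        rel1 = to_relative(st1, (lrx, lry))
        assert rel0[0] == pytest.approx(rel1[0], abs=1e-6)
        assert rel0[1] == pytest.approx(rel1[1], abs=1e-6)


class TestConsolidate:
    def _streams(self):
        ts = np.round(np.arange(99.0, 103.0, 0.1), 1)
        frames = []
        for pid, team, x0 in [("p1", "A", 0.0), ("p2", "B", 10.0)]:
            frames.append(
                pd.DataFrame(
                    {
                        "timestamp": ts,
                        "player_id": pid,
                        "team_id": team,
                        "x": x0 + 0.5 * (ts - 99.0),
                        "y": 0.0,
                    }
                )
            )
        tracking = pd.concat(frames).reset_index(drop=True)
        tx = pd.DataFrame(
            [{"timestamp": 100, "event_type": KICK, "player_id": "p1", "x": 0.5, "y": 0.0}]
        )
        return tracking, tx

    def test_matched_to_start_of_second(self):
        tracking, tx = self._streams()
        result = consolidate(tracking, tx)
        assert result.n_matched == 1
        formation = result.formations[0]
        assert formation.time == 100.0
        # position is the frame at 100.0 exactly, not a later sub-second frame
        assert formation.states["p1"].x == pytest.approx(0.5)

    def test_missing_player_passage_excluded(self):
        tracking, tx = self._streams()
        tracking = tracking[
            ~((tracking["player_id"] == "p2") & (tracking["timestamp"] == 100.0))
        ]
        result = consolidate(tracking, tx)
        assert result.n_matched == 0
        assert result.incomplete == [0]

    def test_out_of_range_transaction_unmatched(self):
        tracking, tx = self._streams()
        tx = pd.concat(
            [tx, pd.DataFrame([{"timestamp": 500, "event_type": SPOIL,
                                "player_id": "p1", "x": 0, "y": 0}])]
        ).reset_index(drop=True)
        result = consolidate(tracking, tx)
        assert result.n_matched == 1
        assert len(result.unmatched) == 1

    def test_synthetic_match_fully_matched(self, small_sim):
        result = consolidate(
            pd.DataFrame(), small_sim.transactions, tracks=small_sim.tracks()
        )
        assert result.n_matched == len(small_sim.transactions)
        assert not result.unmatched and not result.incomplete

    def test_output_never_exceeds_transaction_count(self, small_sim):
        result = consolidate(
            pd.DataFrame(), small_sim.transactions, tracks=small_sim.tracks()
        )
        assert result.n_matched <= len(small_sim.transactions)
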