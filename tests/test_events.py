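"""Collision segmentation and rest/transfer interval bookkeeping."""

import numpy as np
import pytest

from demgaze import (
    align_log_to_chart,
    build_chart,
    build_log,
    detect_hit,
    detect_hits,
    segment_stream,
)
from demgaze.events import EmptyStreamError
from demgaze.geometry import GazeStream
from demgaze.simulate import SimulationConfig, simulate

from conftest import check_conservation, engine_visits, oracle_runs

FS = 60.0


def make_stream(points, fs=FS):
    xy = np.asarray(points, dtype=float)
    return GazeStream(t=np.arange(len(xy)) / fs, xy=xy)


class TestDetectHit:
    def test_center_edge_and_gap(self, vertical_layout):
        tgt = vertical_layout.targets[4]
        cx, cy = tgt.center
        assert detect_hit((cx, cy), vertical_layout) == tgt.ordinal
        # the chart center of the 4-column grid falls between colliders
        assert detect_hit((0.0, 0.0), vertical_layout) is None
        # dropout samples hit nothing
        assert detect_hit((np.nan, cy), vertical_layout) is None

    def test_boundary_inclusive(self):
        """Points exactly on a collider edge or corner count as inside."""
        from demgaze.chart import CharTarget, ChartLayout

        tgt = CharTarget(ordinal=1, digit=5, center=(0.0, 0.0),
                         half_extent=0.02)
        layout = ChartLayout(test_id="pretest", targets=(tgt,), rows=1,
                             cols=1, reading_order="row")
        assert detect_hit((0.02, 0.0), layout) == 1
        assert detect_hit((0.02, -0.02), layout) == 1
        assert detect_hit((-0.02, 0.01), layout) == 1
        assert detect_hit((0.02 + 1e-9, 0.0), layout) is None

    def test_vectorized_agrees_with_scalar(self, horizontal_layout):
        rng = np.random.default_rng(2)
        pts = rng.uniform(-0.5, 0.5, (500, 2))
        labels = detect_hits(pts, horizontal_layout)
        for p, lab in zip(pts, labels):
            expect = detect_hit(tuple(p), horizontal_layout)
            assert (expect or 0) == lab


class TestSegmentStream:
    def test_empty_stream_raises(self, vertical_layout):
        with pytest.raises(EmptyStreamError):
            segment_stream(GazeStream(t=np.zeros(0), xy=np.zeros((0, 2))),
                           vertical_layout)

    def test_all_outside_gives_no_events(self, vertical_layout):
        stream = make_stream([[0.0, 0.0]] * 30)
        assert segment_stream(stream, vertical_layout) == []

    def test_enter_exit_enter_sequence(self, vertical_layout):
        """12 samples in target 1, 6 outside, 12 in target 2."""
        c1 = vertical_layout.targets[0].center
        c2 = vertical_layout.targets[1].center
        stream = make_stream([c1] * 12 + [(0.0, 0.0)] * 6 + [c2] * 12)
        events = segment_stream(stream, vertical_layout)
        assert [(e.kind, e.ordinal) for e in events] == [
            ("enter", 1), ("exit", 1), ("enter", 2)
        ]
        assert events[0].t == 0.0
        assert events[1].t == pytest.approx(12 / FS)
        assert events[2].t == pytest.approx(18 / FS)

    def test_direct_transition_emits_exit_then_enter_same_time(
            self, vertical_layout):
        c1 = vertical_layout.targets[0].center
        c2 = vertical_layout.targets[1].center
        events = segment_stream(make_stream([c1] * 3 + [c2] * 3),
                                vertical_layout)
        kinds = [(e.kind, e.ordinal) for e in events]
        assert kinds == [("enter", 1), ("exit", 1), ("enter", 2)]
        assert events[1].t == events[2].t

    def test_dropout_ends_inside_state(self, vertical_layout):
        c1 = vertical_layout.targets[0].center
        pts = [c1] * 5 + [(np.nan, np.nan)] * 3 + [c1] * 5
        events = segment_stream(make_stream(pts), vertical_layout)
        assert [(e.kind, e.ordinal) for e in events] == [
            ("enter", 1), ("exit", 1), ("enter", 1)
        ]

    @pytest.mark.parametrize("seed", range(8))
    def test_alternation_invariant_random_walk(self, seed, horizontal_layout):
        """Events alternate enter/exit with matching ordinals on any stream."""
        rng = np.random.default_rng(seed)
        steps = rng.normal(0, 0.04, (800, 2))
        xy = np.cumsum(steps, axis=0)  # wandering gaze over the chart
        stream = make_stream(xy)
        events = segment_stream(stream, horizontal_layout)
        visits = engine_visits(events)  # asserts alternation + ordinal match
        runs = oracle_runs(stream, horizontal_layout)
        assert [v[0] for v in visits] == [r[0] for r in runs]


class TestBuildLog:
    def test_single_visit_yields_no_measured_records(self, vertical_layout):
        c1 = vertical_layout.targets[0].center
        events = segment_stream(make_stream([c1] * 10 + [(0, 0)] * 5),
                                vertical_layout)
        log = build_log(events, vertical_layout, "vertical")
        assert log.n_measured == 0
        assert len(log.records) == 1
        assert "terminal" in log.records[0].flags

    def test_zero_events_warns(self, vertical_layout):
        log = build_log([], vertical_layout, "vertical")
        assert log.records == [] and log.warnings

    def test_fixed_dwell_rest_times_within_one_sample(self, vertical_layout):
        """0.20 s dwells at 60 Hz, no noise: rests within one period of 0.20."""
        config = SimulationConfig(seed=3, dwell_mean_v=0.20, dwell_shape=None,
                                  noise_sigma=0.0)
        stream, _ = simulate(vertical_layout, config)
        log = build_log(segment_stream(stream, vertical_layout),
                        vertical_layout, "vertical", t_end=float(stream.t[-1]))
        rests = [r.rest_time for r in log.measured_records]
        assert len(rests) == 78
        assert all(abs(r - 0.20) <= 1 / FS + 1e-9 for r in rests)

    def test_durations_nonnegative_and_quantized(self, horizontal_layout):
        stream, _ = simulate(horizontal_layout, SimulationConfig(seed=9))
        log = build_log(segment_stream(stream, horizontal_layout),
                        horizontal_layout, "horizontal", t_end=float(stream.t[-1]))
        for rec in log.measured_records:
            for d in (rec.rest_time, rec.transfer_time):
                assert d >= 0
                assert abs(d * FS - round(d * FS)) < 1e-6

    def test_timers_never_overlap_and_tile_span(self, vertical_layout):
        """Rest and transfer intervals are disjoint and conserve the span."""
        stream, _ = simulate(vertical_layout, SimulationConfig(seed=21))
        events = segment_stream(stream, vertical_layout)
        log = build_log(events, vertical_layout, "vertical",
                        t_end=float(stream.t[-1]))
        visits = engine_visits(events)
        # the recording ends on the last character: its exit is open
        assert visits[-1][2] is None
        # non-overlap: rest = [enter, exit), transfer = [exit, next enter)
        for (o1, t_in1, t_out1), (o2, t_in2, t_out2) in zip(visits, visits[1:]):
            assert t_in1 <= t_out1 <= t_in2
            if t_out2 is not None:
                assert t_in2 <= t_out2
        check_conservation(log, tol=1e-9)

    def test_vertical_boundary_splits_timers(self, vertical_layout):
        """No transfer spans the gap between subtests A and B."""
        stream, _ = simulate(vertical_layout, SimulationConfig(seed=2))
        log = build_log(segment_stream(stream, vertical_layout),
                        vertical_layout, "vertical", t_end=float(stream.t[-1]))
        assert len(log.spans) == 2
        terminals = [r for r in log.records if "terminal" in r.flags]
        assert [r.serial for r in terminals] == [40, 80]
        assert [r.ordinal for r in terminals] == [40, 80]
        # Test B timing restarts: measured transfers exclude the A->B sweep
        b_first_enter = log.spans[1][0]
        a_last_enter = log.spans[0][1]
        for rec in log.measured_records:
            assert rec.transfer_time < b_first_enter - a_last_enter


class TestAlignment:
    @staticmethod
    def _log_for(layout, config, kind):
        stream, schedule = simulate(layout, config)
        log = build_log(segment_stream(stream, layout), layout, kind,
                        t_end=float(stream.t[-1]))
        return align_log_to_chart(log, layout), schedule

    def test_sequential_log_has_no_errors(self, vertical_layout):
        log, _ = self._log_for(vertical_layout, SimulationConfig(seed=4),
                               "vertical")
        assert (log.omissions, log.additions) == (0, 0)

    def test_injected_omissions_recovered(self, horizontal_layout):
        config = SimulationConfig(seed=14, p_omit=0.05)
        log, schedule = self._log_for(horizontal_layout, config, "horizontal")
        assert schedule.omitted, "seed must actually skip characters"
        assert log.omissions == len(schedule.omitted)
        assert log.additions == 0

    def test_injected_revisits_recovered(self, vertical_layout):
        config = SimulationConfig(seed=23, p_revisit=0.05)
        log, schedule = self._log_for(vertical_layout, config, "vertical")
        assert schedule.n_revisits > 0
        assert log.additions == schedule.n_revisits
        assert log.omissions == 0
        assert sum("revisit" in r.flags for r in log.records) == log.additions
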