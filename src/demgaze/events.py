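"""Collision events and rest/transfer interval extraction.

This is the measurement core of the toolkit.  The calibrated gaze point is
scanned sample by sample over the chart; the first sample inside a collider
after an outside state raises an *enter* event, the first sample outside
after an inside state an *exit* event.  The dwell between an enter and its
exit is the character's **rest time**; the span from that exit to the next
enter is its **transfer time**.  The two timers never run at once and
together tile the span between successive enters, so per subtest

    sum(rest + transfer)  ==  t(last enter) - t(first enter)

holds exactly under this event-time bookkeeping.

Collisions are evaluated at sample times only — the tracker reports at a
fixed frame rate — so all durations are quantized at the sample period.
Event timestamps use the first sample of the *new* state (enter-biased).

The final character read in each subtest yields no interval record: its
rest ends the recording and it has no successor, so a complete sequential
reading of the two 40-character vertical subtests produces 78 records and
of the 80-character horizontal test 79.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .chart import ChartLayout
from .geometry import GazeStream

__all__ = [
    "CollisionEvent",
    "IntervalRecord",
    "TestLog",
    "detect_hit",
    "detect_hits",
    "segment_stream",
    "build_log",
    "align_log_to_chart",
    "EmptyStreamError",
]


class EmptyStreamError(ValueError):
    """segment_stream was given a stream with no samples."""


@dataclass(frozen=True)
class CollisionEvent:
    """An enter or exit of the gaze point at one collider."""

    kind: str      # "enter" | "exit"
    ordinal: int   # 1-based target index
    t: float       # sample time, seconds


@dataclass
class IntervalRecord:
    """One row of the per-character log.

    ``rest_time``/``transfer_time`` are ``None`` on the terminal row of a
    subtest (the last-read character has no successor; the printed log
    shows "-" there).  ``flags`` may contain ``terminal``, ``incomplete``
    (stream ended before the next collision), ``revisit`` and ``omitted``
    markers set by :func:`align_log_to_chart`.
    """

    serial: int
    ordinal: int
    digit: int
    rest_time: float | None
    transfer_time: float | None
    flags: set[str] = field(default_factory=set)

    @property
    def is_measured(self) -> bool:
        return self.rest_time is not None and self.transfer_time is not None


@dataclass
class TestLog:
    """The full interval log of one test run.

    ``records`` lists every visited character in event order, including the
    terminal placeholder row of each subtest; ``measured_records`` excludes
    the placeholders and is what the 78/79 counts refer to.  ``spans`` holds
    one ``(first_enter, last_enter, last_exit)`` triple per subtest; gaze
    between the two vertical subtests belongs to no timer.
    """

    test_kind: str                       # "vertical" | "horizontal"
    records: list[IntervalRecord]
    subtest_boundary: int | None         # ordinal after which timers reset
    stream_span: tuple[float, float]
    spans: list[tuple[float, float, float]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    # gaze-derived reading-error counts, set by align_log_to_chart
    omissions: int | None = None
    additions: int | None = None

    @property
    def measured_records(self) -> list[IntervalRecord]:
        return [r for r in self.records if r.is_measured]

    @property
    def n_measured(self) -> int:
        return len(self.measured_records)


def detect_hit(point: tuple[float, float], layout: ChartLayout) -> int | None:
    """Ordinal of the collider containing ``point`` (boundary inclusive).

    Colliders are disjoint, so at most one can contain the point; NaN
    coordinates (tracker dropout) hit nothing.
    """
    x, y = point
    if not (math.isfinite(x) and math.isfinite(y)):
        return None
    for target in layout.targets:
        if target.contains(x, y):
            return target.ordinal
    return None


def detect_hits(xy: np.ndarray, layout: ChartLayout) -> np.ndarray:
    """Vectorized hit test: ordinal per sample, 0 where outside all colliders."""
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    centers = layout.centers()          # (m, 2)
    half = layout.half_extents()        # (m,)
    d = np.abs(xy[:, None, :] - centers[None, :, :])  # (n, m, 2)
    inside = (d[:, :, 0] <= half) & (d[:, :, 1] <= half)
    labels = np.zeros(xy.shape[0], dtype=int)
    hit_rows, hit_cols = np.nonzero(inside)
    # disjoint colliders: each row appears at most once
    labels[hit_rows] = hit_cols + 1
    labels[~np.all(np.isfinite(xy), axis=1)] = 0
    return labels


def segment_stream(stream: GazeStream, layout: ChartLayout
                   ) -> list[CollisionEvent]:
    """Convert a gaze stream into time-ordered enter/exit collision events.

    An enter fires at the first sample inside a collider following an
    outside (or stream-start) state; an exit at the first sample outside
    following an inside state.  Two consecutive samples in *different*
    colliders fire exit-then-enter at the same timestamp.  A stream ending
    mid-collision leaves its final enter unpaired.
    """
    if len(stream) == 0:
        raise EmptyStreamError("gaze stream has no samples")
    labels = detect_hits(stream.xy, layout)
    t = stream.t
    events: list[CollisionEvent] = []
    current = 0
    for i in range(labels.size):
        lab = int(labels[i])
        if lab == current:
            continue
        if current != 0:
            events.append(CollisionEvent("exit", current, float(t[i])))
        if lab != 0:
            events.append(CollisionEvent("enter", lab, float(t[i])))
        current = lab
    return events


def _visits(events: list[CollisionEvent], t_end: float
            ) -> list[tuple[int, float, float, bool]]:
    """Pair enter/exit events into (ordinal, t_enter, t_exit, closed)."""
    visits = []
    open_ord, open_t = None, None
    for ev in events:
        if ev.kind == "enter":
            open_ord, open_t = ev.ordinal, ev.t
        else:
            visits.append((ev.ordinal, open_t, ev.t, True))
            open_ord = None
    if open_ord is not None:
        visits.append((open_ord, open_t, t_end, False))
    return visits


def build_log(events: list[CollisionEvent], layout: ChartLayout,
              test_kind: str, t_end: float | None = None,
              t_start: float | None = None) -> TestLog:
    """Turn collision events into per-character rest/transfer records.

    ``t_end`` is the stream's final sample time; a recording normally ends
    while the gaze still rests on the last character, so its unpaired
    enter is closed at ``t_end`` (flagged ``incomplete``) and the last
    subtest's span extends to that observed dwell end.  Without ``t_end``
    the last event time is used.

    Every collision — including one with an already-visited collider —
    closes the running transfer timer and opens a rest timer, so records
    follow event order; reconciliation against chart reading order is the
    job of :func:`align_log_to_chart`.  For the vertical test the visit
    sequence splits at the first collision beyond ordinal 40 (Test B):
    the last character of Test A gets a terminal placeholder row, the gap
    between the subtests belongs to no timer, and timing restarts at Test
    B's first enter.
    """
    if test_kind not in ("vertical", "horizontal"):
        raise ValueError(f"test_kind must be vertical or horizontal, got {test_kind!r}")
    boundary = 40 if test_kind == "vertical" else None

    if not events:
        return TestLog(
            test_kind=test_kind, records=[], subtest_boundary=boundary,
            stream_span=(0.0, 0.0), warnings=["no collision events"],
        )
    if t_end is None:
        t_end = events[-1].t
    if t_start is None:
        t_start = events[0].t
    visits = _visits(events, t_end)
    stream_span = (t_start, t_end)

    # split visits into subtests
    if boundary is not None:
        split = next(
            (i for i, v in enumerate(visits) if v[0] > boundary), len(visits)
        )
        groups = [g for g in (visits[:split], visits[split:]) if g]
    else:
        groups = [visits]

    digits = {tgt.ordinal: tgt.digit for tgt in layout.targets}
    records: list[IntervalRecord] = []
    spans: list[tuple[float, float, float]] = []
    warnings: list[str] = []
    serial = 0
    for group in groups:
        spans.append((group[0][1], group[-1][1], group[-1][2]))
        for i, (ordinal, t_in, t_out, closed) in enumerate(group):
            serial += 1
            if i == len(group) - 1:
                # last-read character of the subtest: dash row in the log
                records.append(IntervalRecord(
                    serial, ordinal, digits[ordinal], None, None, {"terminal"}))
                if not closed:
                    records[-1].flags.add("incomplete")
                continue
            rest = t_out - t_in
            transfer = group[i + 1][1] - t_out
            rec = IntervalRecord(serial, ordinal, digits[ordinal],
                                 rest, transfer)
            if not closed:  # cannot happen except for malformed event lists
                rec.flags.add("incomplete")
            records.append(rec)

    n_expected = layout.n_targets - len(groups)
    n_measured = sum(r.is_measured for r in records)
    if n_measured != n_expected:
        warnings.append(
            f"{n_measured} measured records; a complete reading gives {n_expected}"
        )
    return TestLog(
        test_kind=test_kind, records=records, subtest_boundary=boundary,
        stream_span=stream_span, spans=spans, warnings=warnings,
    )


def _longest_increasing_subsequence(seq: list[int]) -> list[int]:
    """Indices of one longest strictly increasing subsequence of ``seq``."""
    if not seq:
        return []
    # patience sorting with predecessor links
    tails: list[int] = []          # index of smallest tail per length
    prev = [-1] * len(seq)
    import bisect
    tail_vals: list[int] = []
    for i, v in enumerate(seq):
        j = bisect.bisect_left(tail_vals, v)
        if j == len(tail_vals):
            tail_vals.append(v)
            tails.append(i)
        else:
            tail_vals[j] = v
            tails[j] = i
        prev[i] = tails[j - 1] if j > 0 else -1
    out = []
    i = tails[-1]
    while i != -1:
        out.append(i)
        i = prev[i]
    return out[::-1]


def align_log_to_chart(log: TestLog, layout: ChartLayout) -> TestLog:
    """Reconcile the visit sequence with chart reading order.

    The longest strictly increasing subsequence of visited ordinals is the
    best sequential reading consistent with the log: chart characters it
    never reaches are counted as omissions ``o``, records outside it
    (revisits, spurious hits) as additions ``a``.  Flags are set in place
    on the log's records and the counts stored on the log, which is also
    returned for chaining.
    """
    ordinals = [r.ordinal for r in log.records]
    keep = set(_longest_increasing_subsequence(ordinals))
    matched = {ordinals[i] for i in keep}
    for i, rec in enumerate(log.records):
        if i not in keep:
            rec.flags.add("revisit")
    omitted = [t.ordinal for t in layout.targets if t.ordinal not in matched]
    log.omissions = len(omitted)
    log.additions = len(ordinals) - len(keep)
    return log
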