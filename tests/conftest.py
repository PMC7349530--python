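"""Shared fixtures and the independent per-sample collision oracle.

The oracle deliberately avoids the package's vectorized hit testing and
event machinery: it labels every sample with a plain Python
point-in-square loop and run-length encodes the labels, giving an
independent reference for enter/exit times and interval durations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from demgaze import build_chart
from demgaze.simulate import SimulationConfig


@pytest.fixture(scope="session")
def vertical_layout():
    return build_chart("vertical", seed=11)


@pytest.fixture(scope="session")
def horizontal_layout():
    return build_chart("C", seed=11)


@pytest.fixture(scope="session")
def error_free_config():
    return SimulationConfig(seed=5)


# ------------------------------------------------------------------ oracle

def oracle_labels(stream, layout) -> list[int]:
    """Per-sample collider label (0 = outside), by direct point-in-square."""
    labels = []
    for x, y in stream.xy:
        lab = 0
        if math.isfinite(x) and math.isfinite(y):
            for tgt in layout.targets:
                cx, cy = tgt.center
                if abs(x - cx) <= tgt.half_extent and abs(y - cy) <= tgt.half_extent:
                    lab = tgt.ordinal
                    break
        labels.append(lab)
    return labels


def oracle_runs(stream, layout) -> list[tuple[int, float, float, bool]]:
    """Run-length encoding of in-collider episodes.

    Returns (ordinal, t_enter, t_exit, closed) per episode, with the same
    first-sample-of-new-state time convention the engine declares: the
    enter time is the first sample inside, the exit time the first sample
    of the following state.  An episode still open at stream end is marked
    ``closed=False`` with the last sample time as its exit.
    """
    labels = oracle_labels(stream, layout)
    t = stream.t
    runs = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and labels[j + 1] == labels[i]:
            j += 1
        closed = j + 1 < n
        t_exit = t[j + 1] if closed else t[n - 1]
        runs.append((labels[i], float(t[i]), float(t_exit), closed))
        i = j + 1
    return runs


def engine_visits(events) -> list[tuple[int, float, float]]:
    """Pair an engine event list into (ordinal, t_enter, t_exit) visits."""
    visits = []
    open_ord = open_t = None
    for ev in events:
        if ev.kind == "enter":
            assert open_ord is None, "enter while a collision is open"
            open_ord, open_t = ev.ordinal, ev.t
        else:
            assert open_ord == ev.ordinal, "exit ordinal mismatches open enter"
            visits.append((ev.ordinal, open_t, ev.t))
            open_ord = open_t = None
    if open_ord is not None:
        visits.append((open_ord, open_t, None))
    return visits


def check_conservation(log, tol: float) -> None:
    """Per subtest, rest+transfer must tile first-enter..last-enter."""
    groups: dict[int, list] = {}
    # measured records tile the span up to each subtest's last enter;
    # reconstruct subtest membership from record order and the spans list
    idx = 0
    for span_i, (first_enter, last_enter, _last_exit) in enumerate(log.spans):
        total = 0.0
        while idx < len(log.records):
            rec = log.records[idx]
            idx += 1
            if "terminal" in rec.flags:
                break
            total += rec.rest_time + rec.transfer_time
        assert abs(total - (last_enter - first_enter)) <= tol, (
            f"subtest {span_i}: sum(rest+transfer)={total} vs "
            f"span={last_enter - first_enter}"
        )
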