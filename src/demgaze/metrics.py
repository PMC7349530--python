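"""Scalar DEM outcomes: measured time, adjusted time, rest/transfer summaries.

The classical DEM score corrects the raw reading time for reading errors:

    adjusted = measured * n / (n - o + a)

with ``n`` the number of characters in the test (80 for both the vertical
and the horizontal reading), ``o`` the characters omitted and ``a`` the
characters repeated or added.  Omitting characters shortens the raw time,
so the correction inflates it; additions deflate it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .events import TestLog

__all__ = ["TestResult", "adjusted_time", "measured_time", "summarize_log",
           "score_test", "MEASURED_TIME_CONVENTIONS"]

#: Supported endpoint rules for the raw reading time.  The recording offers
#: no voice onset, so the span is anchored on collision events:
#: ``first_entry_to_last_exit`` (default) runs from the first collision of
#: each subtest to the end of its last character's dwell;
#: ``stream_start_to_last_exit`` starts the first subtest's clock at the
#: first gaze sample instead (display onset).
MEASURED_TIME_CONVENTIONS = ("first_entry_to_last_exit",
                             "stream_start_to_last_exit")


@dataclass(frozen=True)
class TestResult:
    """Scored outcome of one DEM test run."""

    test_kind: str
    measured_time: float
    omissions: int
    additions: int
    adjusted_time: float
    mean_rest: float
    sd_rest: float
    mean_transfer: float
    sd_transfer: float
    n_records: int
    conventions: dict

    def to_dict(self) -> dict:
        return asdict(self)


def adjusted_time(measured: float, o: int, a: int, n_total: int = 80) -> float:
    """Error-corrected reading time ``measured * n_total / (n_total - o + a)``.

    ``n_total`` defaults to the 80 characters of the vertical/horizontal
    tests but is a parameter so shorter charts (the 9-digit pretest line)
    can be scored with their own length.
    """
    if measured <= 0:
        raise ValueError(f"measured time must be positive, got {measured}")
    if o < 0 or a < 0:
        raise ValueError(f"error counts must be non-negative, got o={o}, a={a}")
    denom = n_total - o + a
    if denom <= 0:
        raise ValueError(
            f"non-positive denominator {denom} (n={n_total}, o={o}, a={a})"
        )
    return measured * n_total / denom


def measured_time(log: TestLog, convention: str = "first_entry_to_last_exit"
                  ) -> float:
    """Raw reading time of a log, excluding the between-subtest gap.

    Per subtest the span runs to the last character's observed dwell end
    (``last_exit``); the start is its first collision, or the stream start
    for the first subtest under ``stream_start_to_last_exit``.
    """
    if convention not in MEASURED_TIME_CONVENTIONS:
        raise ValueError(f"unknown endpoint convention {convention!r}")
    if not log.spans:
        raise ValueError("log contains no visited characters")
    total = 0.0
    for i, (first_enter, _last_enter, last_exit) in enumerate(log.spans):
        start = first_enter
        if convention == "stream_start_to_last_exit" and i == 0:
            start = log.stream_span[0]
        total += last_exit - start
    return total


def summarize_log(log: TestLog) -> dict[str, float]:
    """Mean and sample SD (n-1) of the rest and transfer columns.

    Terminal "-" rows carry no durations and are ignored.
    """
    rest = np.array([r.rest_time for r in log.measured_records], dtype=float)
    transfer = np.array([r.transfer_time for r in log.measured_records],
                        dtype=float)
    if rest.size == 0:
        raise ValueError("log has no measured records to summarize")
    ddof = 1 if rest.size > 1 else 0
    return {
        "mean_rest": float(rest.mean()),
        "sd_rest": float(rest.std(ddof=ddof)),
        "mean_transfer": float(transfer.mean()),
        "sd_transfer": float(transfer.std(ddof=ddof)),
        "n_records": int(rest.size),
    }


def score_test(
    log: TestLog,
    o: int | None = None,
    a: int | None = None,
    n_total: int = 80,
    convention: str = "first_entry_to_last_exit",
) -> TestResult:
    """Assemble the full scored result for one test run.

    ``o`` and ``a`` are the examiner's (voice-based) error counts.  When
    omitted, the gaze-derived counts attached by ``align_log_to_chart`` are
    used instead and the provenance is recorded in the result's conventions.
    """
    error_source = "examiner"
    if o is None or a is None:
        if log.omissions is None or log.additions is None:
            raise ValueError(
                "no error counts given and log has no gaze-derived counts; "
                "run align_log_to_chart or pass o and a"
            )
        o, a = log.omissions, log.additions
        error_source = "gaze"
    measured = measured_time(log, convention)
    summary = summarize_log(log)
    return TestResult(
        test_kind=log.test_kind,
        measured_time=measured,
        omissions=o,
        additions=a,
        adjusted_time=adjusted_time(measured, o, a, n_total),
        conventions={
            "measured_time_endpoint": convention,
            "error_counts": error_source,
            "n_total": n_total,
            "collider_boundary": "inclusive",
        },
        **summary,
    )
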