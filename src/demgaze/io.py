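"""Readers/writers for every artifact the toolkit produces.

Formats
-------
chart JSON
    ``{"test_id", "plane_distance", "gap", "scale_factor", "targets":
    [{"ordinal", "digit", "cx", "cy", "half_extent"}, ...]}``.
gaze stream CSV
    header ``t,x,y`` (plane samples) or ``t,ox,oy,oz,dx,dy,dz`` (rays);
    lines starting with ``#`` carry metadata (seed, conventions).
interval log CSV
    the printed-log dialect: columns ``Serial No.``, ``Character No.``,
    ``Rest Time(s)``, ``Transfer Time(s)``; durations to 2 decimals,
    missing values as ``-`` (the terminal row of each subtest).  Full
    duration precision lives only in results JSON — the printed dialect
    rounds to 10 ms and must not feed statistics.
trail SVG
    collider rectangles, digits, and the gaze polyline.

Every writer embeds the producing seed/conventions as ``#`` header
comments or JSON metadata so outputs are self-describing.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .chart import CharTarget, ChartLayout, TEST_GRIDS
from .events import IntervalRecord, TestLog
from .geometry import GazeStream

__all__ = [
    "write_chart", "read_chart",
    "write_stream", "read_stream",
    "write_log", "read_log",
    "write_result",
    "render_trail",
    "table3_fixture_path",
    "LogParseError",
]

LOG_COLUMNS = ["Serial No.", "Character No.", "Rest Time(s)", "Transfer Time(s)"]


class LogParseError(ValueError):
    """Malformed interval-log file; message carries the line number."""


# ---------------------------------------------------------------- chart JSON

def write_chart(layout: ChartLayout, path: str | Path,
                metadata: dict | None = None) -> None:
    doc = {
        "test_id": layout.test_id,
        "plane_distance": layout.plane_distance,
        "gap": layout.gap,
        "scale_factor": layout.scale_factor,
        "rows": layout.rows,
        "cols": layout.cols,
        "reading_order": layout.reading_order,
        "targets": [
            {"ordinal": t.ordinal, "digit": t.digit,
             "cx": t.center[0], "cy": t.center[1],
             "half_extent": t.half_extent}
            for t in layout.targets
        ],
    }
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


def read_chart(path: str | Path) -> ChartLayout:
    doc = json.loads(Path(path).read_text())
    targets = tuple(
        CharTarget(ordinal=t["ordinal"], digit=t["digit"],
                   center=(t["cx"], t["cy"]), half_extent=t["half_extent"])
        for t in doc["targets"]
    )
    rows = doc.get("rows")
    cols = doc.get("cols")
    reading = doc.get("reading_order")
    if rows is None or cols is None or reading is None:
        grid = TEST_GRIDS.get(doc["test_id"], (1, len(targets), "row"))
        rows, cols, reading = grid
    return ChartLayout(
        test_id=doc["test_id"], targets=targets, rows=rows, cols=cols,
        reading_order=reading, plane_distance=doc["plane_distance"],
        gap=doc["gap"], scale_factor=doc.get("scale_factor", 12.0),
    )


# --------------------------------------------------------------- stream CSV

def write_stream(stream: GazeStream, path: str | Path,
                 metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df = pd.DataFrame({"t": stream.t, "x": stream.xy[:, 0],
                           "y": stream.xy[:, 1]})
        df.to_csv(fh, index=False, float_format="%.9g")


def read_stream(path: str | Path) -> GazeStream:
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    if cols[:3] == ["t", "x", "y"]:
        return GazeStream(t=df["t"].to_numpy(float),
                          xy=df[["x", "y"]].to_numpy(float))
    if cols == ["t", "ox", "oy", "oz", "dx", "dy", "dz"]:
        raise ValueError(
            "ray-format stream: project with geometry.project_rays first"
        )
    raise ValueError(f"unrecognized stream header {cols}")


def read_ray_stream(path: str | Path):
    """Read a ray-format stream; returns (t, origins, directions) arrays."""
    df = pd.read_csv(path, comment="#")
    need = ["t", "ox", "oy", "oz", "dx", "dy", "dz"]
    if list(df.columns) != need:
        raise ValueError(f"expected columns {need}, got {list(df.columns)}")
    return (df["t"].to_numpy(float),
            df[["ox", "oy", "oz"]].to_numpy(float),
            df[["dx", "dy", "dz"]].to_numpy(float))


# ------------------------------------------------------------------ log CSV

def _fmt_duration(value: float | None) -> str:
    return "-" if value is None else f"{value:.2f}"


def write_log(log: TestLog, path: str | Path,
              metadata: dict | None = None) -> None:
    """Emit the printed-log dialect; deterministic byte output."""
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        fh.write(",".join(LOG_COLUMNS) + "\n")
        for rec in log.records:
            fh.write(
                f"{rec.serial},{rec.digit},"
                f"{_fmt_duration(rec.rest_time)},"
                f"{_fmt_duration(rec.transfer_time)}\n"
            )


def read_log(path: str | Path, test_kind: str | None = None) -> TestLog:
    """Parse an interval-log CSV back into a :class:`TestLog`.

    The printed dialect records digits, not chart ordinals, so re-read
    records carry ``ordinal = serial`` as a positional stand-in.  Serial
    numbers must be strictly increasing (a shipped excerpt may have gaps).
    Round-trips with :func:`write_log` byte-exactly for canonical files.
    """
    records: list[IntervalRecord] = []
    last_serial = 0
    with open(path) as fh:
        lines = fh.readlines()
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if [c.strip() for c in line.split(",")] != LOG_COLUMNS:
                raise LogParseError(f"line {lineno}: unexpected header {line!r}")
            header_seen = True
            continue
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != 4:
            raise LogParseError(f"line {lineno}: expected 4 fields, got {len(parts)}")
        try:
            serial = int(parts[0])
            digit = int(parts[1])
            rest = None if parts[2] == "-" else float(parts[2])
            transfer = None if parts[3] == "-" else float(parts[3])
        except ValueError as exc:
            raise LogParseError(f"line {lineno}: {exc}") from None
        if serial <= last_serial:
            raise LogParseError(
                f"line {lineno}: serial {serial} not increasing (after {last_serial})"
            )
        last_serial = serial
        flags = {"terminal"} if rest is None and transfer is None else set()
        records.append(IntervalRecord(serial=serial, ordinal=serial,
                                      digit=digit, rest_time=rest,
                                      transfer_time=transfer, flags=flags))
    if not header_seen:
        raise LogParseError("file has no header row")
    if test_kind is None:
        test_kind = "vertical" if any(
            r.serial == 40 and "terminal" in r.flags for r in records
        ) else "horizontal"
    boundary = 40 if test_kind == "vertical" else None
    return TestLog(test_kind=test_kind, records=records,
                   subtest_boundary=boundary, stream_span=(0.0, 0.0))


def table3_fixture_path(test_kind: str) -> Path:
    """Path of the shipped sample-log excerpt.

    The excerpt comes from a recorded VR DEM session and covers serials
    1-5, 38-42 and 76-80 only; the elided middle rows are absent, so it is
    an excerpt, not a complete 80-row log.
    """
    from importlib.resources import files
    name = {"vertical": "sample_log_vertical.csv",
            "horizontal": "sample_log_horizontal.csv"}[test_kind]
    return Path(str(files("demgaze.data").joinpath(name)))


# -------------------------------------------------------------- results JSON

def write_result(result, path: str | Path, metadata: dict | None = None) -> None:
    doc = result.to_dict() if hasattr(result, "to_dict") else dict(result)
    if metadata:
        doc["metadata"] = metadata
    Path(path).write_text(json.dumps(doc, indent=1) + "\n")


# ---------------------------------------------------------------- trail SVG

def render_trail(stream: GazeStream, layout: ChartLayout, path: str | Path,
                 *, scale: float = 400.0, pad: float = 0.05) -> None:
    """Render the chart and gaze trajectory as an SVG file.

    Colliders are drawn as outlined squares with their digits, the gaze
    trace as a single polyline (one vertex per sample).  ``scale`` is
    pixels per meter; y is flipped so chart-up is screen-up.  An empty
    stream yields a chart-only image.
    """
    centers = layout.centers()
    half = layout.half_extents()
    xs = centers[:, 0]
    ys = centers[:, 1]
    x0, x1 = xs.min() - half.max() - pad, xs.max() + half.max() + pad
    y0, y1 = ys.min() - half.max() - pad, ys.max() + half.max() + pad
    if len(stream):
        finite = stream.xy[np.all(np.isfinite(stream.xy), axis=1)]
        if finite.size:
            x0 = min(x0, finite[:, 0].min() - pad)
            x1 = max(x1, finite[:, 0].max() + pad)
            y0 = min(y0, finite[:, 1].min() - pad)
            y1 = max(y1, finite[:, 1].max() + pad)
    width = (x1 - x0) * scale
    height = (y1 - y0) * scale

    def px(x: float) -> float:
        return (x - x0) * scale

    def py(y: float) -> float:
        return (y1 - y) * scale

    buf = _io.StringIO()
    buf.write(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width:.1f}" height="{height:.1f}" '
        f'viewBox="0 0 {width:.1f} {height:.1f}">\n'
    )
    if len(stream) == 0:
        buf.write("<!-- warning: empty gaze stream; chart only -->\n")
    for t in layout.targets:
        side = 2 * t.half_extent * scale
        buf.write(
            f'<rect x="{px(t.center[0] - t.half_extent):.2f}" '
            f'y="{py(t.center[1] + t.half_extent):.2f}" '
            f'width="{side:.2f}" height="{side:.2f}" '
            f'fill="none" stroke="black" stroke-width="1"/>\n'
        )
        buf.write(
            f'<text x="{px(t.center[0]):.2f}" y="{py(t.center[1]):.2f}" '
            f'font-size="{side * 0.7:.1f}" text-anchor="middle" '
            f'dominant-baseline="central">{t.digit}</text>\n'
        )
    if len(stream):
        pts = " ".join(
            f"{px(x):.2f},{py(y):.2f}" for x, y in stream.xy
            if np.isfinite(x) and np.isfinite(y)
        )
        buf.write(
            f'<polyline points="{pts}" fill="none" stroke="crimson" '
            f'stroke-width="1" stroke-opacity="0.7"/>\n'
        )
    buf.write("</svg>\n")
    Path(path).write_text(buf.getvalue())
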