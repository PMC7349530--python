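"""DEM chart layouts: character targets with square colliders on a viewing plane.

The test presents digit characters on a plane fixed 0.50 m (2 diopters) in
front of the eyes.  Each character carries an axis-aligned square collider of
side 0.04 m; adjacent colliders are separated by a 0.06 m edge-to-edge gap,
giving a 0.10 m center-to-center pitch.  The vertical test reads two 40-digit
subtests (A then B) in columns, top to bottom; the horizontal test (C) reads
80 digits in rows, left to right.  The pretest is a single line of the digits
1-9.

The chart frame is head-fixed, so head pose never enters the geometry: the
plane origin sits at the chart center, x points right, y points up, and all
lengths are meters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CharTarget",
    "ChartLayout",
    "build_chart",
    "validate_layout",
    "TEST_GRIDS",
    "COLLIDER_HALF_EXTENT",
    "COLLIDER_GAP",
    "PLANE_DISTANCE",
    "SCALE_FACTOR",
]

COLLIDER_HALF_EXTENT = 0.02  # half of the 0.04 m collider side
COLLIDER_GAP = 0.06          # edge-to-edge spacing between adjacent colliders
PLANE_DISTANCE = 0.50        # 2-diopter viewing distance
SCALE_FACTOR = 12.0          # enlargement relative to the printed booklet

# (rows, cols, reading order).  "column" = top-to-bottom then next column,
# "row" = left-to-right then next row.  The printed booklet never states the
# grid; these shapes reproduce the standard DEM card counts (40/40/80) and
# are configuration, not physics.
TEST_GRIDS: dict[str, tuple[int, int, str]] = {
    "pretest": (1, 9, "row"),
    "A": (20, 2, "column"),
    "B": (20, 2, "column"),
    "vertical": (20, 4, "column"),  # Tests A and B side by side, read A then B
    "C": (16, 5, "row"),
}


class ChartError(ValueError):
    """Invalid chart specification (unknown test id, bad digits)."""


@dataclass(frozen=True)
class CharTarget:
    """One digit character and its collider square.

    ``ordinal`` is the 1-based position in reading order, ``center`` the
    collider center on the chart plane in meters, ``half_extent`` half the
    collider side length.
    """

    ordinal: int
    digit: int
    center: tuple[float, float]
    half_extent: float = COLLIDER_HALF_EXTENT

    def contains(self, x: float, y: float) -> bool:
        """Boundary-inclusive point-in-collider test."""
        return (
            abs(x - self.center[0]) <= self.half_extent
            and abs(y - self.center[1]) <= self.half_extent
        )


@dataclass(frozen=True)
class ChartLayout:
    """An ordered set of character targets on the viewing plane."""

    test_id: str
    targets: tuple[CharTarget, ...]
    rows: int
    cols: int
    reading_order: str  # "column" | "row"
    plane_distance: float = PLANE_DISTANCE
    gap: float = COLLIDER_GAP
    scale_factor: float = SCALE_FACTOR

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @property
    def pitch(self) -> float:
        """Center-to-center spacing of adjacent colliders."""
        return 2 * self.targets[0].half_extent + self.gap

    @property
    def subtest_boundary(self) -> int | None:
        """Ordinal after which the vertical test's timers reset (A -> B)."""
        return 40 if self.test_id == "vertical" else None

    @property
    def digits(self) -> tuple[int, ...]:
        return tuple(t.digit for t in self.targets)

    def centers(self) -> np.ndarray:
        """(n, 2) array of collider centers in reading order."""
        return np.array([t.center for t in self.targets], dtype=float)

    def half_extents(self) -> np.ndarray:
        return np.array([t.half_extent for t in self.targets], dtype=float)


def _grid_positions(rows: int, cols: int, pitch: float, reading_order: str
                    ) -> list[tuple[float, float]]:
    """Collider centers in reading order, grid centered on the origin."""
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    ys = ((rows - 1) / 2.0 - np.arange(rows)) * pitch  # row 0 at the top
    if reading_order == "column":
        return [(float(xs[c]), float(ys[r])) for c in range(cols) for r in range(rows)]
    return [(float(xs[c]), float(ys[r])) for r in range(rows) for c in range(cols)]


def build_chart(
    test_id: str,
    *,
    digits: list[int] | None = None,
    seed: int | None = None,
    plane_distance: float = PLANE_DISTANCE,
    gap: float = COLLIDER_GAP,
    half_extent: float = COLLIDER_HALF_EXTENT,
) -> ChartLayout:
    """Build a DEM chart layout.

    Digits default to a seeded uniform draw from 1-9 (the commercial digit
    sequences are proprietary); pass ``digits`` explicitly to reproduce a
    known chart.  The pretest defaults to a seeded permutation of 1-9.
    Deterministic for a fixed seed.

    Parameters
    ----------
    test_id
        One of ``pretest``, ``A``, ``B``, ``C`` or ``vertical`` (Tests A and
        B combined into the single 80-character vertical reading).
    digits
        Explicit digit list whose length must match the test size.
    seed
        Seed for the digit draw when ``digits`` is not given.
    """
    if test_id not in TEST_GRIDS:
        raise ChartError(
            f"unknown test_id {test_id!r}; expected one of {sorted(TEST_GRIDS)}"
        )
    rows, cols, reading_order = TEST_GRIDS[test_id]
    n = rows * cols

    if digits is None:
        rng = np.random.default_rng(seed)
        if test_id == "pretest":
            digits = [int(d) for d in rng.permutation(np.arange(1, 10))]
        else:
            digits = [int(d) for d in rng.integers(1, 10, size=n)]
    else:
        digits = [int(d) for d in digits]
        if len(digits) != n:
            raise ChartError(
                f"test {test_id!r} needs {n} digits, got {len(digits)}"
            )
    bad = [d for d in digits if not 1 <= d <= 9]
    if bad:
        raise ChartError(f"digits must lie in 1..9, got {sorted(set(bad))}")

    pitch = 2 * half_extent + gap
    centers = _grid_positions(rows, cols, pitch, reading_order)
    targets = tuple(
        CharTarget(ordinal=i + 1, digit=digits[i], center=centers[i],
                   half_extent=half_extent)
        for i in range(n)
    )
    return ChartLayout(
        test_id=test_id,
        targets=targets,
        rows=rows,
        cols=cols,
        reading_order=reading_order,
        plane_distance=plane_distance,
        gap=gap,
    )


def validate_layout(layout: ChartLayout, *, tol: float = 1e-9) -> list[str]:
    """Check a layout against the structural invariants; return violations.

    Reports (never raises) one message per violated rule: target count,
    digit range, ordinal numbering, adjacent-collider spacing, collider
    overlap and plane distance.  An empty list means the layout is valid.
    """
    problems: list[str] = []
    grid = TEST_GRIDS.get(layout.test_id)
    if grid is not None:
        expected = grid[0] * grid[1]
        if layout.n_targets != expected:
            problems.append(
                f"target count {layout.n_targets} != expected {expected} "
                f"for test {layout.test_id!r}"
            )
    if layout.plane_distance <= 0:
        problems.append(f"plane_distance {layout.plane_distance} must be > 0")

    ordinals = [t.ordinal for t in layout.targets]
    if ordinals != list(range(1, layout.n_targets + 1)):
        problems.append("ordinals are not consecutive from 1")
    for t in layout.targets:
        if not 1 <= t.digit <= 9:
            problems.append(f"ordinal {t.ordinal}: digit {t.digit} outside 1..9")
        if t.half_extent <= 0:
            problems.append(f"ordinal {t.ordinal}: non-positive half_extent")

    # Pairwise checks: overlap everywhere, gap between grid neighbours.
    pitch = 2 * layout.targets[0].half_extent + layout.gap if layout.targets else 0.0
    for i, a in enumerate(layout.targets):
        for b in layout.targets[i + 1:]:
            dx = abs(a.center[0] - b.center[0])
            dy = abs(a.center[1] - b.center[1])
            sum_h = a.half_extent + b.half_extent
            if dx < sum_h - tol and dy < sum_h - tol:
                problems.append(
                    f"colliders {a.ordinal} and {b.ordinal} overlap"
                )
            # grid neighbours: aligned on one axis, one pitch apart on the other
            aligned_x = dx <= tol and abs(dy - pitch) <= pitch / 2
            aligned_y = dy <= tol and abs(dx - pitch) <= pitch / 2
            if aligned_x or aligned_y:
                edge = (dx + dy) - sum_h  # one of dx, dy is ~0
                if abs(edge - layout.gap) > tol:
                    problems.append(
                        f"edge gap between {a.ordinal} and {b.ordinal} is "
                        f"{edge:.6f} m, expected {layout.gap:.6f} m"
                    )
    return problems


def with_gap(layout: ChartLayout, gap: float) -> ChartLayout:
    """Return a copy of ``layout`` declaring a different nominal gap.

    Positions are unchanged; useful for constructing deliberately invalid
    layouts when exercising :func:`validate_layout`.
    """
    return replace(layout, gap=gap)
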