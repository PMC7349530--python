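"""Synthetic gaze streams: a subject reading a DEM chart.

The simulator stands in for the eye-tracking headset.  It plans a
fixation–saccade scanpath over a chart (gamma-distributed dwells on each
character, main-sequence saccade durations between them, optional omission
and revisit reading errors), then renders the plan to a sampled gaze
stream with isotropic Gaussian tracker noise, returning the ground-truth
schedule alongside for parameter-recovery testing.

Default dwell means come from the reported group averages of the VR
reading task: 0.19 s per character on the vertical test and 0.12 s on the
horizontal test, at the tracker's 60 Hz frame rate.

Saccade paths between grid-adjacent characters are straight.  Return
sweeps and other long jumps are routed through the blank corridors between
collider rows/columns (an axis-aligned detour staying >= half a gap away
from every collider), so that an error-free reading touches exactly the
planned characters — a straight 1.9 m return sweep would otherwise graze
colliders near its slow endpoints and register spurious collisions that no
attentive reader produces.  Real return sweeps are curved; the corridor
polyline is the simplest collision-faithful stand-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .chart import ChartLayout
from .geometry import GazeStream

__all__ = [
    "SimulationConfig",
    "Fixation",
    "FixationSchedule",
    "plan_scanpath",
    "render_stream",
    "simulate",
    "saccade_path",
    "saccade_duration",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic reader and tracker.

    ``dwell_mean_v``/``dwell_mean_h`` are mean per-character dwell times
    (s) — the time the gaze spends on a character, i.e. inside its
    collider — for column-wise and row-wise charts; dwells are drawn from
    a gamma distribution with shape ``dwell_shape`` (right-skewed,
    positive, as fixation durations are), or are exactly the mean when
    ``dwell_shape`` is ``None``.  Saccade durations follow the
    main-sequence rule ``intercept + slope * amplitude_deg``.
    ``noise_sigma`` is isotropic tracker noise on the chart plane in
    meters; the default 2 mm corresponds to the ~0.25 deg RMS precision
    typical of consumer VR eye trackers at the 0.5 m viewing distance and
    is a tenth of the collider half-side, so a fixated character is never
    lost to jitter.  ``p_omit``/``p_revisit`` inject per-character reading
    errors.
    """

    sample_rate: float = 60.0
    dwell_mean_v: float = 0.19
    dwell_mean_h: float = 0.12
    dwell_shape: float | None = 8.0  # None: deterministic dwell = mean
    saccade_intercept: float = 0.021    # s
    saccade_slope: float = 0.0022       # s per degree of amplitude
    noise_sigma: float = 0.002          # m on the chart plane
    p_omit: float = 0.0
    p_revisit: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.dwell_mean_v <= 0 or self.dwell_mean_h <= 0:
            raise ValueError("dwell means must be positive")
        if self.dwell_shape is not None and self.dwell_shape <= 0:
            raise ValueError("dwell_shape must be positive (or None)")
        for p in (self.p_omit, self.p_revisit):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def dwell_mean_for(self, layout: ChartLayout) -> float:
        return (self.dwell_mean_v if layout.reading_order == "column"
                else self.dwell_mean_h)

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class Fixation:
    ordinal: int
    t_on: float
    t_off: float


@dataclass(frozen=True)
class FixationSchedule:
    """Ground-truth scanpath: planned fixations plus injected errors."""

    fixations: tuple[Fixation, ...]
    omitted: tuple[int, ...]    # ordinals skipped
    n_revisits: int             # extra fixations on already-read characters
    layout_test_id: str

    @property
    def span(self) -> float:
        return self.fixations[-1].t_off if self.fixations else 0.0

    @property
    def visited_ordinals(self) -> tuple[int, ...]:
        return tuple(f.ordinal for f in self.fixations)


def saccade_duration(amplitude_deg: float, config: SimulationConfig) -> float:
    """Main-sequence saccade duration: linear in angular amplitude."""
    return config.saccade_intercept + config.saccade_slope * amplitude_deg


def _amplitude_deg(p: np.ndarray, q: np.ndarray, plane_distance: float) -> float:
    """Angular separation of two chart-plane points as seen from the eye."""
    a = np.array([p[0], p[1], plane_distance])
    b = np.array([q[0], q[1], plane_distance])
    cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return math.degrees(math.acos(min(1.0, max(-1.0, cos))))


def saccade_path(layout: ChartLayout, src: int, dst: int) -> np.ndarray:
    """Waypoints of the gaze path from target ``src`` to target ``dst``.

    Grid-adjacent targets (one pitch apart along one axis) get a straight
    segment.  Any other jump is routed through the inter-collider
    corridors: exit the source row vertically by half a pitch, travel the
    horizontal corridor, descend the vertical corridor adjacent to the
    destination column, and enter the destination from the side.  Every
    corridor line is ``gap/2 + half_extent`` away from the nearest collider
    center, so the path clears all colliders except source and destination.
    """
    centers = layout.centers()
    p = centers[src - 1]
    q = centers[dst - 1]
    pitch = layout.pitch
    dx, dy = q[0] - p[0], q[1] - p[1]
    tol = 1e-9
    straight = (
        (abs(dx) <= tol and abs(abs(dy) - pitch) <= tol)
        or (abs(dy) <= tol and abs(abs(dx) - pitch) <= tol)
    )
    if straight or (abs(dx) <= tol and abs(dy) <= tol):
        return np.array([p, q])

    half = pitch / 2.0
    gy = p[1] - half if q[1] <= p[1] else p[1] + half   # horizontal corridor
    gx = q[0] - half if p[0] <= q[0] else q[0] + half   # vertical corridor
    waypoints = [
        (p[0], p[1]),
        (p[0], gy),
        (gx, gy),
        (gx, q[1]),
        (q[0], q[1]),
    ]
    # drop zero-length segments (e.g. source already on the corridor line)
    out = [waypoints[0]]
    for w in waypoints[1:]:
        if abs(w[0] - out[-1][0]) > tol or abs(w[1] - out[-1][1]) > tol:
            out.append(w)
    return np.array(out)


def _path_length(path: np.ndarray) -> float:
    return float(np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)))


def plan_scanpath(layout: ChartLayout, config: SimulationConfig
                  ) -> FixationSchedule:
    """Plan the reading scanpath with dwell times and injected errors.

    Characters are visited in reading order; each is skipped with
    probability ``p_omit``; after reading a character, with probability
    ``p_revisit`` the gaze returns to a uniformly chosen earlier character
    before continuing.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    mean = config.dwell_mean_for(layout)
    shape = config.dwell_shape
    scale = mean / shape if shape is not None else None

    sequence: list[int] = []
    omitted: list[int] = []
    n_revisits = 0
    for tgt in layout.targets:
        if rng.random() < config.p_omit:
            omitted.append(tgt.ordinal)
            continue
        sequence.append(tgt.ordinal)
        if sequence[:-1] and rng.random() < config.p_revisit:
            # glance back at an earlier character, then read on
            back = int(rng.choice(sequence[:-1]))
            sequence.append(back)
            n_revisits += 1

    centers = layout.centers()
    fixations: list[Fixation] = []
    t = 0.0
    for i, ordinal in enumerate(sequence):
        dwell = mean if shape is None else float(rng.gamma(shape, scale))
        fixations.append(Fixation(ordinal, t, t + dwell))
        t += dwell
        if i + 1 < len(sequence):
            amp = _amplitude_deg(centers[ordinal - 1],
                                 centers[sequence[i + 1] - 1],
                                 layout.plane_distance)
            t += saccade_duration(amp, config)
    return FixationSchedule(
        fixations=tuple(fixations),
        omitted=tuple(omitted),
        n_revisits=n_revisits,
        layout_test_id=layout.test_id,
    )


def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Smooth 0->1 position profile with zero end velocities."""
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u * u)


#: Clearance (m) kept between saccade samples and the collider boundaries
#: they depart from / arrive at: 5 sigma of the default tracker noise, so
#: jitter cannot flip a traveling sample back inside a collider.
SACCADE_CLEARANCE = 0.01


def _clip_path(path: np.ndarray, p: np.ndarray, rp: float,
               q: np.ndarray, rq: float, n_fine: int = 2048) -> np.ndarray:
    """Sub-path of ``path`` outside the squares of Chebyshev radius ``rp``
    around ``p`` (start) and ``rq`` around ``q`` (end).

    The planned dwell covers the whole in-collider interval, so the
    rendered saccade must travel only between the (margin-expanded)
    collider boundaries.  Clipping is done on a dense resampling of the
    polyline; sub-millimeter accuracy is ample since ``rp``/``rq``
    already include the clearance margin.
    """
    fractions = np.linspace(0.0, 1.0, n_fine)
    pts = _points_along(path, fractions)
    out_p = np.max(np.abs(pts - p), axis=1) > rp
    out_q = np.max(np.abs(pts - q), axis=1) > rq
    i0 = int(np.argmax(out_p)) if out_p.any() else 0
    j1 = n_fine - 1 - int(np.argmax(out_q[::-1])) if out_q.any() else n_fine - 1
    if j1 <= i0:  # targets so close the margins meet; keep the midpoint
        mid = (i0 + j1) // 2
        return pts[mid:mid + 1]
    return pts[i0:j1 + 1]


def _points_along(path: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Points at given arc-length fractions along a polyline."""
    seg = np.diff(path, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if total == 0:
        return np.repeat(path[:1], fractions.size, axis=0)
    s = np.clip(fractions, 0.0, 1.0) * total
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    local = (s - cum[idx]) / np.where(seg_len[idx] > 0, seg_len[idx], 1.0)
    return path[idx] + seg[idx] * local[:, None]


def render_stream(schedule: FixationSchedule, layout: ChartLayout,
                  config: SimulationConfig) -> GazeStream:
    """Sample the planned scanpath into a noisy gaze stream.

    Samples land on the uniform grid ``k / sample_rate``.  During a
    fixation interval the gaze sits at the target center; the schedule's
    dwell is the full in-collider time, so the saccade interval between
    two fixations renders only the out-of-collider traversal: the
    (possibly corridor-routed) path clipped at a :data:`SACCADE_CLEARANCE`
    margin outside the source and destination colliders, traversed with a
    minimum-jerk speed profile.  Isotropic Gaussian noise is added
    throughout.  The noise stream is seeded from the config seed, offset
    so it is independent of the planning draws.
    """
    if not schedule.fixations:
        return GazeStream(t=np.zeros(0), xy=np.zeros((0, 2)))
    fs = config.sample_rate
    span = schedule.span
    n = int(math.ceil(span * fs))
    t = np.arange(n) / fs
    xy = np.empty((n, 2))

    centers = layout.centers()
    half = layout.half_extents()
    fixations = schedule.fixations
    for i, fx in enumerate(fixations):
        mask = (t >= fx.t_on) & (t < fx.t_off)
        xy[mask] = centers[fx.ordinal - 1]
        if i + 1 < len(fixations):
            nxt = fixations[i + 1]
            smask = (t >= fx.t_off) & (t < nxt.t_on)
            if smask.any():
                path = saccade_path(layout, fx.ordinal, nxt.ordinal)
                p, q = centers[fx.ordinal - 1], centers[nxt.ordinal - 1]
                clipped = _clip_path(
                    path, p, half[fx.ordinal - 1] + SACCADE_CLEARANCE,
                    q, half[nxt.ordinal - 1] + SACCADE_CLEARANCE,
                )
                u = (t[smask] - fx.t_off) / (nxt.t_on - fx.t_off)
                xy[smask] = _points_along(clipped, _min_jerk(u))
    # samples beyond the last fixation offset cannot occur: span = last t_off
    noise_rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, 0x6E]))
    if config.noise_sigma > 0:
        xy = xy + noise_rng.normal(0.0, config.noise_sigma, size=xy.shape)
    return GazeStream(t=t, xy=xy)


def simulate(layout: ChartLayout, config: SimulationConfig
             ) -> tuple[GazeStream, FixationSchedule]:
    """Plan and render one reading; returns (stream, ground truth)."""
    schedule = plan_scanpath(layout, config)
    stream = render_stream(schedule, layout, config)
    return stream, schedule
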