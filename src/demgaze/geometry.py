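"""Gaze-ray projection and gaze-point calibration.

The eye tracker reports a gaze direction in a head-fixed frame (x right,
y up, z toward the chart).  The estimated gaze point is the crossing of
that ray with the chart plane ``z = plane_distance``.  Raw gaze points are
then corrected by an affine map fitted to a small set of calibration
targets — by default the six-point protocol, which overdetermines the six
affine coefficients and provides the redundancy that makes the fit robust
to single-point noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GazeRay",
    "GazeStream",
    "CalibrationModel",
    "project_ray",
    "project_rays",
    "fit_calibration",
    "apply_calibration",
    "default_calibration_targets",
    "NoIntersectionError",
    "DegenerateFitError",
]


class NoIntersectionError(ValueError):
    """The gaze ray does not cross the chart plane in front of the eye."""


class DegenerateFitError(ValueError):
    """Too few or collinear calibration points: the affine fit is singular."""


@dataclass(frozen=True)
class GazeRay:
    """A timestamped gaze ray: origin and unit direction in the head frame."""

    t: float
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]

    def __post_init__(self):
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction must be unit length, |d| = {n}")


@dataclass(frozen=True)
class GazeStream:
    """Timestamped gaze points on the chart plane.

    ``t`` is an (n,) array of seconds, non-decreasing; ``xy`` an (n, 2)
    array of plane coordinates in meters.  NaN coordinates mark tracker
    dropout (blinks, lost pupil) and are treated as "outside every
    collider" downstream.
    """

    t: np.ndarray
    xy: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        xy = np.asarray(self.xy, dtype=float)
        if t.ndim != 1 or xy.shape != (t.size, 2):
            raise ValueError("t must be (n,), xy must be (n, 2)")
        if t.size and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "xy", xy)

    def __len__(self) -> int:
        return self.t.size


def project_ray(ray: GazeRay, plane_distance: float) -> tuple[float, float]:
    """Intersect a gaze ray with the chart plane ``z = plane_distance``.

    Returns the (x, y) gaze point in chart-plane coordinates.  Raises
    :class:`NoIntersectionError` when the ray is parallel to the plane or
    points away from it.
    """
    ox, oy, oz = ray.origin
    dx, dy, dz = ray.direction
    if dz <= 0:
        raise NoIntersectionError(
            "gaze ray is parallel to or pointing away from the chart plane"
        )
    s = (plane_distance - oz) / dz
    if s < 0:
        raise NoIntersectionError("chart plane lies behind the ray origin")
    return (ox + s * dx, oy + s * dy)


def project_rays(
    t: np.ndarray, origins: np.ndarray, directions: np.ndarray,
    plane_distance: float,
) -> GazeStream:
    """Vectorized ray-plane crossing for a whole recording.

    Rays that cannot reach the plane (``dz <= 0`` or plane behind origin)
    become NaN samples, mirroring tracker dropout.
    """
    t = np.asarray(t, dtype=float)
    origins = np.asarray(origins, dtype=float).reshape(-1, 3)
    directions = np.asarray(directions, dtype=float).reshape(-1, 3)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (plane_distance - origins[:, 2]) / directions[:, 2]
    bad = (directions[:, 2] <= 0) | (s < 0)
    xy = origins[:, :2] + s[:, None] * directions[:, :2]
    xy[bad] = np.nan
    return GazeStream(t=t, xy=xy)


@dataclass(frozen=True)
class CalibrationModel:
    """Affine correction ``corrected = A @ raw + b`` on the chart plane."""

    linear: np.ndarray   # (2, 2)
    offset: np.ndarray   # (2,)
    residual_rms: float  # meters, over the fitting points

    def __post_init__(self):
        A = np.asarray(self.linear, dtype=float).reshape(2, 2)
        b = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-12:
            raise ValueError("calibration linear part must be invertible")
        if self.residual_rms < 0:
            raise ValueError("residual RMS must be non-negative")
        object.__setattr__(self, "linear", A)
        object.__setattr__(self, "offset", b)

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls(linear=np.eye(2), offset=np.zeros(2), residual_rms=0.0)


def default_calibration_targets(
    half_width: float = 0.15, half_height: float = 0.15
) -> np.ndarray:
    """Six calibration target positions on a 3 x 2 grid spanning the chart.

    The tracking protocol fixes the number of points at six but not their
    placement; a symmetric grid over the chart extent is used here.
    """
    xs = np.array([-half_width, 0.0, half_width])
    ys = np.array([-half_height, half_height])
    return np.array([(x, y) for y in ys for x in xs])


def fit_calibration(raw_points: np.ndarray, reference_points: np.ndarray
                    ) -> CalibrationModel:
    """Least-squares affine map taking raw gaze points to their true targets.

    Needs at least three non-collinear point pairs; the default protocol
    supplies six, so the six affine coefficients are overdetermined and the
    residual RMS reports the leftover tracker error.
    """
    raw = np.asarray(raw_points, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference_points, dtype=float).reshape(-1, 2)
    if raw.shape != ref.shape:
        raise ValueError("raw and reference point sets differ in shape")
    n = raw.shape[0]
    if n < 3:
        raise DegenerateFitError(f"need >= 3 point pairs, got {n}")
    design = np.column_stack([raw, np.ones(n)])  # (n, 3)
    if np.linalg.matrix_rank(design) < 3:
        raise DegenerateFitError("calibration points are collinear")
    coeffs, *_ = np.linalg.lstsq(design, ref, rcond=None)  # (3, 2)
    linear = coeffs[:2].T
    offset = coeffs[2]
    fitted = design @ coeffs
    rms = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return CalibrationModel(linear=linear, offset=offset, residual_rms=rms)


def apply_calibration(model: CalibrationModel, stream: GazeStream) -> GazeStream:
    """Affinely correct every sample; timestamps and count are unchanged."""
    xy = stream.xy @ model.linear.T + model.offset
    return GazeStream(t=stream.t.copy(), xy=xy)
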