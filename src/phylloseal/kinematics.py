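"""Bending-angle kinematics from tracked leaf points.

Wound self-sealing of a succulent leaf is scored from three points tracked
in every video frame: point 1 near the leaf base, point 2 next to the
injury, point 3 at the leaf tip.  With point 2 as the local origin, the
base line (2 -> 1) makes an angle ``alpha`` with the horizontal and the tip
line (2 -> 3) an angle ``beta``.  Subtracting the base motion gives the
actual bending angle ``delta = beta - alpha``; referencing it to the
pre-injury frame gives the relative bending angle ``gamma_n = delta_n -
delta_0``, the self-sealing metric.  Positive ``gamma`` means the wound is
closing, negative that it is opening.

Angles are *line* angles (mod 180 deg, reported in (-90, 90]) rather than
ray angles: the metric is then invariant under rigid motion and uniform
scaling of the whole point configuration as long as no single-frame jump
reaches 90 deg, which is checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TrackSeries",
    "AngleSeries",
    "DegenerateGeometryError",
    "frame_angles",
    "actual_bending",
    "relative_bending",
    "angle_series",
    "sample_at_times",
]


class DegenerateGeometryError(ValueError):
    """Raised when tracked points coincide and no line angle exists."""


def _wrap_line_angle(theta_deg):
    """Map an angle in degrees to the line-angle range (-90, 90]."""
    w = np.mod(np.asarray(theta_deg, dtype=float) + 90.0, 180.0) - 90.0
    # mod gives [-90, 90); move the -90 edge to +90 so the range is (-90, 90]
    w = np.where(w <= -90.0, w + 180.0, w)
    return w if w.ndim else float(w)


@dataclass(frozen=True)
class TrackSeries:
    """Tracked coordinates of the three labelled leaf points.

    Parameters
    ----------
    times : (n,) array
        Frame times in seconds, strictly increasing.  Frame 0 is the
        pre-injury reference image.
    points : (n, 3, 2) array
        ``points[i, k]`` is the (x, y) position of point ``k + 1`` in frame
        ``i``.  Point order is base (1), injury (2), tip (3).
    units : str
        Coordinate units, ``"px"`` or ``"mm"``; angles do not depend on it.
    y_down : bool
        If True the coordinates use an image convention (y grows downward);
        angles are computed after mirroring so that the sign convention of
        ``gamma`` matches the y-up mathematical frame.
    """

    times: np.ndarray
    points: np.ndarray
    units: str = "px"
    y_down: bool = False
    label: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        points = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "points", points)
        if times.ndim != 1 or points.shape != (times.size, 3, 2):
            raise ValueError(
                f"track shape mismatch: times {times.shape}, points {points.shape}"
            )
        if times.size < 1:
            raise ValueError("track must contain at least the pre-injury frame")
        if not np.all(np.isfinite(times)) or not np.all(np.isfinite(points)):
            raise ValueError("non-finite values in track")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        for k in (0, 2):
            if np.any(np.all(points[:, k] == points[:, 1], axis=1)):
                bad = int(
                    np.nonzero(np.all(points[:, k] == points[:, 1], axis=1))[0][0]
                )
                raise DegenerateGeometryError(
                    f"point {k + 1} coincides with point 2 in frame {bad}"
                )

    @property
    def n_frames(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class AngleSeries:
    """Per-frame angles derived from a :class:`TrackSeries` (degrees)."""

    times: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    delta: np.ndarray
    gamma: np.ndarray
    label: str = ""

    def __post_init__(self):
        for name in ("times", "alpha", "beta", "delta", "gamma"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        n = self.times.size
        if not all(getattr(self, a).shape == (n,) for a in ("alpha", "beta", "delta", "gamma")):
            raise ValueError("angle arrays must share the time grid")
        if not np.all(np.isfinite(self.gamma)):
            raise ValueError("non-finite angles")
        if abs(self.gamma[0]) > 1e-12:
            raise ValueError("gamma must be exactly 0 in the pre-injury frame")


def frame_angles(p1, p2, p3):
    """Base and tip line angles ``(alpha, beta)`` of one frame, in degrees.

    ``alpha`` is the orientation of the undirected line through point 2 and
    point 1 relative to the horizontal, mapped to (-90, 90]; ``beta``
    likewise for the line through point 2 and point 3.  Point 2 acts as the
    coordinate origin.
    """
    p1 = np.asarray(p1, float)
    p2 = np.asarray(p2, float)
    p3 = np.asarray(p3, float)
    if np.array_equal(p1, p2) or np.array_equal(p3, p2):
        raise DegenerateGeometryError("tracked points coincide with point 2")
    v1 = p1 - p2
    v3 = p3 - p2
    alpha = _wrap_line_angle(np.degrees(np.arctan2(v1[1], v1[0])))
    beta = _wrap_line_angle(np.degrees(np.arctan2(v3[1], v3[0])))
    return alpha, beta


def actual_bending(alpha, beta):
    """Actual bending angle ``delta = beta - alpha``, wrapped to (-90, 90].

    Invariant under rigid motion of the whole configuration because both
    line angles shift by the rotation angle (mod 180 deg).
    """
    return _wrap_line_angle(np.asarray(beta, float) - np.asarray(alpha, float))


def relative_bending(delta):
    """Relative bending angle ``gamma_n = delta_n - delta_0`` per frame.

    Frame 0 must be the pre-injury reference, so ``gamma[0] == 0``.
    """
    delta = np.asarray(delta, dtype=float)
    if delta.size == 0:
        raise ValueError("missing pre-injury reference frame")
    return delta - delta[0]


def angle_series(track: TrackSeries, max_step_deg: float = 45.0) -> AngleSeries:
    """Full angle pipeline for one track: alpha, beta, delta, gamma.

    ``max_step_deg`` guards the (-90, 90] line-angle wrap: the mod-180
    convention is unambiguous only while the bending angle moves by less
    than 90 deg per frame, and a true jump past 90 deg aliases onto a
    small one.  Steps at or above the threshold (default 45 deg, half the
    ambiguity bound; generous for 30-s frame intervals) therefore raise.
    """
    pts = track.points.copy()
    if track.y_down:
        pts[:, :, 1] = -pts[:, :, 1]
    v1 = pts[:, 0] - pts[:, 1]
    v3 = pts[:, 2] - pts[:, 1]
    alpha = _wrap_line_angle(np.degrees(np.arctan2(v1[:, 1], v1[:, 0])))
    beta = _wrap_line_angle(np.degrees(np.arctan2(v3[:, 1], v3[:, 0])))
    delta = _wrap_line_angle(beta - alpha)
    step = np.abs(np.diff(delta))
    step = np.minimum(step, 180.0 - step)  # distance on the line-angle circle
    if np.any(step >= max_step_deg):
        bad = int(np.argmax(step >= max_step_deg)) + 1
        raise ValueError(
            f"bending angle jumps by >= {max_step_deg} deg into frame {bad}; "
            "line-angle wrap is ambiguous"
        )
    gamma = relative_bending(delta)
    return AngleSeries(track.times, alpha, beta, delta, gamma, label=track.label)


def sample_at_times(series: AngleSeries, times_min, frame_interval_s: float | None = None):
    """Gamma at the requested evaluation times (minutes), nearest frame.

    Ties between two equally distant frames go to the earlier frame.  A
    requested time farther than half a frame interval from every frame is
    outside coverage and raises.

    Returns
    -------
    (times_min, frame_times_s, gamma) arrays; ``frame_times_s`` reports the
    frame actually used for each request.
    """
    req = np.atleast_1d(np.asarray(times_min, dtype=float)) * 60.0
    ft = series.times
    if frame_interval_s is None:
        frame_interval_s = float(np.median(np.diff(ft))) if ft.size > 1 else np.inf
    dist = np.abs(req[:, None] - ft[None, :])
    idx = np.argmin(dist, axis=1)  # argmin takes the first (earlier) on ties
    best = dist[np.arange(req.size), idx]
    if np.any(best > frame_interval_s / 2.0 + 1e-9):
        bad = req[np.argmax(best > frame_interval_s / 2.0 + 1e-9)] / 60.0
        raise ValueError(f"requested time {bad:g} min outside track coverage")
    return (
        np.asarray(times_min, dtype=float),
        ft[idx],
        series.gamma[idx],
    )
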