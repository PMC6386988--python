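"""Gesture-to-stage control and trajectory-tracking error metrics.

The operator's hand is tracked relative to the gesture-sensor center.  While
the hand stays inside a neutral sphere of radius rho0 (default 50 mm) the
stage holds position; outside it, the stage moves along the horizontal
projection of the hand displacement at a speed proportional to the excess
distance rho - rho0, clamped at ``max_speed``.

Tracking performance is scored by extracting a compact boundary around the
executed planar path and comparing its enclosed area with the target
trajectory's area: error rate = 100 * |tracked - target| / target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

__all__ = [
    "HandSample",
    "ControlConfig",
    "StageState",
    "TrajectoryErrorReport",
    "gesture_to_velocity",
    "integrate_stage",
    "enclosed_area",
    "trajectory_error",
    "circle_path",
    "square_path",
    "save_path_csv",
    "load_path_csv",
]

# gesture-sensor operating range above the device, mm
SENSOR_RANGE_MM = (25.0, 600.0)


@dataclass(frozen=True)
class HandSample:
    """Hand center-of-mass position (mm) relative to the sensor center, at time t (s)."""

    t: float
    pos: tuple[float, float, float]
    valid: bool = True

    @property
    def rho(self) -> float:
        """Distance of the hand from the sensor center, mm."""
        return float(np.linalg.norm(self.pos))


@dataclass(frozen=True)
class ControlConfig:
    """Dead-zone proportional velocity control parameters."""

    rho0: float = 50.0          # neutral-sphere radius, mm
    gain: float = 1.0           # mm/s of stage speed per mm of excess displacement
    max_speed: float = 20.0     # clamp on commanded speed, mm/s
    workspace: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 100.0), (0.0, 100.0))

    def __post_init__(self) -> None:
        if not (self.rho0 > 0 and self.gain > 0 and self.max_speed > 0):
            raise ValueError("rho0, gain and max_speed must all be > 0")


@dataclass(frozen=True)
class StageState:
    """Cartesian stage pose and commanded velocity at time t."""

    pos_xy: tuple[float, float]
    vel_xy: tuple[float, float] = (0.0, 0.0)
    t: float = 0.0
    clamped: bool = False


def gesture_to_velocity(hand: HandSample, cfg: ControlConfig) -> tuple[float, float]:
    """Planar stage velocity (mm/s) commanded by a hand sample.

    Zero inside the closed neutral sphere (rho <= rho0); otherwise magnitude
    min(gain * (rho - rho0), max_speed) along the horizontal projection of the
    hand displacement.  Speed is continuous (-> 0) at the sphere boundary.
    """
    rho = hand.rho
    if rho <= cfg.rho0:
        return (0.0, 0.0)
    hx, hy = hand.pos[0], hand.pos[1]
    horiz = float(np.hypot(hx, hy))
    if horiz == 0.0:  # hand displaced purely vertically: no planar motion
        return (0.0, 0.0)
    speed = min(cfg.gain * (rho - cfg.rho0), cfg.max_speed)
    return (speed * hx / horiz, speed * hy / horiz)


def integrate_stage(
    state: StageState, vel: tuple[float, float], dt: float, cfg: ControlConfig
) -> StageState:
    """One Euler step of stage kinematics, position clamped to the workspace."""
    if not dt > 0:
        raise ValueError("dt must be > 0")
    (xlo, xhi), (ylo, yhi) = cfg.workspace
    x = state.pos_xy[0] + vel[0] * dt
    y = state.pos_xy[1] + vel[1] * dt
    cx = min(max(x, xlo), xhi)
    cy = min(max(y, ylo), yhi)
    return StageState(
        pos_xy=(cx, cy), vel_xy=tuple(vel), t=state.t + dt,
        clamped=(cx != x or cy != y),
    )


def enclosed_area(path: np.ndarray, boundary_shrink: float = 0.5) -> float:
    """Area (mm^2) enclosed by a compact boundary of a planar point set.

    ``boundary_shrink`` in [0, 1] controls boundary tightness: 0 gives the
    convex hull, values toward 1 give an increasingly concave boundary that
    hugs the points.  The polygon area is computed by the shoelace formula.
    """
    pts = np.asarray(path, dtype=float)
    if pts.ndim != 2 or pts.shape[1] < 2:
        raise ValueError("path must be an (n, 2) array of planar points")
    pts = pts[:, :2]
    if len(pts) < 3:
        raise ValueError("need at least 3 points to enclose an area")
    if not 0.0 <= boundary_shrink <= 1.0:
        raise ValueError("boundary_shrink must lie in [0, 1]")
    mp = shapely.MultiPoint(pts)
    if boundary_shrink == 0.0:
        poly = shapely.convex_hull(mp)
    else:
        poly = shapely.concave_hull(mp, ratio=1.0 - boundary_shrink)
    if poly.geom_type != "Polygon" or poly.area == 0.0:
        raise ValueError("degenerate path (collinear points enclose no area)")
    return float(poly.area)


@dataclass(frozen=True)
class TrajectoryErrorReport:
    """Area-based trajectory tracking error."""

    target_area: float   # mm^2
    tracked_area: float  # mm^2
    abs_diff: float      # mm^2
    error_rate: float    # percent, 100 * abs_diff / target_area


def trajectory_error(
    target_path: np.ndarray,
    tracked_path: np.ndarray,
    boundary_shrink: float = 0.5,
) -> TrajectoryErrorReport:
    """Score a tracked trajectory against its target by enclosed-area difference."""
    a_t = enclosed_area(target_path, boundary_shrink)
    a_x = enclosed_area(tracked_path, boundary_shrink)
    diff = abs(a_x - a_t)
    return TrajectoryErrorReport(
        target_area=a_t, tracked_area=a_x, abs_diff=diff,
        error_rate=100.0 * diff / a_t,
    )


# ---------------------------------------------------------------------------
# target-trajectory generators and path files

def circle_path(radius: float, n: int = 720, center: tuple[float, float] = (50.0, 50.0)) -> np.ndarray:
    """Ideal circular target trajectory sampled at n points."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.cos(th),
                            center[1] + radius * np.sin(th)])


def square_path(side: float, n: int = 720, center: tuple[float, float] = (50.0, 50.0)) -> np.ndarray:
    """Ideal square target trajectory (side length ``side``) sampled at n points."""
    h = side / 2.0
    per_side = n // 4
    t = np.linspace(-h, h, per_side, endpoint=False)
    cx, cy = center
    pts = np.concatenate([
        np.column_stack([cx + t, np.full_like(t, cy - h)]),
        np.column_stack([np.full_like(t, cx + h), cy + t]),
        np.column_stack([cx - t, np.full_like(t, cy + h)]),
        np.column_stack([np.full_like(t, cx - h), cy - t]),
    ])
    return pts


def save_path_csv(path_xy: np.ndarray, times: np.ndarray, file: str | Path) -> None:
    lines = ["t_s,x_mm,y_mm"]
    lines += [f"{float(t)!r},{float(x)!r},{float(y)!r}"
              for t, (x, y) in zip(times, path_xy)]
    Path(file).write_text("\n".join(lines) + "\n")


def load_path_csv(file: str | Path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(file, delimiter=",", skiprows=1, ndmin=2)
    return data[:, 1:3], data[:, 0]
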