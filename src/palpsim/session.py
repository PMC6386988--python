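"""End-to-end tele-palpation session simulation.

One simulated session ties the whole apparatus together at the control rate:
hand sample -> dead-zone velocity command -> stage integration -> local
stiffness lookup -> vertical force servo (clamped at the 0.5 N protection
threshold) -> latency channel -> resampling to the 5 kHz neuron rate ->
spike encoding -> virtual-subject key presses.  Everything is logged
time-aligned and the whole run is a pure function of configuration + seed.

The two telepresence conditions differ only through the latency channel:
ILS (in line of sight, platform local) uses a near-zero fixed delay, NILS
(not in line of sight, platform ~50 km remote) a jittered delay bounded by
the transport's maximum latency (15 ms).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .control import ControlConfig, HandSample, StageState, gesture_to_velocity, integrate_stage
from .encoder import EncoderCalibration, IzhikevichParams, SpikeTrain, encode_force
from .phantom import Phantom, local_stiffness, phantom_to_dict
from .subject import ResponseEvent, SubjectModel, detect_rate_changes, emit_responses

__all__ = [
    "LatencyModel",
    "SessionConfig",
    "SessionLog",
    "HandTrajectory",
    "run_session",
    "make_trajectory",
    "apply_latency",
    "FORCE_LIMIT_N",
]

# hard protection threshold of the platform, N
FORCE_LIMIT_N = 0.5


@dataclass(frozen=True)
class LatencyModel:
    """Bounded transport delay: fixed, or uniformly jittered in [0, bound]."""

    kind: str = "fixed"       # "fixed" | "jittered"
    bound_s: float = 0.015    # maximum latency, s

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "jittered"):
            raise ValueError(f"unknown latency kind {self.kind!r}")
        if self.bound_s < 0:
            raise ValueError("latency bound must be >= 0")


@dataclass(frozen=True)
class SessionConfig:
    duration: float = 360.0        # s (six-minute protocol)
    control_rate: float = 100.0    # Hz
    encoder_rate: float = 5000.0   # Hz, must match the neuron's 1/dt
    force_setpoint: float = 0.25   # N, <= FORCE_LIMIT_N; half the protection
                                   # threshold so force peaks over the stiffest
                                   # inclusion stay below the clamp
    servo_tau: float = 0.4         # s, first-order depth-servo time constant
                                   # (human pressure-regulation timescale)
    latency: LatencyModel = LatencyModel()
    mode: str = "ILS"              # "ILS" | "NILS" (metadata + latency profile)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.force_setpoint > FORCE_LIMIT_N:
            raise ValueError(f"force_setpoint must be <= {FORCE_LIMIT_N} N")
        if self.mode not in ("ILS", "NILS"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class HandTrajectory:
    """Precomputed hand samples (relative to the sensor center) at the control rate."""

    times: np.ndarray           # s
    positions: np.ndarray       # (n, 3) mm
    stage_ref: np.ndarray | None = None  # intended stage path, for reference

    def sample(self, i: int) -> HandSample:
        j = min(i, len(self.times) - 1)  # hold last sample beyond the end
        return HandSample(t=float(self.times[j]), pos=tuple(self.positions[j]))


@dataclass
class SessionLog:
    """Time-aligned record of one simulated session."""

    config: dict
    hand: pd.DataFrame       # t_s, hx_mm, hy_mm, hz_mm
    stage: pd.DataFrame      # t_s, x_mm, y_mm, depth_mm, force_N, force_delayed_N
    spikes: SpikeTrain
    responses: list[ResponseEvent]

    def stage_path(self) -> np.ndarray:
        return self.stage[["t_s", "x_mm", "y_mm"]].to_numpy()

    def serialize(self) -> dict[str, str]:
        """All streams as text, keyed by filename (used for on-disk layout
        and byte-identity determinism checks)."""
        resp = pd.DataFrame(
            [{"t_s": r.t, "x_mm": r.pos_xy[0], "y_mm": r.pos_xy[1]}
             for r in self.responses],
            columns=["t_s", "x_mm", "y_mm"],
        )
        return {
            "config.json": json.dumps(self.config, indent=2, sort_keys=True) + "\n",
            "hand.csv": self.hand.to_csv(index=False),
            "stage.csv": self.stage.to_csv(index=False),
            "spikes.txt": "".join(f"{float(t)!r}\n" for t in self.spikes.times),
            "responses.csv": resp.to_csv(index=False),
        }

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name, text in self.serialize().items():
            (path / name).write_text(text)


def apply_latency(
    times: np.ndarray,
    values: np.ndarray,
    model: LatencyModel,
    seed: int | None = None,
) -> np.ndarray:
    """Delay a sampled signal through the transport channel.

    The delayed signal is re-read on the original time grid: output(t) =
    input(t - d(t)), with d(t) the (fixed or jittered) per-sample delay
    clamped to [0, bound].  Values before the first sample hold the initial
    value, so the channel is causal and order-preserving.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if model.bound_s == 0.0:
        return values.copy()
    if model.kind == "fixed":
        delays = np.full_like(times, model.bound_s)
    else:
        rng = np.random.default_rng(seed)
        delays = rng.uniform(0.0, model.bound_s, size=len(times))
    read_at = np.clip(times - delays, times[0], None)
    return np.interp(read_at, times, values)


def run_session(
    phantom: Phantom,
    subject_model: SubjectModel,
    control_cfg: ControlConfig,
    neuron: IzhikevichParams,
    calibration: EncoderCalibration,
    session_cfg: SessionConfig,
    hand_source: HandTrajectory,
) -> SessionLog:
    """Simulate one full tele-palpation session.

    Raises configuration errors (rate mismatch, workspace outside the
    phantom footprint, setpoint above the protection threshold) before any
    simulation work starts.
    """
    # --- config consistency -------------------------------------------------
    if not np.isclose(session_cfg.encoder_rate, neuron.sample_rate_hz):
        raise ValueError(
            f"encoder_rate {session_cfg.encoder_rate} Hz does not match the "
            f"neuron integration rate {neuron.sample_rate_hz} Hz"
        )
    (xlo, xhi), (ylo, yhi) = control_cfg.workspace
    sx, sy = phantom.footprint
    if xlo < 0 or ylo < 0 or xhi > sx or yhi > sy:
        raise ValueError("control workspace extends beyond the phantom footprint")

    ss = np.random.SeedSequence(session_cfg.seed)
    seed_latency, seed_subject = (int(c.generate_state(1)[0] % 2**31)
                                  for c in ss.spawn(2))

    dt = 1.0 / session_cfg.control_rate
    n = int(round(session_cfg.duration * session_cfg.control_rate))
    cx = 0.5 * (xlo + xhi)
    cy = 0.5 * (ylo + yhi)
    start = hand_source.stage_ref[0] if hand_source.stage_ref is not None else (cx, cy)
    state = StageState(pos_xy=(float(start[0]), float(start[1])), t=0.0)

    depth = 0.0
    alpha = dt / session_cfg.servo_tau
    t_arr = np.empty(n)
    hand_arr = np.empty((n, 3))
    xy_arr = np.empty((n, 2))
    depth_arr = np.empty(n)
    force_arr = np.empty(n)
    for i in range(n):
        hand = hand_source.sample(i)
        vel = gesture_to_velocity(hand, control_cfg)
        state = integrate_stage(state, vel, dt, control_cfg)
        k = local_stiffness(phantom, state.pos_xy)
        # first-order depth servo toward the force setpoint, clamped at 0.5 N
        depth += alpha * (session_cfg.force_setpoint / k - depth)
        depth = min(depth, FORCE_LIMIT_N / k)
        f = min(k * depth, FORCE_LIMIT_N)
        t_arr[i] = state.t
        hand_arr[i] = hand.pos
        xy_arr[i] = state.pos_xy
        depth_arr[i] = depth
        force_arr[i] = f

    # --- latency channel + spike encoding ------------------------------------
    force_delayed = apply_latency(t_arr, force_arr, session_cfg.latency, seed_latency)
    t_enc = np.arange(int(round(session_cfg.duration * session_cfg.encoder_rate))) \
        / session_cfg.encoder_rate
    force_enc = np.interp(t_enc, t_arr, force_delayed)
    spikes = encode_force(force_enc, calibration, neuron,
                          sample_rate=session_cfg.encoder_rate)

    # --- virtual subject ------------------------------------------------------
    stage_log = np.column_stack([t_arr, xy_arr])
    detections = [t for t in detect_rate_changes(spikes, subject_model)
                  if t <= t_arr[-1]]
    responses = emit_responses(detections, stage_log, subject_model, seed_subject)

    hand_df = pd.DataFrame({
        "t_s": t_arr, "hx_mm": hand_arr[:, 0],
        "hy_mm": hand_arr[:, 1], "hz_mm": hand_arr[:, 2],
    })
    stage_df = pd.DataFrame({
        "t_s": t_arr, "x_mm": xy_arr[:, 0], "y_mm": xy_arr[:, 1],
        "depth_mm": depth_arr, "force_N": force_arr,
        "force_delayed_N": force_delayed,
    })
    config = {
        "session": {**asdict(session_cfg), "latency": asdict(session_cfg.latency)},
        "control": asdict(control_cfg),
        "neuron": asdict(neuron),
        "calibration": asdict(calibration),
        "subject": asdict(subject_model),
        "phantom": phantom_to_dict(phantom),
        "schema_version": 1,
    }
    return SessionLog(config=config, hand=hand_df, stage=stage_df,
                      spikes=spikes, responses=responses)


# ---------------------------------------------------------------------------
# scripted hand trajectories

def _stage_path_to_hand(
    path_xy: np.ndarray,
    cfg: ControlConfig,
    control_rate: float,
) -> HandTrajectory:
    """Invert the control law: hand samples that make the stage trace ``path_xy``.

    For each control step the required stage velocity v maps back to a hand
    displacement of magnitude rho0 + |v| / gain along v (zero displacement
    when the stage should hold).  Raises if the required speed exceeds the
    configured max_speed or the path leaves the workspace.
    """
    path = np.asarray(path_xy, dtype=float)
    (xlo, xhi), (ylo, yhi) = cfg.workspace
    if (path[:, 0].min() < xlo or path[:, 0].max() > xhi
            or path[:, 1].min() < ylo or path[:, 1].max() > yhi):
        raise ValueError("requested stage pattern exceeds the workspace")
    dt = 1.0 / control_rate
    vel = np.diff(path, axis=0) / dt
    speeds = np.hypot(vel[:, 0], vel[:, 1])
    if speeds.max(initial=0.0) > cfg.max_speed + 1e-9:
        raise ValueError(
            f"pattern requires speed {speeds.max():.2f} mm/s above max_speed "
            f"{cfg.max_speed} mm/s"
        )
    n = len(path)
    hand = np.zeros((n, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = cfg.rho0 + speeds / cfg.gain
        unit = np.where(speeds[:, None] > 0, vel / np.maximum(speeds, 1e-300)[:, None], 0.0)
    hand[:-1, :2] = unit * np.where(speeds[:, None] > 0, mag[:, None], 0.0)
    times = np.arange(n) * dt
    return HandTrajectory(times=times, positions=hand, stage_ref=path)


def _raster_stage_path(params: dict, cfg: ControlConfig, control_rate: float) -> np.ndarray:
    (xlo, xhi), (ylo, yhi) = cfg.workspace
    margin = float(params.get("margin", 5.0))
    spacing = float(params.get("line_spacing", 10.0))
    speed = float(params.get("speed", min(10.0, cfg.max_speed)))
    x0, x1 = xlo + margin, xhi - margin
    y0, y1 = ylo + margin, yhi - margin
    ys = np.arange(y0, y1 + 1e-9, spacing)
    waypoints = []
    for i, y in enumerate(ys):
        a, b = (x0, x1) if i % 2 == 0 else (x1, x0)
        waypoints.append((a, y))
        waypoints.append((b, y))
    return _waypoint_stage_path(waypoints, speed, control_rate)


def _waypoint_stage_path(waypoints, speed: float, control_rate: float) -> np.ndarray:
    pts = np.asarray(waypoints, dtype=float).reshape(-1, 2)
    dt = 1.0 / control_rate
    path = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        length = float(np.hypot(*seg))
        if length == 0:
            continue
        n_steps = max(1, int(np.ceil(length / (speed * dt))))
        for j in range(1, n_steps + 1):
            path.append(a + seg * (j / n_steps))
    return np.asarray(path)


def make_trajectory(
    kind: str,
    params: dict,
    cfg: ControlConfig,
    control_rate: float = 100.0,
    seed: int | None = None,
) -> HandTrajectory:
    """Build a scripted hand-sample source.

    kinds
    -----
    raster
        Serpentine sweep of the workspace; params: line_spacing (mm, default
        10), speed (mm/s), margin (mm).  Linear exploratory paths are both
        the natural palpation strategy and the best-tracked geometry.
    waypoints
        Piecewise-linear visit of params["points"] at params["speed"]; with
        no points the hand rests at the sensor center (stage holds).
    replay
        Re-derive hand samples from a recorded stage path,
        params["path_xy"] (n, 2) sampled at the control rate.
    """
    if kind == "raster":
        path = _raster_stage_path(params, cfg, control_rate)
    elif kind == "waypoints":
        pts = params.get("points", [])
        if len(pts) == 0:
            n = max(2, int(params.get("n", 2)))
            times = np.arange(n) / control_rate
            return HandTrajectory(times=times, positions=np.zeros((n, 3)),
                                  stage_ref=None)
        speed = float(params.get("speed", 10.0))
        path = _waypoint_stage_path(pts, speed, control_rate)
    elif kind == "replay":
        path = np.asarray(params["path_xy"], dtype=float)
    else:
        raise ValueError(f"unknown trajectory kind {kind!r}")
    return _stage_path_to_hand(path, cfg, control_rate)
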