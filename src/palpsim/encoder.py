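"""Neuromorphic force-to-spike encoder.

Contact force is converted into a spike train by a regular-spiking Izhikevich
neuron integrated with Euler's method at 5 kHz (dt = 0.2 ms):

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)
    if v >= v_peak:  spike;  v <- c,  u <- u + d

The input current is proportional to the normal force, I(t) = offset +
gain * F(t).  A calibration step chooses the gain so that the working force
range [0, force_max] maps onto the monotone region of the neuron's f-I curve,
with the maximum force producing a target firing rate; this counterbalances
rate saturation of the neural model.

Each spike drives the piezoelectric actuator with a biphasic square pulse
(200 V peak-to-peak about a 105 V offset by default, matching the driver
electronics settings).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "IzhikevichParams",
    "NeuronState",
    "EncoderCalibration",
    "SpikeTrain",
    "ActuationConfig",
    "izhikevich_step",
    "simulate_neuron",
    "encode_force",
    "compute_fI_curve",
    "calibrate_gain",
    "spikes_to_waveform",
    "save_spike_train",
    "load_spike_train",
]


@dataclass(frozen=True)
class IzhikevichParams:
    """Izhikevich neuron parameters; defaults are the canonical regular-spiking set."""

    izh_a: float = 0.02
    izh_b: float = 0.2
    izh_c: float = -65.0
    izh_d: float = 8.0
    v_peak: float = 30.0  # spike cutoff, mV
    dt: float = 0.2       # integration step, ms (0.2 ms = 5 kHz)

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        if not self.v_peak > self.izh_c:
            raise ValueError("v_peak must exceed the reset potential izh_c")

    @property
    def sample_rate_hz(self) -> float:
        return 1000.0 / self.dt

    def rest_state(self) -> "NeuronState":
        return NeuronState(v=self.izh_c, u=self.izh_b * self.izh_c)


@dataclass(frozen=True)
class NeuronState:
    v: float  # membrane potential, mV
    u: float  # recovery variable


@dataclass(frozen=True)
class EncoderCalibration:
    """Affine force-to-current mapping of the encoder."""

    input_gain: float            # current units per N
    input_offset: float = 0.0    # current units
    force_max: float = 0.5       # N

    def __post_init__(self) -> None:
        if not self.input_gain > 0:
            raise ValueError("input_gain must be > 0")
        if not self.force_max > 0:
            raise ValueError("force_max must be > 0")

    def current(self, force: float | np.ndarray) -> float | np.ndarray:
        return self.input_offset + self.input_gain * force


@dataclass
class SpikeTrain:
    """Ordered spike times (s) within [0, duration]."""

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")
        if len(self.times) and (self.times[0] < 0 or self.times[-1] > self.duration):
            raise ValueError("spike times must lie within [0, duration]")

    def __len__(self) -> int:
        return len(self.times)

    def rate(self) -> float:
        """Mean firing rate over the whole train, Hz."""
        return len(self.times) / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class ActuationConfig:
    """Piezoelectric driver electrical settings."""

    gain_db: float = 40.7
    vpp: float = 200.0        # peak-to-peak pulse amplitude, V
    offset_v: float = 105.0   # baseline offset voltage, V
    pulse_width: float = 1.0  # ms

    def __post_init__(self) -> None:
        if not self.vpp > 0:
            raise ValueError("vpp must be > 0")


def izhikevich_step(
    state: NeuronState, I: float, p: IzhikevichParams
) -> tuple[NeuronState, bool]:
    """One Euler step of size ``p.dt``; returns the new state and a spike flag."""
    v, u = state.v, state.u
    v_new = v + p.dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
    u_new = u + p.dt * (p.izh_a * (p.izh_b * v - u))
    # divergence must be caught before the reset can mask an overflow-to-inf
    if not (math.isfinite(v_new) and math.isfinite(u_new)):
        raise FloatingPointError(
            "Izhikevich integration diverged (dt or input current out of range)"
        )
    spiked = v_new >= p.v_peak
    if spiked:
        v_new = p.izh_c
        u_new = u_new + p.izh_d
    return NeuronState(v_new, u_new), spiked


def simulate_neuron(
    currents: np.ndarray,
    p: IzhikevichParams,
    state: NeuronState | None = None,
) -> tuple[np.ndarray, NeuronState]:
    """Run the neuron over a current sample per step; return spike times (s).

    Spike time convention: a spike at step i is stamped at (i + 1) * dt, the
    time at which the threshold crossing is detected.
    """
    if state is None:
        state = p.rest_state()
    a, b, c, d = p.izh_a, p.izh_b, p.izh_c, p.izh_d
    dt, v_peak = p.dt, p.v_peak
    v, u = state.v, state.u
    spike_steps: list[int] = []
    cur = np.asarray(currents, dtype=float)
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(len(cur)):
            I = cur[i]
            v = v + dt * (0.04 * v * v + 5.0 * v + 140.0 - u + I)
            u = u + dt * (a * (b * v - u))
            if v >= v_peak:
                if not math.isfinite(v):
                    raise FloatingPointError(
                        "Izhikevich integration diverged "
                        "(dt or input current out of range)"
                    )
                spike_steps.append(i)
                v = c
                u = u + d
    if not (math.isfinite(v) and math.isfinite(u)):
        raise FloatingPointError(
            "Izhikevich integration diverged (dt or input current out of range)"
        )
    times = (np.array(spike_steps, dtype=float) + 1.0) * (dt / 1000.0)
    return times, NeuronState(v, u)


def encode_force(
    force_series: np.ndarray,
    cal: EncoderCalibration,
    p: IzhikevichParams = IzhikevichParams(),
    sample_rate: float | None = None,
) -> SpikeTrain:
    """Encode a uniformly sampled force series (N) into a spike train.

    The series must be sampled at the neuron's integration rate (1/dt,
    5 kHz by default); pass ``sample_rate`` to have this checked explicitly.
    """
    if sample_rate is not None and not math.isclose(sample_rate, p.sample_rate_hz):
        raise ValueError(
            f"force series sampled at {sample_rate} Hz but the neuron "
            f"integrates at {p.sample_rate_hz} Hz"
        )
    forces = np.asarray(force_series, dtype=float)
    currents = np.asarray(cal.current(forces), dtype=float)
    times, _ = simulate_neuron(currents, p)
    return SpikeTrain(times=times, duration=len(forces) * p.dt / 1000.0)


def compute_fI_curve(
    p: IzhikevichParams,
    I_grid: np.ndarray,
    settle_s: float = 0.5,
    measure_s: float = 1.0,
) -> np.ndarray:
    """Steady-state firing rate (Hz) at each constant input current.

    The neuron runs for ``settle_s`` + ``measure_s`` at each current; spikes
    in the settle window are discarded and the rate is the spike count in the
    measure window divided by its length.  Returns an (n, 2) array of
    (current, rate) rows.
    """
    rows = []
    n_steps = int(round((settle_s + measure_s) * p.sample_rate_hz))
    for I in np.asarray(I_grid, dtype=float):
        times, _ = simulate_neuron(np.full(n_steps, I), p)
        rate = np.count_nonzero(times > settle_s) / measure_s
        rows.append((float(I), float(rate)))
    return np.array(rows)


def _monotone_prefix(curve: np.ndarray) -> np.ndarray:
    """Truncate an f-I curve at the saturation knee (first rate decrease)."""
    rates = curve[:, 1]
    end = len(rates)
    for i in range(1, len(rates)):
        if rates[i] < rates[i - 1]:
            end = i
            break
    return curve[:end]


def calibrate_gain(
    p: IzhikevichParams = IzhikevichParams(),
    force_max: float = 0.5,
    target_rate_range: tuple[float, float] = (0.0, 100.0),
    input_offset: float = 0.0,
    I_grid: np.ndarray | None = None,
) -> EncoderCalibration:
    """Choose the force-to-current gain so the force range stays in the
    monotone region of the f-I curve.

    The gain maps ``force_max`` to the current whose steady-state rate equals
    the top of ``target_rate_range`` (found by inverse interpolation of the
    simulated f-I curve restricted to its monotone prefix).

    Raises
    ------
    ValueError
        If the target top rate is unattainable inside the monotone region.
    """
    if I_grid is None:
        I_grid = np.arange(0.0, 60.0 + 1e-9, 1.0)
    target_top = target_rate_range[1]
    if not target_top > 0:
        raise ValueError("top of target_rate_range must be > 0")
    curve = _monotone_prefix(compute_fI_curve(p, I_grid))
    rates, currents = curve[:, 1], curve[:, 0]
    if target_top > rates[-1]:
        raise ValueError(
            f"target rate {target_top} Hz exceeds the attainable monotone "
            f"f-I range (max {rates[-1]:.1f} Hz on the probed grid)"
        )
    # inverse interpolation on the (non-decreasing) monotone prefix
    I_top = float(np.interp(target_top, rates, currents))
    if I_top <= input_offset:
        raise ValueError("target rate reached at or below the input offset current")
    return EncoderCalibration(
        input_gain=(I_top - input_offset) / force_max,
        input_offset=input_offset,
        force_max=force_max,
    )


def spikes_to_waveform(
    train: SpikeTrain,
    a: ActuationConfig = ActuationConfig(),
    sample_rate: float = 5000.0,
) -> np.ndarray:
    """Render the actuator drive voltage (V) for a spike train.

    Each spike becomes one biphasic square pulse of total width
    ``pulse_width`` (+vpp/2 then -vpp/2 about the offset voltage, peak-to-peak
    excursion vpp); the baseline sits at ``offset_v``.  Overlapping pulses are
    summed then clipped to [offset - vpp/2, offset + vpp/2].
    """
    pw_s = a.pulse_width / 1000.0
    if sample_rate < 2.0 / pw_s:
        raise ValueError("sample_rate too low to resolve the pulse width")
    n = int(round(train.duration * sample_rate)) + 1
    excursion = np.zeros(n)
    half = max(1, int(round(pw_s / 2 * sample_rate)))
    amp = a.vpp / 2.0
    for t in train.times:
        i0 = int(round(t * sample_rate))
        excursion[i0:i0 + half] += amp
        excursion[i0 + half:i0 + 2 * half] -= amp
    np.clip(excursion, -amp, amp, out=excursion)
    return a.offset_v + excursion


# ---------------------------------------------------------------------------
# spike-train files: one spike time (s) per line + JSON sidecar with metadata

def save_spike_train(train: SpikeTrain, path: str | Path, params: dict | None = None) -> None:
    path = Path(path)
    path.write_text("".join(f"{float(t)!r}\n" for t in train.times))
    sidecar = {"duration": train.duration, "n_spikes": len(train)}
    if params:
        sidecar["params"] = params
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_spike_train(path: str | Path) -> SpikeTrain:
    path = Path(path)
    text = path.read_text().split()
    times = np.array([float(x) for x in text])
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return SpikeTrain(times=times, duration=sidecar["duration"])
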