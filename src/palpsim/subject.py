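"""Virtual participant.

The real task was performed by humans who pressed a key whenever they felt
the vibro-tactile pulse frequency change.  This module provides a simple
stand-in with two faces:

* a mechanistic detector (`detect_rate_changes` + `emit_responses`) that
  watches the spike train's sliding-window rate, compares it with a running
  baseline, and presses a "key" (with reaction latency, a refractory period,
  and spatial scatter of the recorded press position);
* a model-faithful psychometric response generator
  (`psychometric_response`) drawing Bernoulli detections from the logistic
  psychometric function with guess (gamma) and lapse (lambda) rates, used by
  the parameter-recovery harness so fitting tests do not depend on the
  detector's heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoder import SpikeTrain
from .psychophysics import logistic_cdf

__all__ = [
    "SubjectModel",
    "ResponseEvent",
    "detect_rate_changes",
    "emit_responses",
    "psychometric_response",
]


@dataclass(frozen=True)
class SubjectModel:
    """Parameters of the virtual key-pressing participant."""

    rate_window: float = 0.25       # sliding-window length for rate estimation, s
    change_threshold: float = 12.0  # rate departure that triggers a press, Hz
    reaction_latency: float = 0.3   # s added to the detection time
    refractory: float = 1.0         # minimum gap between presses, s
    guess_rate: float = 0.0         # gamma of the psychometric function
    lapse_rate: float = 0.0         # lambda of the psychometric function
    press_jitter_sd: float = 2.0    # isotropic scatter of the press position, mm
    baseline_windows: int = 5       # windows pooled into the running baseline

    def __post_init__(self) -> None:
        g, l = self.guess_rate, self.lapse_rate
        if not (0 <= g and 0 <= l and g + l < 1):
            raise ValueError("need 0 <= gamma, lambda and gamma + lambda < 1")
        if not (self.rate_window > 0 and self.refractory > 0):
            raise ValueError("rate_window and refractory must be > 0")


@dataclass(frozen=True)
class ResponseEvent:
    """A key press with the stage position recorded at press time."""

    t: float
    pos_xy: tuple[float, float]


def detect_rate_changes(train: SpikeTrain, m: SubjectModel) -> list[float]:
    """Times at which the subject perceives a spike-rate change.

    The spike rate is estimated in a sliding window (hop = window / 4) and
    compared with a running baseline, the median rate over the previous
    ``baseline_windows`` windows.  A detection fires when the rate departs
    from the baseline by more than ``change_threshold`` Hz, after which the
    detector is refractory; each detection time is shifted by the reaction
    latency.
    """
    w = m.rate_window
    hop = w / 4.0
    if train.duration < w:
        return []
    starts = np.arange(0.0, train.duration - w + 1e-12, hop)
    times = train.times
    rates = (np.searchsorted(times, starts + w, side="left")
             - np.searchsorted(times, starts, side="left")) / w
    detections: list[float] = []
    last = -np.inf
    nb = m.baseline_windows
    for i in range(nb, len(rates)):
        baseline = float(np.median(rates[i - nb:i]))
        t_now = starts[i] + w  # rate estimate attributed to the window end
        if abs(rates[i] - baseline) > m.change_threshold and t_now - last > m.refractory:
            detections.append(t_now + m.reaction_latency)
            last = t_now
    return detections


def emit_responses(
    detections: list[float],
    stage_log: np.ndarray,
    m: SubjectModel,
    seed: int | None = None,
) -> list[ResponseEvent]:
    """Convert detection times into key presses stamped with the stage position.

    ``stage_log`` is an (n, 3) array of (t, x, y) rows covering the detection
    times; positions are linearly interpolated at each detection time and
    scattered isotropically with ``press_jitter_sd``.
    """
    log = np.asarray(stage_log, dtype=float)
    if log.ndim != 2 or log.shape[1] < 3:
        raise ValueError("stage_log must be an (n, 3) array of (t, x, y)")
    rng = np.random.default_rng(seed)
    out: list[ResponseEvent] = []
    for t in detections:
        if not (log[0, 0] <= t <= log[-1, 0]):
            raise ValueError(f"stage log does not cover detection time {t}")
        x = float(np.interp(t, log[:, 0], log[:, 1]))
        y = float(np.interp(t, log[:, 0], log[:, 2]))
        if m.press_jitter_sd > 0:
            dx, dy = rng.normal(0.0, m.press_jitter_sd, size=2)
            x, y = x + dx, y + dy
        out.append(ResponseEvent(t=t, pos_xy=(x, y)))
    return out


def psychometric_response(
    stiffness: float,
    a_thr: float,
    b_scale: float,
    guess_rate: float = 0.0,
    lapse_rate: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> bool:
    """Bernoulli detection of a stimulus of the given stiffness.

    Detection probability is gamma + (1 - gamma - lambda) * G(x), with G the
    logistic CDF with threshold ``a_thr`` and scale ``b_scale``.
    """
    if not b_scale > 0:
        raise ValueError("b_scale must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p = guess_rate + (1.0 - guess_rate - lapse_rate) * logistic_cdf(
        stiffness, a_thr, b_scale
    )
    return bool(rng.random() < p)
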