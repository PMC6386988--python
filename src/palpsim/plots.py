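"""Static report plots of session logs and analyses."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .phantom import Phantom
from .psychophysics import PsychometricFit, ToleranceCurve

__all__ = ["plot_trail", "plot_tolerance_curve", "plot_psychometric"]


def plot_trail(log, phantom: Phantom, out: str | Path) -> None:
    """Probe trail on the phantom surface with inclusions and key presses."""
    fig, ax = plt.subplots(figsize=(6, 6))
    sx, sy = phantom.footprint
    ax.add_patch(plt.Rectangle((0, 0), sx, sy, fill=False, lw=1))
    for inc in phantom.inclusions:
        ax.add_patch(plt.Circle(inc.center_xy, inc.radius, alpha=0.5,
                                label=inc.material.name))
        ax.annotate(inc.material.name, inc.center_xy, ha="center", fontsize=7)
    ax.plot(log.stage["x_mm"], log.stage["y_mm"], color="lightblue", lw=0.8,
            label="probe trail")
    if log.responses:
        xy = np.array([r.pos_xy for r in log.responses])
        ax.plot(xy[:, 0], xy[:, 1], "ko", mfc="none", ms=8, label="key press")
    ax.set_xlabel("X (mm)")
    ax.set_ylabel("Y (mm)")
    ax.set_aspect("equal")
    ax.set_title("Exploration trail and responses")
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_tolerance_curve(curve: ToleranceCurve, out: str | Path) -> None:
    """Mean TP, FP and accuracy vs. classification tolerance radius."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.tolerances, curve.mean_tp, "o-", color="goldenrod", label="mean TP")
    ax.plot(curve.tolerances, curve.mean_fp, "s-", color="firebrick", label="mean FP")
    ax2 = ax.twinx()
    ax2.plot(curve.tolerances, curve.mean_accuracy, "d-", color="steelblue",
             label="mean accuracy")
    ax2.set_ylim(0, 1.05)
    ax.set_xlabel("tolerance radius (mm)")
    ax.set_ylabel("responses per session")
    ax2.set_ylabel("accuracy")
    ax.legend(loc="upper left")
    ax2.legend(loc="lower right")
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)


def plot_psychometric(fit: PsychometricFit, out: str | Path,
                      iqr: dict[float, float] | None = None) -> None:
    """Identification rate vs. stiffness with the fitted logistic CDF."""
    fig, ax = plt.subplots(figsize=(6, 4))
    if len(fit.stiffness):
        if iqr:
            err = [iqr.get(float(x), 0.0) / 2 for x in fit.stiffness]
            ax.errorbar(fit.stiffness, fit.rates, yerr=err, fmt="kd", capsize=3,
                        label="identification rate")
        else:
            ax.plot(fit.stiffness, fit.rates, "kd", label="identification rate")
        lo, hi = fit.stiffness.min() - 0.5, fit.stiffness.max() + 0.5
    else:
        lo, hi = fit.a_thr - 2, fit.a_thr + 2
    xs = np.linspace(lo, hi, 200)
    ax.plot(xs, fit.predict(xs), "r--",
            label=f"logistic CDF fit (a={fit.a_thr:.2f}, b={fit.b_scale:.2f})")
    ax.axvline(fit.a_thr, color="gray", lw=0.5)
    ax.set_xlabel("stiffness (N/mm)")
    ax.set_ylabel("identification rate")
    ax.set_ylim(-0.05, 1.05)
    ax.legend()
    fig.savefig(out, dpi=120, bbox_inches="tight")
    plt.close(fig)
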