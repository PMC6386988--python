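"""Psychophysical analysis of palpation responses.

Each key press is matched to the nearest inclusion center on the phantom
surface: if the Euclidean distance is within the tolerance radius (10 mm
by default, twice the inclusion radius) it is a true positive (TP),
otherwise a false positive (FP).  TP/FP and accuracy are swept across
tolerance radii {5, 10, 15, 20} mm, per-material identification rates are
computed (an inclusion counts as identified when at least one TP press
matches it), and the identification rate as a function of material
stiffness x is fitted with the logistic cumulative distribution function

    G(x) = 1 / (1 + exp(-(x - a) / b)),   b > 0,

whose location parameter a is the perceptual threshold (stiffness at which
detection probability reaches 50%) and b the scale controlling steepness.
The fit is by nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .phantom import Phantom

__all__ = [
    "logistic_cdf",
    "ClassifiedResponses",
    "ToleranceCurve",
    "PsychometricModel",
    "PsychometricFit",
    "classify_responses",
    "accuracy",
    "tolerance_sweep",
    "identification_rate_by_material",
    "fit_cdf",
    "DEFAULT_TOLERANCES_MM",
]

DEFAULT_TOLERANCES_MM = (5.0, 10.0, 15.0, 20.0)


def logistic_cdf(x, a: float, b: float):
    """Logistic CDF G(x) = [1 + exp(-(x - a)/b)]^-1 with threshold a, scale b."""
    x = np.asarray(x, dtype=float)
    out = expit((x - a) / b)
    return out if out.ndim else float(out)


@dataclass
class ClassifiedResponses:
    """Per-response TP/FP labels against the phantom ground truth."""

    labels: list[str]               # "TP" | "FP" per response
    matched_inclusion: list[int | None]  # inclusion index for TPs, None for FPs
    distances: list[float]          # center distance to the nearest inclusion, mm
    tolerance: float

    @property
    def tp_count(self) -> int:
        return sum(1 for l in self.labels if l == "TP")

    @property
    def fp_count(self) -> int:
        return sum(1 for l in self.labels if l == "FP")

    def __len__(self) -> int:
        return len(self.labels)


def _response_positions(responses) -> np.ndarray:
    pos = [r.pos_xy if hasattr(r, "pos_xy") else r for r in responses]
    return np.asarray(pos, dtype=float).reshape(-1, 2)


def classify_responses(responses, phantom: Phantom, tolerance_mm: float = 10.0) -> ClassifiedResponses:
    """Label each response TP/FP by distance to the nearest inclusion center.

    A response is TP iff its distance to the nearest inclusion center is
    <= ``tolerance_mm`` (boundary inclusive).  With no inclusions every
    response is FP.
    """
    if not tolerance_mm > 0:
        raise ValueError("tolerance_mm must be > 0")
    pos = _response_positions(responses)
    labels: list[str] = []
    matched: list[int | None] = []
    dists: list[float] = []
    centers = np.array([inc.center_xy for inc in phantom.inclusions], dtype=float)
    for p in pos:
        if len(centers) == 0:
            labels.append("FP")
            matched.append(None)
            dists.append(float("inf"))
            continue
        d = np.hypot(centers[:, 0] - p[0], centers[:, 1] - p[1])
        i = int(np.argmin(d))
        if d[i] <= tolerance_mm:
            labels.append("TP")
            matched.append(i)
        else:
            labels.append("FP")
            matched.append(None)
        dists.append(float(d[i]))
    return ClassifiedResponses(labels, matched, dists, tolerance_mm)


def accuracy(c: ClassifiedResponses, definition: str = "standard") -> float:
    """Fraction of correct responses.

    ``standard``: TP / (TP + FP), the conventional precision of the declared
    detections.  ``literal``: TP / (n_responses - FP), an alternative reading
    of "TP over positives" that reduces to 1 whenever any TP exists.
    """
    n = len(c)
    if n == 0:
        raise ValueError("accuracy undefined for zero responses")
    if definition == "standard":
        return c.tp_count / n
    if definition == "literal":
        denom = n - c.fp_count
        if denom == 0:
            raise ValueError("literal accuracy undefined when all responses are FP")
        return c.tp_count / denom
    raise ValueError(f"unknown accuracy definition {definition!r}")


@dataclass
class ToleranceCurve:
    """Mean TP / FP / accuracy across sessions at each tolerance radius."""

    tolerances: tuple[float, ...]
    mean_tp: list[float]
    mean_fp: list[float]
    mean_accuracy: list[float]

    def as_dict(self) -> dict:
        return {
            "tolerances_mm": list(self.tolerances),
            "mean_tp": self.mean_tp,
            "mean_fp": self.mean_fp,
            "mean_accuracy": self.mean_accuracy,
        }


def tolerance_sweep(
    sessions,
    phantom: Phantom,
    tolerances=DEFAULT_TOLERANCES_MM,
) -> ToleranceCurve:
    """Sweep the TP/FP classification over tolerance radii, averaging across sessions.

    ``sessions`` is a list of response collections (one per session).
    """
    if len(sessions) < 1:
        raise ValueError("need at least one session")
    mean_tp, mean_fp, mean_acc = [], [], []
    for tol in tolerances:
        cs = [classify_responses(resp, phantom, tol) for resp in sessions]
        mean_tp.append(float(np.mean([c.tp_count for c in cs])))
        mean_fp.append(float(np.mean([c.fp_count for c in cs])))
        accs = [accuracy(c) for c in cs if len(c) > 0]
        mean_acc.append(float(np.mean(accs)) if accs else float("nan"))
    return ToleranceCurve(tuple(tolerances), mean_tp, mean_fp, mean_acc)


def identification_rate_by_material(
    sessions,
    phantom: Phantom,
    tolerance_mm: float = 10.0,
) -> dict[str, dict[str, float]]:
    """Per-material identification rate, averaged across sessions, with IQR.

    Within one session an inclusion counts as identified iff at least one TP
    response matches it; the session's rate for a material is identified /
    total inclusions of that material.  Returns
    {material: {"rate": mean across sessions, "iqr": interquartile range,
    "stiffness": material stiffness}}.
    """
    mats: dict[str, list[int]] = {}
    for idx, inc in enumerate(phantom.inclusions):
        mats.setdefault(inc.material.name, []).append(idx)
    if not mats:
        raise ValueError("phantom has no inclusions")
    per_session: dict[str, list[float]] = {m: [] for m in mats}
    for resp in sessions:
        c = classify_responses(resp, phantom, tolerance_mm)
        hit = {i for i in c.matched_inclusion if i is not None}
        for m, idxs in mats.items():
            per_session[m].append(sum(1 for i in idxs if i in hit) / len(idxs))
    out: dict[str, dict[str, float]] = {}
    for m, rates in per_session.items():
        r = np.array(rates)
        q1, q3 = np.percentile(r, [25, 75])
        k = next(inc.material.stiffness_k for inc in phantom.inclusions
                 if inc.material.name == m)
        out[m] = {"rate": float(r.mean()), "iqr": float(q3 - q1), "stiffness": k}
    return out


# ---------------------------------------------------------------------------
# psychometric-function fitting

@dataclass
class PsychometricFit:
    """Results of the logistic-CDF psychometric fit."""

    a_thr: float                 # perceptual threshold, N/mm
    b_scale: float               # scale, N/mm (> 0)
    rss: float                   # residual sum of squares
    converged: bool
    identifiable: bool = True
    stiffness: np.ndarray = field(default_factory=lambda: np.array([]))
    rates: np.ndarray = field(default_factory=lambda: np.array([]))
    a_se: float = float("nan")   # asymptotic standard errors from the
    b_se: float = float("nan")   # least-squares Jacobian (nan if singular)

    def predict(self, x) -> np.ndarray:
        return logistic_cdf(x, self.a_thr, self.b_scale)

    def summary(self) -> str:
        lines = [
            "Psychometric fit: G(x) = [1 + exp(-(x - a)/b)]^-1",
            f"  n stimulus levels : {len(self.stiffness)}",
            f"  a (threshold)     : {self.a_thr:.4f} N/mm  (SE {self.a_se:.4f})",
            f"  b (scale)         : {self.b_scale:.4f} N/mm  (SE {self.b_se:.4f})",
            f"  residual SS       : {self.rss:.6g}",
            f"  converged         : {self.converged}",
        ]
        if not self.identifiable:
            lines.append("  WARNING: parameters unidentifiable (all rates equal)")
        return "\n".join(lines)


class PsychometricModel:
    """Logistic-CDF psychometric function model for identification rates.

    Parameters
    ----------
    stiffness : array-like
        Stimulus intensities (material stiffness, N/mm); >= 2 distinct values.
    rates : array-like
        Observed identification rates in [0, 1], one per stimulus level.
    """

    def __init__(self, stiffness, rates):
        self.x = np.asarray(stiffness, dtype=float)
        self.y = np.asarray(rates, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("stiffness and rates must be 1-D arrays of equal length")
        if len(np.unique(self.x)) < 2:
            raise ValueError("need >= 2 distinct stiffness values")
        if np.any((self.y < 0) | (self.y > 1)):
            raise ValueError("rates must lie in [0, 1]")

    def fit(self, init: tuple[float, float] | None = None) -> PsychometricFit:
        """Nonlinear least squares with b constrained positive (b >= 1e-6)."""
        if init is None:
            a0 = float(np.median(self.x))
            b0 = float(max((self.x.max() - self.x.min()) / 2.0, 1e-3))
        else:
            a0, b0 = init
        identifiable = len(np.unique(self.y)) > 1

        def resid(theta):
            return logistic_cdf(self.x, theta[0], theta[1]) - self.y

        sol = least_squares(
            resid, x0=[a0, max(b0, 1e-6)],
            bounds=([-np.inf, 1e-6], [np.inf, np.inf]),
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
        )
        rss = float(2.0 * sol.cost)
        a_se = b_se = float("nan")
        dof = len(self.x) - 2
        if sol.success and identifiable and dof > 0:
            try:
                jtj = sol.jac.T @ sol.jac
                cov = np.linalg.inv(jtj) * rss / dof
                a_se, b_se = (float(np.sqrt(cov[i, i])) for i in (0, 1))
            except np.linalg.LinAlgError:
                pass
        return PsychometricFit(
            a_thr=float(sol.x[0]), b_scale=float(sol.x[1]), rss=rss,
            converged=bool(sol.success) and identifiable,
            identifiable=identifiable,
            stiffness=self.x, rates=self.y, a_se=a_se, b_se=b_se,
        )


def fit_cdf(stiffness_values, rates, init: tuple[float, float] | None = None) -> PsychometricFit:
    """Fit the logistic CDF to identification rates vs. stiffness.

    Convenience wrapper around :class:`PsychometricModel`.  Non-convergence
    and unidentifiable input (all rates equal) are flagged on the returned
    fit, not raised.
    """
    return PsychometricModel(stiffness_values, rates).fit(init)
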