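"""Treatment-outcome analysis: tumor volumes, regrowth rates, cure index and
the logistic dose-response linking simulated singlet-oxygen dose to outcome.

The cure index of a treated group is CI = 1 - k/k_ctr, where k is the
exponential tumor regrowth rate fitted over the 14 days after treatment and
k_ctr the rate of the untreated control group; CI = 1 means no regrowth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import (
    FitFailure,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "TumorMeasurement",
    "OutcomeRecord",
    "DoseResponseParams",
    "FIG7_DOSE_RESPONSE",
    "tumor_volume",
    "fit_regrowth",
    "RegrowthFit",
    "cure_index",
    "logistic_ci",
    "correlate_outcomes",
    "DoseResponseFit",
]


@dataclass(frozen=True)
class TumorMeasurement:
    """A caliper measurement: day post-treatment and the two diameters (mm)."""

    day: float
    a: float  # width-axis diameter, mm
    b: float  # length-axis diameter, mm

    def __post_init__(self):
        if self.day < 0 or self.a < 0 or self.b < 0:
            raise InvalidParameterError(f"negative field in {self}")

    @property
    def volume(self) -> float:
        return tumor_volume(self.a, self.b)


@dataclass(frozen=True)
class OutcomeRecord:
    """Regrowth rate, control rate, and the resulting cure index."""

    k: float  # 1/days
    k_ctr: float  # 1/days
    CI: float

    @classmethod
    def from_rates(cls, k: float, k_ctr: float) -> "OutcomeRecord":
        return cls(k=k, k_ctr=k_ctr, CI=cure_index(k, k_ctr))


def tumor_volume(a, b):
    """Ellipsoidal tumor volume V = pi a^2 b / 6 (mm^3) from two diameters."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(a < 0) or np.any(b < 0):
        raise InvalidParameterError("diameters must be >= 0")
    v = np.pi * a**2 * b / 6.0
    return float(v) if v.ndim == 0 else v


@dataclass
class RegrowthFit:
    """Exponential regrowth-rate estimate.

    ``k`` is the reported rate (raw estimate floored at zero; a shrinking
    tumor is a cure, not a negative regrowth); ``k_raw`` the unconstrained
    log-linear slope; ``n_used`` the number of positive-volume points kept.
    """

    k: float
    k_raw: float
    n_used: int
    log_v0: float = float("nan")


def fit_regrowth(measurements) -> RegrowthFit:
    """Fit V(t) = V0 exp(k t) by least squares on ln V vs t (1/days).

    Accepts a list of :class:`TumorMeasurement` or of ``(day, volume)``
    pairs.  Zero-volume points (cured tumors) are dropped; if fewer than 3
    positive points remain, the group is reported as cured (k = 0).
    """
    if len(measurements) < 3:
        raise InsufficientDataError("need >= 3 time points")
    days, vols = [], []
    for m in measurements:
        if isinstance(m, TumorMeasurement):
            days.append(m.day)
            vols.append(m.volume)
        else:
            t, v = m
            days.append(float(t))
            vols.append(float(v))
    days = np.asarray(days)
    vols = np.asarray(vols)
    keep = vols > 0
    if keep.sum() < 3:
        return RegrowthFit(k=0.0, k_raw=0.0, n_used=int(keep.sum()))
    t = days[keep]
    logv = np.log(vols[keep])
    slope, intercept = np.polyfit(t, logv, 1)
    return RegrowthFit(
        k=float(max(slope, 0.0)),
        k_raw=float(slope),
        n_used=int(keep.sum()),
        log_v0=float(intercept),
    )


def cure_index(k: float, k_ctr: float) -> float:
    """CI = 1 - k/k_ctr; 1 for a cure, 0 for control-like regrowth."""
    if k_ctr <= 0:
        raise InvalidParameterError(f"k_ctr must be > 0, got {k_ctr}")
    if k < 0:
        raise InvalidParameterError(f"k must be >= 0, got {k}")
    return 1.0 - k / k_ctr


@dataclass(frozen=True)
class DoseResponseParams:
    """Three-parameter logistic CI(dose) = A / (1 + B exp(-c dose))."""

    A: float  # plateau
    B: float  # scale
    c: float  # rate, per unit dose

    def __post_init__(self):
        if self.A <= 0 or self.B <= 0 or self.c <= 0:
            raise InvalidParameterError("A, B, c must be > 0")


# Published dose-response for BPD on RIF tumors (dose in mM of reacted
# singlet oxygen at 3 mm depth): CI = 1.08 / (1 + 3490 exp(-8.301 x)).
FIG7_DOSE_RESPONSE = DoseResponseParams(A=1.08, B=3490.0, c=8.301)


def logistic_ci(dose, params: DoseResponseParams = FIG7_DOSE_RESPONSE):
    """Predicted cure index at the given singlet-oxygen dose (mM)."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise InvalidParameterError("dose must be >= 0")
    out = params.A / (1.0 + params.B * np.exp(-params.c * dose))
    return float(out) if out.ndim == 0 else out


@dataclass
class DoseResponseFit:
    """Fitted logistic dose-response with residual diagnostics."""

    params: DoseResponseParams
    rms_residual: float
    residuals: np.ndarray

    def predict(self, dose):
        return logistic_ci(dose, self.params)


def correlate_outcomes(doses, cis) -> DoseResponseFit:
    """Fit the 3-parameter logistic CI(dose) by unweighted least squares.

    ``doses`` may be any dose metric (reacted singlet oxygen in mM, or an
    incident fluence in J/cm^2); the input scale is normalized internally so
    the multi-start fit is well-conditioned for either.  Comparing the RMS
    residuals of two metrics ranks their predictive value for outcome.
    """
    x = np.asarray(doses, dtype=float)
    y = np.asarray(cis, dtype=float)
    if x.size != y.size or x.size < 6:
        raise InvalidParameterError("need >= 6 matched (dose, CI) records")
    xscale = float(x.max())
    if xscale <= 0:
        raise InvalidParameterError("doses must contain positive values")
    xs = x / xscale

    a0 = max(float(y.max()), 1e-3)

    def resid(p):
        a, log_b, c = p
        return a / (1.0 + np.exp(log_b - c * xs)) - y

    best = None
    for log_b0, c0 in [(2.0, 4.0), (5.0, 8.0), (8.0, 12.0), (0.5, 1.0)]:
        try:
            res = least_squares(
                resid,
                np.array([a0, log_b0, c0]),
                bounds=([1e-6, -10.0, 1e-6], [10.0, 50.0, 500.0]),
                method="trf",
                xtol=1e-14,
                ftol=1e-14,
            )
        except Exception:  # noqa: BLE001
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailure("logistic fit did not converge from any start")
    a, log_b, c = best.x
    r = resid(best.x)
    return DoseResponseFit(
        params=DoseResponseParams(A=a, B=float(np.exp(log_b)), c=c / xscale),
        rms_residual=float(np.sqrt(np.mean(r**2))),
        residuals=r,
    )
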