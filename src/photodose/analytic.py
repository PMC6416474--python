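"""1-D analytic approximation of the beam-centre fluence-rate ratio.

For a broad collimated disc beam on semi-infinite turbid tissue the ratio of
in-tissue to in-air fluence rate at depth d is well approximated by

    phi/phi_air = (1 - b exp(-lambda1 d)) (C2 exp(-lambda2 d) + C3 exp(-lambda3 d))

a subsurface build-up factor multiplying a two-exponential decay.  The six
coefficients are functions of (mu_a, mu_s', mu_eff, Rd) for a given beam
diameter; here they are either supplied or recovered by nonlinear least
squares from a Monte Carlo centreline profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .exceptions import FitFailure, InvalidParameterError

__all__ = ["Eq5Params", "eq5_ratio", "fit_eq5", "Eq5FitResult"]


@dataclass(frozen=True)
class Eq5Params:
    """Coefficients of the two-exponential build-up model.

    ``rd`` and ``mu_eff`` are optional metadata recording the optical
    configuration the coefficients correspond to.
    """

    b: float
    lambda1: float  # 1/cm
    C2: float
    lambda2: float  # 1/cm
    C3: float
    lambda3: float  # 1/cm
    rd: float | None = None
    mu_eff: float | None = None

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda3) <= 0:
            raise InvalidParameterError("attenuation constants must be > 0")
        if self.rd is not None and not 0 <= self.rd < 1:
            raise InvalidParameterError("Rd must lie in [0, 1)")

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.b, self.lambda1, self.C2, self.lambda2, self.C3, self.lambda3]
        )


def eq5_ratio(d, params: Eq5Params):
    """phi/phi_air at depth(s) d (cm)."""
    d = np.asarray(d, dtype=float)
    p = params
    out = (1.0 - p.b * np.exp(-p.lambda1 * d)) * (
        p.C2 * np.exp(-p.lambda2 * d) + p.C3 * np.exp(-p.lambda3 * d)
    )
    return float(out) if out.ndim == 0 else out


@dataclass
class Eq5FitResult:
    """Fitted coefficients with residual diagnostics."""

    params: Eq5Params
    rms_residual: float
    residuals: np.ndarray
    cost: float


def _model(x, d):
    b, l1, c2, l2, c3, l3 = x
    return (1.0 - b * np.exp(-l1 * d)) * (c2 * np.exp(-l2 * d) + c3 * np.exp(-l3 * d))


def _varpro_resid(q, d, y):
    """Residual with the amplitudes projected out (solved by NNLS).

    ``q`` holds the nonlinear parameters (b, lambda1, lambda2, lambda3); for
    fixed q the model is linear in (C2, C3).
    """
    from scipy.optimize import nnls

    b, l1, l2, l3 = q
    build = 1.0 - b * np.exp(-l1 * d)
    basis = np.column_stack([build * np.exp(-l2 * d), build * np.exp(-l3 * d)])
    c, _ = nnls(basis, y)
    return basis @ c - y, c


def fit_eq5(
    depth,
    ratio,
    rd: float | None = None,
    mu_eff: float | None = None,
    max_rms_fraction: float = 0.05,
) -> Eq5FitResult:
    """Fit the six coefficients to a (depth, ratio) centreline profile.

    Trust-region least squares from three seeded initializations (the
    six-parameter exponential mixture is ill-conditioned); the best of the
    converged starts is returned.  Raises :class:`FitFailure` if no start
    converges to an RMS residual below ``max_rms_fraction`` of the peak ratio.
    """
    d = np.asarray(depth, dtype=float)
    y = np.asarray(ratio, dtype=float)
    if d.size != y.size or d.size < 12:
        raise InvalidParameterError("need >= 12 matched (depth, ratio) points")

    peak = float(y.max())
    if peak <= 0:
        raise InvalidParameterError("profile has no positive values")

    # data-driven scales: tail slope from the deepest third of the profile
    tail = slice(2 * d.size // 3, None)
    with np.errstate(divide="ignore"):
        logy = np.log(np.clip(y[tail], 1e-300, None))
    slope = -np.polyfit(d[tail], logy, 1)[0]
    lam = max(slope, 1.0 / (d.max() - d.min() + 1e-12))

    # stage 1: variable projection over the nonlinear (b, l1, l2, l3) from
    # several seeded starts; the amplitudes come from non-negative LS
    q_starts = [
        np.array([0.5, 5.0 * lam, lam, 3.0 * lam]),
        np.array([0.8, 10.0 * lam, 0.8 * lam, 6.0 * lam]),
        np.array([0.2, 2.0 * lam, 1.2 * lam, 10.0 * lam]),
        np.array([0.6, 8.0 * lam, lam, 1.5 * lam]),
    ]
    q_lower = np.array([0.0, 1e-6, 1e-6, 1e-6])
    q_upper = np.array([1.0, np.inf, np.inf, np.inf])
    x_starts = []
    for q0 in q_starts:
        try:
            qres = least_squares(
                lambda q: _varpro_resid(q, d, y)[0],
                np.clip(q0, q_lower, q_upper),
                bounds=(q_lower, q_upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
            _, c = _varpro_resid(qres.x, d, y)
            b, l1, l2, l3 = qres.x
            x_starts.append(np.array([b, l1, c[0], l2, c[1], l3]))
        except Exception:  # noqa: BLE001 - a failed start is not fatal
            continue
    x_starts.append(np.array([0.5, 5.0 * lam, peak, lam, 0.2 * peak, 2.0 * lam]))

    # stage 2: full six-parameter polish from each candidate
    lower = np.array([0.0, 1e-6, 0.0, 1e-6, 0.0, 1e-6])
    upper = np.array([1.0, np.inf, np.inf, np.inf, np.inf, np.inf])
    best = None
    for x0 in x_starts:
        try:
            res = least_squares(
                lambda x: _model(x, d) - y,
                np.clip(x0, lower, upper),
                bounds=(lower, upper),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:  # noqa: BLE001
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailure("no least-squares start converged")

    resid = _model(best.x, d) - y
    rms = float(np.sqrt(np.mean(resid**2)))
    if rms > max_rms_fraction * peak:
        raise FitFailure(
            f"fit residual {rms:.3g} exceeds {max_rms_fraction:.0%} of peak",
            residuals=resid,
        )
    b, l1, c2, l2, c3, l3 = best.x
    # canonical order: lambda2 is the slower (dominant-tail) decay
    if l3 < l2:
        c2, c3 = c3, c2
        l2, l3 = l3, l2
    params = Eq5Params(
        b=b, lambda1=l1, C2=c2, lambda2=l2, C3=c3, lambda3=l3, rd=rd, mu_eff=mu_eff
    )
    return Eq5FitResult(
        params=params, rms_residual=rms, residuals=resid, cost=float(best.cost)
    )
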