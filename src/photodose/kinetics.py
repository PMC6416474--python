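"""Macroscopic type-II PDT photokinetics.

Per-voxel time evolution of the ground-state photosensitizer concentration
[S0], the ground-state oxygen concentration [O2], and the cumulative reacted
singlet-oxygen concentration [O2^1]rx under a constant local fluence rate phi:

    d[S0]/dt   = -xi sigma phi ([S0] + delta) ([O2]/([O2] + beta)) [S0]
    d[O2]/dt   = -xi phi [S0] ([O2]/([O2] + beta)) + g (1 - [O2]/[O2](0))
    d[O2rx]/dt = +xi phi [S0] ([O2]/([O2] + beta))

with photobleaching (sigma), an oxygen-quenching threshold (beta), a
low-concentration correction (delta), a linear oxygen-resupply term with
maximum rate g, and the excitation-rate proportionality xi.  Concentrations
are in uM, phi in mW/cm^2 (so ``xi * phi`` has units 1/s), time in s.

The system is integrated by an embedded adaptive Runge-Kutta 5(4)
(Dormand-Prince) adjusted to keep every component non-negative at all
accepted steps.  phi is held constant over the treatment: a single transport
solution is applied to the whole session, i.e. optical properties are assumed
unaffected by photobleaching.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _pk_kernels as _pk
from .exceptions import (
    IntegrationFailure,
    InvalidParameterError,
    InvalidStateError,
)
from .mc import FluenceRateMap
from .optics import VoxelGrid

__all__ = [
    "PKParams",
    "PKState",
    "DoseMap",
    "pk_rhs",
    "integrate_pk",
    "dose_map",
    "dose_profile",
    "dose_at_depth",
    "BPD_PARAMS",
]


@dataclass(frozen=True)
class PKParams:
    """Photosensitizer kinetic constants.

    Defaults are the benzoporphyrin-derivative (BPD, Visudyne) values:
    g = 1.7 uM/s, delta = 33 uM, beta = 11.9 uM, sigma = 1.8e-5 1/uM,
    xi = 0.055 cm^2 mW^-1 s^-1, with 40 uM initial ground-state oxygen.
    """

    g_supply: float = 1.7  # uM/s, maximum oxygen resupply rate
    delta: float = 33.0  # uM, low-concentration correction
    beta: float = 11.9  # uM, oxygen quenching threshold
    sigma: float = 1.8e-5  # 1/uM, specific photobleaching ratio
    xi: float = 0.055  # cm^2 / (mW s), excitation-rate proportionality
    O2_initial: float = 40.0  # uM

    def __post_init__(self):
        for name in ("g_supply", "delta", "beta", "sigma", "xi", "O2_initial"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")


BPD_PARAMS = PKParams()


@dataclass
class PKState:
    """Kinetic state (all uM): sensitizer, oxygen, reacted singlet oxygen."""

    S0: float
    O2: float
    O2rx: float = 0.0

    def __post_init__(self):
        if self.S0 < 0 or self.O2 < 0 or self.O2rx < 0:
            raise InvalidStateError(f"negative concentration in {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.O2, self.O2rx])


def pk_rhs(state: PKState, phi: float, params: PKParams = BPD_PARAMS) -> np.ndarray:
    """Time derivatives (dS0, dO2, dO2rx) in uM/s at fluence rate phi."""
    if phi < 0:
        raise InvalidStateError(f"phi must be >= 0, got {phi}")
    if state.S0 < 0 or state.O2 < 0 or state.O2rx < 0:
        raise InvalidStateError(f"negative concentration in {state}")
    p = params
    frac = state.O2 / (state.O2 + p.beta)
    excit = p.xi * phi * state.S0 * frac
    return np.array(
        [
            -p.sigma * p.xi * phi * (state.S0 + p.delta) * frac * state.S0,
            -excit + p.g_supply * (1.0 - state.O2 / p.O2_initial),
            excit,
        ]
    )


def integrate_pk(
    phi: float,
    S0_init: float,
    params: PKParams = BPD_PARAMS,
    T: float = 600.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    first_step: float = 1e-3,
    O2_init: float | None = None,
    return_stats: bool = False,
    t_eval=None,
):
    """Integrate the kinetics from t=0 to t=T at constant phi.

    Returns the final :class:`PKState`; with ``t_eval`` (increasing times in
    [0, T]) returns ``(state, trajectory)`` where ``trajectory`` is an array
    of rows ``(t, S0, O2, O2rx)``; with ``return_stats`` a step-count dict is
    appended.  Raises :class:`IntegrationFailure` on step-size underflow,
    carrying the time reached.
    """
    if T < 0:
        raise InvalidParameterError("T must be >= 0")
    if S0_init < 0 or phi < 0:
        raise InvalidStateError("phi and S0_init must be >= 0")
    o2_0 = params.O2_initial if O2_init is None else O2_init
    kin = (
        params.g_supply,
        params.delta,
        params.beta,
        params.sigma,
        params.xi,
        params.O2_initial,
        rtol,
        atol,
        first_step,
    )

    checkpoints = [float(T)]
    if t_eval is not None:
        checkpoints = [float(t) for t in t_eval]
        if any(b < a for a, b in zip(checkpoints, checkpoints[1:])):
            raise InvalidParameterError("t_eval must be non-decreasing")
        if checkpoints and (checkpoints[0] < 0 or checkpoints[-1] > T):
            raise InvalidParameterError("t_eval must lie in [0, T]")
        if not checkpoints or checkpoints[-1] < T:
            checkpoints.append(float(T))

    s0, o2, o2rx = S0_init, o2_0, 0.0
    t_prev = 0.0
    n_acc = n_rej = 0
    rows = []
    for t_next in checkpoints:
        s0, o2, o2rx, acc, rej, status = _pk.integrate(
            phi, s0, o2, o2rx, t_next - t_prev, *kin
        )
        n_acc += acc
        n_rej += rej
        if status != 0:
            raise IntegrationFailure("adaptive step size underflow", t_reached=t_prev)
        rows.append((t_next, s0, o2, o2rx))
        t_prev = t_next

    state = PKState(S0=max(s0, 0.0), O2=max(o2, 0.0), O2rx=max(o2rx, 0.0))
    out = [state]
    if t_eval is not None:
        traj = np.array(rows)
        out.append(traj[: len(t_eval)])
    if return_stats:
        out.append({"n_accepted": int(n_acc), "n_rejected": int(n_rej)})
    return out[0] if len(out) == 1 else tuple(out)


@dataclass
class DoseMap:
    """3-D reacted-singlet-oxygen dose field [O2^1]rx in mM."""

    values: np.ndarray  # (nx, ny, nz), mM
    grid: VoxelGrid
    treatment_time: float  # s
    params: PKParams
    S0_initial: float | np.ndarray = field(default=0.0)

    @property
    def max_dose_mM(self) -> float:
        return float(self.values.max())


def _integration_args(params: PKParams, T, rtol, atol, first_step):
    return (
        params.O2_initial,
        T,
        params.g_supply,
        params.delta,
        params.beta,
        params.sigma,
        params.xi,
        rtol,
        atol,
        first_step,
    )


def dose_map(
    fluence: FluenceRateMap,
    S0_init,
    params: PKParams = BPD_PARAMS,
    T: float = 600.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
    first_step: float = 1e-3,
) -> DoseMap:
    """Integrate the kinetics independently in every voxel of a fluence map.

    ``S0_init`` is a uniform pre-treatment sensitizer concentration (uM) or a
    per-voxel field on the same grid.  Voxels with phi = 0 yield zero dose.
    Voxels are mutually independent, so any parallel schedule gives results
    identical to this serial loop.
    """
    grid = fluence.grid
    phi_flat = np.ascontiguousarray(fluence.values.ravel(), dtype=float)
    s0 = np.asarray(S0_init, dtype=float)
    if s0.ndim == 0:
        s0_flat = np.full(phi_flat.size, float(s0))
    else:
        if s0.shape != grid.shape:
            raise InvalidParameterError(
                f"S0_init shape {s0.shape} does not match grid {grid.shape}"
            )
        s0_flat = np.ascontiguousarray(s0.ravel())
    if np.any(s0_flat < 0) or np.any(phi_flat < 0):
        raise InvalidStateError("phi and S0_init must be >= 0")

    o2rx, status = _pk.dose_kernel(
        phi_flat, s0_flat, *_integration_args(params, T, rtol, atol, first_step)
    )
    if np.any(status != 0):
        bad = int(np.argmax(status != 0))
        raise IntegrationFailure(
            f"integration failed in voxel {np.unravel_index(bad, grid.shape)}"
        )
    return DoseMap(
        values=o2rx.reshape(grid.shape) / 1000.0,  # uM -> mM
        grid=grid,
        treatment_time=T,
        params=params,
        S0_initial=S0_init,
    )


def dose_profile(
    fluence: FluenceRateMap,
    S0_init: float,
    params: PKParams = BPD_PARAMS,
    T: float = 600.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> np.ndarray:
    """Depth profile of dose (mM) averaged over the beam-centre voxel columns.

    Integrates only the central 2x2 (or 1x1 for odd grids) columns; rows are
    ``(depth_cm, dose_mM)``.
    """
    grid = fluence.grid
    ci, cj = grid.center_columns()
    phi = np.ascontiguousarray(
        fluence.values[np.ix_(ci, cj)].reshape(-1, grid.nz).ravel()
    )
    s0_flat = np.full(phi.size, float(S0_init))
    o2rx, status = _pk.dose_kernel(
        phi, s0_flat, *_integration_args(params, T, rtol, atol, 1e-3)
    )
    if np.any(status != 0):
        raise IntegrationFailure("integration failed on the centre column")
    dose = o2rx.reshape(-1, grid.nz).mean(axis=0) / 1000.0
    return np.column_stack([grid.depths(), dose])


def dose_at_depth(dose: DoseMap | np.ndarray, depth: float, grid: VoxelGrid = None):
    """Beam-centre dose (mM) at a depth plane between two voxel layers.

    The plane must coincide with a voxel boundary; the result is the mean of
    the two adjacent layer values on the beam axis (layers 3&4 of a 1.0-mm
    grid, 6&7 of a 0.5-mm grid, 12&13 of a 0.25-mm grid for the 3-mm plane).
    Accepts a :class:`DoseMap`, or a ``(depth, value)`` profile from
    :func:`dose_profile` together with its grid.
    """
    if isinstance(dose, DoseMap):
        grid = dose.grid
        ci, cj = grid.center_columns()
        column = dose.values[np.ix_(ci, cj)].mean(axis=(0, 1))
    else:
        if grid is None:
            raise InvalidParameterError("grid required with a profile input")
        column = np.asarray(dose)[:, 1]
    h = grid.voxel_size
    layers = depth / h
    k_hi = int(round(layers))
    if abs(layers - k_hi) > 1e-6:
        raise InvalidParameterError(
            f"depth {depth} cm is not a voxel-boundary plane of h={h} cm"
        )
    if k_hi < 1 or k_hi >= grid.nz:
        raise InvalidParameterError(f"depth {depth} cm outside the grid")
    return float(0.5 * (column[k_hi - 1] + column[k_hi]))
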