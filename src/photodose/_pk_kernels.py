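"""Numba kernels for the photokinetic ODE system.

Dormand-Prince embedded RK5(4) with PI-free standard step control, adjusted
for non-negativity: any step whose 5th-order solution has a component below
-1e-12 uM is rejected and the step halved; accepted components with magnitude
below 1e-12 uM are clamped to zero.
"""

import numba as nb
import numpy as np

# Dormand-Prince coefficients
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = (
    19372.0 / 6561.0,
    -25360.0 / 2187.0,
    64448.0 / 6561.0,
    -212.0 / 729.0,
)
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = (
    35.0 / 384.0,
    500.0 / 1113.0,
    125.0 / 192.0,
    -2187.0 / 6784.0,
    11.0 / 84.0,
)
# error weights: b5 - b4star
_E1, _E3, _E4, _E5, _E6, _E7 = (
    35.0 / 384.0 - 5179.0 / 57600.0,
    500.0 / 1113.0 - 7571.0 / 16695.0,
    125.0 / 192.0 - 393.0 / 640.0,
    -2187.0 / 6784.0 + 92097.0 / 339200.0,
    11.0 / 84.0 - 187.0 / 2100.0,
    -1.0 / 40.0,
)

_CLAMP = 1e-12  # uM
_NEG_TOL = -1e-12  # uM


@nb.njit(cache=True, inline="always")
def _rhs(s0, o2, phi, g, delta, beta, sigma, xi, o2_init):
    """Time derivatives (dS0, dO2, dO2rx) in uM/s."""
    frac = o2 / (o2 + beta)
    ex = xi * phi * s0 * frac  # oxygen consumption = singlet-oxygen production
    ds0 = -sigma * xi * phi * (s0 + delta) * frac * s0
    do2 = -ex + g * (1.0 - o2 / o2_init)
    return ds0, do2, ex


@nb.njit(cache=True)
def integrate(
    phi, s0_0, o2_0, o2rx_0, T, g, delta, beta, sigma, xi, o2_init, rtol, atol, h0
):
    """Integrate the kinetics from 0 to T at constant fluence rate phi.

    Returns (S0, O2, O2rx, n_accepted, n_rejected, status); status 0 = ok,
    1 = step-size underflow (state then holds the last accepted point, and
    n_accepted/n_rejected are still meaningful).
    """
    y0, y1, y2 = s0_0, o2_0, o2rx_0
    t = 0.0
    h = h0
    n_acc = 0
    n_rej = 0
    if T <= 0.0:
        return y0, y1, y2, 0, 0, 0

    k10, k11, k12 = _rhs(y0, y1, phi, g, delta, beta, sigma, xi, o2_init)
    while t < T:
        if h > T - t:
            h = T - t
        # stages
        a0 = y0 + h * _A21 * k10
        a1 = y1 + h * _A21 * k11
        k20, k21, k22 = _rhs(a0, a1, phi, g, delta, beta, sigma, xi, o2_init)

        a0 = y0 + h * (_A31 * k10 + _A32 * k20)
        a1 = y1 + h * (_A31 * k11 + _A32 * k21)
        k30, k31, k32 = _rhs(a0, a1, phi, g, delta, beta, sigma, xi, o2_init)

        a0 = y0 + h * (_A41 * k10 + _A42 * k20 + _A43 * k30)
        a1 = y1 + h * (_A41 * k11 + _A42 * k21 + _A43 * k31)
        k40, k41, k42 = _rhs(a0, a1, phi, g, delta, beta, sigma, xi, o2_init)

        a0 = y0 + h * (_A51 * k10 + _A52 * k20 + _A53 * k30 + _A54 * k40)
        a1 = y1 + h * (_A51 * k11 + _A52 * k21 + _A53 * k31 + _A54 * k41)
        k50, k51, k52 = _rhs(a0, a1, phi, g, delta, beta, sigma, xi, o2_init)

        a0 = y0 + h * (_A61 * k10 + _A62 * k20 + _A63 * k30 + _A64 * k40 + _A65 * k50)
        a1 = y1 + h * (_A61 * k11 + _A62 * k21 + _A63 * k31 + _A64 * k41 + _A65 * k51)
        k60, k61, k62 = _rhs(a0, a1, phi, g, delta, beta, sigma, xi, o2_init)

        z0 = y0 + h * (_B1 * k10 + _B3 * k30 + _B4 * k40 + _B5 * k50 + _B6 * k60)
        z1 = y1 + h * (_B1 * k11 + _B3 * k31 + _B4 * k41 + _B5 * k51 + _B6 * k61)
        z2 = y2 + h * (_B1 * k12 + _B3 * k32 + _B4 * k42 + _B5 * k52 + _B6 * k62)

        k70, k71, k72 = _rhs(z0, z1, phi, g, delta, beta, sigma, xi, o2_init)

        # non-negativity: reject and halve
        if z0 < _NEG_TOL or z1 < _NEG_TOL or z2 < _NEG_TOL:
            n_rej += 1
            h *= 0.5
            if h < 1e-12:
                return y0, y1, y2, n_acc, n_rej, 1
            continue

        e0 = h * (_E1 * k10 + _E3 * k30 + _E4 * k40 + _E5 * k50 + _E6 * k60 + _E7 * k70)
        e1 = h * (_E1 * k11 + _E3 * k31 + _E4 * k41 + _E5 * k51 + _E6 * k61 + _E7 * k71)
        e2 = h * (_E1 * k12 + _E3 * k32 + _E4 * k42 + _E5 * k52 + _E6 * k62 + _E7 * k72)

        s0_ = atol + rtol * max(abs(y0), abs(z0))
        s1_ = atol + rtol * max(abs(y1), abs(z1))
        s2_ = atol + rtol * max(abs(y2), abs(z2))
        err = np.sqrt(((e0 / s0_) ** 2 + (e1 / s1_) ** 2 + (e2 / s2_) ** 2) / 3.0)

        if err <= 1.0:
            t += h
            y0, y1, y2 = z0, z1, z2
            if -_CLAMP < y0 < _CLAMP:
                y0 = 0.0
            if -_CLAMP < y1 < _CLAMP:
                y1 = 0.0
            if -_CLAMP < y2 < _CLAMP:
                y2 = 0.0
            k10, k11, k12 = k70, k71, k72  # FSAL
            n_acc += 1
            fac = 5.0 if err == 0.0 else min(5.0, max(0.2, 0.9 * err**-0.2))
            h *= fac
        else:
            n_rej += 1
            h *= max(0.2, 0.9 * err**-0.2)
            if h < 1e-12:
                return y0, y1, y2, n_acc, n_rej, 1
    return y0, y1, y2, n_acc, n_rej, 0


@nb.njit(cache=True)
def dose_kernel(
    phi_flat, s0_flat, o2_init, T, g, delta, beta, sigma, xi, rtol, atol, h0
):
    """Integrate every voxel independently; return (O2rx uM, status) arrays.

    Voxels with phi == 0 produce no singlet oxygen and are skipped.
    """
    nvox = phi_flat.size
    out = np.zeros(nvox)
    status = np.zeros(nvox, dtype=np.int8)
    for v in range(nvox):
        phi = phi_flat[v]
        if phi <= 0.0:
            continue
        _, _, o2rx, _, _, st = integrate(
            phi,
            s0_flat[v],
            o2_init,
            0.0,
            T,
            g,
            delta,
            beta,
            sigma,
            xi,
            o2_init,
            rtol,
            atol,
            h0,
        )
        out[v] = o2rx
        status[v] = st
    return out, status
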