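"""Numba kernels for voxel-based photon transport.

One packet at a time, sequentially over packets, with a counter-based
per-packet RNG substream (splitmix64-seeded xorshift128+) indexed by
(seed, packet id).  Tallies are therefore independent of any scheduling
and bit-identical across repeated runs with the same seed.
"""

import numba as nb
import numpy as np

U64 = np.uint64
_SM_GAMMA = U64(0x9E3779B97F4A7C15)
_SM_M1 = U64(0xBF58476D1CE4E5B9)
_SM_M2 = U64(0x94D049BB133111EB)
_INV53 = 1.0 / 9007199254740992.0  # 2^-53

# exit/termination codes
EXIT_DIFFUSE = 1  # escaped through the illuminated z=0 face
EXIT_TRANSMIT = 2  # escaped through any other exterior face
EXIT_KILLED = 3  # terminated by roulette loss / truncation


@nb.njit(cache=True, inline="always")
def _splitmix64(state):
    state = state + _SM_GAMMA
    z = state
    z = (z ^ (z >> U64(30))) * _SM_M1
    z = (z ^ (z >> U64(27))) * _SM_M2
    z = z ^ (z >> U64(31))
    return state, z


@nb.njit(cache=True, inline="always")
def _init_rng(seed, packet_id):
    s = U64(seed) * _SM_M1 ^ U64(packet_id) * _SM_GAMMA
    s, s0 = _splitmix64(s)
    s, s1 = _splitmix64(s)
    if s0 == U64(0) and s1 == U64(0):
        s1 = _SM_GAMMA
    return s0, s1


@nb.njit(cache=True, inline="always")
def _next_u64(s0, s1):
    # xorshift128+
    x = s0
    y = s1
    s0 = y
    x ^= x << U64(23)
    s1 = x ^ y ^ (x >> U64(17)) ^ (y >> U64(26))
    return s0, s1, s1 + y


@nb.njit(cache=True, inline="always")
def _uniform(s0, s1):
    """Uniform double in [0, 1)."""
    s0, s1, z = _next_u64(s0, s1)
    return s0, s1, float(z >> U64(11)) * _INV53


@nb.njit(cache=True, inline="always")
def _fresnel(n1, n2, cos_i):
    """Unpolarized Fresnel reflectance for incidence cosine cos_i in [0,1]."""
    if cos_i > 1.0:
        cos_i = 1.0
    sin2_i = 1.0 - cos_i * cos_i
    ratio = n1 / n2
    sin2_t = ratio * ratio * sin2_i
    if sin2_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin2_t)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


@nb.njit(cache=True, inline="always")
def _hg_cos(g, u):
    """Sample the deflection cosine of the Henyey-Greenstein phase function."""
    if g == 0.0:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if ct > 1.0:
        ct = 1.0
    elif ct < -1.0:
        ct = -1.0
    return ct


@nb.njit(cache=True, inline="always")
def _scatter(ux, uy, uz, ct, phi):
    """Rotate a unit direction by deflection cosine ct and azimuth phi."""
    st = np.sqrt(max(0.0, 1.0 - ct * ct))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.99999:
        nx = st * cp
        ny = st * sp
        nz = ct if uz >= 0.0 else -ct
    else:
        den = np.sqrt(1.0 - uz * uz)
        nx = st * (ux * uz * cp - uy * sp) / den + ux * ct
        ny = st * (uy * uz * cp + ux * sp) / den + uy * ct
        nz = -st * cp * den + uz * ct
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


# tally slots in the balance vector
B_SPEC = 0
B_DIFF = 1
B_TRANS = 2
B_DEPOSIT = 3
B_RKILL = 4
B_RGAIN = 5


@nb.njit(cache=True)
def _trace_packet(
    pid,
    seed,
    nx,
    ny,
    nz,
    h,
    pidx,
    mu_a,
    mu_s,
    g_arr,
    n_arr,
    beam_radius,
    cx,
    cy,
    w_threshold,
    roulette,
    absorbed,
    tracklen,
    balance,
    rec_idx,
    rec_w,
    max_rec,
):
    """Trace one packet; tally into absorbed/tracklen/balance.

    If ``max_rec > 0`` every deposition is also appended to (rec_idx, rec_w).
    Returns (exit_code, remaining weight, number of recorded depositions).
    """
    s0, s1 = _init_rng(seed, pid)

    # launch position uniform over the source disc; direction +z
    s0, s1, u1 = _uniform(s0, s1)
    s0, s1, u2 = _uniform(s0, s1)
    r = beam_radius * np.sqrt(u1)
    ang = 2.0 * np.pi * u2
    x = cx + r * np.cos(ang)
    y = cy + r * np.sin(ang)
    z = 0.0
    ux = 0.0
    uy = 0.0
    uz = 1.0

    i = int(x / h)
    j = int(y / h)
    if i >= nx:
        i = nx - 1
    if j >= ny:
        j = ny - 1
    k = 0

    # specular split at the air-target interface (normal incidence)
    n_t = n_arr[pidx[(i * ny + j) * nz + k]]
    r_spec = _fresnel(1.0, n_t, 1.0)
    balance[B_SPEC] += r_spec
    w = 1.0 - r_spec

    nrec = 0
    # free-flight optical depth (dimensionless); rescaled across voxels
    s0, s1, u = _uniform(s0, s1)
    tau = -np.log(1.0 - u)

    while True:
        cell = pidx[(i * ny + j) * nz + k]
        mua = mu_a[cell]
        mus = mu_s[cell]

        # distance to the next voxel face along the current direction
        d_b = 1e30
        axis = -1
        if ux > 0.0:
            d = ((i + 1) * h - x) / ux
            if d < d_b:
                d_b = d
                axis = 0
        elif ux < 0.0:
            d = (i * h - x) / ux
            if d < d_b:
                d_b = d
                axis = 0
        if uy > 0.0:
            d = ((j + 1) * h - y) / uy
            if d < d_b:
                d_b = d
                axis = 1
        elif uy < 0.0:
            d = (j * h - y) / uy
            if d < d_b:
                d_b = d
                axis = 1
        if uz > 0.0:
            d = ((k + 1) * h - z) / uz
            if d < d_b:
                d_b = d
                axis = 2
        elif uz < 0.0:
            d = (k * h - z) / uz
            if d < d_b:
                d_b = d
                axis = 2
        if d_b < 0.0:
            d_b = 0.0

        d_s = tau / mus if mus > 0.0 else 1e30
        to_boundary = d_b <= d_s
        step = d_b if to_boundary else d_s

        # deposit absorbed weight along the segment
        if step > 0.0:
            flat = (i * ny + j) * nz + k
            if mua > 0.0:
                dw = w * (1.0 - np.exp(-mua * step))
                absorbed[flat] += dw
                balance[B_DEPOSIT] += dw
                if max_rec > 0 and nrec < max_rec:
                    rec_idx[nrec] = flat
                    rec_w[nrec] = dw
                    nrec += 1
                w -= dw
            else:
                tracklen[flat] += w * step

        if to_boundary:
            tau -= mus * d_b
            if tau < 0.0:
                tau = 0.0
            # advance to the face, snap the crossing coordinate exactly
            x += ux * d_b
            y += uy * d_b
            z += uz * d_b
            if axis == 0:
                step_dir = 1 if ux > 0.0 else -1
                x = (i + (1 if step_dir > 0 else 0)) * h
                ni, nj, nk = i + step_dir, j, k
                cos_face = abs(ux)
            elif axis == 1:
                step_dir = 1 if uy > 0.0 else -1
                y = (j + (1 if step_dir > 0 else 0)) * h
                ni, nj, nk = i, j + step_dir, k
                cos_face = abs(uy)
            else:
                step_dir = 1 if uz > 0.0 else -1
                z = (k + (1 if step_dir > 0 else 0)) * h
                ni, nj, nk = i, j, k + step_dir
                cos_face = abs(uz)

            outside = ni < 0 or ni >= nx or nj < 0 or nj >= ny or nk < 0 or nk >= nz
            if outside:
                n_in = n_arr[cell]
                refl = _fresnel(n_in, 1.0, cos_face)
                s0, s1, u = _uniform(s0, s1)
                if u < refl:
                    # internally reflected: flip the crossing component
                    if axis == 0:
                        ux = -ux
                    elif axis == 1:
                        uy = -uy
                    else:
                        uz = -uz
                else:
                    # escapes; tallied, not geometrically refracted
                    if axis == 2 and step_dir < 0:
                        balance[B_DIFF] += w
                        return EXIT_DIFFUSE, w, nrec
                    balance[B_TRANS] += w
                    return EXIT_TRANSMIT, w, nrec
            else:
                i, j, k = ni, nj, nk
        else:
            # scattering event
            x += ux * d_s
            y += uy * d_s
            z += uz * d_s
            # roulette / truncation checked at scattering sites only, so RNG
            # consumption does not depend on the voxel size
            if w < w_threshold:
                if roulette:
                    s0, s1, u = _uniform(s0, s1)
                    if u < 0.1:
                        balance[B_RGAIN] += 9.0 * w
                        w *= 10.0
                    else:
                        balance[B_RKILL] += w
                        return EXIT_KILLED, w, nrec
                else:
                    balance[B_RKILL] += w
                    return EXIT_KILLED, w, nrec
            g = g_arr[cell]
            s0, s1, u = _uniform(s0, s1)
            ct = _hg_cos(g, u)
            s0, s1, u = _uniform(s0, s1)
            ux, uy, uz = _scatter(ux, uy, uz, ct, 2.0 * np.pi * u)
            s0, s1, u = _uniform(s0, s1)
            tau = -np.log(1.0 - u)


@nb.njit(cache=True)
def run_transport(
    n_photons,
    seed,
    nx,
    ny,
    nz,
    h,
    pidx,
    mu_a,
    mu_s,
    g_arr,
    n_arr,
    beam_radius,
    cx,
    cy,
    w_threshold,
    roulette,
    photon_offset,
):
    """Trace packets ``photon_offset .. photon_offset + n_photons - 1``.

    Returns (absorbed, tracklen, balance).  Because each packet's RNG
    substream is indexed by its id, disjoint offset ranges tile the photon
    set of a single larger run exactly.
    """
    absorbed = np.zeros(nx * ny * nz)
    tracklen = np.zeros(nx * ny * nz)
    balance = np.zeros(6)
    dummy_i = np.empty(0, dtype=np.int64)
    dummy_w = np.empty(0)
    for pid in range(photon_offset, photon_offset + n_photons):
        _trace_packet(
            pid,
            seed,
            nx,
            ny,
            nz,
            h,
            pidx,
            mu_a,
            mu_s,
            g_arr,
            n_arr,
            beam_radius,
            cx,
            cy,
            w_threshold,
            roulette,
            absorbed,
            tracklen,
            balance,
            dummy_i,
            dummy_w,
            0,
        )
    return absorbed, tracklen, balance


@nb.njit(cache=True)
def trace_one(
    pid,
    seed,
    nx,
    ny,
    nz,
    h,
    pidx,
    mu_a,
    mu_s,
    g_arr,
    n_arr,
    beam_radius,
    cx,
    cy,
    w_threshold,
    roulette,
    max_rec,
):
    """Trace a single packet recording each deposition (debug/inspection)."""
    absorbed = np.zeros(nx * ny * nz)
    tracklen = np.zeros(nx * ny * nz)
    balance = np.zeros(6)
    rec_idx = np.empty(max_rec, dtype=np.int64)
    rec_w = np.empty(max_rec)
    code, w, nrec = _trace_packet(
        pid,
        seed,
        nx,
        ny,
        nz,
        h,
        pidx,
        mu_a,
        mu_s,
        g_arr,
        n_arr,
        beam_radius,
        cx,
        cy,
        w_threshold,
        roulette,
        absorbed,
        tracklen,
        balance,
        rec_idx,
        rec_w,
        max_rec,
    )
    return code, w, rec_idx[:nrec], rec_w[:nrec], balance
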