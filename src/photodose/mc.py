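"""Voxel-based Monte Carlo photon transport.

Millions of photon packets are launched from a collimated disc source in air
onto the ``z = 0`` face of a voxel grid.  Specular reflection is split off at
entry (unpolarized Fresnel, normal incidence), free paths are sampled from the
local scattering coefficient and carried across voxel faces as a dimensionless
optical depth, the Henyey-Greenstein phase function redirects packets at each
scattering site, weight is deposited continuously along every traversed voxel
(factor ``exp(-mu_a l)``), and index-mismatched Fresnel reflection is applied
at all six exterior faces.  Low-weight packets are terminated by Russian
roulette (unbiased) or plain truncation.

The absorbed-weight tallies convert to fluence rate via
``phi_v = A_v * P / (mu_a_v * V_voxel * N)`` (track-length estimator in
non-absorbing voxels, where the absorbed-weight form is undefined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _mc_kernels as _k
from .exceptions import InvalidParameterError, TransportError
from .optics import SourceSpec, VoxelGrid

__all__ = [
    "sample_free_path",
    "fresnel_unpolarized",
    "hg_sample",
    "propagate_photon",
    "run_mc",
    "combine_maps",
    "diffuse_reflectance",
    "centerline_profile",
    "FluenceRateMap",
    "EnergyBalance",
]


def sample_free_path(u, mu_s: float):
    """Exponential free path ``-ln(u)/mu_s`` (cm) from a deviate u in (0,1].

    The mean free path between scattering events is ``1/mu_s``.
    """
    if mu_s <= 0:
        raise InvalidParameterError(f"mu_s must be > 0, got {mu_s}")
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u > 1):
        raise InvalidParameterError("u must lie in (0, 1]")
    out = -np.log(u) / mu_s
    return float(out) if out.ndim == 0 else out


def fresnel_unpolarized(n1: float, n2: float, cos_theta_i) -> float:
    """Unpolarized Fresnel reflectance (mean of s and p power reflectances).

    Returns 1.0 beyond the critical angle when ``n1 > n2``.
    """
    if n1 < 1 or n2 < 1:
        raise InvalidParameterError("refractive indices must be >= 1")
    c = np.asarray(cos_theta_i, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise InvalidParameterError("cos_theta_i must lie in [0, 1]")
    sin2_i = 1.0 - c**2
    sin2_t = (n1 / n2) ** 2 * sin2_i
    with np.errstate(invalid="ignore"):
        cos_t = np.sqrt(np.clip(1.0 - sin2_t, 0.0, None))
        rs = (n1 * c - n2 * cos_t) / (n1 * c + n2 * cos_t)
        rp = (n1 * cos_t - n2 * c) / (n1 * cos_t + n2 * c)
        r = 0.5 * (rs**2 + rp**2)
    r = np.where(sin2_t >= 1.0, 1.0, r)
    return float(r) if r.ndim == 0 else r


def hg_sample(g_aniso: float, u):
    """Henyey-Greenstein deflection cosine for deviate(s) u in [0, 1).

    ``cos_theta = (1/2g) [1 + g^2 - ((1-g^2)/(1-g+2gu))^2]`` for g != 0 and
    the isotropic limit ``2u - 1`` for g = 0.  The mean over u equals g.
    """
    if not abs(g_aniso) < 1:
        raise InvalidParameterError(f"|g_aniso| must be < 1, got {g_aniso}")
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u >= 1):
        raise InvalidParameterError("u must lie in [0, 1)")
    if g_aniso == 0.0:
        ct = 2.0 * u - 1.0
    else:
        g = g_aniso
        tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
        ct = (1.0 + g * g - tmp**2) / (2.0 * g)
    ct = np.clip(ct, -1.0, 1.0)
    return float(ct) if ct.ndim == 0 else ct


@dataclass(frozen=True)
class EnergyBalance:
    """Launched-weight fractions; the four fields sum to 1."""

    specular_reflected: float
    diffuse_reflected: float
    transmitted: float
    absorbed: float

    @property
    def total(self) -> float:
        return (
            self.specular_reflected
            + self.diffuse_reflected
            + self.transmitted
            + self.absorbed
        )

    def as_dict(self) -> dict:
        return {
            "specular_reflected": self.specular_reflected,
            "diffuse_reflected": self.diffuse_reflected,
            "transmitted": self.transmitted,
            "absorbed": self.absorbed,
        }


@dataclass
class FluenceRateMap:
    """3-D fluence-rate field phi (mW/cm^2) on a voxel grid."""

    values: np.ndarray  # (nx, ny, nz), mW/cm^2
    grid: VoxelGrid
    source: SourceSpec
    n_photons: int
    energy_balance: EnergyBalance

    def scaled_to(self, incident_fluence_rate: float) -> "FluenceRateMap":
        """The same transport solution rescaled to a new incident rate.

        Photon transport is linear in source power, so for identical optics
        the fluence-rate field scales exactly with the in-air fluence rate.
        """
        if incident_fluence_rate < 0:
            raise InvalidParameterError("incident_fluence_rate must be >= 0")
        factor = (
            incident_fluence_rate / self.source.incident_fluence_rate
            if self.source.incident_fluence_rate > 0
            else 0.0
        )
        return FluenceRateMap(
            values=self.values * factor,
            grid=self.grid,
            source=SourceSpec(self.source.beam_diameter, incident_fluence_rate),
            n_photons=self.n_photons,
            energy_balance=self.energy_balance,
        )


def _kernel_args(grid: VoxelGrid, source: SourceSpec):
    mu_a, mu_s, g, n = grid.property_arrays()
    ex, ey, _ = grid.extent
    return (
        grid.nx,
        grid.ny,
        grid.nz,
        grid.voxel_size,
        np.ascontiguousarray(grid.property_index.ravel()),
        mu_a,
        mu_s,
        g,
        n,
        source.beam_diameter / 2.0,
        ex / 2.0,
        ey / 2.0,
    )


def propagate_photon(
    photon_id: int,
    grid: VoxelGrid,
    source: SourceSpec,
    seed: int,
    weight_threshold: float = 1e-4,
    roulette: bool = True,
    max_records: int = 200_000,
):
    """Trace one packet, returning its full deposition list and exit record.

    Returns ``(depositions, exit_record)`` where ``depositions`` is a list of
    ``((i, j, k), weight)`` and ``exit_record`` a dict with the exit kind
    (``"diffuse"``, ``"transmitted"``, ``"terminated"``) and final weight.
    """
    if not 0 < weight_threshold < 1:
        raise InvalidParameterError("weight_threshold must lie in (0, 1)")
    code, w, idx, dw, balance = _k.trace_one(
        photon_id,
        seed,
        *_kernel_args(grid, source),
        weight_threshold,
        roulette,
        max_records,
    )
    if len(idx) >= max_records:
        raise TransportError("deposition record buffer overflow")
    ny, nz = grid.ny, grid.nz
    deps = [
        ((int(f // (ny * nz)), int((f // nz) % ny), int(f % nz)), float(v))
        for f, v in zip(idx, dw)
    ]
    kind = {1: "diffuse", 2: "transmitted", 3: "terminated"}[int(code)]
    return deps, {"exit": kind, "weight": float(w), "specular": float(balance[0])}


def run_mc(
    grid: VoxelGrid,
    source: SourceSpec,
    n_photons: int,
    seed: int = 0,
    weight_threshold: float = 1e-4,
    roulette: bool = True,
    photon_offset: int = 0,
) -> FluenceRateMap:
    """Launch ``n_photons`` packets and estimate the fluence-rate map.

    Packets start uniformly over the source disc in air, travel losslessly to
    the surface, and undergo the specular split there.  Runs are bit-identical
    for a fixed seed (per-packet RNG substreams, fixed-order reduction).
    ``photon_offset`` selects the packet-id range, so several runs with
    disjoint ranges partition the photon set of one larger run; see
    :func:`combine_maps`.
    """
    if n_photons < 1:
        raise InvalidParameterError("n_photons must be >= 1")
    if not 0 < weight_threshold < 1:
        raise InvalidParameterError("weight_threshold must lie in (0, 1)")
    if n_photons < 10_000:
        warnings.warn(
            f"n_photons={n_photons} is small; fluence estimates will be noisy",
            stacklevel=2,
        )
    absorbed, tracklen, balance = _k.run_transport(
        n_photons,
        seed,
        *_kernel_args(grid, source),
        weight_threshold,
        roulette,
        photon_offset,
    )
    spec, diff, trans, deposited, rkill, rgain = balance
    # roulette net loss joins the absorbed bucket so the balance closes exactly
    absorbed_total = deposited + rkill - rgain
    eb = EnergyBalance(
        specular_reflected=spec / n_photons,
        diffuse_reflected=diff / n_photons,
        transmitted=trans / n_photons,
        absorbed=absorbed_total / n_photons,
    )
    if abs(eb.total - 1.0) > 1e-6:
        raise TransportError(f"energy balance violated: total={eb.total!r}")

    mu_a, _, _, _ = grid.property_arrays()
    mu_a_vox = mu_a[grid.property_index]  # (nx, ny, nz)
    v = grid.voxel_volume
    p_mw = source.power_mW
    a = absorbed.reshape(grid.shape)
    t = tracklen.reshape(grid.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        phi = np.where(
            mu_a_vox > 0,
            a * p_mw / (np.maximum(mu_a_vox, 1e-300) * v * n_photons),
            t * p_mw / (v * n_photons),
        )
    return FluenceRateMap(
        values=phi,
        grid=grid,
        source=source,
        n_photons=n_photons,
        energy_balance=eb,
    )


def combine_maps(maps: list[FluenceRateMap]) -> FluenceRateMap:
    """Pool independent batches (same grid/source/seed, disjoint photon
    ranges) into the photon-weighted single-run estimate."""
    if not maps:
        raise InvalidParameterError("no maps to combine")
    n_tot = sum(m.n_photons for m in maps)
    values = sum(m.values * m.n_photons for m in maps) / n_tot
    eb = EnergyBalance(
        specular_reflected=sum(
            m.energy_balance.specular_reflected * m.n_photons for m in maps
        )
        / n_tot,
        diffuse_reflected=sum(
            m.energy_balance.diffuse_reflected * m.n_photons for m in maps
        )
        / n_tot,
        transmitted=sum(m.energy_balance.transmitted * m.n_photons for m in maps)
        / n_tot,
        absorbed=sum(m.energy_balance.absorbed * m.n_photons for m in maps) / n_tot,
    )
    first = maps[0]
    return FluenceRateMap(
        values=values,
        grid=first.grid,
        source=first.source,
        n_photons=n_tot,
        energy_balance=eb,
    )


def diffuse_reflectance(fluence_map: FluenceRateMap) -> float:
    """Diffuse reflectance Rd: launched-weight fraction escaping the
    illuminated face, excluding the specular component."""
    return fluence_map.energy_balance.diffuse_reflected


def centerline_profile(fluence_map: FluenceRateMap) -> np.ndarray:
    """Depth profile of phi/phi_air on the beam axis.

    Returns an array of rows ``(depth_cm, phi_mW_per_cm2, ratio)`` at voxel
    centres; with an even lateral voxel count the 2x2 columns adjacent to the
    axis are averaged.
    """
    grid = fluence_map.grid
    ci, cj = grid.center_columns()
    col = fluence_map.values[np.ix_(ci, cj)].mean(axis=(0, 1))
    depths = grid.depths()
    phi_air = fluence_map.source.incident_fluence_rate
    ratio = col / phi_air if phi_air > 0 else np.zeros_like(col)
    return np.column_stack([depths, col, ratio])
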