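"""Optical property records, the voxel grid, source geometry and phantoms.

Conventions (fixed throughout the package):

* lengths in cm, cubic voxels of edge ``voxel_size``;
* 0-based voxel indices, voxel ``(i, j, k)`` spans the half-open box
  ``[i*h, (i+1)*h) x [j*h, (j+1)*h) x [k*h, (k+1)*h)``;
* the illuminated surface is the ``z = 0`` face, depth increases with ``k``;
* the beam axis passes through the lateral centre of the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError

__all__ = [
    "OpticalProperties",
    "VoxelGrid",
    "SourceSpec",
    "Phantom",
    "make_phantom",
]


@dataclass(frozen=True)
class OpticalProperties:
    """Homogeneous optical properties of a tissue type.

    Parameters
    ----------
    mu_a : float
        Absorption coefficient (1/cm), >= 0.
    mu_s_prime : float
        Reduced scattering coefficient mu_s' = mu_s (1 - g) (1/cm), > 0.
    g_aniso : float
        Scattering anisotropy (mean cosine of the deflection angle), |g| < 1.
    n : float
        Refractive index, >= 1.
    """

    mu_a: float
    mu_s_prime: float
    g_aniso: float = 0.9
    n: float = 1.4

    def __post_init__(self):
        if self.mu_a < 0:
            raise InvalidParameterError(f"mu_a must be >= 0, got {self.mu_a}")
        if self.mu_s_prime <= 0:
            raise InvalidParameterError(
                f"mu_s_prime must be > 0, got {self.mu_s_prime}"
            )
        if not abs(self.g_aniso) < 1:
            raise InvalidParameterError(f"|g_aniso| must be < 1, got {self.g_aniso}")
        if self.n < 1:
            raise InvalidParameterError(f"n must be >= 1, got {self.n}")

    @property
    def mu_s(self) -> float:
        """Scattering coefficient mu_s = mu_s' / (1 - g) (1/cm)."""
        return self.mu_s_prime / (1.0 - self.g_aniso)

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3 mu_a (mu_a + mu_s')) (1/cm)."""
        return float(np.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime)))


# Tumour-typical defaults used for every homogeneous run unless overridden.
DEFAULT_OPTICS = OpticalProperties(mu_a=0.69, mu_s_prime=11.0, g_aniso=0.9, n=1.4)


@dataclass
class VoxelGrid:
    """A rectangular grid of identical cubic voxels with per-voxel optics.

    ``property_index[i, j, k]`` selects one of ``properties``; a homogeneous
    grid has a single property record and an all-zero index array.
    """

    nx: int
    ny: int
    nz: int
    voxel_size: float
    properties: list[OpticalProperties]
    property_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if min(self.nx, self.ny, self.nz) < 1:
            raise InvalidParameterError("voxel counts must be >= 1")
        if self.voxel_size <= 0:
            raise InvalidParameterError("voxel_size must be > 0 cm")
        if not self.properties:
            raise InvalidParameterError("at least one OpticalProperties required")
        if self.property_index is None:
            self.property_index = np.zeros(self.shape, dtype=np.int32)
        self.property_index = np.ascontiguousarray(
            self.property_index, dtype=np.int32
        )
        if self.property_index.shape != self.shape:
            raise InvalidParameterError(
                f"property_index shape {self.property_index.shape} != {self.shape}"
            )
        if self.property_index.min() < 0 or self.property_index.max() >= len(
            self.properties
        ):
            raise InvalidParameterError("property_index out of range")

    @classmethod
    def homogeneous(
        cls, n: int, voxel_size: float, optics: OpticalProperties = DEFAULT_OPTICS
    ) -> "VoxelGrid":
        return cls(n, n, n, voxel_size, [optics])

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.nx, self.ny, self.nz)

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical edge lengths (cm)."""
        h = self.voxel_size
        return (self.nx * h, self.ny * h, self.nz * h)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume (cm^3)."""
        return self.voxel_size**3

    def depths(self) -> np.ndarray:
        """Voxel-centre depths (cm) of each layer below the surface."""
        h = self.voxel_size
        return (np.arange(self.nz) + 0.5) * h

    def center_columns(self) -> tuple[np.ndarray, np.ndarray]:
        """Lateral indices of the voxel columns adjacent to the beam axis.

        With an even voxel count the axis lies on a voxel boundary, so the
        four (2x2) central columns straddle it; with an odd count the single
        central column contains it.
        """
        def _central(n: int) -> np.ndarray:
            if n % 2 == 0:
                return np.array([n // 2 - 1, n // 2])
            return np.array([n // 2])

        return _central(self.nx), _central(self.ny)

    def property_arrays(self):
        """Flat per-type arrays (mu_a, mu_s, g, n) for the transport kernel."""
        mu_a = np.array([p.mu_a for p in self.properties])
        mu_s = np.array([p.mu_s for p in self.properties])
        g = np.array([p.g_aniso for p in self.properties])
        n = np.array([p.n for p in self.properties])
        return mu_a, mu_s, g, n


@dataclass(frozen=True)
class SourceSpec:
    """Collimated disc beam in air, normal to the z=0 face, uniform profile.

    ``incident_fluence_rate`` is the in-air fluence rate (mW/cm^2); the total
    power follows from the disc area.
    """

    beam_diameter: float  # cm
    incident_fluence_rate: float  # mW/cm^2

    def __post_init__(self):
        if self.beam_diameter <= 0:
            raise InvalidParameterError("beam_diameter must be > 0 cm")
        if self.incident_fluence_rate < 0:
            raise InvalidParameterError("incident_fluence_rate must be >= 0")

    @property
    def area(self) -> float:
        """Disc area (cm^2); 0.7854 cm^2 for the 10-mm beam."""
        return float(np.pi * (self.beam_diameter / 2.0) ** 2)

    @property
    def power(self) -> float:
        """Total beam power (W)."""
        return self.incident_fluence_rate * self.area / 1000.0

    @property
    def power_mW(self) -> float:
        return self.incident_fluence_rate * self.area


@dataclass
class Phantom:
    """A voxel grid with named regions (background, layers, spheres)."""

    grid: VoxelGrid
    regions: list[tuple[dict, OpticalProperties]]


def make_phantom(
    n: int,
    voxel_size: float,
    regions: list[tuple[dict, OpticalProperties]],
) -> Phantom:
    """Voxelize a list of (shape spec, optics) regions onto an n^3 grid.

    Shape specs are dicts: ``{"shape": "background"}``,
    ``{"shape": "layer", "z_min_cm": a, "z_max_cm": b}`` or
    ``{"shape": "sphere", "center_cm": (x, y, z), "radius_cm": r}``.
    Membership is decided at voxel centres.  Later regions override earlier
    ones where they overlap; exactly one region must be a background.
    """
    backgrounds = [i for i, (s, _) in enumerate(regions) if s["shape"] == "background"]
    if len(backgrounds) != 1:
        raise InvalidParameterError("exactly one background region required")

    props = [p for _, p in regions]
    idx = np.full((n, n, n), backgrounds[0], dtype=np.int32)
    h = voxel_size
    extent = n * h
    centers = (np.arange(n) + 0.5) * h

    for r, (shape, _) in enumerate(regions):
        kind = shape["shape"]
        if kind == "background":
            continue
        if kind == "layer":
            z0, z1 = shape["z_min_cm"], shape["z_max_cm"]
            if not (0 <= z0 < z1 <= extent):
                raise InvalidParameterError(
                    f"layer [{z0}, {z1}] cm outside grid depth [0, {extent}]"
                )
            mask = (centers >= z0) & (centers < z1)
            idx[:, :, mask] = r
        elif kind == "sphere":
            cx, cy, cz = shape["center_cm"]
            rad = shape["radius_cm"]
            if rad <= 0:
                raise InvalidParameterError("sphere radius must be > 0")
            if not (
                rad <= cx <= extent - rad
                and rad <= cy <= extent - rad
                and rad <= cz <= extent - rad
            ):
                raise InvalidParameterError("sphere extends outside the grid")
            dx = centers - cx
            dy = centers - cy
            dz = centers - cz
            mask = (
                dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2
                <= rad**2
            )
            idx[mask] = r
        else:
            raise InvalidParameterError(f"unknown shape kind {kind!r}")

    grid = VoxelGrid(n, n, n, voxel_size, props, idx)
    return Phantom(grid=grid, regions=regions)
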