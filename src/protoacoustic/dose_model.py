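"""Proton depth-dose and 3-D energy-deposition model.

An analytic stand-in for a Monte Carlo transport code: the pristine Bragg
curve follows the Bragg-Kleeman differential form D(z) ∝ (R−z)^(1/p − 1)
convolved with a Gaussian range-straggling kernel, normalised so that the
depth integral equals the beam energy minus a configurable nuclear-loss
fraction.  Deposition is voxelised by exact cell averaging (the pristine
curve has an integrable singularity at z = R; pointwise sampling there is
grid-phase dependent and does not converge).

Units: lengths in mm, energies in MeV (grids store J/m^3), angles in rad.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.special import erf

__all__ = [
    "BeamConfig",
    "DoseGrid",
    "BoneLayer",
    "bragg_range",
    "depth_dose",
    "deposit_3d",
    "peak_region",
    "PeakRegion",
    "BRAGG_KLEEMAN_A",
    "BRAGG_KLEEMAN_P",
    "WATER_DENSITY",
    "MEV_TO_J",
]

#: Bragg-Kleeman water constants, R = a * E**p with R in mm and E in MeV.
BRAGG_KLEEMAN_A = 0.022
BRAGG_KLEEMAN_P = 1.77

#: Density of the water phantom material (kg/m^3).
WATER_DENSITY = 1003.0

MEV_TO_J = 1.602176634e-13

#: Beam energies (MeV) for which the depth-dose parametrisation is validated.
VALIDATED_ENERGY_BAND = (80.0, 150.0)


@dataclass
class BeamConfig:
    """Monoenergetic proton pencil beam.

    Parameters
    ----------
    energy : float
        Kinetic energy per proton, MeV.
    n_protons : float
        Protons per pulse.
    sigma_lateral : float
        Gaussian beam width, mm.
    pulse_duration : float
        Beam pulse duration, seconds.
    pulse_shape : str
        ``"gaussian"`` or ``"rectangular"``.
    entry_point : array-like of 3 floats
        Beam entry position, mm.
    direction : array-like of 3 floats
        Unit beam direction (must be axis-aligned for deposition).
    """

    energy: float = 100.0
    n_protons: float = 5e6
    sigma_lateral: float = 1.0
    pulse_duration: float = 10e-6
    pulse_shape: str = "gaussian"
    entry_point: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.entry_point = np.asarray(self.entry_point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.energy < 0:
            raise ValueError("beam energy must be non-negative")
        if not (VALIDATED_ENERGY_BAND[0] <= self.energy <= VALIDATED_ENERGY_BAND[1]):
            warnings.warn(
                f"beam energy {self.energy} MeV outside the validated band "
                f"{VALIDATED_ENERGY_BAND}",
                stacklevel=2,
            )
        if self.n_protons <= 0:
            raise ValueError("n_protons must be positive")
        if self.sigma_lateral <= 0:
            raise ValueError("sigma_lateral must be positive")
        if self.pulse_shape not in ("gaussian", "rectangular"):
            raise ValueError(f"unknown pulse shape {self.pulse_shape!r}")
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ValueError("direction must be a non-zero vector")
        self.direction = self.direction / n


@dataclass
class BoneLayer:
    """Water-equivalent bone slab crossed by the beam.

    The layer shifts the Bragg peak proximally by
    ``thickness * (relative_stopping_power - 1)``; lateral scatter broadening
    is not modelled.
    """

    thickness: float = 10.0
    relative_stopping_power: float = 1.6
    position_along_beam: float = 0.0

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("bone thickness must be >= 0")
        if self.relative_stopping_power <= 0:
            raise ValueError("relative stopping power must be positive")

    def water_equivalent_depth(self, z: np.ndarray) -> np.ndarray:
        """Map geometric depth to water-equivalent depth."""
        z = np.asarray(z, dtype=float)
        overlap = np.clip(z - self.position_along_beam, 0.0, self.thickness)
        return z + overlap * (self.relative_stopping_power - 1.0)


@dataclass
class DoseGrid:
    """Voxelised deposited energy density (the ε(r) source term).

    ``values`` has units J/m^3, ``origin``/``spacing`` are mm.  Grids are
    cell-centred: voxel (i, j, k) is centred at
    ``origin + (i + 0.5, j + 0.5, k + 0.5) * spacing``.
    """

    origin: np.ndarray
    spacing: np.ndarray
    values: np.ndarray
    beam_axis: int = 2

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.spacing = np.broadcast_to(
            np.asarray(self.spacing, dtype=float), (3,)
        ).copy()
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if (self.values < 0).any():
            raise ValueError("dose values must be non-negative")
        if (self.spacing <= 0).any():
            raise ValueError("spacing must be positive")

    @property
    def voxel_volume_m3(self) -> float:
        return float(np.prod(self.spacing)) * 1e-9

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing[axis]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(self.axis_centers(a) for a in range(3))

    def total_energy_J(self) -> float:
        return float(self.values.sum()) * self.voxel_volume_m3

    def axial_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """Depth coordinate (mm) and laterally integrated dose (J/m)."""
        axes = tuple(a for a in range(3) if a != self.beam_axis)
        area = float(np.prod(self.spacing[list(axes)])) * 1e-6  # m^2
        prof = self.values.sum(axis=axes) * area
        return self.axis_centers(self.beam_axis), prof

    # -- serialization: flat array + JSON sidecar --------------------------
    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".txt"), self.values.ravel())
        sidecar = {
            "origin_mm": self.origin.tolist(),
            "spacing_mm": self.spacing.tolist(),
            "shape": list(self.values.shape),
            "beam_axis": self.beam_axis,
            "units": "J/m^3",
        }
        prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "DoseGrid":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        values = np.loadtxt(prefix.with_suffix(".txt")).reshape(meta["shape"])
        return cls(
            origin=meta["origin_mm"],
            spacing=meta["spacing_mm"],
            values=values,
            beam_axis=meta["beam_axis"],
        )


def bragg_range(
    energy: float, a: float = BRAGG_KLEEMAN_A, p: float = BRAGG_KLEEMAN_P
) -> float:
    """Proton range in water, R = a * E**p (mm).

    Strictly increasing in energy; R(0) = 0.
    """
    if energy < 0:
        raise ValueError("energy must be non-negative")
    return a * float(energy) ** p


class _DepthDoseCurve:
    """Converged straggling-smeared Bragg curve on a fine internal grid.

    Exposes pointwise evaluation and the cumulative energy function used for
    exact cell averaging.
    """

    def __init__(
        self,
        energy: float,
        nuclear_loss: float = 0.10,
        straggle_frac: float = 0.01,
        a: float = BRAGG_KLEEMAN_A,
        p: float = BRAGG_KLEEMAN_P,
    ) -> None:
        if not 0 <= nuclear_loss < 1:
            raise ValueError("nuclear_loss must be in [0, 1)")
        self.energy = float(energy)
        self.range_mm = bragg_range(energy, a, p)
        self.sigma_mm = straggle_frac * self.range_mm
        R, p_ = self.range_mm, p
        total = energy * (1.0 - nuclear_loss)  # MeV per proton deposited
        if R <= 0 or total <= 0:
            self.z = np.array([0.0, 1.0])
            self.d = np.zeros(2)
            self.dz = 1.0
            return
        self.dz = max(self.sigma_mm / 8.0, R * 1e-5)
        zmax = R + max(6.0 * self.sigma_mm, 3.0 * self.dz)
        edges = np.arange(0.0, zmax + self.dz, self.dz)
        # exact cell averages of the pristine curve via its primitive
        prim = -np.clip(R - edges, 0.0, None) ** (1.0 / p_)
        dd = (prim[1:] - prim[:-1]) / self.dz * total / R ** (1.0 / p_)
        dd = gaussian_filter1d(dd, self.sigma_mm / self.dz, mode="constant")
        self.z = 0.5 * (edges[1:] + edges[:-1])
        self.d = dd  # MeV/mm per proton

    def __call__(self, z: np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        return np.interp(z, self.z, self.d, left=0.0, right=0.0)

    def cumulative(self, z: np.ndarray) -> np.ndarray:
        """Energy (MeV) deposited between depth 0 and z, per proton."""
        edges = np.concatenate([[0.0], self.z + 0.5 * self.dz])
        cum = np.concatenate([[0.0], np.cumsum(self.d) * self.dz])
        return np.interp(np.asarray(z, dtype=float), edges, cum)

    @property
    def peak_depth(self) -> float:
        return float(self.z[np.argmax(self.d)])


def depth_dose(
    energy: float,
    z: np.ndarray,
    nuclear_loss: float = 0.10,
    straggle_frac: float = 0.01,
    a: float = BRAGG_KLEEMAN_A,
    p: float = BRAGG_KLEEMAN_P,
) -> np.ndarray:
    """Per-proton linear energy deposition (MeV/mm) at depths ``z`` (mm).

    Non-negative, single maximum just proximal of ``bragg_range(energy)``,
    essentially zero beyond R + a few straggling widths.
    """
    z = np.asarray(z, dtype=float)
    if (z < 0).any():
        raise ValueError("depths must be non-negative")
    return _DepthDoseCurve(energy, nuclear_loss, straggle_frac, a, p)(z)


def _lateral_cell_weights(edges: np.ndarray, sigma: float) -> np.ndarray:
    """Cell-averaged density (1/mm) of a zero-mean Gaussian over cells."""
    cdf = 0.5 * (1.0 + erf(edges / (np.sqrt(2.0) * sigma)))
    return (cdf[1:] - cdf[:-1]) / np.diff(edges)


def deposit_3d(
    beam: BeamConfig,
    spacing: float = 1.0,
    bone: BoneLayer | None = None,
    margin: float = 10.0,
    lateral_halfwidth: float | None = None,
    grid_extent: float | None = None,
    nuclear_loss: float = 0.10,
    straggle_frac: float = 0.01,
) -> DoseGrid:
    """Voxelise the deposited energy density of one beam pulse.

    The grid is built in world coordinates with the beam along
    ``beam.direction`` (must be a positive coordinate axis) starting at
    ``beam.entry_point``.  The lateral profile is Gaussian with
    ``beam.sigma_lateral``; voxel values are exact cell averages.

    ``grid_extent`` optionally fixes the axial grid length (mm); an error is
    raised if it cannot contain the (bone-shifted) range plus straggling.
    """
    axis_candidates = np.where(np.abs(np.abs(beam.direction) - 1.0) < 1e-12)[0]
    if len(axis_candidates) != 1 or beam.direction[axis_candidates[0]] < 0:
        raise NotImplementedError(
            "deposit_3d supports beams along a positive coordinate axis"
        )
    beam_axis = int(axis_candidates[0])

    curve = _DepthDoseCurve(beam.energy, nuclear_loss, straggle_frac)
    R = curve.range_mm
    shift = 0.0 if bone is None else bone.thickness * (
        bone.relative_stopping_power - 1.0
    )
    needed = R - shift + max(3.0 * curve.sigma_mm, spacing)
    extent = (R - shift) + margin if grid_extent is None else grid_extent
    if extent < needed:
        raise ValueError(
            f"axial grid extent {extent:.1f} mm cannot contain the beam range "
            f"({needed:.1f} mm required); enlarge the grid"
        )

    half = lateral_halfwidth
    if half is None:
        half = max(5.0 * beam.sigma_lateral, 5.0 * spacing)
    n_lat = int(np.ceil(half / spacing))
    lat_edges = (np.arange(-n_lat, n_lat + 1)) * spacing
    w_lat = _lateral_cell_weights(lat_edges, beam.sigma_lateral)  # 1/mm

    n_ax = int(np.ceil(extent / spacing))
    ax_edges = np.arange(n_ax + 1) * spacing
    weq = ax_edges if bone is None else bone.water_equivalent_depth(ax_edges)
    e_cells = np.diff(curve.cumulative(weq)) / spacing  # MeV/mm per proton

    # assemble (lat, lat, axial) then roll the axial axis into place
    dens = np.einsum("i,j,k->ijk", w_lat, w_lat, e_cells)  # MeV/mm^3 per proton
    dens = np.moveaxis(dens, 2, beam_axis)
    values = beam.n_protons * dens * MEV_TO_J * 1e9  # J/m^3

    origin = np.empty(3)
    for ax in range(3):
        if ax == beam_axis:
            origin[ax] = beam.entry_point[ax]
        else:
            origin[ax] = beam.entry_point[ax] - n_lat * spacing
    return DoseGrid(origin=origin, spacing=spacing, values=values, beam_axis=beam_axis)


@dataclass
class PeakRegion:
    """Bounding sphere of the super-threshold dose region."""

    centroid: np.ndarray
    diameter: float
    voxel_indices: np.ndarray
    fraction: float


def peak_region(grid: DoseGrid, fraction: float = 0.5) -> PeakRegion:
    """Voxels with value >= fraction * max, with centroid and bounding sphere.

    The diameter includes the voxel extent (a single voxel has diameter equal
    to the voxel size).  A uniform non-zero grid returns the full-grid sphere
    (documented degenerate choice); an all-zero grid raises.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    vmax = grid.values.max() if grid.values.size else 0.0
    if grid.values.size == 0 or vmax <= 0:
        raise ValueError("peak_region of an empty or all-zero grid is undefined")
    mask = grid.values >= fraction * vmax
    idx = np.argwhere(mask)
    centers = grid.origin + (idx + 0.5) * grid.spacing
    w = grid.values[mask]
    centroid = (centers * w[:, None]).sum(axis=0) / w.sum()
    if len(idx) == 1:
        diameter = float(grid.spacing.max())
    elif len(idx) > 2000:
        # large region: bounding-box diagonal avoids the O(n^2) pairwise scan
        span = centers.max(axis=0) - centers.min(axis=0)
        diameter = float(np.linalg.norm(span)) + float(grid.spacing.max())
    else:
        # max pairwise distance of voxel centers, plus one voxel extent
        d2 = ((centers[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        diameter = float(np.sqrt(d2.max())) + float(grid.spacing.max())
    return PeakRegion(
        centroid=centroid, diameter=diameter, voxel_indices=idx, fraction=fraction
    )
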