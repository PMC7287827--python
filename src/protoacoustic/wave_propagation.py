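"""Small 2-D time-domain finite-difference solver for heterogeneous media.

Solves the variable-density acoustic wave equation

    (1 / rho c^2) d^2p/dt^2 = div( (1/rho) grad p )

with a second-order leapfrog scheme, face-averaged 1/rho, an exponential
sponge absorbing boundary, and pressure injection at source cells (the
monopole/dipole domain sources are taken as zero).  Being two-dimensional,
amplitudes follow cylindrical rather than spherical spreading: this module
validates arrival times and layer transmission only; pipeline amplitudes
come from the thermoacoustic model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MediumMap2D", "FDTDConfig", "fdtd_run", "first_arrival"]


@dataclass
class MediumMap2D:
    """Density (kg/m^3) and sound-speed (m/s) grids with cell size dx (mm)."""

    density: np.ndarray
    speed: np.ndarray
    dx: float

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        if self.density.shape != self.speed.shape or self.density.ndim != 2:
            raise ValueError("density and speed must be equal-shape 2-D arrays")
        if (self.density <= 0).any() or (self.speed <= 0).any():
            raise ValueError("density and speed must be positive everywhere")
        if self.dx <= 0:
            raise ValueError("dx must be positive")

    @property
    def bulk_modulus(self) -> np.ndarray:
        """Adiabatic bulk modulus rho * c^2 (Pa) per cell."""
        return self.density * self.speed**2

    def cfl_limit(self) -> float:
        """Largest stable time step (s) for the 2-D scheme."""
        return self.dx * 1e-3 / (float(self.speed.max()) * np.sqrt(2.0))


@dataclass
class FDTDConfig:
    dt: float
    n_steps: int
    sponge_width: int = 20
    sponge_strength: float = 0.3

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.n_steps <= 0:
            raise ValueError("dt and n_steps must be positive")
        if self.sponge_width < 0 or self.sponge_strength < 0:
            raise ValueError("sponge parameters must be non-negative")


def _sponge_taper(shape: tuple[int, int], width: int, strength: float) -> np.ndarray:
    """Multiplicative per-step damping profile (1 in the interior)."""
    ny, nx = shape
    taper = np.ones(shape)
    if width == 0 or strength == 0:
        return taper
    for n, axis in ((ny, 0), (nx, 1)):
        idx = np.arange(n)
        depth = np.maximum(width - idx, idx - (n - 1 - width))
        depth = np.clip(depth, 0, width) / max(width, 1)
        prof = np.exp(-strength * depth**2)
        taper *= prof[:, None] if axis == 0 else prof[None, :]
    return taper


def fdtd_run(
    medium: MediumMap2D,
    source_cells: list[tuple[int, int]],
    source_waveform: np.ndarray,
    sensor_cells: list[tuple[int, int]],
    cfg: FDTDConfig,
    record_energy: bool = False,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Run the solver; returns traces of shape (n_sensors, n_steps).

    Raises if the CFL condition dt <= dx / (c_max sqrt(2)) is violated.
    With ``record_energy=True`` additionally returns the potential-energy
    proxy sum(p^2 / 2 rho c^2) over the interior (non-sponge) cells at every
    step; once the source has stopped its envelope decays as the sponge
    absorbs the outgoing field.
    """
    limit = medium.cfl_limit()
    if cfg.dt > limit:
        raise ValueError(
            f"CFL violation: dt={cfg.dt:.3g} s exceeds the stability bound "
            f"dx/(c_max*sqrt(2)) = {limit:.3g} s"
        )
    waveform = np.asarray(source_waveform, dtype=float)
    rho = medium.density
    kappa = medium.bulk_modulus  # rho c^2
    dx_m = medium.dx * 1e-3
    inv_rho = 1.0 / rho
    # face-averaged 1/rho (harmonic mean is standard for flux continuity)
    by_y = 2.0 / (rho[1:, :] + rho[:-1, :])
    by_x = 2.0 / (rho[:, 1:] + rho[:, :-1])

    taper = _sponge_taper(rho.shape, cfg.sponge_width, cfg.sponge_strength)

    p = np.zeros_like(rho)
    p_prev = np.zeros_like(rho)
    out = np.zeros((len(sensor_cells), cfg.n_steps))
    coef = (cfg.dt**2) * kappa / dx_m**2
    w = cfg.sponge_width
    interior = (slice(w, rho.shape[0] - w), slice(w, rho.shape[1] - w))
    energy = np.zeros(cfg.n_steps) if record_energy else None

    for n in range(cfg.n_steps):
        if n < len(waveform) and waveform[n] != 0.0:
            for (i, j) in source_cells:
                p[i, j] += waveform[n]
        # div((1/rho) grad p) with zero-flux edges
        flux_y = by_y * (p[1:, :] - p[:-1, :])
        flux_x = by_x * (p[:, 1:] - p[:, :-1])
        div = np.zeros_like(p)
        div[:-1, :] += flux_y
        div[1:, :] -= flux_y
        div[:, :-1] += flux_x
        div[:, 1:] -= flux_x
        p_new = 2.0 * p - p_prev + coef * div
        p_new *= taper
        p *= taper
        p_prev = p
        p = p_new
        for k, (i, j) in enumerate(sensor_cells):
            out[k, n] = p[i, j]
        if record_energy:
            energy[n] = float(
                (p[interior] ** 2 / (2.0 * kappa[interior])).sum()
            )
    if record_energy:
        return out, energy
    return out


def first_arrival(
    trace: np.ndarray, dt: float, threshold_fraction: float = 0.1
) -> float:
    """Time of the first |trace| crossing of threshold_fraction * peak.

    The crossing is refined by linear interpolation between the bracketing
    samples.  Raises if the trace never crosses (e.g. all zero).
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")
    a = np.abs(np.asarray(trace, dtype=float))
    peak = a.max()
    if peak <= 0.0:
        raise ValueError("trace never crosses the threshold (all zero)")
    thr = threshold_fraction * peak
    above = np.nonzero(a >= thr)[0]
    k = int(above[0])
    if k == 0:
        return 0.0
    frac = (thr - a[k - 1]) / (a[k] - a[k - 1])
    return (k - 1 + frac) * dt
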