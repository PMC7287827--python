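"""Thermoacoustic pressure generation and signal characterisation.

The pressure at an observation point is the retarded-potential solution of
the thermoacoustic wave equation,

    p(r, t) = alpha / (4 pi Cp) * d^2/dt^2 \int dV' eps(r', t - |r-r'|/cs) / |r-r'|,

with a separable source eps(r, t) = eps(r) * S_cum(t) where S_cum is the
cumulative beam-pulse profile.  Numerically: the per-voxel weights
eps dV / |r - r'| are binned into retarded-time bins, the binned kernel is
convolved with the pulse profile S = dS_cum/dt, and one second-order central
time difference yields the pressure.

Each heated volume element emits a bipolar micro-pulse; doubling the protons
per pulse doubles the emitted amplitude exactly (the model is linear in the
deposited energy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .dose_model import DoseGrid

__all__ = [
    "AcousticMedium",
    "PulseProfile",
    "PressureTrace",
    "thermoacoustic_pressure",
    "attenuated_amplitude",
    "central_frequency",
    "max_pressure_vs_distance",
]


@dataclass
class AcousticMedium:
    """Homogeneous fluid medium (defaults: body-temperature water phantom).

    ``alpha_thermal`` is the volumetric thermal-expansion coefficient (1/K);
    the default 3.7e-4 corresponds to ~37 °C water since the application is
    in vivo.  ``alpha_atten`` is the plane-wave amplitude absorption (Np/m)
    at ``atten_ref_freq``; it is applied as a frequency-independent factor.
    """

    cs: float = 1500.0  # m/s
    Cp: float = 4180.0  # J/(kg K)
    alpha_thermal: float = 3.7e-4  # 1/K
    rho: float = 1003.0  # kg/m^3
    alpha_atten: float = 0.95  # Np/m
    atten_ref_freq: float = 300e3  # Hz

    def __post_init__(self) -> None:
        for name in ("cs", "Cp", "alpha_thermal", "rho"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha_atten < 0:
            raise ValueError("alpha_atten must be non-negative")

    @property
    def grueneisen(self) -> float:
        """Grueneisen-type efficiency alpha * cs^2 / Cp (dimensionless)."""
        return self.alpha_thermal * self.cs**2 / self.Cp


@dataclass
class PulseProfile:
    """Beam-pulse time profile S(t), normalised so that its integral is 1.

    ``shape="gaussian"`` is a Gaussian centred at duration/2 with
    sigma = duration/6, baseline-subtracted so it reaches zero continuously
    at the support edges [0, duration] (a hard truncation would inject
    spurious derivative spikes into the pressure);
    ``shape="rectangular"`` is a flat top over [0, duration].
    """

    duration: float = 10e-6  # s
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")
        if self.shape not in ("gaussian", "rectangular"):
            raise ValueError(f"unknown pulse shape {self.shape!r}")

    @property
    def sigma(self) -> float:
        return self.duration / 6.0

    def samples(self, dt: float) -> np.ndarray:
        """S(t) sampled on [0, duration] with step dt; sum * dt == 1."""
        n = max(int(round(self.duration / dt)), 1)
        t = (np.arange(n) + 0.5) * dt
        if self.shape == "rectangular":
            s = np.ones(n)
        else:
            c = self.duration / 2.0
            s = np.exp(-((t - c) ** 2) / (2.0 * self.sigma**2))
            s = np.clip(s - np.exp(-(c**2) / (2.0 * self.sigma**2)), 0.0, None)
        return s / (s.sum() * dt)

    def samples_derivative(self, dt: float) -> np.ndarray:
        """Analytic dS/dt for the Gaussian profile (oracle support)."""
        if self.shape != "gaussian":
            raise ValueError("analytic derivative only defined for gaussian")
        n = max(int(round(self.duration / dt)), 1)
        t = (np.arange(n) + 0.5) * dt
        c = self.duration / 2.0
        s = np.exp(-((t - c) ** 2) / (2.0 * self.sigma**2))
        base = np.exp(-(c**2) / (2.0 * self.sigma**2))
        norm = np.clip(s - base, 0.0, None).sum() * dt
        return -(t - c) / self.sigma**2 * s / norm


@dataclass
class PressureTrace:
    """Uniformly sampled pressure time series at a point."""

    t: np.ndarray
    p: np.ndarray
    dt: float
    observation_point: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.observation_point = np.asarray(self.observation_point, dtype=float)
        if len(self.t) != len(self.p):
            raise ValueError("t and p must have equal length")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def peak_amplitude(self) -> float:
        return float(np.abs(self.p).max())

    def shifted(self, offset: float) -> "PressureTrace":
        """Same samples on a time axis shifted by ``offset`` seconds."""
        return PressureTrace(
            t=self.t + offset,
            p=self.p.copy(),
            dt=self.dt,
            observation_point=self.observation_point,
        )

    def save(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        np.savetxt(
            prefix.with_suffix(".txt"),
            np.column_stack([self.t, self.p]),
            header="t_s p_Pa",
        )
        meta = {
            "dt_s": self.dt,
            "observation_point_mm": self.observation_point.tolist(),
            "n_samples": len(self.t),
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, prefix: str | Path) -> "PressureTrace":
        prefix = Path(prefix)
        data = np.loadtxt(prefix.with_suffix(".txt"))
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            t=data[:, 0],
            p=data[:, 1],
            dt=meta["dt_s"],
            observation_point=meta["observation_point_mm"],
        )


def thermoacoustic_pressure(
    dose: DoseGrid,
    obs: np.ndarray,
    medium: AcousticMedium | None = None,
    pulse: PulseProfile | None = None,
    dt: float = 1e-8,
    smooth_window: int = 0,
) -> PressureTrace:
    """Pressure trace at ``obs`` (mm) from a dose grid.

    ``dt`` must resolve the retarded-time structure of the grid
    (dt <= min(spacing)/cs).  ``smooth_window`` optionally applies a
    Savitzky-Golay filter (odd window length, order 2) to the binned kernel
    to control voxel-binning noise; 0 disables it.
    """
    medium = medium or AcousticMedium()
    pulse = pulse or PulseProfile()
    obs = np.asarray(obs, dtype=float)
    dt_max = float(dose.spacing.min()) * 1e-3 / medium.cs
    if dt > dt_max:
        raise ValueError(
            f"dt={dt:.3g} s too coarse for this grid; need dt <= "
            f"min(spacing)/cs = {dt_max:.3g} s"
        )

    xs, ys, zs = dose.voxel_centers()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    d = np.sqrt((X - obs[0]) ** 2 + (Y - obs[1]) ** 2 + (Z - obs[2]) ** 2) * 1e-3
    d = np.maximum(d, float(dose.spacing.min()) * 1e-3 / 2.0)

    nz = dose.values != 0
    q = dose.values[nz] * dose.voxel_volume_m3 / d[nz]  # J/m
    t_ret = d[nz] / medium.cs

    n_pulse = len(pulse.samples(dt))
    if q.size == 0:
        n = max(n_pulse + 2, 64)
        t = np.arange(n) * dt
        return PressureTrace(t=t, p=np.zeros(n), dt=dt, observation_point=obs)

    t_hi = t_ret.max() + 2.0 * pulse.duration
    nb = int(np.ceil(t_hi / dt)) + 2
    h, _ = np.histogram(t_ret, bins=nb, range=(0.0, nb * dt), weights=q)
    h /= dt  # J/(m s)
    if smooth_window and smooth_window >= 5:
        h = savgol_filter(h, smooth_window | 1, 2)

    kern = np.convolve(h, pulse.samples(dt)) * dt
    p = np.zeros_like(kern)
    p[1:-1] = (kern[2:] - kern[:-2]) / (2.0 * dt)
    p *= medium.alpha_thermal / (4.0 * np.pi * medium.Cp)
    t = np.arange(len(p)) * dt
    return PressureTrace(t=t, p=p, dt=dt, observation_point=obs)


def attenuated_amplitude(
    P_ref: float, d_ref: float, d: float, alpha_atten: float
) -> float:
    """Propagate a reference amplitude with 1/d spreading plus absorption.

    P(d) = P_ref * (d_ref / d) * exp(-alpha_atten * (d - d_ref)), with
    ``d_ref`` and ``d`` in mm and ``alpha_atten`` in Np/m.
    """
    if d_ref <= 0:
        raise ValueError("d_ref must be positive")
    if d < d_ref:
        raise ValueError("no back-propagation: require d >= d_ref")
    return P_ref * (d_ref / d) * np.exp(-alpha_atten * (d - d_ref) * 1e-3)


def central_frequency(
    trace: PressureTrace,
    return_edges: bool = False,
    min_resolution_hz: float = 1e3,
):
    """Frequency of the amplitude-spectrum maximum (Hz).

    The trace is mean-removed and Hann-tapered; the FFT is zero-padded so
    the bin width is at most ``min_resolution_hz``.  With
    ``return_edges=True`` also returns the -6 dB bandwidth edges (Hz).
    """
    if len(trace.p) < 64:
        raise ValueError("trace too short for spectral analysis (need >= 64)")
    p = trace.p - trace.p.mean()
    if not np.any(p):
        raise ValueError("central frequency of an all-zero trace is undefined")
    w = np.hanning(len(p))
    nfft = max(len(p), int(np.ceil(1.0 / (min_resolution_hz * trace.dt))))
    nfft = 1 << (nfft - 1).bit_length()
    spec = np.abs(np.fft.rfft(p * w, n=nfft))
    f = np.fft.rfftfreq(nfft, trace.dt)
    k = int(np.argmax(spec))
    fc = float(f[k])
    if not return_edges:
        return fc
    half = spec[k] / 2.0  # -6 dB in amplitude
    above = np.nonzero(spec >= half)[0]
    lo = above[above <= k].min()
    hi = above[above >= k].max()
    return fc, (float(f[lo]), float(f[hi]))


def max_pressure_vs_distance(
    P_ref: float,
    d_ref: float,
    distances: np.ndarray,
    alpha_atten: float,
) -> pd.DataFrame:
    """Peak pressure vs sensor distance (mm), as a table.

    Distances must be sorted ascending and >= d_ref; amplitudes are strictly
    decreasing for any non-negative absorption.
    """
    distances = np.asarray(distances, dtype=float)
    if np.any(np.diff(distances) <= 0):
        raise ValueError("distances must be sorted strictly ascending")
    vals = [attenuated_amplitude(P_ref, d_ref, d, alpha_atten) for d in distances]
    return pd.DataFrame({"distance_mm": distances, "pressure_Pa": vals})
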