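"""Bragg-peak localization from sensor pressure traces.

Arrival times are estimated by normalised cross-correlation against the
source-side template (with parabolic sub-sample refinement), corrected for
the skull-layer propagation, assembled into a time-difference-of-arrival
(TDOA) system

    F_i(x) = |x - s_i| - |x - s_ref| - c dt_i = 0,

and solved by damped Gauss-Newton (Armijo backtracking line search) with a
multistart fallback from the corners and centroid of a search box.  The
level set of each equation is a hyperboloid of revolution; at least four
non-coplanar sensors are required for a unique three-dimensional fix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate

from .thermoacoustic import PressureTrace

__all__ = [
    "SensorArray",
    "TDOASet",
    "ReconstructionResult",
    "LowCorrelationWarning",
    "estimate_toa",
    "correct_toas",
    "tdoas_from_toas",
    "solve_position",
    "localization_error",
]


class LowCorrelationWarning(UserWarning):
    """The cross-correlation peak is below the significance threshold."""


@dataclass
class SensorArray:
    """Sensor positions (mm), at least four and not coplanar."""

    positions: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[0] < 4 or self.positions.shape[1] != 3:
            raise ValueError(
                "a minimum of 4 sensors (x, y, z) is needed for a 3-D fix"
            )
        if self.labels is None:
            self.labels = [str(i + 1) for i in range(len(self.positions))]
        if len(self.labels) != len(self.positions):
            raise ValueError("labels must match the number of sensors")
        centered = self.positions - self.positions.mean(axis=0)
        sv = np.linalg.svd(centered, compute_uv=False)
        if sv[2] < 1e-9 * sv[0]:
            raise ValueError("sensor positions are coplanar: no unique 3-D fix")
        if sv[2] < 0.05 * sv[0]:
            warnings.warn(
                "sensor array is nearly coplanar; the out-of-plane coordinate "
                "will be poorly conditioned",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.positions)

    def max_baseline(self) -> float:
        d2 = (
            (self.positions[:, None, :] - self.positions[None, :, :]) ** 2
        ).sum(-1)
        return float(np.sqrt(d2.max()))


@dataclass
class TDOASet:
    """Arrival-time differences relative to a reference sensor."""

    delta_t: np.ndarray  # s, one per sensor; delta_t[reference] == 0
    reference: int = 0
    c: float = 1500.0  # m/s

    def __post_init__(self) -> None:
        self.delta_t = np.asarray(self.delta_t, dtype=float)
        if abs(self.delta_t[self.reference]) > 1e-15:
            raise ValueError("delta_t at the reference sensor must be zero")

    def validate_against(self, array: SensorArray) -> None:
        bound = array.max_baseline() * 1e-3 / self.c
        if np.any(np.abs(self.delta_t) > bound + 1e-12):
            raise ValueError(
                "a TDOA exceeds max baseline / c; arrival times are inconsistent"
            )


@dataclass
class ReconstructionResult:
    position: np.ndarray
    residual_norm: float  # mm
    iterations: int
    converged: bool
    predicted_tdoa: np.ndarray = field(default_factory=lambda: np.array([]))
    measured_tdoa: np.ndarray = field(default_factory=lambda: np.array([]))


def estimate_toa(
    trace: PressureTrace,
    template: PressureTrace,
    min_correlation: float = 0.2,
) -> float:
    """Arrival delay (s) of ``trace`` relative to ``template``.

    The lag maximising the normalised cross-correlation, refined to
    sub-sample precision by parabolic interpolation of the correlation peak,
    plus the offset between the two time axes.  Emits
    :class:`LowCorrelationWarning` when the normalised peak is below
    ``min_correlation``; raises on a flat trace.
    """
    if abs(trace.dt - template.dt) > 1e-15:
        raise ValueError("trace and template must share the sampling step")
    if len(template.p) > len(trace.p):
        raise ValueError("template must not be longer than the trace")
    x = trace.p - trace.p.mean()
    y = template.p - template.p.mean()
    if not np.any(x) or not np.any(y):
        raise ValueError("cannot correlate a flat trace")
    cc = correlate(x, y, mode="full")
    norm = np.linalg.norm(x) * np.linalg.norm(y)
    k = int(np.argmax(cc))
    peak = cc[k] / norm
    if peak < min_correlation:
        warnings.warn(
            f"correlation peak {peak:.3f} below threshold {min_correlation}; "
            "arrival time is unreliable",
            LowCorrelationWarning,
            stacklevel=2,
        )
    lag = k - (len(y) - 1)
    if 0 < k < len(cc) - 1:
        c_m, c_0, c_p = cc[k - 1], cc[k], cc[k + 1]
        denom = c_m - 2.0 * c_0 + c_p
        if denom != 0.0:
            lag += 0.5 * (c_m - c_p) / denom
    return lag * trace.dt + (trace.t[0] - template.t[0])


def correct_toas(
    toas: np.ndarray, correction: float | np.ndarray
) -> np.ndarray:
    """Apply the skull-layer time correction to measured arrival times.

    ``correction`` is the positive fluid-vs-bone time deficit from
    :func:`protoacoustic.interface_acoustics.toa_correction` (scalar for
    constant mode, vector for per-sensor mode); it is ADDED to the measured
    times, which arrive early through the faster bone, emulating the
    all-fluid path assumed by the solver.  A constant correction leaves all
    TDOAs unchanged.
    """
    return np.asarray(toas, dtype=float) + np.asarray(correction, dtype=float)


def tdoas_from_toas(
    toas: np.ndarray, reference: int = 0, c: float = 1500.0
) -> TDOASet:
    toas = np.asarray(toas, dtype=float)
    return TDOASet(delta_t=toas - toas[reference], reference=reference, c=c)


def _objective(x, positions, ref, cdt_mm, idx):
    diff = x - positions
    dist = np.linalg.norm(diff, axis=1)
    F = (dist - dist[ref] - cdt_mm)[idx]
    J = (diff / dist[:, None] - diff[ref] / dist[ref])[idx]
    return F, J


def solve_position(
    array: SensorArray,
    tdoas: TDOASet,
    c: float | None = None,
    init: np.ndarray | None = None,
    search_box: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> ReconstructionResult:
    """Solve the TDOA system for the source position (mm).

    Damped Gauss-Newton on the least-squares objective 0.5 ||F||^2 with
    Armijo backtracking; on non-convergence the solver restarts from the
    eight corners and centroid of ``search_box`` (default: the sensor
    bounding box inflated by 20%) and returns the best minimiser found.
    ``residual_norm`` is reported in mm.
    """
    c = tdoas.c if c is None else c
    positions = array.positions
    ref = tdoas.reference
    idx = np.array([i for i in range(len(positions)) if i != ref])
    if len(idx) < 3:
        raise ValueError("need at least 3 independent TDOA equations")
    cdt_mm = c * 1e3 * tdoas.delta_t  # mm

    if search_box is None:
        lo = positions.min(axis=0)
        hi = positions.max(axis=0)
        pad = 0.2 * (hi - lo) + 1.0
        search_box = (lo - pad, hi + pad)
    lo, hi = (np.asarray(v, dtype=float) for v in search_box)

    starts = []
    if init is not None:
        starts.append(np.asarray(init, dtype=float))
    starts.append(0.5 * (lo + hi))
    starts.extend(
        np.array([lo[0] if a else hi[0], lo[1] if b else hi[1], lo[2] if d else hi[2]])
        for a in (0, 1)
        for b in (0, 1)
        for d in (0, 1)
    )

    best: ReconstructionResult | None = None
    for x0 in starts:
        x = x0.copy()
        n_it = 0
        converged = False
        for n_it in range(1, max_iter + 1):
            F, J = _objective(x, positions, ref, cdt_mm, idx)
            f0 = 0.5 * float(F @ F)
            # regularised Gauss-Newton step (damps singular Jacobians)
            JtJ = J.T @ J + 1e-12 * np.eye(3)
            step = np.linalg.solve(JtJ, -J.T @ F)
            alpha, accepted = 1.0, False
            g = J.T @ F
            while alpha > 1e-12:
                xn = x + alpha * step
                Fn, _ = _objective(xn, positions, ref, cdt_mm, idx)
                if 0.5 * float(Fn @ Fn) <= f0 + 1e-4 * alpha * float(g @ step):
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                break
            x = x + alpha * step
            if np.linalg.norm(alpha * step) < tol:
                converged = True
                break
        F, _ = _objective(x, positions, ref, cdt_mm, idx)
        res = float(np.linalg.norm(F))
        cand = ReconstructionResult(
            position=x,
            residual_norm=res,
            iterations=n_it,
            converged=converged and res < 1e3,
            predicted_tdoa=(
                np.linalg.norm(x - positions, axis=1)
                - np.linalg.norm(x - positions[ref])
            )
            / (c * 1e3),
            measured_tdoa=tdoas.delta_t.copy(),
        )
        if best is None or cand.residual_norm < best.residual_norm:
            best = cand
        if best.converged and best.residual_norm < 1e-6:
            break
    return best


def localization_error(
    result: ReconstructionResult | np.ndarray, true_position: np.ndarray
) -> float:
    """Euclidean distance (mm) between estimate and truth."""
    pos = result.position if isinstance(result, ReconstructionResult) else result
    return float(
        np.linalg.norm(np.asarray(pos, dtype=float) - np.asarray(true_position, dtype=float))
    )
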