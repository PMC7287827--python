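"""Radial-mode resonance model and geometry optimisation for PZT discs.

The full piezoelectric FEM impedance sweep is replaced by an analytic
radial-mode model: the n-th radial resonance of a thin disc scales as
fr_n = lambda_n * N_p / d (N_p the planar frequency constant, lambda_n the
Bessel-root mode constants), with a monotone aspect-ratio correction
g(th/d) for finite thickness, and fa_n = fr_n / sqrt(1 - k_n^2).

The electromechanical coupling of each radial mode is reduced when that mode
approaches the thickness resonance f_t = N_t / th (radial-thickness mode
veering): a Lorentzian suppression models the hybridisation.  It is this
interaction that makes the ratio k1/k2 geometry dependent: k2 collapses when
the second radial overtone crosses the thickness mode, which for PIC255-like
constants happens near th ~ 0.55 d.

The optimisation logic itself - feasibility band fr1 <= f0 <= fa1 plus
argmax of k1/k2 on an integer-mm grid - is preserved exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiscGeometry",
    "PiezoMaterial",
    "ResonancePair",
    "PIC255",
    "radial_resonances",
    "coupling_coefficient",
    "optimize_geometry",
    "OptimizationResult",
]

#: Search band for disc diameter and thickness (mm).
SEARCH_BAND = (5.0, 40.0)


@dataclass
class DiscGeometry:
    """PZT disc geometry (mm)."""

    diameter: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("diameter", "thickness"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"{name} must be positive")
            if not SEARCH_BAND[0] <= v <= SEARCH_BAND[1]:
                warnings.warn(
                    f"{name}={v} mm outside the [5, 40] mm design band",
                    stacklevel=2,
                )

    @property
    def aspect(self) -> float:
        return self.thickness / self.diameter


@dataclass
class PiezoMaterial:
    """Datasheet scalars of a piezoceramic (PIC255-like defaults).

    N_p / N_t are the planar / thickness frequency constants (Hz m);
    k_p / k_t the planar / thickness coupling factors; lambda1/lambda2 the
    mode constants of the first two radial modes (normalised so that
    lambda1 = 1, lambda2 = ratio of the radial Bessel roots).
    """

    N_p: float = 1420.0  # Hz m
    N_t: float = 2000.0  # Hz m
    k_p: float = 0.62
    k_t: float = 0.47
    lambda1: float = 1.0
    lambda2: float = 2.60
    # aspect-ratio correction and mode-veering shape constants
    aspect_coeff: float = 0.20
    veering_depth: float = 0.70
    veering_width: float = 0.25

    def __post_init__(self) -> None:
        if min(self.N_p, self.N_t, self.k_p, self.k_t, self.lambda1) <= 0:
            raise ValueError("material constants must be positive")
        if self.lambda2 <= self.lambda1:
            raise ValueError("lambda2 must exceed lambda1")


PIC255 = PiezoMaterial()


@dataclass
class ResonancePair:
    """Resonance (impedance minimum) and anti-resonance (maximum), Hz."""

    fr: float
    fa: float
    mode: int

    def __post_init__(self) -> None:
        if not self.fa > self.fr > 0:
            raise ValueError("require fa > fr > 0")


def _aspect_correction(aspect: float, coeff: float) -> float:
    """g(th/d): 1 at zero aspect ratio, monotone decreasing."""
    return 1.0 / (1.0 + coeff * aspect**2)


def _mode_coupling(
    fr: float, mode_lambda: float, geom: DiscGeometry, mat: PiezoMaterial
) -> float:
    """Effective coupling of a radial mode, with thickness-mode veering."""
    base = mat.k_p * mat.lambda1 / mode_lambda
    f_t = mat.N_t / (geom.thickness * 1e-3)
    detune = (fr - f_t) / (mat.veering_width * f_t)
    k2 = base**2 * (1.0 - mat.veering_depth / (1.0 + detune**2))
    return float(np.sqrt(max(k2, 1e-6)))


def radial_resonances(
    geom: DiscGeometry, material: PiezoMaterial | None = None, n_modes: int = 2
) -> list[ResonancePair]:
    """(fr, fa) of the first ``n_modes`` radial modes of a disc.

    fr_n = lambda_n * N_p / d * g(th/d); fa_n = fr_n / sqrt(1 - k_n^2).
    Geometries with th/d > 1.5 fall outside the model's validity band and
    trigger a warning.
    """
    material = material or PIC255
    if n_modes not in (1, 2):
        raise ValueError("n_modes must be 1 or 2")
    if geom.aspect > 1.5:
        warnings.warn(
            f"aspect ratio th/d = {geom.aspect:.2f} > 1.5: outside the "
            "radial-mode model validity band",
            stacklevel=2,
        )
    g = _aspect_correction(geom.aspect, material.aspect_coeff)
    pairs = []
    for mode, lam in enumerate((material.lambda1, material.lambda2)[:n_modes], 1):
        fr = lam * material.N_p / (geom.diameter * 1e-3) * g
        k = _mode_coupling(fr, lam, geom, material)
        fa = fr / np.sqrt(1.0 - k**2)
        pairs.append(ResonancePair(fr=fr, fa=fa, mode=mode))
    return pairs


def coupling_coefficient(pair: ResonancePair) -> float:
    """Electromechanical coupling k = sqrt(1 - (fr/fa)^2), in [0, 1)."""
    if pair.fa < pair.fr:
        raise ValueError("anti-resonance must not be below resonance")
    return float(np.sqrt(1.0 - (pair.fr / pair.fa) ** 2))


@dataclass
class OptimizationResult:
    geometry: DiscGeometry
    score: float
    surface: pd.DataFrame


def optimize_geometry(
    target_freq: float,
    material: PiezoMaterial | None = None,
    grid_step: float = 1.0,
    band: tuple[float, float] = SEARCH_BAND,
) -> OptimizationResult:
    """Grid search maximising k1/k2 over geometries whose first-mode
    (fr1, fa1) band contains ``target_freq``.

    Deterministic: ties break toward smaller diameter, then smaller
    thickness.  Raises (naming the nearest feasible geometry) if no grid
    point is feasible.
    """
    material = material or PIC255
    values = np.arange(band[0], band[1] + grid_step / 2.0, grid_step)
    rows = []
    best = None
    nearest = None  # (band distance, d, th)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for d in values:
            for th in values:
                geom = DiscGeometry(diameter=float(d), thickness=float(th))
                m1, m2 = radial_resonances(geom, material, n_modes=2)
                k1 = coupling_coefficient(m1)
                k2 = coupling_coefficient(m2)
                score = k1 / k2
                feasible = m1.fr <= target_freq <= m1.fa
                rows.append(
                    {
                        "diameter_mm": d,
                        "thickness_mm": th,
                        "fr1_Hz": m1.fr,
                        "fa1_Hz": m1.fa,
                        "fr2_Hz": m2.fr,
                        "fa2_Hz": m2.fa,
                        "k1": k1,
                        "k2": k2,
                        "score": score,
                        "feasible": feasible,
                    }
                )
                if feasible:
                    if best is None or score > best[0]:
                        best = (score, float(d), float(th))
                else:
                    gap = max(m1.fr - target_freq, target_freq - m1.fa)
                    if nearest is None or gap < nearest[0]:
                        nearest = (gap, float(d), float(th))
    surface = pd.DataFrame(rows)
    if best is None:
        g = nearest
        raise ValueError(
            "no geometry on the grid has a first-mode band containing "
            f"{target_freq:.3g} Hz; nearest is d={g[1]} mm, th={g[2]} mm "
            f"(band misses the target by {g[0]:.3g} Hz)"
        )
    return OptimizationResult(
        geometry=DiscGeometry(diameter=best[1], thickness=best[2]),
        score=best[0],
        surface=surface,
    )
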