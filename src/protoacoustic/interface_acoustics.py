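"""Cerebrospinal-fluid / skull interface physics.

Snell refraction of the incident longitudinal wave into longitudinal and
shear waves in the bone, plane-wave power transmission/reflection
coefficients of the fluid-solid boundary, and the time-of-arrival correction
that the localiser applies to emulate an all-fluid path.

Default bone parameters (longitudinal speed 2000 m/s, layer thickness
6.48 mm, shear speed 1400 m/s, density 1900 kg/m^3) are not measured
quantities: the speed/thickness pair is pinned by the 1.08 us
normal-incidence correction together with the ~2 mm uncorrected localization
bias of the reference scene, and sits inside the literature spread for
parietal bone.  All four are configuration values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "FluidSolidInterface",
    "SnellAngles",
    "PowerCoefficients",
    "snell_angles",
    "power_coefficients",
    "toa_correction",
    "transmission_table",
]


@dataclass
class FluidSolidInterface:
    """Plane fluid-solid interface with a solid layer of finite thickness."""

    c_fluid: float = 1500.0  # m/s
    c_long: float = 2000.0  # m/s, skull longitudinal
    c_shear: float = 1400.0  # m/s, skull shear
    rho_fluid: float = 1003.0  # kg/m^3
    rho_solid: float = 1900.0  # kg/m^3
    layer_thickness: float = 6.48  # mm

    def __post_init__(self) -> None:
        if not self.c_long > self.c_shear > 0:
            raise ValueError("require c_long > c_shear > 0")
        if self.c_fluid <= 0 or self.rho_fluid <= 0 or self.rho_solid <= 0:
            raise ValueError("speeds and densities must be positive")
        if self.layer_thickness < 0:
            raise ValueError("layer thickness must be >= 0")

    @property
    def critical_angle_long(self) -> float:
        """Longitudinal critical angle (rad); pi/2 if none exists."""
        if self.c_long <= self.c_fluid:
            return math.pi / 2.0
        return math.asin(self.c_fluid / self.c_long)

    @property
    def critical_angle_shear(self) -> float:
        if self.c_shear <= self.c_fluid:
            return math.pi / 2.0
        return math.asin(self.c_fluid / self.c_shear)


class SnellAngles(NamedTuple):
    """Refracted angles (rad); ``None`` marks an evanescent wave."""

    theta_p: float | None
    theta_s: float | None


class PowerCoefficients(NamedTuple):
    T_p: float
    T_s: float
    R: float


def _check_incidence(theta_i: float) -> float:
    theta_i = float(theta_i)
    if not 0.0 <= theta_i < math.pi / 2.0:
        raise ValueError("incidence angle must be in [0, pi/2)")
    return theta_i


def snell_angles(theta_i: float, iface: FluidSolidInterface) -> SnellAngles:
    """Refracted longitudinal and shear angles for fluid-side incidence.

    sin(theta_p) = (c_long/c_fluid) sin(theta_i) and likewise for shear;
    beyond the corresponding critical angle the wave is evanescent (None).
    """
    theta_i = _check_incidence(theta_i)
    out = []
    for c in (iface.c_long, iface.c_shear):
        s = c / iface.c_fluid * math.sin(theta_i)
        out.append(math.asin(s) if s < 1.0 else None)
    return SnellAngles(*out)


def power_coefficients(
    theta_i: float, iface: FluidSolidInterface
) -> PowerCoefficients:
    """Energy transmission (longitudinal, shear) and reflection coefficients.

    Standard fluid-solid boundary solution written with the normal acoustic
    impedances Z = rho c / cos(theta):

        Z_in = Z_p cos^2(2 theta_s) + Z_s sin^2(2 theta_s)
        R_pressure = (Z_in - Z_f) / (Z_in + Z_f)

    with complex cosines beyond the critical angles.  The transmitted power
    splits between the longitudinal and shear branches in proportion to the
    real part of their impedance terms, so T_p + T_s + |R|^2 = 1 below both
    critical angles and R -> 1 under total internal reflection.
    """
    theta_i = _check_incidence(theta_i)
    si = math.sin(theta_i)
    sp = iface.c_long / iface.c_fluid * si
    ss = iface.c_shear / iface.c_fluid * si
    cos_i = math.cos(theta_i)
    cos_p = np.sqrt(complex(1.0 - sp * sp))
    cos_s = np.sqrt(complex(1.0 - ss * ss))

    Zf = iface.rho_fluid * iface.c_fluid / cos_i
    Zp = iface.rho_solid * iface.c_long / cos_p
    Zs = iface.rho_solid * iface.c_shear / cos_s

    cos2s = 1.0 - 2.0 * ss * ss  # cos(2 theta_s), real
    sin2s = 2.0 * ss * cos_s  # sin(2 theta_s), complex past critical
    term_p = Zp * cos2s**2
    term_s = Zs * sin2s**2
    Zin = term_p + term_s

    Rp = (Zin - Zf) / (Zin + Zf)
    refl = float(abs(Rp) ** 2)
    transmitted = max(1.0 - refl, 0.0)
    re_in = Zin.real
    if re_in <= 0.0:
        return PowerCoefficients(0.0, 0.0, 1.0)
    T_p = transmitted * max(term_p.real, 0.0) / re_in
    T_s = transmitted * max(term_s.real, 0.0) / re_in
    return PowerCoefficients(float(T_p), float(T_s), refl)


def toa_correction(
    iface: FluidSolidInterface, theta_i: float = 0.0
) -> float:
    """Time deficit (s) of the bone path relative to an all-fluid path.

    The refracted longitudinal ray crosses the layer along a segment of
    length L / cos(theta_p); the correction is the time that segment would
    take at c_fluid minus the time it takes at c_long:

        dt = (L / cos theta_p) * (1/c_fluid - 1/c_long)

    Positive for c_long > c_fluid (bone arrivals are EARLY by dt); at normal
    incidence dt = L (1/c_fluid - 1/c_long).  Adding dt to a measured TOA
    emulates the uniform-fluid propagation the localiser assumes.
    """
    theta_i = _check_incidence(theta_i)
    sp = iface.c_long / iface.c_fluid * math.sin(theta_i)
    if sp >= 1.0:
        raise ValueError(
            "longitudinal wave is evanescent at this incidence angle; "
            "no ray correction is defined"
        )
    cos_p = math.sqrt(1.0 - sp * sp)
    L = iface.layer_thickness * 1e-3  # m
    return L / cos_p * (1.0 / iface.c_fluid - 1.0 / iface.c_long)


def transmission_table(
    thetas_deg: np.ndarray, iface: FluidSolidInterface | None = None
) -> pd.DataFrame:
    """Refraction angles and power coefficients over a sweep of incidence."""
    iface = iface or FluidSolidInterface()
    rows = []
    for th in np.asarray(thetas_deg, dtype=float):
        ti = math.radians(th)
        ang = snell_angles(ti, iface)
        pc = power_coefficients(ti, iface)
        rows.append(
            {
                "theta_i_deg": th,
                "theta_p_deg": math.degrees(ang.theta_p)
                if ang.theta_p is not None
                else np.nan,
                "theta_s_deg": math.degrees(ang.theta_s)
                if ang.theta_s is not None
                else np.nan,
                "T_p": pc.T_p,
                "T_s": pc.T_s,
                "R": pc.R,
            }
        )
    return pd.DataFrame(rows)
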