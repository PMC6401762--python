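"""Stokes-flow quantities in the pore annulus.

Velocities are in nm/s, positive for cis -> trans motion.  The drift
velocity combines the electrophoretic pull of the field on the polymer
charges, the opposing electroosmotic drag of the pore counterions, and
the pressure-driven streaming flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constants import thermal_energy
from .electrostatics import Electrolyte, PoreSystem, RadialField

__all__ = [
    "FlowProfile",
    "geometric_factor",
    "ep_mobility",
    "diffusion_coefficient",
    "pore_diffusion_coefficient",
    "drift_velocity",
    "polymer_velocity",
    "fluid_velocity_profile",
]


def geometric_factor(a: float, d: float) -> float:
    """Annular streaming-flow factor gamma = d^2/a^2 - 1 - 2 ln(d/a).

    Vanishes as d -> a (no annular gap) and grows monotonically with d/a.
    """
    if not (0 < a < d):
        raise ValueError(f"require 0 < a < d, got a={a}, d={d}")
    x = d / a
    return x * x - 1.0 - 2.0 * math.log(x)


def ep_mobility(electrolyte: Electrolyte) -> float:
    """Electrophoretic mobility coefficient mu_e = eps0 eps_w kBT/(e eta).

    Returned in m^2/(V s); ~2.04e-8 for water at room temperature.
    """
    from .constants import E_CHARGE, EPSILON_0

    return (EPSILON_0 * electrolyte.eps_water * thermal_energy(electrolyte.temperature)
            / (E_CHARGE * electrolyte.viscosity))


def _log_diffusion(log_arg: float, eta: float, Lp_nm: float, T: float,
                   strict: bool = True) -> float:
    """Shared helper kBT ln(arg)/(c pi eta Lp); returns nm^2/s per unit c.

    ``strict`` rejects a non-positive logarithm (bulk D of a too-short
    rod); the in-pore coefficient legitimately vanishes at the wall.
    """
    if log_arg <= 1.0 and strict:
        raise ValueError(
            f"diffusion logarithm requires argument > 1, got {log_arg:g}")
    Lp_m = Lp_nm * 1e-9
    D_si = thermal_energy(T) * math.log(log_arg) / (math.pi * eta * Lp_m)
    return D_si * 1e18  # m^2/s -> nm^2/s


def diffusion_coefficient(system: PoreSystem) -> float:
    """Bulk transverse diffusion coefficient of the rodlike polymer,
    D = kBT ln(Lp/2a) / (3 pi eta Lp), in nm^2/s."""
    el = system.electrolyte
    return _log_diffusion(system.Lp / (2.0 * system.a), el.viscosity,
                          system.Lp, el.temperature) / 3.0


def pore_diffusion_coefficient(system: PoreSystem, r: float | None = None) -> float:
    """In-pore diffusion coefficient Dp(r) = kBT ln(d/r)/(2 pi eta Lp), nm^2/s.

    Defaults to the polymer surface r = a, the value entering the polymer
    mobility against the pore wall.
    """
    if r is None:
        r = system.a
    if not (0 < r <= system.d):
        raise ValueError(f"radius {r} outside (0, d]")
    el = system.electrolyte
    return _log_diffusion(system.d / r, el.viscosity, system.Lp,
                          el.temperature, strict=False) / 2.0


def drift_velocity(system: PoreSystem, field: RadialField | None = None) -> float:
    """Drift velocity v_dr from voltage and pressure, in nm/s.

    v_dr = mu_e (dV/Lm) [phi(d) - phi(a)] + gamma a^2 dP / (4 eta Lm).
    The first (electro)term combines electrophoresis and electroosmosis;
    the second is the streaming-flow contribution.
    """
    from .electrostatics import dh_annulus_potential

    if field is None:
        field = dh_annulus_potential(system)
    el = system.electrolyte
    mu_nm = ep_mobility(el) * 1e18  # nm^2/(V s)
    dphi = float(field(system.d)) - float(field(system.a))
    v_electro = mu_nm * (system.delta_V / system.Lm) * dphi
    gamma = geometric_factor(system.a, system.d)
    v_stream = gamma * system.a**2 * system.delta_P / (4.0 * el.viscosity * system.Lm)
    return v_electro + v_stream


def polymer_velocity(system: PoreSystem, zp, dVp=None,
                     field: RadialField | None = None):
    """Polymer velocity vp(zp) = v_dr - beta Dp(a) dVp/dzp, nm/s.

    ``dVp`` is the zp-derivative of the interaction potential in kBT/nm
    (callable or array matching zp); beta Dp(a) has units nm^2/s per kBT.
    """
    vdr = drift_velocity(system, field)
    if dVp is None:
        return vdr if np.isscalar(zp) else np.full(np.shape(zp), vdr)
    dv = dVp(zp) if callable(dVp) else np.asarray(dVp, dtype=float)
    return vdr - pore_diffusion_coefficient(system) * dv


@dataclass
class FlowProfile:
    """Axial fluid velocity u_c(r) on the annulus, nm/s."""

    r: np.ndarray
    uc: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"r_nm": self.r, "uc_nm_per_us": self.uc * 1e-6})


def fluid_velocity_profile(system: PoreSystem, field: RadialField | None = None,
                           zp: float | None = None, dVp=None,
                           n_grid: int = 201) -> FlowProfile:
    """Convective liquid velocity profile u_c(r) across the annulus.

    u_c(r) = mu_e (dV/Lm)[phi(d) - phi(r)] - beta Dp(r) dVp/dzp
           + (dP / 4 eta Lm)(d^2 - r^2 - 2 a^2 ln(d/r)).
    Satisfies no-slip at the wall, u_c(d) = 0, and matches the polymer
    velocity at the polymer surface, u_c(a) = vp(zp).
    """
    from .electrostatics import dh_annulus_potential

    if field is None:
        field = dh_annulus_potential(system)
    el = system.electrolyte
    r = np.linspace(system.a, system.d, n_grid)
    mu_nm = ep_mobility(el) * 1e18
    u = mu_nm * (system.delta_V / system.Lm) * (float(field(system.d)) - field(r))
    if dVp is not None and zp is not None:
        slope = float(dVp(zp)) if callable(dVp) else float(dVp)
        Dp_r = np.array([pore_diffusion_coefficient(system, ri) for ri in r])
        u = u - Dp_r * slope
    u = u + (system.delta_P / (4.0 * el.viscosity * system.Lm)) * (
        system.d**2 - r**2 - 2.0 * system.a**2 * np.log(system.d / r))
    return FlowProfile(r, u)
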