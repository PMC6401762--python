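"""Steady-state Smoluchowski transport of a stiff polymer through the pore.

The translocation coordinate zp runs from 0 (polymer tip at the pore
mouth) to zex = Lp + Lm (polymer fully escaped), with a source c(0) =
c_cis and an absorbing exit c(zex) = 0.  All observables -- capture rate,
translocation time and its capture/plateau/escape components, density
profile, mean velocity -- are direct quadratures of the steady-state
integral solutions; closed-form drift limits serve as cross-checks only.

Boltzmann factors are evaluated with the maximum of beta*Up subtracted,
since the effective potential can exceed +-100 kBT for biological-pore
parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .constants import pascal_to_kT_nm3, volts_to_kT
from .electrostatics import (
    PoreSystem,
    SelfEnergyParams,
    dh_annulus_potential,
    image_self_energy,
    membrane_potential,
)
from .hydrodynamics import (
    diffusion_coefficient,
    drift_velocity,
    geometric_factor,
    pore_diffusion_coefficient,
)

__all__ = [
    "OccupancyGeometry",
    "EffectivePotential",
    "TransportResult",
    "pore_occupancy",
    "build_effective_potential",
    "capture_rate",
    "translocation_time",
    "density_profile",
    "mean_velocity",
    "solve",
    "critical_pressure",
    "TrappingDensities",
    "trapping_salt_densities",
    "dilute_expansion_coefficients",
    "critical_length",
]


@dataclass(frozen=True)
class OccupancyGeometry:
    """Characteristic lengths of the piecewise pore occupancy."""

    L_minus: float
    L_plus: float
    zex: float

    def __post_init__(self):
        if not (0 < self.L_minus <= self.L_plus < self.zex):
            raise ValueError("require 0 < L- <= L+ < zex")

    @classmethod
    def from_system(cls, system: PoreSystem) -> "OccupancyGeometry":
        return cls(min(system.Lm, system.Lp), max(system.Lm, system.Lp),
                   system.zex)

    @classmethod
    def from_lengths(cls, Lm: float, Lp: float) -> "OccupancyGeometry":
        return cls(min(Lm, Lp), max(Lm, Lp), Lm + Lp)


def pore_occupancy(geometry: OccupancyGeometry, zp):
    """Length of the polymer portion inside the pore, lp(zp).

    Rises linearly during capture (zp < L-), plateaus at L- while the
    polymer translocates at constant in-pore length, and falls linearly
    during escape (zp > L+).  Continuous and piecewise linear.
    """
    zp_arr = np.asarray(zp, dtype=float)
    if np.any(zp_arr < -1e-9) or np.any(zp_arr > geometry.zex + 1e-9):
        raise ValueError(f"zp outside [0, {geometry.zex}]")
    lp = np.minimum(np.minimum(zp_arr, geometry.L_minus), geometry.zex - zp_arr)
    lp = np.maximum(lp, 0.0)
    return float(lp) if np.isscalar(zp) else lp


def occupancy_slope(geometry: OccupancyGeometry, zp):
    """d(lp)/d(zp): +1 during capture, 0 on the plateau, -1 during escape."""
    zp_arr = np.asarray(zp, dtype=float)
    s = np.where(zp_arr < geometry.L_minus, 1.0,
                 np.where(zp_arr > geometry.L_plus, -1.0, 0.0))
    return float(s) if np.isscalar(zp) else s


@dataclass
class EffectivePotential:
    """Effective potential beta*Up(zp) over [0, zex] and transport scales.

    ``beta_Up``/``dbeta_Up`` are vectorized callables (kBT and kBT/nm);
    ``D`` the bulk diffusion coefficient and ``Dp_a`` the in-pore one
    (nm^2/s); ``lambda_d``/``lambda_b`` the drift/barrier inverse lengths
    when the potential has the piecewise-linear mean-field form.
    """

    beta_Up: Callable
    dbeta_Up: Callable
    D: float
    Dp_a: float
    geometry: OccupancyGeometry
    lambda_d: float = 0.0
    lambda_b: float | None = None

    @property
    def zex(self) -> float:
        return self.geometry.zex

    @property
    def breakpoints(self) -> tuple:
        return (self.geometry.L_minus, self.geometry.L_plus)

    def vp(self, zp):
        """Local polymer velocity vp(zp) = -beta D Up'(zp), nm/s."""
        return -self.D * self.dbeta_Up(zp)


def build_effective_potential(system: PoreSystem, barrier: str = "mf",
                              Vp: Callable | None = None,
                              dVp: Callable | None = None,
                              n_tab: int = 81) -> EffectivePotential:
    """Assemble beta*Up(zp) = (Dp(a)/D) beta*Vp(zp) - lambda_d zp.

    barrier:
      "mf"    -- mean-field membrane-polymer coupling, linear in lp(zp)
                 (beta Up = lambda_b lp - lambda_d zp);
      "image" -- dielectric image-charge self-energy of the in-pore
                 portion, tabulated over lp and interpolated;
      "none"  -- pure drift;
      "custom"-- user-supplied Vp(zp), dVp(zp) in kBT, kBT/nm.
    """
    geom = OccupancyGeometry.from_system(system)
    D = diffusion_coefficient(system)
    Dp_a = pore_diffusion_coefficient(system)
    field = dh_annulus_potential(system)
    vdr = drift_velocity(system, field)
    lam_d = vdr / D
    ratio = Dp_a / D

    if barrier == "none":
        bVp = lambda z: np.zeros_like(np.asarray(z, dtype=float))
        dbVp = bVp
        lam_b = 0.0
    elif barrier == "mf":
        phim_a = float(membrane_potential(system)(system.a))
        slope = -system.tau * phim_a  # kBT per nm of occupancy, >= 0
        bVp = lambda z: slope * pore_occupancy(geom, z)
        dbVp = lambda z: slope * occupancy_slope(geom, z)
        lam_b = slope * ratio
    elif barrier == "image":
        lps = np.linspace(0.0, geom.L_minus, n_tab)
        energies = np.array([
            image_self_energy(SelfEnergyParams.from_system(system, lp))
            for lp in lps])
        spl = PchipInterpolator(lps, energies)
        dspl = spl.derivative()
        bVp = lambda z: spl(pore_occupancy(geom, z))
        dbVp = lambda z: dspl(pore_occupancy(geom, z)) * occupancy_slope(geom, z)
        lam_b = None
    elif barrier == "custom":
        if Vp is None or dVp is None:
            raise ValueError("custom barrier requires Vp and dVp callables")
        bVp, dbVp = Vp, dVp
        lam_b = None
    else:
        raise ValueError(f"unknown barrier kind {barrier!r}")

    beta_Up = lambda z: ratio * bVp(z) - lam_d * np.asarray(z, dtype=float)
    dbeta_Up = lambda z: ratio * dbVp(z) - lam_d
    return EffectivePotential(beta_Up, dbeta_Up, D, Dp_a, geom,
                              lambda_d=lam_d, lambda_b=lam_b)


def _segments(pot: EffectivePotential):
    g = pot.geometry
    pts = sorted({0.0, g.L_minus, g.L_plus, g.zex})
    return list(zip(pts[:-1], pts[1:]))


def _segment_grids(pot: EffectivePotential, n_per_seg: int):
    """Per-segment grids (odd point counts, kinks as endpoints only)."""
    n = n_per_seg if n_per_seg % 2 == 1 else n_per_seg + 1
    return [np.linspace(z0, z1, n) for z0, z1 in _segments(pot)]


def _potential_max(pot: EffectivePotential, n: int = 2001) -> float:
    vals = [np.max(pot.beta_Up(g)) for g in _segment_grids(pot, n)]
    return float(max(vals))


def capture_rate(pot: EffectivePotential, n_per_seg: int = 4001) -> float:
    """Capture rate Rc = D / Int_0^zex exp(beta[Up(z) - Up(0)]) dz, nm/s.

    The steady-state flux per unit cis concentration; for a flat potential
    Rc = D/zex, and in the pure-drift limit Rc = v_dr/(1 - e^(-v_dr zex/D)).
    Composite Simpson per potential segment with the maximum of beta*Up
    factored out of the Boltzmann weights.
    """
    from scipy.integrate import simpson

    M = _potential_max(pot)
    total = 0.0
    for g in _segment_grids(pot, n_per_seg):
        total += float(simpson(np.exp(pot.beta_Up(g) - M), x=g))
    u0 = float(pot.beta_Up(0.0))
    log_denom = (M - u0) + math.log(total)
    if log_denom > 700.0:
        return 0.0
    return pot.D * math.exp(-log_denom)


def translocation_time(pot: EffectivePotential,
                       geometry: OccupancyGeometry | None = None,
                       n_per_seg: int = 4001):
    """Mean translocation time and its capture/plateau/escape components.

    tau_p = (1/D) Int_0^zex dz e^(-beta Up(z)) Int_z^zex dz'' e^(beta Up(z''))
    with the outer integral split at L- and L+ into (tau1, tau2, tau3).
    The inner integral is a reverse cumulative trapezoid (computed from
    the absorbing end, so no cancellation); the outer weight is handled in
    log domain since beta*Up can span hundreds of kBT.  Returns
    (tau_p, tau1, tau2, tau3) with tau_p = tau1 + tau2 + tau3 exactly.
    """
    if geometry is None:
        geometry = pot.geometry
    grids = _segment_grids(pot, n_per_seg)
    bus = [pot.beta_Up(g) for g in grids]
    M = float(max(np.max(b) for b in bus))

    # reverse cumulative inner integral across all segments
    inner_starts = []  # I at the start of each segment
    I_end = 0.0
    inners = [None] * len(grids)
    for k in range(len(grids) - 1, -1, -1):
        g, b = grids[k], bus[k]
        w = np.exp(b - M)
        seg = 0.5 * np.diff(g) * (w[:-1] + w[1:])
        I = I_end + np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
        inners[k] = I
        I_end = I[0]

    comps = []
    with np.errstate(divide="ignore", over="raise"):
        for g, b, I in zip(grids, bus, inners):
            logh = (M - b) + np.log(np.where(I > 0, I, 1.0))
            logh[I <= 0] = -np.inf
            shift = float(np.max(logh))
            if shift - 700.0 > 0 and not math.isfinite(shift):
                comps.append(math.inf)
                continue
            try:
                h = np.exp(logh - shift)
                val = float(np.trapezoid(h, g)) * math.exp(shift)
            except (FloatingPointError, OverflowError):
                val = math.inf
            comps.append(val / pot.D)
    while len(comps) < 3:  # Lm == Lp collapses the plateau segment
        comps.insert(1, 0.0)
    tau1, tau2, tau3 = comps
    return tau1 + tau2 + tau3, tau1, tau2, tau3


def _steady_grid(pot: EffectivePotential, n_per_seg: int = 1500):
    """Union grid over the potential segments plus the shifted Boltzmann
    factor and the reverse cumulative integral I(z) = Int_z^zex e^(bUp-M)."""
    zs = np.unique(np.concatenate([
        np.linspace(z0, z1, n_per_seg) for z0, z1 in _segments(pot)]))
    bu = pot.beta_Up(zs)
    M = float(np.max(bu))
    w = np.exp(bu - M)
    # reverse cumulative trapezoid
    dz = np.diff(zs)
    seg = 0.5 * dz * (w[:-1] + w[1:])
    I = np.concatenate([np.cumsum(seg[::-1])[::-1], [0.0]])
    return zs, bu, M, I


def _log_density(pot: EffectivePotential, n_per_seg: int):
    """Grid zs and log of c(zp)/ccis.

    c(zp)/ccis = e^(beta[Up(0) - Up(zp)]) * I(zp)/I(0) with
    I(z) = Int_z^zex e^(beta Up - M); computed in log domain since the
    Boltzmann prefactor can span hundreds of kBT.
    """
    zs, bu, _, I = _steady_grid(pot, n_per_seg)
    if I[0] <= 0:
        raise ArithmeticError("vanishing steady-state normalization")
    with np.errstate(divide="ignore"):
        logc = (bu[0] - bu) + np.log(I / I[0])
    logc[I <= 0] = -np.inf  # absorbing exit
    return zs, logc


def density_profile(pot: EffectivePotential, ccis: float = 1.0,
                    n_per_seg: int = 1500):
    """Steady-state polymer density c(zp) and pore population N.

    c(zp) = ccis e^(-beta Up(zp)) Int_zp^zex e^(beta Up) dz
          / [e^(-beta Up(0)) Int_0^zex e^(beta Up) dz],
    so c(0) = ccis and c(zex) = 0 (absorbing exit).  Returns (zp, c, N).
    """
    if ccis <= 0:
        raise ValueError("ccis must be positive")
    zs, logc = _log_density(pot, n_per_seg)
    with np.errstate(over="ignore"):
        c = ccis * np.exp(logc)
    N = float(np.trapezoid(c, zs))
    return zs, c, N


def mean_velocity(pot: EffectivePotential, n_per_seg: int = 1500) -> float:
    """Density-weighted average polymer velocity, nm/s.

    <vp> = Int c(zp) vp(zp) dzp / Int c(zp) dzp with vp = -beta D Up'.
    The density weight is normalized by its maximum before exponentiation
    (the average is shift-invariant), so deep wells do not overflow.  In
    both the drift- and barrier-dominated regimes this is well
    approximated by D (lambda_d - lambda_b).
    """
    zs, logc = _log_density(pot, n_per_seg)
    shift = float(np.max(logc))
    w = np.exp(logc - shift)
    num = 0.0
    den = 0.0
    for z0, z1 in _segments(pot):
        m = (zs >= z0) & (zs <= z1)
        zseg = zs[m]
        mid = 0.5 * (zseg[:-1] + zseg[1:])  # avoid kink points of vp
        vseg = pot.vp(mid)
        wm = 0.5 * (w[m][:-1] + w[m][1:])
        dz = np.diff(zseg)
        num += float(np.sum(wm * vseg * dz))
        den += float(np.sum(wm * dz))
    return num / den


@dataclass
class TransportResult:
    """Bundle of steady-state transport observables."""

    Rc: float
    tau_p: float
    tau1: float
    tau2: float
    tau3: float
    vp_mean: float
    zp: np.ndarray
    c: np.ndarray
    N: float

    def to_frame(self):
        import pandas as pd

        pot = getattr(self, "_pot", None)
        data = {"zp_nm": self.zp, "c_over_ccis": self.c}
        if pot is not None:
            data["Up_kT"] = pot.beta_Up(self.zp)
            data["vp_nm_per_us"] = pot.vp(self.zp) * 1e-6
        return pd.DataFrame(data)

    def scalars(self) -> dict:
        return {
            "Rc_nm_per_s": self.Rc,
            "tau_p_s": self.tau_p,
            "tau1_s": self.tau1,
            "tau2_s": self.tau2,
            "tau3_s": self.tau3,
            "vp_mean_nm_per_s": self.vp_mean,
            "N_pore": self.N,
        }


def solve(system: PoreSystem, barrier: str = "mf", ccis: float = 1.0,
          **kwargs) -> TransportResult:
    """Full steady-state solution for a pore system."""
    pot = build_effective_potential(system, barrier=barrier, **kwargs)
    Rc = capture_rate(pot)
    tau_p, t1, t2, t3 = translocation_time(pot)
    zp, c, N = density_profile(pot, ccis=ccis)
    vbar = mean_velocity(pot)
    res = TransportResult(Rc, tau_p, t1, t2, t3, vbar, zp, c * ccis, N)
    res._pot = pot
    return res


def _vp_mean_for(system: PoreSystem, barrier: str, **replacements) -> float:
    sys2 = system.with_(**replacements) if replacements else system
    pot = build_effective_potential(sys2, barrier=barrier)
    return mean_velocity(pot)


def critical_pressure(system: PoreSystem, barrier: str = "mf",
                      p_range: tuple = (-2.0e6, 2.0e6),
                      n_scan: int = 41) -> float | None:
    """Pressure dP* at which the mean translocation velocity vanishes (Pa).

    Found by a bracketed root search on <vp>(dP); near the root the
    velocity is linear with slope gamma a^2/(4 eta Lm).  Returns None when
    no sign change exists in the scanned range (no trapping).
    """
    ps = np.linspace(p_range[0], p_range[1], n_scan)
    vs = np.array([_vp_mean_for(system, barrier, delta_P=float(p)) for p in ps])
    sign_flips = np.nonzero(np.diff(np.sign(vs)) != 0)[0]
    if len(sign_flips) == 0:
        return None
    i = sign_flips[0]
    return brentq(lambda p: _vp_mean_for(system, barrier, delta_P=float(p)),
                  ps[i], ps[i + 1], xtol=1e-6 * (1 + abs(ps[i])))


def dilute_expansion_coefficients(a: float, d: float) -> tuple:
    """Coefficients (ap, am) of the dilute-salt drift expansion.

    ap = -a/2 + a d^2 ln(d/a)/(d^2 - a^2);
    am =  d/2 - a^2 d ln(d/a)/(d^2 - a^2).
    """
    L = math.log(d / a)
    den = d * d - a * a
    ap = -a / 2.0 + a * d * d * L / den
    am = d / 2.0 - a * a * d * L / den
    return ap, am


@dataclass
class TrappingDensities:
    """Characteristic trapping salt densities, in nm^-3 (NaN when absent)."""

    high_closed: float
    low_closed: float
    high_root: float
    low_root: float


def _closed_trapping_high(system: PoreSystem) -> float:
    """High-salt trapping density: kappa* = -4 (sp - sm) beta e dV /
    (gamma a^2 beta dP), rho* = kappa*^2/(8 pi lB)."""
    el = system.electrolyte
    dV = volts_to_kT(system.delta_V, el.temperature)
    dP = pascal_to_kT_nm3(system.delta_P, el.temperature)
    gamma = geometric_factor(system.a, system.d)
    if dP == 0.0:
        return math.nan
    X = (system.sigma_p - system.sigma_m) * dV / (gamma * system.a**2 * dP)
    if X >= 0.0:
        return math.nan
    kappa_star = -4.0 * X
    return kappa_star**2 / (8.0 * math.pi * el.lb)


def _closed_trapping_low(system: PoreSystem) -> float:
    el = system.electrolyte
    dV = volts_to_kT(system.delta_V, el.temperature)
    dP = pascal_to_kT_nm3(system.delta_P, el.temperature)
    a, d = system.a, system.d
    ap, am = dilute_expansion_coefficients(a, d)
    gamma = geometric_factor(a, d)
    den = ((d * d - a * a) * system.Lp
           * (gamma * a * a * dP + 4.0 * (ap * system.sigma_p - am * system.sigma_m) * dV))
    if den <= 0.0:
        return math.nan
    num = 4.0 * d * a * math.log(d / a) * system.Lm * system.sigma_p * system.sigma_m
    return num / den


def trapping_salt_densities(system: PoreSystem, barrier: str = "mf",
                            rho_range: tuple = (1e-4, 3.0),
                            n_scan: int = 49) -> TrappingDensities:
    """Characteristic salt densities where <vp> changes sign.

    Closed forms from the high-salt (kappa a, kappa d >> 1) and dilute
    (kappa a, kappa d << 1) expansions of the drift approximation, plus
    numerical roots of <vp>(rho_b) from the full engine.  rho_range in M;
    all returned densities in nm^-3.
    """
    from .constants import molar_to_nm3

    def vbar(molar):
        el = Electrolyte_monovalent_like(system, molar)
        return _vp_mean_for(system, barrier, electrolyte=el)

    ms = np.geomspace(rho_range[0], rho_range[1], n_scan)
    vs = np.array([vbar(float(m)) for m in ms])
    low_root = high_root = math.nan
    for i in np.nonzero(np.diff(np.sign(vs)) != 0)[0]:
        r = molar_to_nm3(brentq(vbar, ms[i], ms[i + 1], xtol=1e-12, rtol=1e-10))
        # velocity turning negative with added salt marks the high-salt
        # trapping density; turning positive marks the dilute one
        if vs[i] > vs[i + 1]:
            high_root = r
        else:
            low_root = r
    return TrappingDensities(
        high_closed=_closed_trapping_high(system),
        low_closed=_closed_trapping_low(system),
        high_root=high_root,
        low_root=low_root,
    )


def Electrolyte_monovalent_like(system: PoreSystem, molar: float):
    """1:1 electrolyte at the given molarity, other solvent properties kept."""
    from .electrostatics import Electrolyte

    el = system.electrolyte
    return Electrolyte.monovalent(molar, temperature=el.temperature,
                                  viscosity=el.viscosity,
                                  eps_water=el.eps_water,
                                  eps_membrane=el.eps_membrane)


def critical_length(system: PoreSystem, barrier: str = "mf",
                    Lp_range: tuple | None = None,
                    n_scan: int = 41) -> float | None:
    """Critical polymer length Lp* below which the polymer is trapped (nm).

    Root of <vp>(Lp) = 0: the drift force scales with the full polymer
    length while the electrostatic barrier comes only from the in-pore
    portion, so short polymers are rejected.  None when no root exists
    (e.g. no barrier at all).
    """
    if Lp_range is None:
        Lp_range = (2.2 * system.a * math.e, 100.0 * system.Lm)

    def vbar(Lp):
        return _vp_mean_for(system, barrier, Lp=float(Lp))

    Ls = np.geomspace(Lp_range[0], Lp_range[1], n_scan)
    vs = np.array([vbar(L) for L in Ls])
    flips = np.nonzero(np.diff(np.sign(vs)) != 0)[0]
    if len(flips) == 0:
        return None
    i = flips[0]
    return brentq(vbar, Ls[i], Ls[i + 1], xtol=1e-9, rtol=1e-12)


def critical_length_closed(system: PoreSystem) -> float:
    """Dilute-salt closed form of the critical length (nm)."""
    el = system.electrolyte
    rho = sum(rho for q, rho in el.species if q > 0)  # 1:1 salt density
    dV = volts_to_kT(system.delta_V, el.temperature)
    dP = pascal_to_kT_nm3(system.delta_P, el.temperature)
    a, d = system.a, system.d
    ap, am = dilute_expansion_coefficients(a, d)
    gamma = geometric_factor(a, d)
    den = ((d * d - a * a) * rho
           * (gamma * a * a * dP + 4.0 * (ap * system.sigma_p - am * system.sigma_m) * dV))
    if den <= 0.0:
        return math.nan
    return 4.0 * d * a * math.log(d / a) * system.Lm * system.sigma_p * system.sigma_m / den
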