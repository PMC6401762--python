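"""Debye-Hückel electrostatics of a charged cylinder inside a charged pore.

The geometry is an annulus a <= r <= d: a polymer of radius ``a`` on the
axis of a cylindrical membrane pore of radius ``d``.  Both surfaces carry
fixed anionic charge; magnitudes sigma_p, sigma_m are stored positive and
the sign is applied internally.  The electrolyte screens the field with
the Debye parameter kappa.  Potentials are dimensionless (thermal units).

Also provided: the mean-field polymer-membrane interaction potential, the
cumulative charge profile, and the dielectric image-charge self-energy of
a charged line in a low-permittivity membrane pore.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.special import iv, ive, kv, kve

from .constants import (
    DEFAULT_TEMPERATURE,
    MEMBRANE_PERMITTIVITY,
    WATER_PERMITTIVITY,
    WATER_VISCOSITY,
    bjerrum_length,
    molar_to_nm3,
)

__all__ = [
    "Electrolyte",
    "PoreSystem",
    "RadialField",
    "SelfEnergyParams",
    "bjerrum_length",
    "debye_parameter",
    "dh_annulus_potential",
    "membrane_potential",
    "mf_interaction_potential",
    "dielectric_jump",
    "image_self_energy",
    "cumulative_charge",
    "pb_annulus_potential",
]


@dataclass(frozen=True)
class Electrolyte:
    """Bulk electrolyte: ionic species, temperature and solvent properties.

    ``species`` is a sequence of (valency, bulk density in nm^-3) pairs and
    must be electroneutral.  Derived members: the Bjerrum length ``lb`` and
    the Debye parameter ``kappa`` (both in nm units), and the dielectric
    contrast ``gamma_eps`` = eps_m / eps_w used by the image-charge
    self-energy.
    """

    species: tuple
    temperature: float = DEFAULT_TEMPERATURE
    viscosity: float = WATER_VISCOSITY
    eps_water: float = WATER_PERMITTIVITY
    eps_membrane: float = MEMBRANE_PERMITTIVITY

    def __post_init__(self):
        object.__setattr__(self, "species", tuple((int(q), float(r)) for q, r in self.species))
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")
        if not (self.eps_water > self.eps_membrane > 0):
            raise ValueError("require eps_water > eps_membrane > 0")
        for q, rho in self.species:
            if rho < 0:
                raise ValueError(f"negative bulk density for valency {q}")
        net = sum(q * rho for q, rho in self.species)
        scale = sum(abs(q) * rho for q, rho in self.species) or 1.0
        if abs(net) > 1e-10 * scale:
            raise ValueError(f"species are not electroneutral (net {net:g})")

    @classmethod
    def monovalent(cls, molar: float, **kwargs) -> "Electrolyte":
        """Symmetric 1:1 salt of the given molar concentration."""
        rho = molar_to_nm3(molar)
        return cls(species=((1, rho), (-1, rho)), **kwargs)

    @property
    def lb(self) -> float:
        """Bjerrum length in nm."""
        return bjerrum_length(self.temperature, self.eps_water)

    @property
    def kappa(self) -> float:
        """Debye screening parameter in nm^-1."""
        return debye_parameter(self)

    @property
    def gamma_eps(self) -> float:
        """Dielectric contrast eps_m / eps_w."""
        return self.eps_membrane / self.eps_water


def debye_parameter(electrolyte: Electrolyte) -> float:
    """kappa = sqrt(4 pi lB sum_i q_i^2 rho_i) in nm^-1.

    Reduces to sqrt(8 pi lB rho_b) for a symmetric 1:1 salt.
    """
    s = sum(q * q * rho for q, rho in electrolyte.species)
    return math.sqrt(4.0 * math.pi * electrolyte.lb * s)


@dataclass(frozen=True)
class PoreSystem:
    """Geometry, charges and driving forces of the translocation setup.

    Lengths in nm; sigma_p, sigma_m are charge-magnitude surface densities
    in e/nm^2 (both surfaces are anionic, the sign is applied internally);
    delta_V in volts (V_trans - V_cis); delta_P in Pa (P_cis - P_trans).
    """

    a: float
    d: float
    Lm: float
    Lp: float
    sigma_p: float = 0.0
    sigma_m: float = 0.0
    delta_V: float = 0.0
    delta_P: float = 0.0
    electrolyte: Electrolyte = field(default_factory=lambda: Electrolyte.monovalent(0.1))

    def __post_init__(self):
        if not (0 < self.a < self.d):
            raise ValueError(f"require 0 < a < d, got a={self.a}, d={self.d}")
        if self.Lm <= 0 or self.Lp <= 0:
            raise ValueError("pore and polymer lengths must be positive")
        if self.sigma_p < 0 or self.sigma_m < 0:
            raise ValueError("surface charge densities are magnitudes, must be >= 0")

    @property
    def tau(self) -> float:
        """Magnitude of the polymer linear charge density 2 pi a sigma_p, in e/nm."""
        return 2.0 * math.pi * self.a * self.sigma_p

    @property
    def zex(self) -> float:
        """Pore-exit coordinate Lp + Lm (nm)."""
        return self.Lp + self.Lm

    def with_(self, **kwargs) -> "PoreSystem":
        """Copy with replaced fields."""
        return replace(self, **kwargs)


@dataclass
class RadialField:
    """Dimensionless electrostatic potential on the annulus [a, d].

    Callable at any radius in [a, d]; carries an exact evaluator when
    built from the Bessel solution, plus a sampled grid for export.
    """

    r: np.ndarray
    phi: np.ndarray
    _func: Callable[[np.ndarray], np.ndarray] | None = None
    _dfunc: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        lo, hi = self.r[0], self.r[-1]
        if np.any(r < lo - 1e-9) or np.any(r > hi + 1e-9):
            raise ValueError(f"radius outside [{lo}, {hi}]")
        r = np.clip(r, lo, hi)
        if self._func is not None:
            return self._func(r)
        return np.interp(r, self.r, self.phi)

    def derivative(self, r):
        """d(phi)/dr at radius r (nm^-1)."""
        r = np.asarray(r, dtype=float)
        if self._dfunc is not None:
            return self._dfunc(r)
        return np.gradient(self.phi, self.r)[np.searchsorted(self.r, r)]

    def to_frame(self):
        """Two-column table (r_nm, phi_kT) for CSV export."""
        import pandas as pd

        return pd.DataFrame({"r_nm": self.r, "phi_kT": self.phi})


def _dh_field(a: float, d: float, kappa: float, lb: float,
              sigma_p: float, sigma_m: float, n_grid: int = 201) -> RadialField:
    """Solve the linearized radial equation phi'' + phi'/r = kappa^2 phi on
    [a, d] with Gauss conditions phi'(a) = +4 pi lB sigma_p and
    phi'(d) = -4 pi lB sigma_m (thermal units, anionic surfaces).
    """
    grid = np.linspace(a, d, n_grid)
    if sigma_p == 0.0 and sigma_m == 0.0:
        zero = np.zeros_like(grid)
        return RadialField(grid, zero,
                           _func=lambda r: np.zeros_like(np.asarray(r, float)),
                           _dfunc=lambda r: np.zeros_like(np.asarray(r, float)))
    if kappa <= 0.0:
        # A Laplace solution in the annulus has a single flux constant and
        # cannot satisfy two independent Gauss conditions for same-sign
        # surface charges.
        raise ValueError("unscreened annulus (kappa=0) supports no solution "
                         "with non-zero surface charge; add salt")

    gp = 4.0 * math.pi * lb * sigma_p
    gm = 4.0 * math.pi * lb * sigma_m

    # Scaled basis, O(1) on [a, d]: u1 = I0(kr)/I0(kd), u2 = K0(kr)/K0(ka).
    def u1(r):
        r = np.asarray(r, dtype=float)
        return ive(0, kappa * r) / ive(0, kappa * d) * np.exp(kappa * (r - d))

    def du1(r):
        r = np.asarray(r, dtype=float)
        return kappa * ive(1, kappa * r) / ive(0, kappa * d) * np.exp(kappa * (r - d))

    def u2(r):
        r = np.asarray(r, dtype=float)
        return kve(0, kappa * r) / kve(0, kappa * a) * np.exp(kappa * (a - r))

    def du2(r):
        r = np.asarray(r, dtype=float)
        return -kappa * kve(1, kappa * r) / kve(0, kappa * a) * np.exp(kappa * (a - r))

    M = np.array([[du1(a), du2(a)], [du1(d), du2(d)]], dtype=float)
    rhs = np.array([gp, -gm])
    A, B = np.linalg.solve(M, rhs)

    func = lambda r: A * u1(r) + B * u2(r)
    dfunc = lambda r: A * du1(r) + B * du2(r)
    return RadialField(grid, func(grid), _func=func, _dfunc=dfunc)


def dh_annulus_potential(system: PoreSystem, n_grid: int = 201) -> RadialField:
    """Net Debye-Hückel potential phi(r) of polymer + membrane charges."""
    el = system.electrolyte
    return _dh_field(system.a, system.d, el.kappa, el.lb,
                     system.sigma_p, system.sigma_m, n_grid)


def membrane_potential(system: PoreSystem, n_grid: int = 201) -> RadialField:
    """Potential phi_m(r) of the membrane charges alone (sigma_p -> 0)."""
    el = system.electrolyte
    return _dh_field(system.a, system.d, el.kappa, el.lb,
                     0.0, system.sigma_m, n_grid)


def mf_interaction_potential(system: PoreSystem, zp, phim: RadialField | None = None):
    """Mean-field polymer-membrane coupling V_p(zp) in kBT.

    V_p(zp) = -2 pi a sigma_p * phi_m(a) * l_p(zp): the charge of the
    in-pore polymer portion times the membrane potential at the polymer
    surface.  For two anionic surfaces phi_m(a) < 0, so V_p >= 0 is a
    repulsive barrier, linear in the pore occupancy l_p.
    """
    from .transport import OccupancyGeometry, pore_occupancy

    geom = OccupancyGeometry.from_system(system)
    lp = pore_occupancy(geom, zp)
    if phim is None:
        phim = membrane_potential(system)
    return -system.tau * float(phim(system.a)) * lp


@dataclass(frozen=True)
class SelfEnergyParams:
    """Inputs of the image-charge self-energy integral.

    lp: in-pore polymer length (nm); tau: linear charge-density magnitude
    (e/nm); kappa: screening parameter (nm^-1); d: pore radius (nm);
    gamma_eps: dielectric contrast eps_m/eps_w; lb: Bjerrum length (nm).
    """

    lp: float
    tau: float
    kappa: float
    d: float
    gamma_eps: float
    lb: float = bjerrum_length()

    def __post_init__(self):
        if self.lp < 0:
            raise ValueError("lp must be >= 0")
        if self.kappa < 0 or self.d <= 0:
            raise ValueError("require kappa >= 0 and d > 0")
        if not (0 < self.gamma_eps < 1):
            raise ValueError("require 0 < gamma_eps < 1")

    @classmethod
    def from_system(cls, system: PoreSystem, lp: float) -> "SelfEnergyParams":
        el = system.electrolyte
        return cls(lp=lp, tau=system.tau, kappa=el.kappa, d=system.d,
                   gamma_eps=el.gamma_eps, lb=el.lb)


def dielectric_jump(q, params: SelfEnergyParams):
    """Dielectric jump function Delta(q) of the membrane pore.

    Delta(q) = [pb K0(|q|d) K1(pb d) - g |q| K1(|q|d) K0(pb d)]
             / [pb K0(|q|d) I1(pb d) + g |q| K1(|q|d) I0(pb d)],
    with pb = sqrt(kappa^2 + q^2) and g = eps_m/eps_w.  Even in q; decays
    exponentially (~e^(-2 pb d)) at large |q|d.  The q -> 0 limit is
    K1(kappa d)/I1(kappa d).
    """
    q = np.abs(np.asarray(q, dtype=float))
    d, g, kappa = params.d, params.gamma_eps, params.kappa
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    out = np.empty_like(q)
    small = q * d < 1e-12
    if np.any(small):
        if kappa <= 0:
            raise ValueError("Delta(0) diverges without screening (kappa=0)")
        out[small] = kv(1, kappa * d) / iv(1, kappa * d)
    qs = q[~small]
    if qs.size:
        pb = np.sqrt(kappa**2 + qs**2)
        # scaled Bessels: K_n(x) = kve(n,x) e^-x, I_n(x) = ive(n,x) e^x
        k0q, k1q = kve(0, qs * d), kve(1, qs * d)
        num = pb * k0q * kve(1, pb * d) - g * qs * k1q * kve(0, pb * d)
        den = pb * k0q * ive(1, pb * d) + g * qs * k1q * ive(0, pb * d)
        out[~small] = num / den * np.exp(-2.0 * pb * d)
    return out[0] if scalar else out


def image_self_energy(params: SelfEnergyParams, qmax: float | None = None,
                      rtol: float = 1e-8) -> float:
    """Image-charge self-energy beta*dOmega_p(lp) in kBT.

    Fourier integral of the charged-line self-interaction with its
    dielectric image:  lp lB tau^2 * Int dq [2 sin^2(q lp/2)/(pi lp q^2)]
    Delta(q), taken over the whole real line (even integrand, computed as
    twice the half-line integral).  Positive for gamma_eps < 1: the
    low-permittivity membrane repels the polymer charge.
    """
    lp, tau = params.lp, params.tau
    if lp == 0.0 or tau == 0.0:
        return 0.0
    if qmax is None:
        qmax = max(40.0 / params.d, 20.0 * params.kappa)

    def integrand(q):
        if q * lp < 1e-8:
            return lp / (2.0 * math.pi) * float(dielectric_jump(0.0, params))
        w = 2.0 * math.sin(q * lp / 2.0) ** 2 / (math.pi * lp * q * q)
        return w * float(dielectric_jump(q, params))

    val, err = quad(integrand, 0.0, qmax, limit=800, epsrel=rtol, epsabs=1e-13)
    if not math.isfinite(val) or (abs(val) > 0 and err > 1e-3 * abs(val)):
        raise ArithmeticError(
            f"self-energy quadrature failed: value={val:g}, abs err={err:g}")
    return lp * params.lb * tau**2 * 2.0 * val


def cumulative_charge(system: PoreSystem, field: RadialField, r: float) -> float:
    """Net charge per unit length enclosed within radius r, in e/nm.

    Q_cum(r) = -2 pi a sigma_p + 2 pi Int_a^r r' rho_c(r') dr', including
    the full polymer surface shell at r = a.  The mobile-charge density is
    the linearized Boltzmann response rho_c = -kappa^2 phi / (4 pi lB)
    consistent with the Debye-Hückel field.  For a neutral membrane the
    annulus is globally electroneutral: Q_cum(d) = 0.
    """
    if not (system.a - 1e-9 <= r <= system.d + 1e-9):
        raise ValueError(f"radius {r} outside [{system.a}, {system.d}]")
    el = system.electrolyte
    pref = -el.kappa**2 / (2.0 * el.lb)
    integral, _ = quad(lambda x: x * float(field(x)), system.a, min(r, system.d),
                       limit=200)
    return -system.tau + pref * integral


def pb_annulus_potential(system: PoreSystem, n_grid: int = 401) -> RadialField:
    """Nonlinear Poisson-Boltzmann solution on the annulus (validation oracle).

    Solves phi'' + phi'/r = -4 pi lB sum_i q_i rho_i e^(-q_i phi) with the
    same Gauss boundary conditions as the linear solver.  Used in tests to
    validate the Debye-Hückel field at weak coupling; not a primary path.
    """
    from scipy.integrate import solve_bvp

    el = system.electrolyte
    lb = el.lb
    gp = 4.0 * math.pi * lb * system.sigma_p
    gm = 4.0 * math.pi * lb * system.sigma_m

    def rho_c(phi):
        return sum(q * rho * np.exp(-q * phi) for q, rho in el.species)

    def rhs(r, y):
        return np.vstack([y[1], -y[1] / r - 4.0 * math.pi * lb * rho_c(y[0])])

    def bc(ya, yb):
        return np.array([ya[1] - gp, yb[1] + gm])

    r0 = np.linspace(system.a, system.d, n_grid)
    guess = dh_annulus_potential(system)
    y0 = np.vstack([guess(r0), np.gradient(guess(r0), r0)])
    sol = solve_bvp(rhs, bc, r0, y0, tol=1e-8, max_nodes=200000)
    if not sol.success:
        raise ArithmeticError(f"PB boundary-value solve failed: {sol.message}")
    grid = np.linspace(system.a, system.d, n_grid)
    return RadialField(grid, sol.sol(grid)[0],
                       _func=lambda r: sol.sol(np.asarray(r, float))[0],
                       _dfunc=lambda r: sol.sol(np.asarray(r, float))[1])
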