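"""Iso-flux tension propagation (IFTP) dynamics of driven translocation.

A long chain driven through a thin pore does not move as a whole: tension
propagates from the pore along the backbone, and only the sub-chain
behind the tension front (at distance R from the pore on the cis side)
is mobile.  The translocation coordinate s (number of translocated
segments) obeys overdamped Brownian dynamics with a time-dependent
friction Gamma = R + eta_p (pore-driven) or R + eta_p + s (end-pulled,
where the straightened trans-side sub-chain adds its own friction).  The
monomer flux phi = ds/dt is taken uniform over the mobile domain
(iso-flux), giving phi = f_tot / Gamma.

Everything is in the reduced units of the coarse-grained chain: segment
length, thermal energy and solvent friction per monomer all equal one.
Only the strong-stretching (SS) regime is implemented: the mobile
sub-chain is fully straightened, so the number of mobile cis monomers
equals the front distance, l = R.

Stages: during tension propagation (TP) the front advances following
R = A_nu N^nu with N = l + s the number of tensed monomers; when
N = N0 the post-propagation (PP) stage begins and the front retreats,
dR/dt = -phi, until the chain leaves the pore at s = N0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "IFTPParams",
    "IFTPResult",
    "iftp_solve",
    "waiting_time",
    "analytic_translocation_time",
    "scaling_exponent",
    "scaling_sweep",
]

FLORY_3D = 0.588
FLORY_2D = 0.75
SURFACE_3D = 0.69
SURFACE_2D = 0.95


@dataclass(frozen=True)
class IFTPParams:
    """Parameters of an IFTP run (reduced units).

    N0: chain contour length in segments; f: driving force (at the pore
    for ``mode='pore'``, on the head monomer for ``mode='end'``); eta_p:
    pore friction; nu: Flory exponent (0.588 in 3D, 0.75 in 2D);
    gamma_prime: surface exponent of the entropic pore force; A_nu:
    end-to-end amplitude in R = A_nu N^nu; chain: 'flexible' or 'stiff'
    (rodlike, R = N); entropic: include the (1-gamma') entropic force;
    noise: thermal noise (Euler-Maruyama, fixed step dt, mandatory seed);
    kT: reduced temperature of the noise.
    """

    N0: int
    f: float
    eta_p: float
    nu: float = FLORY_3D
    gamma_prime: float = SURFACE_3D
    A_nu: float = 1.15
    mode: str = "pore"
    chain: str = "flexible"
    entropic: bool = False
    noise: bool = False
    kT: float = 1.0
    dt: float = 1e-3
    seed: int | None = None

    def __post_init__(self):
        if self.N0 < 2:
            raise ValueError("N0 must be >= 2")
        if self.f <= 0:
            raise ValueError("driving force must be positive")
        if self.eta_p < 0:
            raise ValueError("pore friction must be >= 0")
        if not (0 < self.nu <= 1):
            raise ValueError("Flory exponent must be in (0, 1]")
        if not (0 <= self.gamma_prime <= 1):
            raise ValueError("surface exponent must be in [0, 1]")
        if self.A_nu <= 0:
            raise ValueError("A_nu must be positive")
        if self.mode not in ("pore", "end"):
            raise ValueError("mode must be 'pore' or 'end'")
        if self.chain not in ("flexible", "stiff"):
            raise ValueError("chain must be 'flexible' or 'stiff'")
        if self.noise and self.seed is None:
            raise ValueError("stochastic runs require an explicit seed")

    def with_(self, **kwargs) -> "IFTPParams":
        return replace(self, **kwargs)


@dataclass
class IFTPResult:
    """Trajectory and timing of one IFTP solution.

    Trajectory arrays sample (t, s, R, phi, Gamma) with ``stage`` 0 for
    TP and 1 for PP; tau = tau_TP + tau_PP is the translocation time.
    """

    t: np.ndarray
    s: np.ndarray
    R: np.ndarray
    phi: np.ndarray
    Gamma: np.ndarray
    stage: np.ndarray
    tau: float
    tau_TP: float
    tau_PP: float
    params: IFTPParams

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "s": self.s, "R": self.R, "phi": self.phi,
            "Gamma": self.Gamma,
            "stage": np.where(self.stage == 0, "TP", "PP"),
        })


def _entropic_force(params: IFTPParams, s: float) -> float:
    if not params.entropic:
        return 0.0
    sc = min(max(s, 1.0), params.N0 - 1.0)  # singular at the chain ends
    return (1.0 - params.gamma_prime) * (1.0 / (params.N0 - sc) - 1.0 / sc)


def _friction(params: IFTPParams, R: float, s: float) -> float:
    g = R + params.eta_p
    if params.mode == "end":
        g += s  # straightened trans-side sub-chain
    return g


def _solve_deterministic(params: IFTPParams, rtol: float, atol: float,
                         max_step: float | None):
    N0, f, A, nu = params.N0, params.f, params.A_nu, params.nu

    def flux(R, s):
        return (f + _entropic_force(params, s)) / _friction(params, R, s)

    kwargs = dict(method="RK45", rtol=rtol, atol=atol, dense_output=True)
    if max_step is not None:
        kwargs["max_step"] = max_step

    if params.chain == "stiff":
        # Rodlike limit: tension spans the chain immediately (R = N0 - s
        # on the cis side), the TP stage is negligible and the whole
        # process is PP with constant total friction for the end-pulled
        # and pore-driven cases alike.
        def rhs(t, y):
            s = y[0]
            R = N0 - s
            g = R + params.eta_p + s  # cis rod + pore + trans rod
            return [(f + _entropic_force(params, s)) / g]

        def done(t, y):
            return y[0] - N0
        done.terminal = True
        done.direction = 1
        t_hi = 10.0 * (params.eta_p * N0 + N0**2) / f + 1.0
        sol = solve_ivp(rhs, (0.0, t_hi), [0.0], events=done, **kwargs)
        if not sol.t_events[0].size:
            raise ArithmeticError("stiff-chain integration did not finish")
        tau = float(sol.t_events[0][0])
        t = np.append(sol.t, tau)
        s = np.append(sol.y[0], N0)
        R = N0 - s
        phi = np.array([flux_stiff(params, si, f) for si in s])
        Gamma = np.full_like(s, N0 + params.eta_p)
        stage = np.ones_like(s, dtype=int)
        res = IFTPResult(t, s, R, phi, Gamma, stage, tau, 0.0, tau, params)
        res._s_of_t = lambda tt: float(sol.sol(min(tt, tau))[0])
        return res

    # --- flexible chain, TP stage ---
    c = nu * A ** (1.0 / nu)  # R-dot = c R^((nu-1)/nu) phi / (1 - c R^((nu-1)/nu))
    R0 = A  # front seeded with one tensed segment, N(0) = 1

    def denom(R):
        return 1.0 - c * R ** ((nu - 1.0) / nu)

    if denom(R0) <= 0.0:
        raise ArithmeticError(
            "tension-front equation singular at the initial front position; "
            f"need nu*A_nu < 1 in the seeded state (got {c * R0**((nu-1)/nu):.3f})")

    def rhs_tp(t, y):
        s, R = y
        ph = flux(R, s)
        dn = denom(R)
        if dn <= 0.0:
            raise ArithmeticError("tension-front denominator crossed zero "
                                  f"at R={R:.4g}; reduce the step size")
        return [ph, c * R ** ((nu - 1.0) / nu) * ph / dn]

    def tp_done(t, y):
        return (y[0] + y[1]) - N0  # N = s + l, l = R in SS
    tp_done.terminal = True
    tp_done.direction = 1

    tau_cap = 10.0 * analytic_translocation_time(params) + 10.0
    sol_tp = solve_ivp(rhs_tp, (0.0, tau_cap), [0.0, R0], events=tp_done,
                       **kwargs)
    if not sol_tp.t_events[0].size:
        raise ArithmeticError("TP stage did not reach the chain end")
    tau_tp = float(sol_tp.t_events[0][0])
    s_sw, R_sw = sol_tp.y_events[0][0]

    # --- PP stage: front retreats, dR/dt = -phi ---
    def rhs_pp(t, y):
        s, R = y
        ph = flux(R, s)
        return [ph, -ph]

    def pp_done(t, y):
        return y[0] - N0
    pp_done.terminal = True
    pp_done.direction = 1

    sol_pp = solve_ivp(rhs_pp, (tau_tp, tau_tp + tau_cap), [s_sw, R_sw],
                       events=pp_done, **kwargs)
    if not sol_pp.t_events[0].size:
        raise ArithmeticError("PP stage did not finish")
    tau = float(sol_pp.t_events[0][0])

    t = np.concatenate([sol_tp.t, [tau_tp], sol_pp.t[1:], [tau]])
    s = np.concatenate([sol_tp.y[0], [s_sw], sol_pp.y[0][1:], [N0]])
    R = np.concatenate([sol_tp.y[1], [R_sw], sol_pp.y[1][1:],
                        [max(R_sw - (N0 - s_sw), 0.0)]])
    stage = np.concatenate([np.zeros(sol_tp.t.size + 1, dtype=int),
                            np.ones(sol_pp.t.size, dtype=int)])
    phi = np.array([flux(Ri, si) for Ri, si in zip(R, s)])
    Gamma = np.array([_friction(params, Ri, si) for Ri, si in zip(R, s)])
    res = IFTPResult(t, s, R, phi, Gamma, stage, tau, tau_tp, tau - tau_tp,
                     params)

    def s_of_t(tt):
        if tt <= tau_tp:
            return float(sol_tp.sol(tt)[0])
        return float(sol_pp.sol(min(tt, tau))[0])

    def R_of_t(tt):
        if tt <= tau_tp:
            return float(sol_tp.sol(tt)[1])
        return float(sol_pp.sol(min(tt, tau))[1])

    res._s_of_t = s_of_t
    res._R_of_t = R_of_t
    return res


def flux_stiff(params: IFTPParams, s: float, f: float) -> float:
    return (f + _entropic_force(params, s)) / (params.N0 + params.eta_p)


def _solve_stochastic(params: IFTPParams):
    """Fixed-step Euler-Maruyama with noise variance 2 Gamma kT dt."""
    rng = np.random.default_rng(params.seed)
    N0, f, A, nu, dt = params.N0, params.f, params.A_nu, params.nu, params.dt
    c = nu * A ** (1.0 / nu)
    stiff = params.chain == "stiff"
    s = 1e-12
    R = float(N0) if stiff else A
    t = 0.0
    in_pp = stiff
    ts, ss, Rs, phis, Gs, stages = [], [], [], [], [], []
    w = np.zeros(N0)  # waiting-time bins accumulated online
    max_steps = int(5e8)
    stride = max(1, int(round(0.01 / dt)))  # record every ~0.01 time units
    for step in range(max_steps):
        if stiff:
            R = N0 - s
            G = N0 + params.eta_p
        else:
            G = _friction(params, R, s)
        fdet = f + _entropic_force(params, s)
        noise = math.sqrt(2.0 * G * params.kT * dt) * rng.standard_normal()
        ds = (fdet * dt + noise) / G
        phi = fdet / G
        if step % stride == 0:
            ts.append(t); ss.append(s); Rs.append(R); phis.append(phi)
            Gs.append(G); stages.append(1 if in_pp else 0)
        w[min(int(s), N0 - 1)] += dt
        s_new = s + ds
        if s_new < 0.0:
            s_new = -s_new  # reflect at the pore entrance
        if not stiff:
            if not in_pp:
                dn = 1.0 - c * R ** ((nu - 1.0) / nu)
                if dn <= 0.0:
                    raise ArithmeticError("tension-front denominator crossed "
                                          "zero in the stochastic TP stage")
                R = R + c * R ** ((nu - 1.0) / nu) * max(ds, 0.0) / dn
                if s_new + R >= N0:
                    in_pp = True
                    R = max(N0 - s_new, 0.0)
            else:
                R = max(R - max(ds, 0.0), 0.0)
        s = min(s_new, float(N0))
        t += dt
        if s >= N0:
            break
    else:
        raise ArithmeticError("stochastic integration exceeded step budget")
    ts.append(t); ss.append(s); Rs.append(0.0 if not stiff else N0 - s)
    phis.append(phi); Gs.append(G); stages.append(1)
    tau_tp = 0.0
    arr_stage = np.array(stages)
    if not stiff and np.any(arr_stage == 1):
        idx = int(np.argmax(arr_stage == 1))
        tau_tp = ts[idx]
    res = IFTPResult(np.array(ts), np.array(ss), np.array(Rs),
                     np.array(phis), np.array(Gs), arr_stage,
                     t, tau_tp, t - tau_tp, params)
    res._w = w
    return res


def iftp_solve(params: IFTPParams, rtol: float = 1e-10, atol: float = 1e-12,
               max_step: float | None = None) -> IFTPResult:
    """Integrate the IFTP equations of motion to full translocation.

    Deterministic runs use an adaptive Runge-Kutta scheme with event
    detection for the TP -> PP switch (l + s = N0) and for termination
    (s = N0); stochastic runs use fixed-step Euler-Maruyama.
    """
    if params.noise:
        return _solve_stochastic(params)
    out = _solve_deterministic(params, rtol, atol, max_step)
    if isinstance(out, IFTPResult):
        return out
    t, s, R, phi, Gamma, stage, tau_tp, tau = out
    return IFTPResult(t, s, R, phi, Gamma, stage, tau, tau_tp, tau - tau_tp,
                      params)


def waiting_time(result: IFTPResult) -> np.ndarray:
    """Waiting-time profile w(k): time spent with s in [k-1, k), k = 1..N0.

    The per-monomer residence time at the pore; its sum over bins equals
    the translocation time up to discretization of the trajectory.
    """
    params = result.params
    N0 = params.N0
    if result.s[-1] < N0 - 1e-6:
        raise RuntimeError("trajectory incomplete; cannot bin waiting times")
    w_online = getattr(result, "_w", None)
    if w_online is not None:  # stochastic runs accumulate bins online
        return w_online
    s_of_t = getattr(result, "_s_of_t", None)
    if s_of_t is not None:
        # invert the monotone dense solution s(t) at integer s
        from scipy.optimize import brentq

        tau = result.tau
        times = [0.0]
        for k in range(1, N0):
            times.append(brentq(lambda t: s_of_t(t) - k, times[-1], tau,
                                xtol=1e-12 * max(tau, 1.0)))
        times.append(tau)
        return np.diff(np.array(times))
    # fallback: bin the recorded trajectory
    t, s = result.t, result.s
    edges = np.arange(0, N0 + 1)
    w = np.zeros(N0)
    mids = 0.5 * (s[:-1] + s[1:])
    dts = np.diff(t)
    idx = np.clip(np.searchsorted(edges, mids, side="right") - 1, 0, N0 - 1)
    np.add.at(w, idx, dts)
    return w


def mean_waiting_time(params: IFTPParams, n_traj: int,
                      seed: int) -> np.ndarray:
    """Average stochastic waiting-time profile over ``n_traj`` trajectories."""
    seq = np.random.SeedSequence(seed)
    profiles = []
    for child in seq.spawn(n_traj):
        p = params.with_(noise=True, seed=int(child.generate_state(1)[0] % 2**31))
        profiles.append(waiting_time(iftp_solve(p)))
    return np.mean(profiles, axis=0)


def analytic_translocation_time(params: IFTPParams) -> float:
    """Closed-form SS translocation time (f_tot ~ f approximation).

    pore-driven flexible: [A_nu N0^(1+nu)/(1+nu) + eta_p N0] / f
    end-pulled flexible:  ... + N0^2/2 inside the bracket
    stiff (either mode):  (eta_p N0 + N0^2) / f
    """
    N0, f, A, nu = params.N0, params.f, params.A_nu, params.nu
    if params.chain == "stiff":
        return (params.eta_p * N0 + N0**2) / f
    bracket = A * N0 ** (1.0 + nu) / (1.0 + nu) + params.eta_p * N0
    if params.mode == "end":
        bracket += N0**2 / 2.0
    return bracket / f


def _rescale(taus, N0s, mode, f, eta_p, A_nu, nu):
    taus = np.asarray(taus, dtype=float)
    N0s = np.asarray(N0s, dtype=float)
    if mode in (None, "none"):
        return taus
    if mode in ("pore-friction", "pore_friction"):
        return taus - eta_p * N0s / f
    if mode in ("trans-side", "trans_side"):
        cis = A_nu * N0s ** (1.0 + nu) / (1.0 + nu)
        return taus - (cis + eta_p * N0s) / f
    raise ValueError(f"unknown rescale mode {mode!r}")


def scaling_exponent(N0s: Sequence, taus: Sequence, rescale: str = "none",
                     f: float = 1.0, eta_p: float = 0.0, A_nu: float = 1.15,
                     nu: float = FLORY_3D, window: tuple | None = None) -> float:
    """Log-log slope of the (rescaled) translocation time versus N0.

    rescale='pore-friction' subtracts the pore-friction term eta_p N0/f
    (exposes the cis-side contribution, slope 1+nu); 'trans-side'
    additionally subtracts the cis-side integral (end-pulled case,
    exposes the trans-side N0^2 term, slope 2).  ``window`` restricts the
    fit to N0 in [lo, hi].
    """
    N0s = np.asarray(N0s, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if N0s.size < 4:
        raise ValueError("need at least 4 points to fit an exponent")
    y = _rescale(taus, N0s, rescale, f, eta_p, A_nu, nu)
    if window is not None:
        m = (N0s >= window[0]) & (N0s <= window[1])
        N0s, y = N0s[m], y[m]
    if np.any(y <= 0):
        bad = N0s[y <= 0]
        raise ValueError(f"non-positive rescaled times at N0 = {bad}")
    slope, _ = np.polyfit(np.log(N0s), np.log(y), 1)
    return float(slope)


def scaling_sweep(base: IFTPParams, N0s: Sequence) -> np.ndarray:
    """Deterministic translocation times over a chain-length grid."""
    return np.array([iftp_solve(base.with_(N0=int(n))).tau for n in N0s])
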