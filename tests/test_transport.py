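"""Steady-state Smoluchowski engine: rates, times, profiles, criticals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanotransloc import (
    Electrolyte,
    build_effective_potential,
    capture_rate,
    critical_length,
    critical_pressure,
    density_profile,
    mean_velocity,
    pore_occupancy,
    translocation_time,
    trapping_salt_densities,
)
from nanotransloc.constants import ATM_TO_PA, nm3_to_molar
from nanotransloc.hydrodynamics import geometric_factor
from nanotransloc.transport import (
    EffectivePotential,
    OccupancyGeometry,
    _vp_mean_for,
    dilute_expansion_coefficients,
)

from conftest import make_system


class TestPoreOccupancy:
    GEOM = OccupancyGeometry.from_lengths(Lm=5.0, Lp=10.0)

    def test_empty_at_both_ends(self):
        assert pore_occupancy(self.GEOM, 0.0) == 0.0
        assert pore_occupancy(self.GEOM, 15.0) == 0.0

    def test_plateau_value(self):
        # between L- and L+ the in-pore length is pinned at min(Lm, Lp)
        assert pore_occupancy(self.GEOM, 7.0) == 5.0

    def test_continuity_at_breakpoints(self):
        for zb in (5.0, 10.0):
            left = pore_occupancy(self.GEOM, zb - 1e-12)
            right = pore_occupancy(self.GEOM, zb + 1e-12)
            assert left == pytest.approx(right, abs=1e-11)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(Lm=st.floats(1.0, 50.0), Lp=st.floats(1.0, 50.0),
           frac=st.floats(0.0, 1.0))
    def test_piecewise_linear_bounds(self, Lm, Lp, frac):
        geom = OccupancyGeometry.from_lengths(Lm, Lp)
        zp = frac * geom.zex
        lp = pore_occupancy(geom, zp)
        assert 0.0 <= lp <= geom.L_minus + 1e-12
        assert lp <= zp + 1e-12 and lp <= geom.zex - zp + 1e-12

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            pore_occupancy(self.GEOM, 16.0)


def _flat_potential(D=1e7, Lm=5.0, Lp=10.0):
    geom = OccupancyGeometry.from_lengths(Lm, Lp)
    zero = lambda z: np.zeros_like(np.asarray(z, dtype=float))
    return EffectivePotential(zero, zero, D=D, Dp_a=D, geometry=geom)


def _linear_potential(lam_d, D=1e7, Lm=5.0, Lp=10.0):
    geom = OccupancyGeometry.from_lengths(Lm, Lp)
    f = lambda z: -lam_d * np.asarray(z, dtype=float)
    df = lambda z: np.full_like(np.asarray(z, dtype=float), -lam_d)
    return EffectivePotential(f, df, D=D, Dp_a=D, geometry=geom,
                              lambda_d=lam_d)


class TestEffectivePotential:
    def test_drift_only_slope(self):
        sys_ = make_system(sigma_m=0.0)
        pot = build_effective_potential(sys_, barrier="none")
        z = np.linspace(0, pot.zex, 9)
        np.testing.assert_allclose(pot.beta_Up(z), -pot.lambda_d * z,
                                   rtol=1e-12, atol=1e-14)

    def test_barrier_inverse_length_positive_for_anionic_pair(self):
        pot = build_effective_potential(make_system(), barrier="mf")
        assert pot.lambda_b > 0

    def test_mean_field_breakpoint_identity(self):
        # beta Up(L-) - beta Up(0) = (lambda_b - lambda_d) L-
        pot = build_effective_potential(make_system(), barrier="mf")
        Lm_ = pot.geometry.L_minus
        lhs = float(pot.beta_Up(Lm_)) - float(pot.beta_Up(0.0))
        assert lhs == pytest.approx((pot.lambda_b - pot.lambda_d) * Lm_,
                                    rel=1e-10)

    def test_gauge_choice(self):
        pot = build_effective_potential(make_system(), barrier="mf")
        assert float(pot.beta_Up(0.0)) == 0.0


class TestCaptureRate:
    def test_flat_potential_closed_form(self):
        pot = _flat_potential()
        assert capture_rate(pot) == pytest.approx(pot.D / pot.zex, rel=1e-10)

    @pytest.mark.parametrize("lam_zex", [-30.0, -5.0, 5.0, 30.0])
    def test_drift_identity(self, lam_zex):
        """Pure drift: Rc = v_dr / (1 - e^(-v_dr zex / D)) for both signs."""
        pot = _linear_potential(lam_zex / 15.0)
        vdr = pot.lambda_d * pot.D
        expected = vdr / (1.0 - math.exp(-vdr * pot.zex / pot.D))
        assert capture_rate(pot) == pytest.approx(expected, rel=1e-8)

    def test_riemann_oracle(self):
        """Arbitrary potential: quadrature agrees with a brute-force
        midpoint Riemann sum on 1e6 points."""
        geom = OccupancyGeometry.from_lengths(5.0, 10.0)
        f = lambda z: 2.0 * np.sin(np.asarray(z) * 1.3) - 0.4 * np.asarray(z)
        df = lambda z: 2.6 * np.cos(np.asarray(z) * 1.3) - 0.4
        pot = EffectivePotential(f, df, D=1e7, Dp_a=1e7, geometry=geom)
        z = (np.arange(1_000_000) + 0.5) * geom.zex / 1_000_000
        riemann = pot.D / (np.mean(np.exp(f(z) - f(np.array(0.0)))) * geom.zex)
        assert capture_rate(pot) == pytest.approx(riemann, rel=1e-6)

    def test_monotone_decreasing_under_potential_increase(self):
        geom = OccupancyGeometry.from_lengths(5.0, 10.0)
        rates = []
        for h in (0.0, 1.0, 2.0, 4.0):
            f = lambda z, h=h: h * np.sin(np.asarray(z) / geom.zex * math.pi) ** 2
            pot = EffectivePotential(f, lambda z: 0 * np.asarray(z),
                                     D=1e7, Dp_a=1e7, geometry=geom)
            rates.append(capture_rate(pot))
        assert np.all(np.diff(rates) < 0)

    def test_gauge_invariance(self):
        pot = _linear_potential(0.3)
        shifted = EffectivePotential(
            lambda z: pot.beta_Up(z) + 7.5, pot.dbeta_Up, D=pot.D,
            Dp_a=pot.Dp_a, geometry=pot.geometry, lambda_d=pot.lambda_d)
        assert capture_rate(shifted) == pytest.approx(capture_rate(pot),
                                                      rel=1e-12)


class TestTranslocationTime:
    def test_flat_potential_closed_form(self):
        pot = _flat_potential()
        tau, *_ = translocation_time(pot)
        assert tau == pytest.approx(pot.zex**2 / (2 * pot.D), rel=1e-8)

    def test_component_sum_rule(self):
        pot = _linear_potential(0.8)
        tau, t1, t2, t3 = translocation_time(pot)
        assert tau == t1 + t2 + t3  # exact by construction

    def test_strong_drift_limit(self):
        """v_dr zex / D > 50: tau approaches the ballistic time zex/v_dr."""
        pot = _linear_potential(60.0 / 15.0)  # lambda_d * zex = 60
        vdr = pot.lambda_d * pot.D
        tau, *_ = translocation_time(pot)
        assert tau == pytest.approx(pot.zex / vdr, rel=0.05)

    def test_gauge_invariance(self):
        pot = _linear_potential(-0.5)
        shifted = EffectivePotential(
            lambda z: pot.beta_Up(z) - 3.0, pot.dbeta_Up, D=pot.D,
            Dp_a=pot.Dp_a, geometry=pot.geometry, lambda_d=pot.lambda_d)
        assert translocation_time(shifted)[0] == pytest.approx(
            translocation_time(pot)[0], rel=1e-10)

    def test_double_integral_oracle(self):
        """Nested trapezoid on an independent uniform grid reproduces the
        segment-wise evaluation."""
        pot = _linear_potential(0.6)
        z = np.linspace(0, pot.zex, 3001)
        bu = pot.beta_Up(z)
        inner = np.concatenate([
            np.cumsum((0.5 * np.diff(z) * (np.exp(bu)[:-1] + np.exp(bu)[1:]))[::-1])[::-1],
            [0.0]])
        oracle = np.trapezoid(np.exp(-bu) * inner, z) / pot.D
        tau, *_ = translocation_time(pot)
        assert tau == pytest.approx(oracle, rel=1e-6)


class TestDensityProfile:
    def test_boundary_conditions(self):
        pot = _linear_potential(0.4)
        zs, c, _ = density_profile(pot, ccis=2.0)
        assert c[0] == pytest.approx(2.0, rel=1e-12)
        assert c[-1] == 0.0

    def test_flat_potential_linear_profile(self):
        pot = _flat_potential()
        zs, c, N = density_profile(pot)
        np.testing.assert_allclose(c, 1 - zs / pot.zex, rtol=0, atol=1e-13)
        assert N == pytest.approx(pot.zex / 2, rel=1e-9)

    def test_flux_constancy(self):
        """J = -D c' + vp c from the computed profile is constant (= Rc ccis)
        at interior points away from the potential kinks."""
        sys_ = make_system()
        pot = build_effective_potential(sys_, barrier="mf")
        zs, c, _ = density_profile(pot)
        Rc = capture_rate(pot)
        L_minus, L_plus = pot.breakpoints
        for z_target in (0.3 * L_minus, 0.7 * L_minus,
                         0.5 * (L_minus + L_plus),
                         L_plus + 0.3 * (pot.zex - L_plus),
                         L_plus + 0.7 * (pot.zex - L_plus)):
            i = int(np.argmin(np.abs(zs - z_target)))
            dz = zs[i + 1] - zs[i - 1]
            cp = (c[i + 1] - c[i - 1]) / dz
            J = -pot.D * cp + float(pot.vp(zs[i])) * c[i]
            assert J == pytest.approx(Rc, rel=1e-5)

    def test_invalid_ccis(self):
        with pytest.raises(ValueError):
            density_profile(_flat_potential(), ccis=0.0)


class TestMeanVelocity:
    def test_flat_is_zero_and_pure_drift_is_vdr(self):
        assert mean_velocity(_flat_potential()) == pytest.approx(0.0, abs=1e-6)
        pot = _linear_potential(0.9)
        vdr = pot.lambda_d * pot.D
        assert mean_velocity(pot) == pytest.approx(vdr, rel=1e-10)

    def test_drift_barrier_approximation(self):
        """In both the drift-dominated and barrier-dominated regimes
        <vp> ~ D (lambda_d - lambda_b) within 10%."""
        drift_sys = make_system()  # lambda_d >> lambda_b
        pot = build_effective_potential(drift_sys, barrier="mf")
        assert pot.lambda_d > 5 * pot.lambda_b
        assert mean_velocity(pot) == pytest.approx(
            pot.D * (pot.lambda_d - pot.lambda_b), rel=0.10)

        barrier_sys = make_system(delta_V=-0.005, sigma_m=0.3,
                                  electrolyte=Electrolyte.monovalent(0.03))
        potb = build_effective_potential(barrier_sys, barrier="mf")
        assert potb.lambda_b > 5 * abs(potb.lambda_d)
        assert mean_velocity(potb) == pytest.approx(
            potb.D * (potb.lambda_d - potb.lambda_b), rel=0.10)

    def test_against_independent_quadrature(self):
        """Average of vp weighted by an independently computed Riemann
        density reproduces the engine value."""
        sys_ = make_system()
        pot = build_effective_potential(sys_, barrier="mf")
        z = (np.arange(400_000) + 0.5) * pot.zex / 400_000
        bu = pot.beta_Up(z)
        dz = pot.zex / 400_000
        inner = (np.cumsum(np.exp(bu)[::-1])[::-1]) * dz
        c = np.exp(-bu) * inner  # un-normalized steady profile
        oracle = float(np.sum(c * pot.vp(z)) / np.sum(c))
        assert mean_velocity(pot) == pytest.approx(oracle, rel=1e-4)


class TestCriticalPressure:
    def test_force_free_system_has_zero_critical_pressure(self):
        sys_ = make_system(sigma_p=0.0, sigma_m=0.0, delta_V=0.0)
        ps = critical_pressure(sys_, p_range=(-1e5, 1e5))
        assert ps == pytest.approx(0.0, abs=1.0)

    def test_local_slope_is_streaming_mobility(self):
        """Near dP*, d<vp>/d(dP) = gamma a^2 / (4 eta Lm) within 5%.

        A weak-barrier system keeps the density weighting close to
        uniform, where the linearized form holds."""
        sys_ = make_system(sigma_p=0.05, sigma_m=0.02, delta_V=-0.005)
        ps = critical_pressure(sys_, p_range=(-10 * ATM_TO_PA, 10 * ATM_TO_PA))
        assert ps is not None
        eps = 0.02 * ATM_TO_PA
        slope = (_vp_mean_for(sys_, "mf", delta_P=ps + eps)
                 - _vp_mean_for(sys_, "mf", delta_P=ps - eps)) / (2 * eps)
        eta = sys_.electrolyte.viscosity
        predicted = geometric_factor(sys_.a, sys_.d) * sys_.a**2 / (4 * eta * sys_.Lm)
        assert slope == pytest.approx(predicted, rel=0.05)

    def test_root_agrees_with_dense_scan(self):
        sys_ = make_system(sigma_p=0.05, sigma_m=0.02, delta_V=-0.005)
        ps = critical_pressure(sys_, p_range=(-10 * ATM_TO_PA, 10 * ATM_TO_PA))
        grid = np.linspace(-10 * ATM_TO_PA, 10 * ATM_TO_PA, 2001)
        vs = np.array([_vp_mean_for(sys_, "mf", delta_P=float(p)) for p in grid])
        i = np.nonzero(np.diff(np.sign(vs)))[0][0]
        assert grid[i] <= ps <= grid[i + 1]

    def test_no_trapping_reported_as_none(self):
        sys_ = make_system(delta_V=0.2, sigma_m=0.0)
        assert critical_pressure(sys_, p_range=(1e4, 1e5)) is None


class TestTrappingSaltDensities:
    # voltage-driven, pressure-limited configuration deep in both regimes
    HIGH_SYS = make_system(a=2.0, d=6.0, Lm=50.0, Lp=100.0, sigma_p=0.4,
                           sigma_m=0.1, delta_V=0.1,
                           delta_P=-1.36 * ATM_TO_PA)

    def test_dilute_expansion_coefficients(self):
        # independent arithmetic at d/a = 2
        a, d = 1.0, 2.0
        L, den = math.log(2.0), 3.0
        ap, am = dilute_expansion_coefficients(a, d)
        assert ap == pytest.approx(-0.5 + 4 * L / den, rel=1e-14)
        assert am == pytest.approx(1.0 - 2 * L / den, rel=1e-14)

    def test_high_salt_closed_form_against_root(self):
        """In the validity regime kappa a >> 1 the closed-form trapping
        density agrees with the numerical root within 25%."""
        td = trapping_salt_densities(self.HIGH_SYS, rho_range=(0.05, 6.0))
        assert math.isfinite(td.high_closed) and math.isfinite(td.high_root)
        kappa_a = Electrolyte.monovalent(
            nm3_to_molar(td.high_root)).kappa * self.HIGH_SYS.a
        assert kappa_a > 5
        assert td.high_closed == pytest.approx(td.high_root, rel=0.25)

    def test_pressure_magnitude_lowers_trapping_density(self):
        """|dP| up => rho*> down (inverse-square dependence)."""
        from nanotransloc.transport import _closed_trapping_high

        rhos = [_closed_trapping_high(self.HIGH_SYS.with_(delta_P=-p * ATM_TO_PA))
                for p in (1.0, 2.0, 4.0)]
        assert np.all(np.diff(rhos) < 0)
        assert rhos[0] / rhos[1] == pytest.approx(4.0, rel=1e-10)

    def test_dilute_closed_form_against_root(self):
        """Dilute regime kappa a << 1: closed form within 25% of the root."""
        sys_ = make_system(a=1.0, d=5.0, Lm=20.0, Lp=180.0, sigma_p=0.4,
                           sigma_m=0.13, delta_V=0.15, delta_P=-0.05 * ATM_TO_PA)
        td = trapping_salt_densities(sys_, rho_range=(1e-4, 0.05))
        assert math.isfinite(td.low_closed)
        root = td.low_root if math.isnan(td.high_root) else min(td.low_root,
                                                                td.high_root)
        kappa_a = Electrolyte.monovalent(nm3_to_molar(root)).kappa * sys_.a
        assert kappa_a < 0.35
        assert td.low_closed == pytest.approx(root, rel=0.25)


class TestCriticalLength:
    def test_no_barrier_no_critical_length(self):
        sys_ = make_system(sigma_m=0.0, delta_V=0.05)
        assert critical_length(sys_, barrier="mf") is None

    def test_added_salt_shrinks_critical_length(self):
        base = make_system(delta_V=0.03, sigma_p=0.4, sigma_m=0.15)
        Ls = []
        for molar in (0.03, 0.05, 0.1):
            s = base.with_(electrolyte=Electrolyte.monovalent(molar))
            Ls.append(critical_length(s))
        assert all(L is not None for L in Ls)
        assert np.all(np.diff(Ls) < 0)

    def test_added_pressure_shrinks_critical_length(self):
        base = make_system(delta_V=0.03, sigma_p=0.4, sigma_m=0.15,
                           electrolyte=Electrolyte.monovalent(0.05))
        Ls = [critical_length(base.with_(delta_P=p * ATM_TO_PA))
              for p in (0.0, 0.5, 1.0)]
        assert all(L is not None for L in Ls)
        assert np.all(np.diff(Ls) < 0)


class TestAlphaHemolysinPhenomenology:
    def test_barrier_to_drift_transition_with_salt(self, ahl_system):
        """At 0.04 M the image-charge barrier reverses the local velocity
        inside the pore; at 0.1 M the drift wins everywhere."""
        pot_low = build_effective_potential(ahl_system, barrier="image")
        z_capture = np.linspace(0.05, ahl_system.Lm - 0.05, 60)
        v_low = pot_low.vp(z_capture)
        assert v_low.max() > 0 and v_low.min() < 0  # sign change before Lm

        high = ahl_system.with_(electrolyte=Electrolyte.monovalent(0.1))
        pot_high = build_effective_potential(high, barrier="image")
        z_all = np.linspace(0.05, high.zex - 0.05, 200)
        assert np.all(pot_high.vp(z_all) > 0)

    def test_capture_rate_saturates_at_drift_velocity(self, ahl_system):
        """Rc/v_dr grows monotonically with voltage and approaches 1."""
        from nanotransloc import drift_velocity

        high = ahl_system.with_(electrolyte=Electrolyte.monovalent(0.1))
        ratios = []
        for mV in (60, 80, 120, 200, 450):
            s = high.with_(delta_V=mV * 1e-3)
            pot = build_effective_potential(s, barrier="image")
            ratios.append(capture_rate(pot) / drift_velocity(s))
        assert np.all(np.diff(ratios) > 0)
        assert ratios[0] < 0.9
        assert 0.97 < ratios[-1] <= 1.0 + 1e-9
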