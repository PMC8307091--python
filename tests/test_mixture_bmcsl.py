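"""BMCSL mixture resummation: coefficient identities, coupled
self-consistency, mixture thermodynamics and binary coexistence."""

import numpy as np
import pytest

from hardnem.geometry import ProlateSpheroid
from hardnem.mixture_bmcsl import (
    MixtureSpec,
    MixtureSystem,
    bmcsl_g,
    bmcsl_g_derivatives,
    mixture_thermo,
)
from hardnem.pure_onsager import PureSystem, lp_prefactor

SPEC = MixtureSpec(ProlateSpheroid(3.0, 12.0), ProlateSpheroid(3.0, 9.0))
SPEC_EQ = MixtureSpec(ProlateSpheroid(3.0, 9.0), ProlateSpheroid(3.0, 9.0))


class TestBmcslCoefficients:
    def test_equal_species_quadratic_form_reduces_to_pure(self, rng):
        """sum_kl rho_k rho_l g_kl equals rho^2 (4-3 eta)/(z (1-eta)^2) for
        identical species at any composition split."""
        v = SPEC_EQ.v_A
        for _ in range(20):
            eta = rng.uniform(0.05, 0.85)
            x = rng.uniform(0.01, 0.99)
            z = float(rng.choice([3.0, 4.0]))
            rA, rB = x * eta / v, (1 - x) * eta / v
            t = bmcsl_g(SPEC_EQ, rA, rB, z)
            lhs = rA**2 * t.g_AA + rA * rB * t.g_cross_sym + rB**2 * t.g_BB
            rhs = (rA + rB) ** 2 * lp_prefactor(eta, z)
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_one_component_limit_is_pure_prefactor(self):
        eta = 0.47
        t = bmcsl_g(SPEC, eta / SPEC.v_A, 0.0, 3.0)
        assert t.g_AA == pytest.approx(lp_prefactor(eta, 3.0), rel=1e-13)
        assert np.isinf(t.g_BB)
        # the finite product rho_B g_BB stays defined at rho_B = 0
        assert np.isfinite(t.rhoB_gBB)

    def test_dilute_limit_normalization(self):
        # n3 -> 0 with z = 4 recovers the second-virial normalization g = 1
        t = bmcsl_g(SPEC, 1e-10 / SPEC.v_A, 0.0, 4.0)
        assert t.g_AA == pytest.approx(1.0, abs=1e-6)

    def test_overpacked_state_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            bmcsl_g(SPEC, 0.6 / SPEC.v_A, 0.6 / SPEC.v_B, 3.0)

    def test_species_relabeling_symmetry(self):
        t = bmcsl_g(SPEC, 0.25 / SPEC.v_A, 0.2 / SPEC.v_B, 3.0)
        ts = bmcsl_g(SPEC.swapped(), 0.2 / SPEC.v_B, 0.25 / SPEC.v_A, 3.0)
        assert t.g_AA == pytest.approx(ts.g_BB, rel=1e-14)
        assert t.g_AB == pytest.approx(ts.g_BA, rel=1e-14)


class TestBmcslDerivatives:
    def test_matches_finite_differences(self, rng):
        for _ in range(8):
            eA, eB = rng.uniform(0.05, 0.4, 2)
            rA, rB = eA / SPEC.v_A, eB / SPEC.v_B
            d = bmcsl_g_derivatives(SPEC, rA, rB, 3.0)
            h = 1e-6 / max(SPEC.v_A, SPEC.v_B)
            for (i, j, k), val in d.d.items():
                dA, dB = (h, 0.0) if k == "A" else (0.0, h)
                gp = getattr(bmcsl_g(SPEC, rA + dA, rB + dB, 3.0), f"g_{i}{j}")
                gm = getattr(bmcsl_g(SPEC, rA - dA, rB - dB, 3.0), f"g_{i}{j}")
                assert val == pytest.approx((gp - gm) / (2 * h), rel=1e-6)

    def test_relabeling_maps_diagonal_derivatives(self):
        d = bmcsl_g_derivatives(SPEC, 0.2 / SPEC.v_A, 0.2 / SPEC.v_B, 3.0)
        ds = bmcsl_g_derivatives(SPEC.swapped(), 0.2 / SPEC.v_B, 0.2 / SPEC.v_A, 3.0)
        assert d[("A", "A", "A")] == pytest.approx(ds[("B", "B", "B")], rel=1e-14)
        assert d[("A", "B", "A")] == pytest.approx(ds[("B", "A", "B")], rel=1e-14)

    def test_equal_species_quadratic_derivative_sum(self, rng):
        """Differentiating the equal-species reduction identity:
        sum_kl rho_k rho_l dg_kl/drho_A + 2 rho_A g_AA + rho_B (g_AB+g_BA)
        equals d/drho_A [rho^2 (4-3eta)/(z(1-eta)^2)]."""
        v = SPEC_EQ.v_A
        for _ in range(5):
            eta = rng.uniform(0.1, 0.7)
            x = rng.uniform(0.05, 0.95)
            rA, rB = x * eta / v, (1 - x) * eta / v
            t = bmcsl_g(SPEC_EQ, rA, rB, 3.0)
            d = bmcsl_g_derivatives(SPEC_EQ, rA, rB, 3.0)
            rr = d.rr
            lhs = (
                rr[("A", "A", "A")] + rr[("A", "B", "A")] + rr[("B", "A", "A")] + rr[("B", "B", "A")]
                + 2 * rA * t.g_AA + rB * t.g_cross_sym
            )
            rho = rA + rB
            rhs = 2 * rho * lp_prefactor(eta, 3.0) + rho**2 * v * (5 - 3 * eta) / (
                3.0 * (1 - eta) ** 3
            )
            assert lhs == pytest.approx(rhs, rel=1e-10)


class TestCoupledSolver:
    def test_isotropic_is_fixed_point(self, mix_12_9):
        st = mix_12_9.solve(0.2 / SPEC.v_A, 0.2 / SPEC.v_B, init="isotropic")
        assert np.max(np.abs(st.f_A.values - 1.0)) < 1e-7
        assert np.max(np.abs(st.f_B.values - 1.0)) < 1e-7

    def test_vanishing_species_recovers_pure_distribution(self, mix_12_9, grid_default):
        rho = 0.40 / SPEC.v_A
        st = mix_12_9.solve(rho, 0.0, init="nematic")
        pure = PureSystem(SPEC.A, "rigorous", 3.0, grid=grid_default).state(rho, init="nematic")
        assert np.max(np.abs(st.f_A.values - pure.f.values)) < 1e-8

    def test_equal_species_even_split_recovers_pure(self, grid_default):
        sysE = MixtureSystem(SPEC_EQ, 3.0, grid=grid_default)
        pure = PureSystem(SPEC_EQ.A, "rigorous", 3.0, grid=grid_default)
        rho = 0.53 / SPEC_EQ.v_A
        st = sysE.solve(0.5 * rho, 0.5 * rho, init="nematic")
        ps = pure.state(rho, init="nematic")
        assert np.max(np.abs(st.f_A.values - ps.f.values)) < 1e-7
        assert np.max(np.abs(st.f_B.values - ps.f.values)) < 1e-7
        assert st.pressure == pytest.approx(ps.pressure, rel=1e-8)
        # the mixture free energy carries the ideal entropy of mixing of the
        # two (distinguishable) labels on top of the pure free energy
        mixing = st.rho_A * np.log(0.5) + st.rho_B * np.log(0.5)
        assert st.helmholtz - mixing == pytest.approx(ps.helmholtz, rel=1e-8)
        assert st.mu_A_star - np.log(0.5) == pytest.approx(ps.mu_star, rel=1e-8)

    def test_longer_species_orders_more(self, mix_12_9):
        st = mix_12_9.solve(0.28 / SPEC.v_A, 0.22 / SPEC.v_B, init="nematic")
        assert st.S_A > st.S_B > 0.1


@pytest.fixture(scope="module")
def nematic_state(mix_12_9):
    return mix_12_9.solve(0.28 / SPEC.v_A, 0.22 / SPEC.v_B, init="nematic")


class TestMixtureThermo:
    def test_gibbs_duhem(self, mix_12_9, nematic_state):
        for st in (mix_12_9.solve(0.2 / SPEC.v_A, 0.25 / SPEC.v_B), nematic_state):
            lhs = st.pressure
            rhs = st.rho_A * st.mu_A_star + st.rho_B * st.mu_B_star - st.helmholtz
            assert abs(lhs - rhs) / lhs < 1e-6

    def test_mu_matches_partial_density_derivatives(self, mix_12_9, nematic_state):
        st = nematic_state
        for which in ("A", "B"):
            rho_i = st.rho_A if which == "A" else st.rho_B
            h = rho_i * 1e-6
            args = dict(init=(st.f_A, st.f_B))
            if which == "A":
                fp = mix_12_9.solve(st.rho_A + h, st.rho_B, **args).helmholtz
                fm = mix_12_9.solve(st.rho_A - h, st.rho_B, **args).helmholtz
                mu = st.mu_A_star
            else:
                fp = mix_12_9.solve(st.rho_A, st.rho_B + h, **args).helmholtz
                fm = mix_12_9.solve(st.rho_A, st.rho_B - h, **args).helmholtz
                mu = st.mu_B_star
            assert mu == pytest.approx((fp - fm) / (2 * h), rel=1e-5)

    def test_vanishing_species_recovers_pure_thermo(self, mix_12_9, grid_default):
        rho = 0.40 / SPEC.v_A
        st = mix_12_9.solve(rho, 0.0, init="nematic")
        pure = PureSystem(SPEC.A, "rigorous", 3.0, grid=grid_default).state(rho, init="nematic")
        F, muA, muB, P, Pstar, SA, SB = mixture_thermo(st)
        assert F == pytest.approx(pure.helmholtz, rel=1e-10)
        assert muA == pytest.approx(pure.mu_star, rel=1e-8)
        assert P == pytest.approx(pure.pressure, rel=1e-10)
        assert Pstar == pytest.approx(pure.pressure_star, rel=1e-10)
        assert SA == pytest.approx(pure.order_parameter, abs=1e-9)


class TestBinaryCoexistence:
    def test_equal_species_even_split_satisfies_all_equilibrium_conditions(self, grid_default):
        """Splitting each phase of the pure coexistence 50/50 between two
        identical species solves the four binary coexistence equations."""
        sysE = MixtureSystem(SPEC_EQ, 3.0, grid=grid_default)
        co = PureSystem(SPEC_EQ.A, "rigorous", 3.0, grid=grid_default).coexistence()
        iso = sysE.solve(0.5 * co.isotropic.rho, 0.5 * co.isotropic.rho, init="isotropic")
        nem = sysE.solve(
            0.5 * co.nematic.rho, 0.5 * co.nematic.rho, init=(co.nematic.f, co.nematic.f)
        )
        assert iso.pressure_star == pytest.approx(nem.pressure_star, abs=2e-5)
        assert iso.mu_A_star == pytest.approx(nem.mu_A_star, abs=2e-5)
        assert iso.mu_B_star == pytest.approx(nem.mu_B_star, abs=2e-5)
        assert iso.pressure_star == pytest.approx(co.pressure_star, rel=1e-8)

    def test_coexistence_point_contract(self, mix_12_9):
        from hardnem.mixture_bmcsl import binary_coexistence

        pt = binary_coexistence(mix_12_9, 18.0)
        assert pt.x_A_nem > pt.x_A_iso
        assert pt.nematic.n3 > pt.isotropic.n3
        assert pt.isotropic.pressure_star == pytest.approx(18.0, rel=1e-5)
        assert pt.nematic.pressure_star == pytest.approx(18.0, rel=1e-5)
        assert pt.isotropic.mu_A_star == pytest.approx(pt.nematic.mu_A_star, abs=1e-5)
        assert pt.isotropic.mu_B_star == pytest.approx(pt.nematic.mu_B_star, abs=1e-5)
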