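"""Excluded-volume geometry: closed forms, the rigorous apse-frame
integral, the Perram-Wertheim overlap test and the Monte Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hardnem.geometry import (
    ExcludedVolumeTable,
    ProlateSpheroid,
    gaussian_overlap_vex,
    interp_vex,
    mc_excluded_volume,
    pw_contact_value,
    pw_overlap,
    rigorous_vex,
    spheroid_volume,
    tabulate_vex,
)


class TestProlateSpheroid:
    @pytest.mark.parametrize(
        "a,c,expected",
        [(3.0, 9.0, 108 * np.pi), (3.0, 8.25, 99 * np.pi), (1.0, 1.0, 4 * np.pi / 3)],
    )
    def test_volume(self, a, c, expected):
        assert spheroid_volume(ProlateSpheroid(a, c)) == pytest.approx(expected, rel=1e-14)

    @given(a=st.floats(0.3, 5.0), ratio=st.floats(1.0, 8.0))
    @settings(max_examples=50, deadline=None)
    def test_shape_invariants(self, a, ratio):
        sp = ProlateSpheroid(a, a * ratio)
        assert 0.0 <= sp.chi < 1.0
        assert sp.eps >= 0.0
        # sigma is the equal-volume-sphere diameter
        assert np.pi / 6 * sp.sigma**3 == pytest.approx(sp.volume, rel=1e-12)

    @pytest.mark.parametrize("a,c", [(-1.0, 2.0), (0.0, 1.0), (3.0, 2.0)])
    def test_invalid_geometry_rejected(self, a, c):
        with pytest.raises(ValueError):
            ProlateSpheroid(a, c)


class TestGaussianOverlap:
    def test_aligned_pair_is_eight_particle_volumes(self, sp39):
        assert gaussian_overlap_vex(sp39, 1.0) == pytest.approx(8 * sp39.volume, rel=1e-14)
        assert gaussian_overlap_vex(sp39, -1.0) == pytest.approx(8 * sp39.volume, rel=1e-14)

    def test_sphere_limit_orientation_independent(self, sphere_unit):
        t = np.linspace(-1, 1, 7)
        assert gaussian_overlap_vex(sphere_unit, t) == pytest.approx(
            8 * sphere_unit.volume * np.ones(7), rel=1e-14
        )

    def test_perpendicular_closed_form(self, sp39):
        # c/a = 3 gives chi = 0.8; vex(0) = 8 v / sqrt(1 - chi^2) = 8 v / 0.6
        assert gaussian_overlap_vex(sp39, 0.0) == pytest.approx(8 * sp39.volume / 0.6, rel=1e-14)

    def test_heterogeneous_pair_rejected(self, sp39):
        with pytest.raises(ValueError, match="identical"):
            gaussian_overlap_vex(sp39, 0.5, other=ProlateSpheroid(3.0, 12.0))


class TestRigorousVex:
    def test_aligned_identity(self, sp39):
        assert rigorous_vex(sp39, sp39, 1.0) == pytest.approx(8 * sp39.volume, rel=1e-3)

    def test_sphere_pair_is_minkowski_sum(self):
        s1, s2 = ProlateSpheroid(1.0, 1.0), ProlateSpheroid(2.0, 2.0)
        expected = 4 / 3 * np.pi * (1 + 2) ** 3
        for t in (-0.7, 0.0, 0.4, 1.0):
            assert rigorous_vex(s1, s2, t) == pytest.approx(expected, rel=1e-12)

    def test_swap_and_head_tail_symmetry(self, sp39):
        spB = ProlateSpheroid(3.0, 12.0)
        t = np.array([0.0, 0.3, 0.8])
        # swap symmetry holds to quadrature tolerance (the frame puts one
        # particle on the polar axis, so the discretization differs)
        np.testing.assert_allclose(
            rigorous_vex(sp39, spB, t), rigorous_vex(spB, sp39, t), rtol=1e-5
        )
        np.testing.assert_allclose(
            rigorous_vex(sp39, spB, t, 200, 100), rigorous_vex(spB, sp39, t, 200, 100), rtol=1e-9
        )
        np.testing.assert_allclose(
            rigorous_vex(sp39, spB, t), rigorous_vex(sp39, spB, -t), rtol=1e-12
        )

    def test_quadrature_convergence_on_doubling(self, sp39):
        v1 = rigorous_vex(sp39, sp39, 0.37, 100, 50)
        v2 = rigorous_vex(sp39, sp39, 0.37, 200, 100)
        assert abs(v2 - v1) / v1 < 1e-4

    @pytest.mark.parametrize("ratio", [2.75, 3.0, 4.0, 5.0])
    def test_gaussian_bounds_rigorous_from_above(self, ratio):
        sp = ProlateSpheroid(3.0, 3.0 * ratio)
        t = np.linspace(0.0, 1.0, 21)
        gap = gaussian_overlap_vex(sp, t) - rigorous_vex(sp, sp, t)
        assert np.all(gap >= -1e-9 * sp.volume)
        assert gap[-1] == pytest.approx(0.0, abs=1e-8 * sp.volume)
        assert gap[0] > 0.0

    def test_gap_grows_with_aspect_ratio(self):
        gaps = []
        for ratio in (2.75, 3.0, 4.0, 5.0):
            sp = ProlateSpheroid(3.0, 3.0 * ratio)
            gaps.append(
                (gaussian_overlap_vex(sp, 0.0) - rigorous_vex(sp, sp, 0.0)) / sp.volume
            )
        assert np.all(np.diff(gaps) > 0)


class TestPerramWertheim:
    def test_sphere_contact(self):
        s1, s2 = ProlateSpheroid(1.0, 1.0), ProlateSpheroid(2.0, 2.0)
        z = np.array([0.0, 0.0, 1.0])
        assert pw_overlap(s1, s2, z, z, [0, 0, 2.9])
        assert not pw_overlap(s1, s2, z, z, [0, 0, 3.1])
        # contact value is exactly 1 at touching distance
        assert pw_contact_value(s1, s2, z, z, [0, 0, 3.0]) == pytest.approx(1.0, rel=1e-8)

    def test_aligned_spheroids_tip_and_side_contact(self, sp39):
        z = np.array([0.0, 0.0, 1.0])
        # tip-to-tip contact at separation 2c, side-by-side at 2a
        assert pw_overlap(sp39, sp39, z, z, [0, 0, 2 * sp39.c - 0.05])
        assert not pw_overlap(sp39, sp39, z, z, [0, 0, 2 * sp39.c + 0.05])
        assert pw_overlap(sp39, sp39, z, z, [2 * sp39.a - 0.05, 0, 0])
        assert not pw_overlap(sp39, sp39, z, z, [2 * sp39.a + 0.05, 0, 0])


class TestMonteCarloOracle:
    def test_unit_sphere_pair(self):
        s = ProlateSpheroid(1.0, 1.0)
        est = mc_excluded_volume(s, s, 0.0, n_samples=100_000, seed=7)
        expected = 4 / 3 * np.pi * 8
        assert abs(est.estimate - expected) < 3 * est.stderr
        assert not est.degenerate

    def test_aligned_identical_pair(self, sp39):
        est = mc_excluded_volume(sp39, sp39, 1.0, n_samples=100_000, seed=11)
        assert abs(est.estimate - 8 * sp39.volume) < 3 * est.stderr

    @pytest.mark.parametrize(
        "pair,cos_gamma,seed",
        [
            ((9.0, 9.0), 0.5, 21),
            ((12.0, 9.0), 0.0, 22),   # heterogeneous pair
            ((15.0, 15.0), 0.25, 23),
        ],
    )
    def test_agrees_with_rigorous_integral(self, pair, cos_gamma, seed):
        sp1 = ProlateSpheroid(3.0, pair[0])
        sp2 = ProlateSpheroid(3.0, pair[1])
        direct = rigorous_vex(sp1, sp2, cos_gamma)
        est = mc_excluded_volume(sp1, sp2, cos_gamma, n_samples=60_000, seed=seed)
        assert abs(est.estimate - direct) < 3 * est.stderr

    def test_reproducible_from_seed(self, sp39):
        a = mc_excluded_volume(sp39, sp39, 0.3, n_samples=10_000, seed=5)
        b = mc_excluded_volume(sp39, sp39, 0.3, n_samples=10_000, seed=5)
        assert a.estimate == b.estimate and a.n_overlaps == b.n_overlaps

    def test_zero_hits_flagged_degenerate(self):
        needle = ProlateSpheroid(0.05, 10.0)
        with pytest.warns(RuntimeWarning, match="degenerate"):
            est = mc_excluded_volume(needle, needle, 1.0, n_samples=1_000, seed=3)
        assert est.degenerate

    def test_requires_seed_and_minimum_samples(self, sp39):
        with pytest.raises(ValueError):
            mc_excluded_volume(sp39, sp39, 0.5, n_samples=10_000, seed=None)
        with pytest.raises(ValueError):
            mc_excluded_volume(sp39, sp39, 0.5, n_samples=10, seed=1)


@pytest.fixture(scope="module")
def table39(sp39):
    return tabulate_vex(sp39, sp39, "rigorous")


class TestExcludedVolumeTable:
    def test_aligned_endpoint_ratio(self, table39, sp39):
        assert table39.aligned_value / sp39.volume == pytest.approx(8.0, rel=1e-3)

    def test_sphere_pair_constant(self, sphere_unit):
        tab = tabulate_vex(sphere_unit, sphere_unit, "rigorous", n_grid_points=17)
        np.testing.assert_allclose(tab.vex, tab.vex[0], rtol=1e-12)

    def test_gaussian_table_dominates_rigorous(self, sp39, table39):
        gauss = tabulate_vex(sp39, sp39, "gaussian")
        assert np.all(gauss.vex - table39.vex >= -1e-8 * sp39.volume)
        assert gauss.vex[-1] == pytest.approx(table39.vex[-1], rel=1e-6)

    def test_interpolation_exact_at_nodes_and_even(self, table39):
        i = 37
        assert interp_vex(table39, table39.cos_gamma[i]) == table39.vex[i]
        assert interp_vex(table39, -0.41) == interp_vex(table39, 0.41)

    def test_interpolation_error_against_direct_evaluation(self, table39, sp39):
        probe = np.linspace(0.0, 1.0, 509)
        direct = rigorous_vex(sp39, sp39, probe)
        err = np.abs(interp_vex(table39, probe) - direct) / direct
        assert err.max() < 1e-4

    def test_out_of_range_query_rejected(self, table39):
        with pytest.raises(ValueError):
            interp_vex(table39, 1.2)

    def test_positive_values_required(self):
        with pytest.raises(ValueError):
            ExcludedVolumeTable("x", "rigorous", np.linspace(0, 1, 9), -np.ones(9))
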