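"""Binary mixtures of hard prolate spheroids with a BMCSL-based
Parsons-Lee resummation.

The pure-component Carnahan-Starling resummation prefactor is replaced by
composition-dependent coefficients ``g_ij(rho_A, rho_B)`` derived from the
Boublik-Mansoori-Carnahan-Starling-Leland (BMCSL) hard-sphere-mixture
equation of state, one coefficient per species pair.  Each pair term of the
excess free energy reads ``(1/2) rho_i rho_j g_ij <<f_i f_j vex_ij>>`` with
the rigorous pair excluded volume (the Gaussian overlap model is undefined
for unlike pairs).  The mixing enters through the total packing fraction
``n3 = eta_A + eta_B`` and the equal-volume-sphere diameters ``sigma_i =
(8 c_i a_i^2)^(1/3)``.

The cross coefficients carry the dimensionless diameter ratio
``4 sigma_A sigma_B / (sigma_A + sigma_B)^2``: this is the unique
normalization of the sigma_A sigma_B asymmetry that reproduces the BMCSL
``3 xi_1 xi_2 / (1 - xi_3)`` mixing term for hard spheres and collapses the
whole free energy onto the pure Lee-Parsons form when the two species are
identical (for any composition split) or when one density vanishes.

The diagonal coefficients contain ``1/eta_i`` pieces that diverge as
``rho_i -> 0`` while every physical use multiplies them by at least one
power of ``rho_i``; the class below therefore exposes the finite products
(``rho_i g_ii``, ``rho_i^2 g_ii``, ``rho_i rho_j dg_ij/drho_k``) alongside
the raw coefficients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, root

from hardnem.angular import (
    AngularGrid,
    KernelMatrix,
    OrientationDistribution,
    build_grid,
    build_kernel,
    excess_integral,
    order_parameter,
    orientational_entropy,
)
from hardnem.geometry import ProlateSpheroid, tabulate_vex
from hardnem.pure_onsager import ConvergenceError, NoNematicPhaseError, S_THRESHOLD, PureSystem

__all__ = [
    "MixtureSpec",
    "BMCSLTerms",
    "BMCSLDerivatives",
    "bmcsl_g",
    "bmcsl_g_derivatives",
    "solve_f_mixture",
    "MixtureState",
    "mixture_thermo",
    "MixtureSystem",
    "BinaryCoexistencePoint",
    "binary_coexistence",
    "trace_px_diagram",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Two spheroid species A and B with their volumes and effective
    diameters."""

    A: ProlateSpheroid
    B: ProlateSpheroid

    @property
    def v_A(self) -> float:
        return self.A.volume

    @property
    def v_B(self) -> float:
        return self.B.volume

    @property
    def sigma_A(self) -> float:
        return self.A.sigma

    @property
    def sigma_B(self) -> float:
        return self.B.sigma

    @property
    def cross_ratio(self) -> float:
        """Dimensionless cross-coefficient weight
        4 sigma_A sigma_B / (sigma_A + sigma_B)^2 (= 1 for equal sizes)."""
        return 4.0 * self.sigma_A * self.sigma_B / (self.sigma_A + self.sigma_B) ** 2

    def swapped(self) -> "MixtureSpec":
        return MixtureSpec(self.B, self.A)


def _L(n3: float) -> float:
    """ln(1-n3)/n3^2 + 1/(n3 (1-n3)^2), series-stabilized near n3 = 0
    (limit 3/2)."""
    if n3 < 1e-3:
        # sum_k (k+1)(k+3)/(k+2) n^k
        return sum((k + 1) * (k + 3) / (k + 2) * n3**k for k in range(6))
    return math.log1p(-n3) / n3**2 + 1.0 / (n3 * (1.0 - n3) ** 2)


def _Lp(n3: float) -> float:
    """d/d(n3) of :func:`_L`; limit 8/3 at n3 = 0."""
    if n3 < 1e-3:
        return sum(k * (k + 1) * (k + 3) / (k + 2) * n3 ** (k - 1) for k in range(1, 7))
    return (
        -2.0 * math.log1p(-n3) / n3**3
        + 2.0 / (n3 * (1.0 - n3) ** 3)
        - 1.0 / (n3**2 * (1.0 - n3))
        - 1.0 / (n3**2 * (1.0 - n3) ** 2)
    )


def _check_densities(spec: MixtureSpec, rho_A: float, rho_B: float) -> tuple[float, float, float]:
    if rho_A < 0 or rho_B < 0:
        raise ValueError("densities must be non-negative")
    eta_A = rho_A * spec.v_A
    eta_B = rho_B * spec.v_B
    n3 = eta_A + eta_B
    if n3 >= 1.0:
        raise ValueError(f"total packing fraction n3 = {n3:.4f} must be < 1")
    return eta_A, eta_B, n3


@dataclass(frozen=True)
class BMCSLTerms:
    """BMCSL resummation coefficients g_ij at one mixture state point.

    ``g_AA``/``g_BB`` are ``inf`` when the corresponding density vanishes;
    the finite products ``rhoA_gAA = rho_A g_AA`` etc. remain well defined
    there and are what the free energy and solver consume.
    """

    spec: MixtureSpec
    z: float
    rho_A: float
    rho_B: float
    eta_A: float
    eta_B: float
    n3: float
    g_AA: float
    g_AB: float
    g_BA: float
    g_BB: float
    rhoA_gAA: float
    rhoB_gBB: float
    rho2_gAA: float
    rho2_gBB: float

    @property
    def g_cross_sym(self) -> float:
        """(g_AB + g_BA), the symmetrized cross coupling."""
        return self.g_AB + self.g_BA


def bmcsl_g(spec: MixtureSpec, rho_A: float, rho_B: float, z: float) -> BMCSLTerms:
    """Evaluate the four BMCSL resummation coefficients.

    g_AA = -ln(1-n3)/(z eta_A) + 3/(z(1-n3)) + (eta_A/z) L(n3)
    g_AB = 3 r /(z(1-n3)) + (3 eta_A r / z) L(n3)        (r = cross ratio)
    g_BA = same with eta_B; g_BB mirrors g_AA.

    At rho_B = 0 the coefficient g_AA reduces exactly to the pure
    Lee-Parsons prefactor (4 - 3 eta_A)/(z (1 - eta_A)^2).
    """
    eta_A, eta_B, n3 = _check_densities(spec, rho_A, rho_B)
    L = _L(n3)
    one = 1.0 - n3
    S = -math.log1p(-n3) / z  # coefficient of the 1/eta_i singular piece
    r = spec.cross_ratio
    reg_AA = 3.0 / (z * one) + eta_A * L / z
    reg_BB = 3.0 / (z * one) + eta_B * L / z
    g_AB = 3.0 * r / (z * one) + 3.0 * eta_A * r * L / z
    g_BA = 3.0 * r / (z * one) + 3.0 * eta_B * r * L / z
    g_AA = S / eta_A + reg_AA if eta_A > 0 else math.inf
    g_BB = S / eta_B + reg_BB if eta_B > 0 else math.inf
    return BMCSLTerms(
        spec, z, rho_A, rho_B, eta_A, eta_B, n3,
        g_AA, g_AB, g_BA, g_BB,
        rhoA_gAA=S / spec.v_A + rho_A * reg_AA,
        rhoB_gBB=S / spec.v_B + rho_B * reg_BB,
        rho2_gAA=rho_A * S / spec.v_A + rho_A**2 * reg_AA,
        rho2_gBB=rho_B * S / spec.v_B + rho_B**2 * reg_BB,
    )


@dataclass(frozen=True)
class BMCSLDerivatives:
    """Density derivatives d g_ij / d rho_k (nm^3) and the finite triple
    products rho_i rho_j (d g_ij / d rho_k)."""

    d: dict
    rr: dict

    def __getitem__(self, key: tuple[str, str, str]) -> float:
        return self.d[key]


def bmcsl_g_derivatives(spec: MixtureSpec, rho_A: float, rho_B: float, z: float) -> BMCSLDerivatives:
    """Closed-form derivatives of the BMCSL coefficients with respect to the
    two species densities (eight combinations).

    Keys of the returned dicts are ("i", "j", "k") for d g_ij / d rho_k.
    Diagonal derivatives carry 1/eta and 1/eta^2 singular pieces at
    vanishing density; the ``rr`` products stay finite.
    """
    eta_A, eta_B, n3 = _check_densities(spec, rho_A, rho_B)
    L, Lp = _L(n3), _Lp(n3)
    one = 1.0 - n3
    S = -math.log1p(-n3) / z
    r = spec.cross_ratio
    vA, vB = spec.v_A, spec.v_B

    # regular parts of the diagonal derivatives
    reg_AA_A = 3.0 * vA / (z * one**2) + vA * L / z + eta_A * vA * Lp / z
    reg_AA_B = 3.0 * vB / (z * one**2) + eta_A * vB * Lp / z
    reg_BB_B = 3.0 * vB / (z * one**2) + vB * L / z + eta_B * vB * Lp / z
    reg_BB_A = 3.0 * vA / (z * one**2) + eta_B * vA * Lp / z

    # cross derivatives are regular everywhere
    d_AB_A = 3.0 * r * vA / (z * one**2) + 3.0 * r * vA * L / z + 3.0 * eta_A * r * vA * Lp / z
    d_AB_B = 3.0 * r * vB / (z * one**2) + 3.0 * eta_A * r * vB * Lp / z
    d_BA_A = 3.0 * r * vA / (z * one**2) + 3.0 * eta_B * r * vA * Lp / z
    d_BA_B = 3.0 * r * vB / (z * one**2) + 3.0 * r * vB * L / z + 3.0 * eta_B * r * vB * Lp / z

    def diag(eta_i, v_i, v_k, reg, same):
        # d g_ii / d rho_k = [S' terms]/eta_i(^2) + regular
        if eta_i == 0.0:
            return math.inf
        out = v_k / (z * one * eta_i) + reg
        if same:
            out -= S * v_i / eta_i**2
        return out

    d = {
        ("A", "A", "A"): diag(eta_A, vA, vA, reg_AA_A, True),
        ("A", "A", "B"): diag(eta_A, vA, vB, reg_AA_B, False),
        ("A", "B", "A"): d_AB_A,
        ("A", "B", "B"): d_AB_B,
        ("B", "A", "A"): d_BA_A,
        ("B", "A", "B"): d_BA_B,
        ("B", "B", "B"): diag(eta_B, vB, vB, reg_BB_B, True),
        ("B", "B", "A"): diag(eta_B, vB, vA, reg_BB_A, False),
    }
    rr = {
        ("A", "A", "A"): -S / vA + rho_A / (z * one) + rho_A**2 * reg_AA_A,
        ("A", "A", "B"): rho_A * vB / (z * one * vA) + rho_A**2 * reg_AA_B,
        ("A", "B", "A"): rho_A * rho_B * d_AB_A,
        ("A", "B", "B"): rho_A * rho_B * d_AB_B,
        ("B", "A", "A"): rho_A * rho_B * d_BA_A,
        ("B", "A", "B"): rho_A * rho_B * d_BA_B,
        ("B", "B", "B"): -S / vB + rho_B / (z * one) + rho_B**2 * reg_BB_B,
        ("B", "B", "A"): rho_B * vA / (z * one * vB) + rho_B**2 * reg_BB_A,
    }
    return BMCSLDerivatives(d, rr)


def _coupled_picard(
    cAA: float,
    cXA: float,
    cBB: float,
    cXB: float,
    K_AA: KernelMatrix,
    K_AB: KernelMatrix,
    K_BB: KernelMatrix,
    fA0: np.ndarray,
    fB0: np.ndarray,
    mixing: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, float, float, int]:
    """Damped Picard iteration of the coupled two-species fixed point.

    f_A = exp(-cAA K_AA f_A - cXA K_AB f_B) / q_A  (and B analogously,
    with cXB the cross coefficient seen by B).
    Returns (f_A, f_B, ln q_A, ln q_B, iterations).
    """
    g = K_AA.grid
    w = g.w_theta
    fA = fA0 / (w @ fA0)
    fB = fB0 / (w @ fB0)
    lnqA = lnqB = 0.0
    res = np.inf
    for it in range(1, max_iter + 1):
        uA = -(cAA * (K_AA.reduced @ (w * fA)) + cXA * (K_AB.reduced @ (w * fB)))
        uB = -(cBB * (K_BB.reduced @ (w * fB)) + cXB * (K_AB.reduced @ (w * fA)))
        mA, mB = uA.max(), uB.max()
        eA, eB = np.exp(uA - mA), np.exp(uB - mB)
        qA, qB = w @ eA, w @ eB
        lnqA, lnqB = mA + np.log(qA), mB + np.log(qB)
        fA_new, fB_new = eA / qA, eB / qB
        res = max(float(np.max(np.abs(fA_new - fA))), float(np.max(np.abs(fB_new - fB))))
        if res < tol:
            return fA_new, fB_new, lnqA, lnqB, it
        fA = (1.0 - mixing) * fA + mixing * fA_new
        fB = (1.0 - mixing) * fB + mixing * fB_new
    raise ConvergenceError(
        f"coupled Picard iteration did not converge in {max_iter} steps "
        f"(residual {res:.3e})",
        res,
    )


def solve_f_mixture(
    spec: MixtureSpec,
    rho_A: float,
    rho_B: float,
    z: float,
    kernels: tuple[KernelMatrix, KernelMatrix, KernelMatrix],
    grid: AngularGrid | None = None,
    init="isotropic",
    mixing: float = 0.3,
    tol: float = 1e-9,
    max_iter: int = 20_000,
) -> tuple[OrientationDistribution, OrientationDistribution]:
    """Coupled self-consistent distributions (f_A, f_B) of the binary
    mixture.

    ``kernels`` is (K_AA, K_AB, K_BB), all built with the rigorous
    excluded volume.  ``init`` is "isotropic", "nematic", or an explicit
    pair of distributions/arrays.  The cross coupling seen by each species
    is the symmetrized (1/2)(g_AB + g_BA) weighted by the other species'
    density.
    """
    K_AA, K_AB, K_BB = kernels
    grid = grid or K_AA.grid
    terms = bmcsl_g(spec, rho_A, rho_B, z)
    cXA = 0.5 * rho_B * terms.g_cross_sym
    cXB = 0.5 * rho_A * terms.g_cross_sym
    if isinstance(init, str):
        if init == "isotropic":
            fA0 = fB0 = np.ones(grid.n_theta)
        elif init == "nematic":
            fA0 = fB0 = np.exp(20.0 * grid.u**2)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        fa, fb = init
        fA0 = np.asarray(fa.values if isinstance(fa, OrientationDistribution) else fa, float)
        fB0 = np.asarray(fb.values if isinstance(fb, OrientationDistribution) else fb, float)
    fA, fB, _, _, _ = _coupled_picard(
        terms.rhoA_gAA, cXA, terms.rhoB_gBB, cXB, K_AA, K_AB, K_BB,
        fA0, fB0, mixing, tol, max_iter,
    )
    return (
        OrientationDistribution(fA, grid, species="A"),
        OrientationDistribution(fB, grid, species="B"),
    )


@dataclass
class MixtureState:
    """A solved two-species state with its thermodynamics.

    Reduced pressure uses the species-A volume scale:
    betaP* = betaP * (8 a_A^2 c_A).
    """

    spec: MixtureSpec
    rho_A: float
    rho_B: float
    z: float
    f_A: OrientationDistribution
    f_B: OrientationDistribution
    lnq_A: float
    lnq_B: float
    kernels: tuple[KernelMatrix, KernelMatrix, KernelMatrix]

    @property
    def grid(self) -> AngularGrid:
        return self.kernels[0].grid

    @property
    def eta_A(self) -> float:
        return self.rho_A * self.spec.v_A

    @property
    def eta_B(self) -> float:
        return self.rho_B * self.spec.v_B

    @property
    def n3(self) -> float:
        return self.eta_A + self.eta_B

    @property
    def rho(self) -> float:
        return self.rho_A + self.rho_B

    @property
    def x_A(self) -> float:
        return self.rho_A / self.rho if self.rho > 0 else math.nan

    @cached_property
    def terms(self) -> BMCSLTerms:
        return bmcsl_g(self.spec, self.rho_A, self.rho_B, self.z)

    @cached_property
    def derivs(self) -> BMCSLDerivatives:
        return bmcsl_g_derivatives(self.spec, self.rho_A, self.rho_B, self.z)

    @cached_property
    def W(self) -> dict:
        """Pair orientational averages <<f_i f_j vex_ij>> in nm^3."""
        K_AA, K_AB, K_BB = self.kernels
        return {
            "AA": excess_integral(self.f_A, self.f_A, K_AA),
            "AB": excess_integral(self.f_A, self.f_B, K_AB),
            "BB": excess_integral(self.f_B, self.f_B, K_BB),
        }

    @cached_property
    def S_A(self) -> float:
        return order_parameter(self.f_A, self.grid)

    @cached_property
    def S_B(self) -> float:
        return order_parameter(self.f_B, self.grid)

    @property
    def is_nematic(self) -> bool:
        return max(self.S_A, self.S_B) > S_THRESHOLD

    @cached_property
    def helmholtz(self) -> float:
        """beta F / V in nm^-3 (lambda_i = 1)."""
        t, W = self.terms, self.W
        out = 0.0
        for rho_i, f_i in ((self.rho_A, self.f_A), (self.rho_B, self.f_B)):
            if rho_i > 0:
                out += rho_i * (math.log(rho_i) - 1.0)
                out += rho_i * orientational_entropy(f_i, self.grid)
        out += 0.5 * (
            t.rho2_gAA * W["AA"]
            + self.rho_A * self.rho_B * t.g_cross_sym * W["AB"]
            + t.rho2_gBB * W["BB"]
        )
        return out

    def _mu_excess(self, k: str) -> float:
        rr, W = self.derivs.rr, self.W
        return 0.5 * (
            rr[("A", "A", k)] * W["AA"]
            + (rr[("A", "B", k)] + rr[("B", "A", k)]) * W["AB"]
            + rr[("B", "B", k)] * W["BB"]
        )

    @cached_property
    def mu_A_star(self) -> float:
        """Reduced chemical potential of species A (lambda_A = 1,
        densities in nm^-3)."""
        if self.rho_A <= 0:
            return -math.inf
        return math.log(self.rho_A) - self.lnq_A + self._mu_excess("A")

    @cached_property
    def mu_B_star(self) -> float:
        if self.rho_B <= 0:
            return -math.inf
        return math.log(self.rho_B) - self.lnq_B + self._mu_excess("B")

    @cached_property
    def pressure(self) -> float:
        """beta P in nm^-3."""
        t, rr, W = self.terms, self.derivs.rr, self.W
        pair = {
            "AA": t.rho2_gAA,
            "AB": self.rho_A * self.rho_B * t.g_cross_sym,
            "BB": t.rho2_gBB,
        }
        out = self.rho
        for key, rrA, rrB in (
            ("AA", rr[("A", "A", "A")], rr[("A", "A", "B")]),
            ("AB", rr[("A", "B", "A")] + rr[("B", "A", "A")], rr[("A", "B", "B")] + rr[("B", "A", "B")]),
            ("BB", rr[("B", "B", "A")], rr[("B", "B", "B")]),
        ):
            out += 0.5 * (pair[key] + self.rho_A * rrA + self.rho_B * rrB) * W[key]
        return out

    @property
    def pressure_star(self) -> float:
        return self.pressure * 8.0 * self.spec.A.a**2 * self.spec.A.c


def mixture_thermo(state: MixtureState) -> tuple[float, float, float, float, float, float, float]:
    """(beta F/V, betamu_A*, betamu_B*, beta P, beta P*, S_A, S_B) of a
    solved mixture state."""
    return (
        state.helmholtz,
        state.mu_A_star,
        state.mu_B_star,
        state.pressure,
        state.pressure_star,
        state.S_A,
        state.S_B,
    )


class MixtureSystem:
    """Binary mixture with the three rigorous excluded-volume kernels built
    once and shared by all solves."""

    def __init__(
        self,
        spec: MixtureSpec,
        z: float,
        grid: AngularGrid | None = None,
        n_table: int = 201,
        n_theta_k: int = 100,
        n_phi_k: int = 50,
    ):
        self.spec = spec
        self.z = float(z)
        self.grid = grid or build_grid()
        kw = dict(n_grid_points=n_table, n_theta_k=n_theta_k, n_phi_k=n_phi_k)
        self.kernels = (
            build_kernel(self.grid, tabulate_vex(spec.A, spec.A, "rigorous", **kw)),
            build_kernel(self.grid, tabulate_vex(spec.A, spec.B, "rigorous", **kw)),
            build_kernel(self.grid, tabulate_vex(spec.B, spec.B, "rigorous", **kw)),
        )

    def solve(
        self,
        rho_A: float,
        rho_B: float,
        init="isotropic",
        mixing: float = 0.3,
        tol: float = 1e-9,
        max_iter: int = 20_000,
    ) -> MixtureState:
        f_A, f_B = solve_f_mixture(
            self.spec, rho_A, rho_B, self.z, self.kernels, self.grid,
            init=init, mixing=mixing, tol=tol, max_iter=max_iter,
        )
        # recover ln q_i from the converged distributions: f_i = exp(u_i)/q_i
        terms = bmcsl_g(self.spec, rho_A, rho_B, self.z)
        w = self.grid.w_theta
        K_AA, K_AB, K_BB = self.kernels
        uA = -(terms.rhoA_gAA * (K_AA.reduced @ (w * f_A.values))
               + 0.5 * rho_B * terms.g_cross_sym * (K_AB.reduced @ (w * f_B.values)))
        uB = -(terms.rhoB_gBB * (K_BB.reduced @ (w * f_B.values))
               + 0.5 * rho_A * terms.g_cross_sym * (K_AB.reduced @ (w * f_A.values)))
        mA, mB = uA.max(), uB.max()
        lnqA = mA + np.log(w @ np.exp(uA - mA))
        lnqB = mB + np.log(w @ np.exp(uB - mB))
        return MixtureState(self.spec, rho_A, rho_B, self.z, f_A, f_B, lnqA, lnqB, self.kernels)

    def pure_endpoint(self, species: Literal["A", "B"]) -> "PureSystem":
        """Pure-component system of one species sharing this mixture's grid
        and z (rigorous kernel)."""
        sp = self.spec.A if species == "A" else self.spec.B
        return PureSystem(sp, "rigorous", self.z, grid=self.grid)

    # -- coexistence -------------------------------------------------------

    def _phase_state(self, eta_A: float, eta_B: float, init, nematic: bool) -> MixtureState:
        st = self.solve(eta_A / self.spec.v_A, eta_B / self.spec.v_B, init=init)
        if nematic and not st.is_nematic:
            raise NoNematicPhaseError(
                f"nematic solution lost at eta_A={eta_A:.4f}, eta_B={eta_B:.4f}"
            )
        return st

    def coexistence_at_pressure(
        self,
        betaP_star: float,
        init: Sequence[float],
        tol: float = 1e-9,
    ) -> "BinaryCoexistencePoint":
        """Solve the four phase-equilibrium equations at a target reduced
        pressure: P(iso) = P(nem) = target, mu_A and mu_B equal across
        phases.

        ``init`` is (eta_A_iso, eta_B_iso, eta_A_nem, eta_B_nem); unknowns
        are iterated in log space to preserve positivity.  Distributions
        warm-start from the previous residual evaluation.
        """
        seeds = {"iso": "isotropic", "nem": "nematic"}

        def residuals(y):
            ea_i, eb_i, ea_n, eb_n = np.exp(y)
            # graded penalty outside the physical domain so the trust region
            # backs off instead of crashing
            excess = max(ea_i + eb_i, ea_n + eb_n) - 0.92
            if excess > 0:
                return [1e4 * (1.0 + excess)] * 4
            try:
                iso = self._phase_state(ea_i, eb_i, seeds["iso"], nematic=False)
                nem = self._phase_state(ea_n, eb_n, seeds["nem"], nematic=True)
            except (ConvergenceError, NoNematicPhaseError):
                return [1e4] * 4
            seeds["iso"] = (iso.f_A, iso.f_B)
            seeds["nem"] = (nem.f_A, nem.f_B)
            return [
                (iso.pressure_star - betaP_star) / max(abs(betaP_star), 1.0),
                (nem.pressure_star - betaP_star) / max(abs(betaP_star), 1.0),
                iso.mu_A_star - nem.mu_A_star,
                iso.mu_B_star - nem.mu_B_star,
            ]

        sol = root(residuals, np.log(np.asarray(init, dtype=float)), method="hybr", tol=tol)
        resid = float(np.max(np.abs(sol.fun)))
        if not (sol.success or resid < 1e-6):
            raise ConvergenceError(f"binary coexistence failed: {sol.message}", resid)
        ea_i, eb_i, ea_n, eb_n = np.exp(sol.x)
        iso = self._phase_state(ea_i, eb_i, seeds["iso"], nematic=False)
        nem = self._phase_state(ea_n, eb_n, seeds["nem"], nematic=True)
        if nem.n3 <= iso.n3:
            raise ConvergenceError("collapsed to a trivial root (equal phases)", resid)
        return BinaryCoexistencePoint(betaP_star, iso, nem)

    def trace_px_diagram(
        self,
        n_points: int = 12,
        margin: float = 0.04,
        pressures: Sequence[float] | None = None,
    ) -> list["BinaryCoexistencePoint"]:
        """Pressure-composition coexistence band between the two pure
        endpoints.

        The pure-A and pure-B transition pressures (both in species-A
        reduced units) anchor the band; interior pressures are swept with
        continuation warm starts from the pure-A end.  Per-point failures
        are skipped.
        """
        co_A = self.pure_endpoint("A").coexistence()
        co_B = self.pure_endpoint("B").coexistence()
        scale = 8.0 * self.spec.A.a**2 * self.spec.A.c
        pA = co_A.isotropic.pressure * scale
        pB = co_B.isotropic.pressure * scale
        if pressures is None:
            lo, hi = sorted((pA, pB))
            span = hi - lo
            pressures = np.linspace(lo + margin * span, hi - margin * span, n_points)
            if pA > pB:
                pressures = pressures[::-1]
        # seed near the pure-A endpoint with a trace of species B
        init = np.array([
            co_A.eta_iso * 0.97, co_A.eta_iso * 0.03,
            co_A.eta_nem * 0.985, co_A.eta_nem * 0.015,
        ])
        points: list[BinaryCoexistencePoint] = []
        for p in pressures:
            try:
                pt = self.coexistence_at_pressure(float(p), init)
            except (ConvergenceError, NoNematicPhaseError):
                continue
            points.append(pt)
            init = np.array([
                pt.isotropic.eta_A, pt.isotropic.eta_B,
                pt.nematic.eta_A, pt.nematic.eta_B,
            ])
        points.sort(key=lambda pt: pt.betaP_star)
        return points

    def state_at_pressure(
        self,
        betaP_star: float,
        x_A: float,
        phase: Literal["isotropic", "nematic"],
        n3_max: float = 0.88,
    ) -> MixtureState:
        """Solve one phase at fixed composition and reduced pressure by
        walking the total packing fraction upward (with warm-started
        distributions) until the target pressure is bracketed, then
        refining with Brent."""
        scale = 8.0 * self.spec.A.a**2 * self.spec.A.c
        p_target = betaP_star / scale
        vbar = x_A * self.spec.v_A + (1.0 - x_A) * self.spec.v_B
        seed = {"f": "isotropic" if phase == "isotropic" else "nematic"}

        def try_state(n3: float) -> MixtureState | None:
            rho = n3 / vbar
            try:
                st = self.solve(x_A * rho, (1.0 - x_A) * rho, init=seed["f"])
            except ConvergenceError:
                return None
            if phase == "nematic" and not st.is_nematic:
                return None
            seed["f"] = (st.f_A, st.f_B)
            return st

        bracket = None
        prev = None
        for n3 in np.arange(0.04, n3_max, 0.04):
            st = try_state(float(n3))
            if st is None:
                prev = None
                continue
            if st.pressure >= p_target and prev is not None:
                bracket = (prev.n3, st.n3)
                break
            prev = st
        if bracket is None:
            raise NoNematicPhaseError(
                f"no {phase} state at betaP*={betaP_star:.3f}, x_A={x_A:.3f}"
            )
        cache: dict[float, MixtureState] = {}

        def p_resid(n3: float) -> float:
            st = try_state(n3)
            if st is None:
                raise NoNematicPhaseError(f"{phase} solution lost at n3={n3:.4f}")
            cache[n3] = st
            return st.pressure - p_target

        n3_sol = brentq(p_resid, *bracket, xtol=1e-12)
        return cache[min(cache, key=lambda k: abs(k - n3_sol))]

    def gibbs_per_particle(
        self, betaP_star: float, x_A: float, phase: Literal["isotropic", "nematic"]
    ) -> float:
        """beta G / N = (beta F/V + beta P) / rho at fixed reduced pressure
        and composition; scanning it over composition probes for demixing
        (a concave stretch would signal phase separation within one phase)."""
        st = self.state_at_pressure(betaP_star, x_A, phase)
        return (st.helmholtz + st.pressure) / st.rho


@dataclass
class BinaryCoexistencePoint:
    """Isotropic and nematic mixture states sharing pressure and both
    chemical potentials."""

    betaP_star: float
    isotropic: MixtureState
    nematic: MixtureState

    @property
    def x_A_iso(self) -> float:
        return self.isotropic.x_A

    @property
    def x_A_nem(self) -> float:
        return self.nematic.x_A

    @property
    def mu_A_star(self) -> float:
        return 0.5 * (self.isotropic.mu_A_star + self.nematic.mu_A_star)

    @property
    def mu_B_star(self) -> float:
        return 0.5 * (self.isotropic.mu_B_star + self.nematic.mu_B_star)


def binary_coexistence(
    system: MixtureSystem,
    betaP_star: float,
    init: Sequence[float] | None = None,
    tol: float = 1e-9,
) -> BinaryCoexistencePoint:
    """Binary isotropic-nematic coexistence at one reduced pressure.

    Without an explicit ``init`` the solver walks a short pressure
    continuation from the pure-A endpoint to the target.
    """
    if init is not None:
        return system.coexistence_at_pressure(betaP_star, init, tol=tol)
    co_A = system.pure_endpoint("A").coexistence()
    scale = 8.0 * system.spec.A.a**2 * system.spec.A.c
    pA = co_A.isotropic.pressure * scale
    init_ = np.array([
        co_A.eta_iso * 0.97, co_A.eta_iso * 0.03,
        co_A.eta_nem * 0.985, co_A.eta_nem * 0.015,
    ])
    steps = np.linspace(pA + 0.03 * abs(betaP_star - pA), betaP_star, 6)
    pt = None
    for p in steps:
        pt = system.coexistence_at_pressure(float(p), init_, tol=tol)
        init_ = np.array([
            pt.isotropic.eta_A, pt.isotropic.eta_B,
            pt.nematic.eta_A, pt.nematic.eta_B,
        ])
    return pt


def trace_px_diagram(system: MixtureSystem, n_points: int = 12, **kw) -> list[BinaryCoexistencePoint]:
    """See :meth:`MixtureSystem.trace_px_diagram`."""
    return system.trace_px_diagram(n_points=n_points, **kw)
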