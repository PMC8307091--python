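"""Pure-component Onsager theory with the Lee-Parsons resummation.

The Helmholtz free energy per volume (beta F / V, with the thermal
wavelength set to 1) of a fluid of hard prolate spheroids is

    rho (ln rho - 1) + rho <f ln f> + (1/2) rho^2 G(eta) <<f f vex>>,

where ``G(eta) = (4 - 3 eta) / (z (1 - eta)^2)`` is the Carnahan-Starling
resummation prefactor, ``eta = rho v_lc`` the packing fraction and ``z`` the
excluded-volume divisor (z = 4 divides the aligned excluded volume 8 v_lc
down to the particle volume; z = 3 is the correction appropriate to the
rigorous excluded volume).  Functional minimization over the orientational
distribution f gives the self-consistency condition

    f(theta) = exp(-rho G(eta) (1/4 pi) oint f vex dOmega') / q,

solved here by damped Picard iteration.  The chemical potential and
pressure follow by density differentiation and the Gibbs-Duhem relation;
isotropic-nematic coexistence equates pressure and chemical potential
between the two self-consistent branches.

Reduced units follow the convention betaP* = betaP * (8 a^2 c) and
betamu* = betamu - ln lambda^3 (so betamu* = betamu with lambda = 1 and
densities in nm^-3).
"""

from __future__ import annotations

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

__all__ = [
    "ConvergenceError",
    "NoNematicPhaseError",
    "lp_prefactor",
    "solve_f",
    "PureState",
    "PureCoexistence",
    "PureSystem",
    "helmholtz",
    "chem_potential",
    "pressure",
    "trace_branch",
    "find_metastability_limit",
    "pure_coexistence",
]

S_THRESHOLD = 1e-3  # order parameter below which a fixed point counts as isotropic


class ConvergenceError(RuntimeError):
    """Picard iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class NoNematicPhaseError(RuntimeError):
    """No self-consistent nematic branch exists for this system."""


def lp_prefactor(eta: float, z: float) -> float:
    """Lee-Parsons resummation prefactor (4 - 3 eta) / (z (1 - eta)^2)."""
    if not 0.0 <= eta < 1.0:
        raise ValueError(f"packing fraction must lie in [0, 1), got {eta}")
    return (4.0 - 3.0 * eta) / (z * (1.0 - eta) ** 2)


def _lp_prefactor_deta(eta: float, z: float) -> float:
    """d/d(eta) of the resummation prefactor: (5 - 3 eta) / (z (1 - eta)^3)."""
    return (5.0 - 3.0 * eta) / (z * (1.0 - eta) ** 3)


def _picard(
    coupling: float,
    kernel: KernelMatrix,
    f0: np.ndarray,
    mixing: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, float, int, float]:
    """Damped Picard iteration for f = exp(-coupling * K f) / q.

    Returns (f, ln q, iterations, final residual); f comes back normalized.
    """
    g = kernel.grid
    w = g.w_theta
    f = f0 / (w @ f0)
    lnq = 0.0
    res = np.inf
    for it in range(1, max_iter + 1):
        u = -coupling * (kernel.reduced @ (w * f))
        umax = u.max()
        e = np.exp(u - umax)
        qt = w @ e
        lnq = umax + np.log(qt)
        f_new = e / qt
        res = float(np.max(np.abs(f_new - f)))
        if res < tol:
            return f_new, lnq, it, res
        f = (1.0 - mixing) * f + mixing * f_new
    raise ConvergenceError(
        f"Picard iteration did not converge in {max_iter} steps (residual {res:.3e})",
        res,
    )


def solve_f(
    spheroid: ProlateSpheroid,
    rho: float,
    z: float,
    kernel: KernelMatrix,
    grid: AngularGrid | None = None,
    init: Literal["isotropic", "nematic"] | np.ndarray | OrientationDistribution = "isotropic",
    mixing: float = 0.3,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> OrientationDistribution:
    """Self-consistent orientational distribution at number density ``rho``.

    ``init`` selects the Picard seed: ``"isotropic"`` (f = 1, always an
    exact fixed point), ``"nematic"`` (f propto exp(20 cos^2 theta)) or an
    explicit distribution.  Raises :class:`ConvergenceError` on failure.
    """
    if rho < 0:
        raise ValueError("density must be non-negative")
    grid = grid or kernel.grid
    eta = rho * spheroid.volume
    coupling = rho * lp_prefactor(eta, z)
    if isinstance(init, str):
        if init == "isotropic":
            f0 = np.ones(grid.n_theta)
        elif init == "nematic":
            f0 = np.exp(20.0 * grid.u**2)
        else:
            raise ValueError(f"unknown init {init!r}")
    else:
        f0 = np.asarray(init.values if isinstance(init, OrientationDistribution) else init, dtype=float)
    f, _, _, _ = _picard(coupling, kernel, f0, mixing, tol, max_iter)
    return OrientationDistribution(f, grid)


@dataclass
class PureState:
    """A solved single-phase state: geometry, density, distribution and the
    derived thermodynamics."""

    spheroid: ProlateSpheroid
    rho: float  # nm^-3
    z: float
    f: OrientationDistribution
    lnq: float
    kernel: KernelMatrix

    @property
    def grid(self) -> AngularGrid:
        return self.kernel.grid

    @property
    def eta(self) -> float:
        return self.rho * self.spheroid.volume

    @property
    def q(self) -> float:
        return float(np.exp(self.lnq))

    @cached_property
    def excess_vex(self) -> float:
        """<<f f vex>>: double orientational average of the excluded volume,
        nm^3."""
        return excess_integral(self.f, self.f, self.kernel)

    @cached_property
    def order_parameter(self) -> float:
        return order_parameter(self.f, self.grid)

    @property
    def S(self) -> float:
        return self.order_parameter

    @property
    def is_nematic(self) -> bool:
        return self.order_parameter > S_THRESHOLD

    @cached_property
    def helmholtz(self) -> float:
        """beta F / V in nm^-3 (lambda = 1)."""
        if self.rho == 0.0:
            return 0.0
        s = orientational_entropy(self.f, self.grid)
        G = lp_prefactor(self.eta, self.z)
        return (
            self.rho * (np.log(self.rho) - 1.0)
            + self.rho * s
            + 0.5 * self.rho**2 * G * self.excess_vex
        )

    @cached_property
    def mu_star(self) -> float:
        """Reduced chemical potential betamu - ln lambda^3 (dimensionless,
        densities in nm^-3)."""
        dG = _lp_prefactor_deta(self.eta, self.z)
        return (
            np.log(self.rho)
            - self.lnq
            + 0.5 * self.rho**2 * self.spheroid.volume * dG * self.excess_vex
        )

    @cached_property
    def pressure(self) -> float:
        """beta P in nm^-3."""
        G = lp_prefactor(self.eta, self.z)
        dG = _lp_prefactor_deta(self.eta, self.z)
        return self.rho + 0.5 * (
            self.rho**2 * G + self.rho**3 * self.spheroid.volume * dG
        ) * self.excess_vex

    @property
    def pressure_star(self) -> float:
        """Reduced pressure betaP * (8 a^2 c)."""
        return self.pressure * 8.0 * self.spheroid.a**2 * self.spheroid.c


def helmholtz(state: PureState) -> float:
    """beta F / V of a solved state, nm^-3."""
    return state.helmholtz


def chem_potential(state: PureState) -> float:
    """Reduced chemical potential betamu* of a solved state."""
    return state.mu_star


def pressure(state: PureState) -> tuple[float, float]:
    """(beta P in nm^-3, reduced beta P* = beta P * 8 a^2 c)."""
    return state.pressure, state.pressure_star


@dataclass
class PureCoexistence:
    """Isotropic-nematic coexistence point: two states sharing pressure and
    chemical potential."""

    isotropic: PureState
    nematic: PureState

    @property
    def eta_iso(self) -> float:
        return self.isotropic.eta

    @property
    def eta_nem(self) -> float:
        return self.nematic.eta

    @property
    def pressure_star(self) -> float:
        return 0.5 * (self.isotropic.pressure_star + self.nematic.pressure_star)

    @property
    def mu_star(self) -> float:
        return 0.5 * (self.isotropic.mu_star + self.nematic.mu_star)

    @property
    def S_nematic(self) -> float:
        return self.nematic.order_parameter


class PureSystem:
    """One particle geometry + excluded-volume method + divisor z, with the
    kernel built once and reused by every solve.

    Both ``method`` ("gaussian" or "rigorous") and ``z`` are required:
    their pairing is the physically meaningful choice (the Gaussian overlap
    model pairs with z = 4, the rigorous excluded volume with z = 3).
    """

    def __init__(
        self,
        spheroid: ProlateSpheroid,
        method: Literal["gaussian", "rigorous"],
        z: float,
        grid: AngularGrid | None = None,
        n_table: int = 201,
        n_theta_k: int = 100,
        n_phi_k: int = 50,
    ):
        if z <= 0:
            raise ValueError("z must be positive")
        self.spheroid = spheroid
        self.method = method
        self.z = float(z)
        self.grid = grid or build_grid()
        self.table = tabulate_vex(
            spheroid, spheroid, method, n_grid_points=n_table,
            n_theta_k=n_theta_k, n_phi_k=n_phi_k,
        )
        self.kernel = build_kernel(self.grid, self.table)
        self._iso_vex = float(self.grid.w_theta @ self.kernel.reduced @ self.grid.w_theta)

    # -- single states -----------------------------------------------------

    def isotropic_state(self, rho: float) -> PureState:
        """Isotropic state (f = 1 is an exact fixed point; no iteration)."""
        if rho < 0:
            raise ValueError("density must be non-negative")
        eta = rho * self.spheroid.volume
        lnq = -rho * lp_prefactor(eta, self.z) * self._iso_vex
        f = OrientationDistribution.isotropic(self.grid)
        return PureState(self.spheroid, rho, self.z, f, lnq, self.kernel)

    def state(
        self,
        rho: float,
        init: Literal["isotropic", "nematic"] | np.ndarray | OrientationDistribution = "isotropic",
        mixing: float = 0.3,
        tol: float = 1e-9,
        max_iter: int = 10_000,
    ) -> PureState:
        """Solve the self-consistency at density ``rho`` from ``init`` and
        assemble the full state."""
        if isinstance(init, str) and init == "isotropic":
            return self.isotropic_state(rho)
        eta = rho * self.spheroid.volume
        coupling = rho * lp_prefactor(eta, self.z)
        if isinstance(init, str):
            f0 = np.exp(20.0 * self.grid.u**2)
        else:
            f0 = np.asarray(init.values if isinstance(init, OrientationDistribution) else init, dtype=float)
        f, lnq, _, _ = _picard(coupling, self.kernel, f0, mixing, tol, max_iter)
        return PureState(self.spheroid, rho, self.z, OrientationDistribution(f, self.grid), lnq, self.kernel)

    def nematic_state(self, rho: float, f0=None, **kw) -> PureState:
        """Nematic state at ``rho``; raises :class:`NoNematicPhaseError` if
        the iteration collapses to the isotropic fixed point."""
        st = self.state(rho, init="nematic" if f0 is None else f0, **kw)
        if not st.is_nematic:
            raise NoNematicPhaseError(
                f"no nematic fixed point at eta={st.eta:.4f} (S={st.order_parameter:.2e})"
            )
        return st

    # -- branches ----------------------------------------------------------

    def trace_branch(
        self,
        branch: Literal["isotropic", "nematic"],
        eta_start: float,
        eta_stop: float,
        n_points: int = 25,
        **solver_kw,
    ) -> list[PureState]:
        """States along one branch of the equation of state.

        The nematic branch is traced by continuation from high packing
        fraction downward, reusing the previous distribution as the seed;
        points where the nematic solution collapses to isotropic are
        dropped (the collapse density is the metastability limit).
        """
        v = self.spheroid.volume
        etas = np.linspace(eta_start, eta_stop, n_points)
        states: list[PureState] = []
        if branch == "isotropic":
            for eta in etas:
                states.append(self.isotropic_state(eta / v))
            return states
        if branch != "nematic":
            raise ValueError(f"unknown branch {branch!r}")
        etas = np.sort(etas)[::-1]  # high -> low continuation
        f_prev = None
        for eta in etas:
            st = self.state(eta / v, init="nematic" if f_prev is None else f_prev, **solver_kw)
            if not st.is_nematic:
                break
            states.append(st)
            f_prev = st.f
        return states[::-1]

    def find_metastability_limit(self, resolution: float = 1e-4) -> dict[str, float | None]:
        """Metastability limits of both branches.

        nematic: lowest packing fraction at which a nematic fixed point
        (S > threshold) survives, located by bisection with branch
        continuation.  isotropic: lowest packing fraction at which the
        isotropic fixed point is linearly unstable under the Picard map
        (growth of an infinitesimal P2(cos theta) perturbation), i.e. the
        isotropic spinodal.  ``None`` marks a limit that does not exist.
        """
        return {
            "nematic": self._nematic_limit(resolution),
            "isotropic": self._isotropic_spinodal(resolution),
        }

    def _nematic_exists(self, eta: float, f0) -> tuple[bool, OrientationDistribution | None]:
        try:
            st = self.state(eta / self.spheroid.volume, init=f0)
        except ConvergenceError:
            return False, None
        return (st.is_nematic, st.f if st.is_nematic else None)

    def _nematic_limit(self, resolution: float) -> float | None:
        hi = 0.65
        ok, f = self._nematic_exists(hi, "nematic")
        while not ok and hi < 0.78:
            hi += 0.04
            ok, f = self._nematic_exists(hi, "nematic")
        if not ok:
            return None
        lo = hi
        step = 0.02
        while lo > step:
            cand = lo - step
            ok2, f2 = self._nematic_exists(cand, f)
            if not ok2:
                break
            lo, f = cand, f2
        else:
            return None
        a, b = lo - step, lo  # nematic dies somewhere in (a, b]
        while b - a > resolution:
            mid = 0.5 * (a + b)
            ok2, f2 = self._nematic_exists(mid, f)
            if ok2:
                b, f = mid, f2
            else:
                a = mid
        return b

    def _iso_growth(self, eta: float) -> float:
        """Largest eigenvalue of the Picard map linearized at f = 1."""
        rho = eta / self.spheroid.volume
        w = self.grid.w_theta
        K = self.kernel.reduced
        col = w @ K  # (1/4 pi) oint vex(., theta') dOmega
        M = -rho * lp_prefactor(eta, self.z) * (K - col[None, :]) * w[None, :]
        ev = np.linalg.eigvals(M)
        return float(np.max(ev.real))

    def _isotropic_spinodal(self, resolution: float) -> float | None:
        hi = 0.95
        if self._iso_growth(hi) < 1.0:
            return None
        lo = 1e-3
        while hi - lo > resolution:
            mid = 0.5 * (lo + hi)
            if self._iso_growth(mid) > 1.0:
                hi = mid
            else:
                lo = mid
        return hi

    # -- coexistence -------------------------------------------------------

    def _iso_rho_at_pressure(self, p: float) -> float:
        """Invert the (monotone) isotropic equation of state."""
        v = self.spheroid.volume
        return brentq(
            lambda r: self.isotropic_state(r).pressure - p,
            1e-12, 0.97 / v, xtol=1e-16, rtol=1e-14,
        )

    def coexistence(
        self,
        tol: float = 1e-9,
        eta_scan: Sequence[float] | None = None,
    ) -> PureCoexistence:
        """Isotropic-nematic coexistence: equal pressure and chemical
        potential across the two branches.

        A downward scan of the nematic branch brackets the sign change of
        ``mu_nem - mu_iso`` at matched pressure; Brent refinement in the
        nematic packing fraction, followed by a two-variable Newton polish
        on (rho_iso, rho_nem), drives both residuals below ``tol`` (in
        reduced units).  Raises :class:`NoNematicPhaseError` when no
        nematic branch exists (e.g. spheres).
        """
        v = self.spheroid.volume
        if eta_scan is None:
            eta_scan = np.arange(0.70, 0.30, -0.01)
        f_cache: dict[float, OrientationDistribution] = {}
        f_last: list = [None]

        def dmu(eta_nem: float) -> float:
            key = min(f_cache, key=lambda e: abs(e - eta_nem)) if f_cache else None
            seed = f_cache[key] if key is not None else "nematic"
            st = self.state(eta_nem / v, init=seed)
            if not st.is_nematic:
                raise NoNematicPhaseError(f"nematic branch lost at eta={eta_nem:.4f}")
            f_cache[eta_nem] = st.f
            f_last[0] = st.f
            rho_iso = self._iso_rho_at_pressure(st.pressure)
            return st.mu_star - self.isotropic_state(rho_iso).mu_star

        def find_bracket(hi: float, lo: float, step: float) -> tuple[float, float] | None:
            # Scan downward; if the nematic branch dies mid-scan, refine the
            # step toward the metastability limit (the mu crossing can sit
            # just above it).
            prev = None
            eta = hi
            while eta > lo - 1e-12:
                try:
                    val = dmu(eta)
                except (NoNematicPhaseError, ConvergenceError):
                    if prev is not None and step > 2e-4:
                        return find_bracket(prev[0], max(lo, eta), step / 5.0)
                    return None
                if prev is not None and np.sign(val) != np.sign(prev[1]):
                    return (eta, prev[0])
                prev = (eta, val)
                eta -= step
            return None

        etas = np.sort(np.asarray(eta_scan, dtype=float))
        bracket = find_bracket(float(etas[-1]), float(etas[0]), float(np.diff(etas).mean()))
        if bracket is None:
            raise NoNematicPhaseError(
                "no isotropic-nematic coexistence found in the scanned "
                "packing-fraction range"
            )
        eta_nem = brentq(dmu, *bracket, xtol=1e-12)

        # Newton polish on (rho_iso, rho_nem) for equal P and mu
        nem = self.state(eta_nem / v, init=f_last[0])
        rho_iso0 = self._iso_rho_at_pressure(nem.pressure)
        scale_p = 8.0 * self.spheroid.a**2 * self.spheroid.c

        def residuals(x):
            iso_s = self.isotropic_state(x[0] / v)
            nem_s = self.state(x[1] / v, init=f_last[0])
            f_last[0] = nem_s.f
            return [
                (iso_s.pressure - nem_s.pressure) * scale_p,
                iso_s.mu_star - nem_s.mu_star,
            ]

        sol = root(residuals, [rho_iso0 * v, eta_nem], method="hybr", tol=tol)
        if not sol.success or np.max(np.abs(sol.fun)) > 100 * tol:
            raise ConvergenceError(
                f"coexistence polish failed: {sol.message}", float(np.max(np.abs(sol.fun)))
            )
        iso_state = self.isotropic_state(sol.x[0] / v)
        nem_state = self.state(sol.x[1] / v, init=f_last[0])
        if not nem_state.is_nematic or nem_state.eta <= iso_state.eta:
            raise NoNematicPhaseError("coexistence polish collapsed to a trivial root")
        return PureCoexistence(iso_state, nem_state)


# -- module-level operation wrappers ---------------------------------------


def trace_branch(
    system: PureSystem,
    branch: Literal["isotropic", "nematic"],
    eta_start: float,
    eta_stop: float,
    n_points: int = 25,
    **solver_kw,
) -> list[PureState]:
    """See :meth:`PureSystem.trace_branch`."""
    return system.trace_branch(branch, eta_start, eta_stop, n_points, **solver_kw)


def find_metastability_limit(system: PureSystem, resolution: float = 1e-4) -> dict[str, float | None]:
    """See :meth:`PureSystem.find_metastability_limit`."""
    return system.find_metastability_limit(resolution)


def pure_coexistence(system: PureSystem, tol: float = 1e-9) -> PureCoexistence:
    """See :meth:`PureSystem.coexistence`."""
    return system.coexistence(tol=tol)
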