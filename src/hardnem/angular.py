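"""Angular grids, orientational distribution functions and the
orientational integrals of the Onsager free energy.

Conventions: the nematic director lies along ``theta = 0``; equilibrium
distributions are azimuthally symmetric, so solvers work with
``f(theta)`` vectors and an azimuthally pre-averaged kernel
``K(theta, theta') = (1/2 pi) int vex(cos gamma) d(dphi)``.  The full
``(theta, phi)`` representation is retained for cross-checks; the two paths
agree to quadrature precision because the azimuthal average is the same
discrete sum.

All angular averages use the normalized solid-angle measure
``(1/4 pi) dOmega``, so the isotropic distribution is ``f = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hardnem.geometry import ExcludedVolumeTable, interp_vex
from hardnem.quadrature import azimuth_nodes_weight, polar_nodes_weights

__all__ = [
    "AngularGrid",
    "OrientationDistribution",
    "KernelMatrix",
    "build_grid",
    "relative_cos",
    "build_kernel",
    "excess_integral",
    "orientational_entropy",
    "order_parameter",
]

NORM_TOL = 1e-6


@dataclass(frozen=True)
class AngularGrid:
    """Quadrature grid over the unit sphere of orientations.

    ``n_theta`` evenly spaced midpoint polar angles (Fejer-1 weights in
    cos(theta)) and ``n_phi`` evenly spaced azimuthal midpoints.  The stored
    polar weights ``w_theta`` are normalized to sum to 1, so that for an
    azimuthally symmetric ``v(theta)``,

        (1/4 pi) oint v dOmega  =  sum_i w_theta[i] v[i].
    """

    n_theta: int = 100
    n_phi: int = 50
    theta: np.ndarray = field(init=False, repr=False)
    u: np.ndarray = field(init=False, repr=False)
    w_theta: np.ndarray = field(init=False, repr=False)
    phi: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_theta < 4 or self.n_phi < 4:
            raise ValueError("grid needs n_theta >= 4 and n_phi >= 4")
        theta, w = polar_nodes_weights(self.n_theta)
        w = w / w.sum()  # exact constant-function normalization
        phi, _ = azimuth_nodes_weight(self.n_phi)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "u", np.cos(theta))
        object.__setattr__(self, "w_theta", w)
        object.__setattr__(self, "phi", phi)

    def integrate(self, values: np.ndarray) -> float:
        """Normalized solid-angle average (1/4 pi) oint v dOmega of a
        ``(n_theta,)`` or ``(n_theta, n_phi)`` sample array."""
        v = np.asarray(values, dtype=float)
        if v.shape == (self.n_theta,):
            return float(self.w_theta @ v)
        if v.shape == (self.n_theta, self.n_phi):
            return float(self.w_theta @ v.mean(axis=1))
        raise ValueError(f"values shape {v.shape} does not match grid")


def build_grid(n_theta: int = 100, n_phi: int = 50) -> AngularGrid:
    """Construct an :class:`AngularGrid` (defaults 100 x 50)."""
    return AngularGrid(n_theta, n_phi)


@dataclass
class OrientationDistribution:
    """Normalized orientational distribution ``f`` on an angular grid.

    ``values`` may be a ``(n_theta,)`` vector (azimuthally symmetric, the
    form all solvers use) or a full ``(n_theta, n_phi)`` array.  Normalized
    means ``(1/4 pi) oint f dOmega = 1``; the isotropic state is ``f = 1``.
    """

    values: np.ndarray
    grid: AngularGrid
    species: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("distribution values must be non-negative")
        self.grid.integrate(self.values)  # shape check

    @property
    def norm(self) -> float:
        return self.grid.integrate(self.values)

    @property
    def is_normalized(self) -> bool:
        return abs(self.norm - 1.0) < NORM_TOL

    def normalized(self) -> "OrientationDistribution":
        return OrientationDistribution(self.values / self.norm, self.grid, self.species)

    @classmethod
    def isotropic(cls, grid: AngularGrid, species: str = "") -> "OrientationDistribution":
        return cls(np.ones(grid.n_theta), grid, species)

    @classmethod
    def peaked(cls, grid: AngularGrid, kappa: float = 20.0, species: str = "") -> "OrientationDistribution":
        """Nematic seed ``f propto exp(kappa cos^2 theta)``."""
        v = np.exp(kappa * (grid.u**2 - 1.0))  # shifted to avoid overflow
        d = cls(v, grid, species)
        return d.normalized()


def _values(f, grid: AngularGrid, require_normalized: bool = True) -> np.ndarray:
    if isinstance(f, OrientationDistribution):
        v = f.values
    else:
        v = np.asarray(f, dtype=float)
    if require_normalized and abs(grid.integrate(v) - 1.0) >= NORM_TOL:
        raise ValueError("distribution is not normalized on this grid")
    return v


def relative_cos(theta, phi, theta_p, phi_p):
    """cos(gamma) between directions (theta, phi) and (theta', phi'):
    spherical law of cosines."""
    return np.cos(theta) * np.cos(theta_p) + np.sin(theta) * np.sin(theta_p) * np.cos(
        np.asarray(phi) - np.asarray(phi_p)
    )


@dataclass
class KernelMatrix:
    """Discretized excluded-volume kernel for one species pair.

    ``reduced[i, j]`` is the azimuthal average ``(1/2 pi) int
    vex(cos gamma(theta_i, theta_j, dphi)) d(dphi)`` evaluated with the
    grid's ``n_phi`` uniform offsets -- exactly the quantity the discrete
    double azimuthal sum produces for azimuthally symmetric distributions.
    """

    grid: AngularGrid
    table: ExcludedVolumeTable
    reduced: np.ndarray

    def full_matrix(self) -> np.ndarray:
        """Dense ``(n_theta * n_phi) x (n_theta * n_phi)`` kernel
        ``vex(theta, phi; theta', phi')``; intended for small grids only."""
        g = self.grid
        th = np.repeat(g.theta, g.n_phi)
        ph = np.tile(g.phi, g.n_theta)
        cg = relative_cos(th[:, None], ph[:, None], th[None, :], ph[None, :])
        return interp_vex(self.table, np.clip(cg, -1.0, 1.0))

    def row_average(self, f) -> np.ndarray:
        """(1/4 pi) int f(theta') vex(.,theta') dOmega' as a theta-vector."""
        v = _values(f, self.grid, require_normalized=False)
        return self.reduced @ (self.grid.w_theta * v)


def build_kernel(grid: AngularGrid, table: ExcludedVolumeTable) -> KernelMatrix:
    """Assemble the azimuthally pre-averaged kernel matrix from an
    excluded-volume table."""
    ct, st = grid.u, np.sin(grid.theta)
    dphi = 2.0 * np.pi * np.arange(grid.n_phi) / grid.n_phi
    cg = ct[:, None, None] * ct[None, :, None] + st[:, None, None] * st[None, :, None] * np.cos(dphi)[None, None, :]
    K = interp_vex(table, np.clip(cg, -1.0, 1.0)).mean(axis=2)
    K = 0.5 * (K + K.T)  # symmetrize roundoff
    return KernelMatrix(grid, table, K)


def excess_integral(fA, fB, kernel: KernelMatrix) -> float:
    """Double orientational average ``(1/(4 pi)^2) oint oint fA(w) fB(w')
    vex(w, w') dOmega dOmega'`` in nm^3; bilinear and symmetric in its
    distribution arguments.  Inputs must be normalized."""
    g = kernel.grid
    vA = _values(fA, g)
    vB = _values(fB, g)
    wA = g.w_theta * vA
    wB = g.w_theta * vB
    return float(wA @ kernel.reduced @ wB)


def orientational_entropy(f, grid: AngularGrid) -> float:
    """Orientational entropy deficit ``(1/4 pi) oint f ln f dOmega``
    (dimensionless, >= 0, zero only for the isotropic state)."""
    v = _values(f, grid)
    if np.any(v < 0):
        raise ValueError("distribution must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        flnf = np.where(v > 0.0, v * np.log(np.where(v > 0.0, v, 1.0)), 0.0)
    return grid.integrate(flnf)


def order_parameter(f, grid: AngularGrid) -> float:
    """Nematic order parameter S = <P2(cos theta)> = (3/2) <f cos^2 theta>
    - 1/2; 0 in the isotropic phase, 1 at perfect alignment."""
    v = _values(f, grid)
    if v.ndim == 1:
        m2 = float(grid.w_theta @ (grid.u**2 * v))
    else:
        m2 = grid.integrate(grid.u[:, None] ** 2 * v)
    return 1.5 * m2 - 0.5
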