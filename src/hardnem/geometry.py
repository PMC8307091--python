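"""Particle geometry and the excluded volume of two hard prolate spheroids.

A prolate spheroid is an ellipsoid of revolution with minor semi-axis ``a``
and major semi-axis ``c >= a`` (both in nm).  The excluded volume of a pair
at fixed relative orientation -- the region around one particle that the
center of the other cannot enter -- is evaluated three ways:

* the closed-form Gaussian-overlap (Berne-Pechukas) model, valid for a pair
  of identical spheroids;
* a rigorous surface integral over the apse vector (the unit normal of the
  common tangent plane at contact), valid for arbitrary pairs;
* Monte Carlo integration of the overlap indicator built on the
  Perram-Wertheim ellipsoid contact function, used as an independent check.

All excluded volumes depend on the orientations only through
``cos_gamma = u1 . u2``, the dot product of the two symmetry axes, and are
even in it (spheroids have head-tail symmetry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from hardnem.quadrature import azimuth_nodes_weight, polar_nodes_weights

__all__ = [
    "ProlateSpheroid",
    "ExcludedVolumeTable",
    "gaussian_overlap_vex",
    "rigorous_vex",
    "pw_contact_value",
    "pw_overlap",
    "mc_excluded_volume",
    "MCExcludedVolume",
    "tabulate_vex",
    "interp_vex",
]


@dataclass(frozen=True)
class ProlateSpheroid:
    """Hard prolate spheroid with minor radius ``a`` and major radius ``c``.

    Attributes
    ----------
    a, c : float
        Minor and major semi-axes in nm, with ``c >= a > 0``.
    """

    a: float
    c: float

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"minor radius must be positive, got a={self.a}")
        if not (self.c >= self.a):
            raise ValueError(
                f"major radius must satisfy c >= a (prolate), got a={self.a}, c={self.c}"
            )

    @property
    def volume(self) -> float:
        """Particle volume (4/3) pi a^2 c in nm^3."""
        return (4.0 / 3.0) * np.pi * self.a**2 * self.c

    @property
    def aspect_ratio(self) -> float:
        return self.c / self.a

    @property
    def chi(self) -> float:
        """Shape anisotropy ((c/a)^2 - 1) / ((c/a)^2 + 1) of the Gaussian
        overlap model; 0 for a sphere, -> 1 for needles."""
        k2 = (self.c / self.a) ** 2
        return (k2 - 1.0) / (k2 + 1.0)

    @property
    def eps(self) -> float:
        """Eccentricity parameter c^2/a^2 - 1 of the apse-frame integrand."""
        return (self.c / self.a) ** 2 - 1.0

    @property
    def sigma(self) -> float:
        """Equal-volume-sphere diameter (8 c a^2)^(1/3) in nm, satisfying
        (pi/6) sigma^3 = volume exactly."""
        return (8.0 * self.c * self.a**2) ** (1.0 / 3.0)

    @property
    def is_sphere(self) -> bool:
        return self.c == self.a

    def quadratic_form(self, axis: np.ndarray) -> np.ndarray:
        """Matrix A with surface (x-r)^T A (x-r) = 1 for symmetry axis
        ``axis`` (unit vector)."""
        u = np.asarray(axis, dtype=float)
        u = u / np.linalg.norm(u)
        P = np.outer(u, u)
        return (np.eye(3) - P) / self.a**2 + P / self.c**2


def spheroid_volume(sp: ProlateSpheroid) -> float:
    """Volume (4/3) pi a^2 c of a single prolate spheroid, nm^3."""
    return sp.volume


def _check_cos_gamma(cos_gamma) -> np.ndarray:
    t = np.asarray(cos_gamma, dtype=float)
    if np.any(np.abs(t) > 1.0 + 1e-12):
        raise ValueError("cos_gamma must lie in [-1, 1]")
    return np.clip(t, -1.0, 1.0)


def gaussian_overlap_vex(sp: ProlateSpheroid, cos_gamma, other: ProlateSpheroid | None = None):
    """Gaussian-overlap (Berne-Pechukas) excluded volume of two *identical*
    prolate spheroids, nm^3.

    vex = 8 v_lc sqrt((1 - chi^2 cos^2 gamma) / (1 - chi^2))

    The model is defined only for a same-size pair; passing a different
    ``other`` spheroid raises ``ValueError``.
    """
    if other is not None and (other.a != sp.a or other.c != sp.c):
        raise ValueError(
            "the Gaussian overlap model applies only to identical pairs; "
            "use rigorous_vex for a heterogeneous pair"
        )
    t = _check_cos_gamma(cos_gamma)
    chi2 = sp.chi**2
    out = 8.0 * sp.volume * np.sqrt((1.0 - chi2 * t**2) / (1.0 - chi2))
    return out if out.ndim else float(out)


def rigorous_vex(
    sp1: ProlateSpheroid,
    sp2: ProlateSpheroid,
    cos_gamma,
    n_theta_k: int = 100,
    n_phi_k: int = 50,
):
    """Excluded volume of two prolate spheroids by the rigorous apse-frame
    surface integral, nm^3.

    The integral runs over the apse direction k (the common-tangent normal
    at contact).  With x_i = k.u_i, h_i = a_i sqrt(1 + eps_i x_i^2),
    h_i' = x_i a_i^2 eps_i / h_i, h_i'' = a_i^4 eps_i / h_i^3,
    F = h_1 - x_1 h_1' + h_2 - x_2 h_2', g_i = (1 - x_i^2) h_i'' and
    lambda_ee = (u_1 x u_2) . k,

        vex = (1/3) oint h12 { F [F + g_1 + g_2] + h_1'' h_2'' lambda_ee^2 } dk.

    The quadrature uses ``n_theta_k`` evenly spaced midpoint polar angles
    (with Fejer-1 weights in cos(theta_k)) and ``n_phi_k`` azimuthal points.
    Accepts scalar or array ``cos_gamma``; vectorized over it.
    """
    if n_theta_k < 2 or n_phi_k < 2:
        raise ValueError("quadrature resolutions must be >= 2")
    t = _check_cos_gamma(cos_gamma)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    sin_g = np.sqrt(np.clip(1.0 - t**2, 0.0, None))

    theta_k, w_th = polar_nodes_weights(n_theta_k)
    phi_k, w_ph = azimuth_nodes_weight(n_phi_k)
    ct = np.cos(theta_k)[:, None]
    st = np.sin(theta_k)[:, None]
    cp = np.cos(phi_k)[None, :]
    sp_ = np.sin(phi_k)[None, :]

    # frame: u1 = z, u2 = (sin gamma, 0, cos gamma); u1 x u2 = (0, sin gamma, 0)
    x1 = np.broadcast_to(ct, (n_theta_k, n_phi_k))[None, :, :]
    x2 = st[None, :, :] * cp[None, :, :] * sin_g[:, None, None] + ct[None, :, :] * t[:, None, None]
    lam = sin_g[:, None, None] * (st * sp_)[None, :, :]

    e1, e2 = sp1.eps, sp2.eps
    h1 = sp1.a * np.sqrt(1.0 + e1 * x1**2)
    h2 = sp2.a * np.sqrt(1.0 + e2 * x2**2)
    h1p = x1 * sp1.a**2 * e1 / h1
    h2p = x2 * sp2.a**2 * e2 / h2
    h1pp = sp1.a**4 * e1 / h1**3
    h2pp = sp2.a**4 * e2 / h2**3
    F = h1 - x1 * h1p + h2 - x2 * h2p
    g1 = (1.0 - x1**2) * h1pp
    g2 = (1.0 - x2**2) * h2pp
    h12 = h1 + h2
    integrand = h12 * (F * (F + g1 + g2) + h1pp * h2pp * lam**2)
    if not np.all(np.isfinite(integrand)):
        raise FloatingPointError("non-finite apse-frame integrand")

    vex = (1.0 / 3.0) * w_ph * np.einsum("gtp,t->g", integrand, w_th)
    return float(vex[0]) if scalar else vex


def pw_contact_value(
    sp1: ProlateSpheroid,
    sp2: ProlateSpheroid,
    axis1,
    axis2,
    r12,
    xatol: float = 1e-12,
) -> float:
    """Perram-Wertheim contact function of two ellipsoids of revolution.

    ``F = max_{lambda in (0,1)} lambda (1-lambda) r^T [(1-lambda) A1^{-1}
    + lambda A2^{-1}]^{-1} r`` with A_i the quadratic-form matrices.  The
    bodies overlap iff F < 1 (F = 1 at external tangency).
    """
    A1 = sp1.quadratic_form(axis1)
    A2 = sp2.quadratic_form(axis2)
    B1 = np.linalg.inv(A1)
    B2 = np.linalg.inv(A2)
    r = np.asarray(r12, dtype=float)

    def neg_S(lam: float) -> float:
        G = (1.0 - lam) * B1 + lam * B2
        y = np.linalg.solve(G, r)
        return -lam * (1.0 - lam) * float(r @ y)

    res = minimize_scalar(neg_S, bounds=(0.0, 1.0), method="bounded", options={"xatol": xatol})
    if not res.success:
        raise RuntimeError(f"contact-function maximization failed: {res.message}")
    return -res.fun


def pw_overlap(sp1: ProlateSpheroid, sp2: ProlateSpheroid, axis1, axis2, r12) -> bool:
    """True iff the two ellipsoids of revolution intersect (Perram-Wertheim
    criterion, contact value < 1)."""
    return pw_contact_value(sp1, sp2, axis1, axis2, r12) < 1.0


@dataclass(frozen=True)
class MCExcludedVolume:
    """Monte Carlo excluded-volume estimate with its binomial standard error."""

    estimate: float
    stderr: float
    n_samples: int
    n_overlaps: int

    @property
    def degenerate(self) -> bool:
        """True when no overlaps were sampled, so the estimate is unusable."""
        return self.n_overlaps == 0


def mc_excluded_volume(
    sp1: ProlateSpheroid,
    sp2: ProlateSpheroid,
    cos_gamma: float,
    n_samples: int = 100_000,
    seed: int | None = None,
    n_lambda: int = 201,
) -> MCExcludedVolume:
    """Monte Carlo estimate of the pair excluded volume at fixed relative
    orientation, nm^3.

    Center separations are sampled uniformly in a cuboid of half-width
    ``c1 + c2`` per axis (a guaranteed bound on the Minkowski-sum reach);
    the overlap indicator uses the Perram-Wertheim contact function,
    maximized over a dense lambda grid with parabolic refinement (the
    contact function is concave in lambda).

    Returns the estimate and its binomial standard error.  A run with zero
    overlap hits is flagged ``degenerate`` and warned about.
    """
    if n_samples < 1_000:
        raise ValueError("n_samples must be >= 1000")
    if seed is None:
        raise ValueError("a seed is required for reproducibility")
    t = float(_check_cos_gamma(cos_gamma))
    sin_g = np.sqrt(max(0.0, 1.0 - t * t))
    u1 = np.array([0.0, 0.0, 1.0])
    u2 = np.array([sin_g, 0.0, t])

    B1 = np.linalg.inv(sp1.quadratic_form(u1))
    B2 = np.linalg.inv(sp2.quadratic_form(u2))
    lam = np.linspace(0.0, 1.0, n_lambda)[1:-1]
    # M(lam) = lam (1-lam) G(lam)^{-1}; S(r) = max_lam r.M(lam).r
    M = np.empty((lam.size, 3, 3))
    for i, l in enumerate(lam):
        M[i] = l * (1.0 - l) * np.linalg.inv((1.0 - l) * B1 + l * B2)

    L = sp1.c + sp2.c
    box_volume = (2.0 * L) ** 3
    rng = np.random.default_rng(seed)
    n_hits = 0
    chunk = 50_000
    for start in range(0, n_samples, chunk):
        m = min(chunk, n_samples - start)
        r = rng.uniform(-L, L, size=(m, 3))
        S = np.einsum("mi,lij,mj->ml", r, M, r)
        jmax = np.argmax(S, axis=1)
        jc = np.clip(jmax, 1, lam.size - 2)
        rows = np.arange(m)
        y0, y1, y2 = S[rows, jc - 1], S[rows, jc], S[rows, jc + 1]
        denom = y0 - 2.0 * y1 + y2
        # parabolic vertex value through the three best grid points
        corr = np.where(np.abs(denom) > 0, (y0 - y2) ** 2 / (8.0 * np.abs(denom)), 0.0)
        Smax = np.maximum(S[rows, jmax], y1 + corr)
        n_hits += int(np.count_nonzero(Smax < 1.0))

    p = n_hits / n_samples
    est = p * box_volume
    se = box_volume * np.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
    result = MCExcludedVolume(est, se, n_samples, n_hits)
    if result.degenerate:
        warnings.warn("no overlaps sampled; Monte Carlo estimate is degenerate", RuntimeWarning)
    return result


@dataclass
class ExcludedVolumeTable:
    """Tabulated excluded volume vs ``cos_gamma`` for one species pair.

    The grid covers cos_gamma in [0, 1]; head-tail symmetry supplies the
    negative half.  Interpolation is a cubic spline with an even reflection
    (zero slope) at cos_gamma = 0.
    """

    pair: str
    method: Literal["gaussian", "rigorous"]
    cos_gamma: np.ndarray
    vex: np.ndarray
    n_theta_k: int | None = None
    n_phi_k: int | None = None
    _spline: CubicSpline = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if np.any(self.vex <= 0):
            raise ValueError("excluded volume must be positive everywhere")
        self._spline = CubicSpline(
            self.cos_gamma, self.vex, bc_type=((1, 0.0), "not-a-knot")
        )

    def __call__(self, cos_gamma):
        return interp_vex(self, cos_gamma)

    @property
    def aligned_value(self) -> float:
        """vex at cos_gamma = 1 (8 v_lc for an identical pair)."""
        return float(self.vex[-1])

    def isotropic_average(self) -> float:
        """Orientational average <vex> over an isotropic distribution,
        i.e. the uniform average over cos_gamma in [0, 1]."""
        return float(self._spline.integrate(0.0, 1.0))


def tabulate_vex(
    sp1: ProlateSpheroid,
    sp2: ProlateSpheroid,
    method: Literal["gaussian", "rigorous"] = "rigorous",
    n_grid_points: int = 201,
    n_theta_k: int = 100,
    n_phi_k: int = 50,
) -> ExcludedVolumeTable:
    """Build an :class:`ExcludedVolumeTable` on a uniform cos_gamma grid.

    For prolate pairs vex must be non-increasing in |cos_gamma|; violations
    beyond quadrature tolerance are warned about with diagnostics.
    """
    if n_grid_points < 8:
        raise ValueError("need at least 8 grid points")
    t = np.linspace(0.0, 1.0, n_grid_points)
    if method == "gaussian":
        if sp1.a != sp2.a or sp1.c != sp2.c:
            raise ValueError("gaussian method is limited to identical pairs")
        v = gaussian_overlap_vex(sp1, t)
        res = (None, None)
    elif method == "rigorous":
        v = rigorous_vex(sp1, sp2, t, n_theta_k=n_theta_k, n_phi_k=n_phi_k)
        res = (n_theta_k, n_phi_k)
    else:
        raise ValueError(f"unknown method {method!r}")
    dv = np.diff(v)
    tol = 1e-8 * v[0]
    if np.any(dv > tol):
        i = int(np.argmax(dv))
        warnings.warn(
            f"excluded-volume table not monotone: rise {dv[i]:.3e} nm^3 "
            f"at cos_gamma={t[i]:.4f} (method={method})",
            RuntimeWarning,
        )
    pair = f"({sp1.a},{sp1.c})-({sp2.a},{sp2.c})"
    return ExcludedVolumeTable(pair, method, t, np.asarray(v, dtype=float), *res)


def interp_vex(table: ExcludedVolumeTable, cos_gamma):
    """Interpolated excluded volume at ``cos_gamma`` (even in cos_gamma);
    exact at the table nodes.  Raises for queries outside [-1, 1]."""
    t = np.asarray(cos_gamma, dtype=float)
    if np.any(np.abs(t) > 1.0 + 1e-12):
        raise ValueError("cos_gamma must lie in [-1, 1]")
    out = table._spline(np.abs(np.clip(t, -1.0, 1.0)))
    return out if out.ndim else float(out)
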