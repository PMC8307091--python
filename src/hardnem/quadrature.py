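"""Polar-angle quadrature shared by the excluded-volume and orientational
integrals.

Nodes are evenly spaced midpoints of the polar angle, ``theta_j =
(2j+1)*pi/(2n)``, so the endpoints ``theta = 0, pi`` (where ``sin(theta)``
degenerates) are never sampled.  The weights attached to those nodes are the
Fejer first-rule weights for integration in ``x = cos(theta)``: the midpoint
angles map exactly onto the Fejer-1 Chebyshev nodes ``x_j = cos(theta_j)``,
so the rule is interpolatory and integrates polynomials in ``cos(theta)`` up
to degree ``n - 1`` exactly.  This keeps the advertised "evenly spaced polar
discretization" while making low moments (normalization, ``<cos^2 theta>``)
accurate to machine precision at the default resolution.
"""

from __future__ import annotations

import numpy as np


def polar_nodes_weights(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint polar angles and Fejer-1 weights for ``int_0^pi f(theta)
    sin(theta) dtheta = int_{-1}^{1} f dx``.

    Parameters
    ----------
    n : int
        Number of polar nodes (>= 2).

    Returns
    -------
    theta : ndarray, shape (n,)
        Evenly spaced midpoint angles in (0, pi), decreasing in cos(theta).
    w : ndarray, shape (n,)
        Positive weights summing to 2 (the measure of [-1, 1]).
    """
    if n < 2:
        raise ValueError("need at least 2 polar nodes")
    j = np.arange(n)
    theta = (2 * j + 1) * np.pi / (2 * n)
    m = np.arange(1, n // 2 + 1)
    # Fejer-1: w_j = (2/n) * [1 - 2 sum_m cos(2 m theta_j) / (4 m^2 - 1)]
    w = (2.0 / n) * (
        1.0 - 2.0 * np.sum(np.cos(2.0 * m[:, None] * theta[None, :]) / (4.0 * m**2 - 1.0)[:, None], axis=0)
    )
    return theta, w


def azimuth_nodes_weight(n: int) -> tuple[np.ndarray, float]:
    """Evenly spaced azimuthal midpoints on [0, 2*pi) and the common weight.

    The trapezoidal/midpoint rule is spectrally accurate for periodic
    integrands, so uniform weights ``2*pi/n`` are already optimal.
    """
    if n < 2:
        raise ValueError("need at least 2 azimuthal nodes")
    k = np.arange(n)
    phi = (2 * k + 1) * np.pi / n  # midpoints of n equal bins on [0, 2 pi)
    return phi, 2.0 * np.pi / n
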