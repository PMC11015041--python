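"""Independent brute-force oracles used by the tests.

These deliberately re-derive reference answers with different numerics than
the production code (1-D spherical finite differences, closed forms), so that
agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded

from psmasim.params import ParameterSet


def radial_two_region_pressure(
    params: ParameterSet,
    tumor_radius: float,
    outer_radius: float,
    n_nodes: int = 6000,
) -> tuple[np.ndarray, np.ndarray]:
    """High-resolution 1-D spherically symmetric Darcy--Starling solve.

    Conservative finite differences on ``d/dr(K r^2 dp/dr) = r^2 (b p - a)``
    with regularity at the origin, coefficient jumps at the tumor radius
    (harmonic face averaging), and ``p = 0`` at the outer radius.  Returns
    ``(r, p)`` at node centers.
    """
    dr = outer_radius / n_nodes
    r = (np.arange(n_nodes) + 0.5) * dr          # cell centers
    r_face = np.arange(1, n_nodes) * dr          # interior faces

    def per_region(tval, nval):
        return np.where(r <= tumor_radius, tval, nval)

    tf, nf = params.tumor, params.normal
    K = per_region(tf.K, nf.K)
    a = per_region(
        tf.Lp * tf.S_V * tf.p_equilibrium + tf.lymph_conductance * tf.p_L,
        nf.Lp * nf.S_V * nf.p_equilibrium + nf.lymph_conductance * nf.p_L,
    )
    b = per_region(
        tf.Lp * tf.S_V + tf.lymph_conductance,
        nf.Lp * nf.S_V + nf.lymph_conductance,
    )

    k_face = 2.0 * K[:-1] * K[1:] / (K[:-1] + K[1:])
    t_face = k_face * r_face**2 / dr             # interior transmissibilities
    vol = r**2 * dr

    diag = b * vol
    lower = np.zeros(n_nodes)
    upper = np.zeros(n_nodes)
    diag[:-1] += t_face
    diag[1:] += t_face
    upper[1:] = -t_face                          # superdiagonal entries
    lower[:-1] = -t_face                         # subdiagonal entries
    # outer Dirichlet p=0 at r = outer_radius (half-cell distance)
    t_out = K[-1] * outer_radius**2 / (0.5 * dr)
    diag[-1] += t_out

    ab = np.zeros((3, n_nodes))
    ab[0] = upper
    ab[1] = diag
    ab[2] = lower
    p = solve_banded((1, 1), ab, a * vol)
    return r, p


def bolus_plasma_closed_form(amount, volume, alpha_per_min, t_min):
    """C_p(t) for a bolus, evaluated directly."""
    return amount / volume * np.exp(-alpha_per_min * np.asarray(t_min))
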