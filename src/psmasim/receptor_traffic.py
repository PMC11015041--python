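"""PSMA receptor trafficking: synthesis, endocytosis, recycling, degradation.

Four per-voxel pools (all nmol/L):

* ``F_s``  free receptors on the cell surface
* ``F_e``  free receptors in the sorting endosome
* ``RP_s`` occupied (ligand-bound) receptors on the surface
* ``RP_e`` occupied receptors in the endosome

Free surface receptors bind extracellular ligand (labeled plus unlabeled) at
``k_on``; occupied receptors release it at ``k_off`` or are internalized at
``k_int``.  Free receptors undergo constitutive endocytosis at ``k_ec``.  In
the endosome a fraction ``1 - f`` is recycled to the surface at ``k_rec``
while the sorted fraction ``f`` is degraded at ``k_deg`` (``f1`` for occupied,
``f2`` for free receptors).  Receptor supply combines a constitutive term
``V_r`` and a synthesis term ``k_syn * RP_s`` proportional to surface
occupancy.  Receptors are cell-bound and do not advect or diffuse.

The bound-receptor pools evolve in parallel with the bound-ligand fields of
the transport model; the two ledgers are not mutually conservative (recycled
occupied receptors return without a matching bound-ligand source), so the
simulator logs ``|RP_s - (C_B + C_BU)|`` as a diagnostic rather than forcing
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .params import ParameterSet

__all__ = ["ReceptorState", "receptor_rhs", "initial_receptor_state", "ligand_free_steady_state"]


@dataclass
class ReceptorState:
    """The four receptor pools, each an array over tissue voxels (nmol/L)."""

    F_s: np.ndarray
    F_e: np.ndarray
    RP_s: np.ndarray
    RP_e: np.ndarray

    def pools(self) -> dict[str, np.ndarray]:
        return {"F_s": self.F_s, "F_e": self.F_e, "RP_s": self.RP_s, "RP_e": self.RP_e}

    def total(self) -> np.ndarray:
        return self.F_s + self.F_e + self.RP_s + self.RP_e

    def copy(self) -> "ReceptorState":
        return ReceptorState(
            self.F_s.copy(), self.F_e.copy(), self.RP_s.copy(), self.RP_e.copy()
        )


def initial_receptor_state(
    tumor_cells: np.ndarray, params: ParameterSet
) -> ReceptorState:
    """Initial pools: all receptors free on the surface at the tissue density.

    ``tumor_cells`` is a boolean per-voxel array; tumor voxels start at the
    tumor receptor density, normal voxels at the reduced normal density.
    """
    d = np.where(
        tumor_cells, params.receptor_density_tumor, params.receptor_density_normal
    ).astype(float)
    zeros = np.zeros_like(d)
    return ReceptorState(F_s=d, F_e=zeros.copy(), RP_s=zeros.copy(), RP_e=zeros.copy())


def receptor_rhs(
    state: ReceptorState,
    C_F: np.ndarray,
    C_FU: np.ndarray,
    params: ParameterSet,
    k_rec: float | np.ndarray | None = None,
) -> ReceptorState:
    """Time derivatives of the four receptor pools (per second).

    ``C_F`` / ``C_FU`` are the free labeled / unlabeled ligand fields
    (nmol/L) co-registered with the pools.  ``k_rec`` optionally overrides
    the recycling rate (1/s), e.g. for sweeps; it may be an array
    broadcastable against the pools.
    """
    for name, pool in state.pools().items():
        if np.any(np.asarray(pool) < 0.0):
            raise ValidationError(f"receptor pool {name} has negative entries")
    p = params
    kr = p.k_rec if k_rec is None else k_rec
    ligand = np.asarray(C_F) + np.asarray(C_FU)
    bind = p.k_on * state.F_s * ligand
    dF_s = (
        -bind
        + p.V_r
        + (p.k_syn + p.k_off) * state.RP_s
        - p.k_ec * state.F_s
        + (1.0 - p.f2) * kr * state.F_e
    )
    dF_e = p.k_ec * state.F_s - ((1.0 - p.f2) * kr + p.f2 * p.k_deg) * state.F_e
    dRP_s = bind + (1.0 - p.f1) * kr * state.RP_e - (p.k_off + p.k_int) * state.RP_s
    dRP_e = -((1.0 - p.f1) * kr + p.f1 * p.k_deg) * state.RP_e + p.k_int * state.RP_s
    return ReceptorState(F_s=dF_s, F_e=dF_e, RP_s=dRP_s, RP_e=dRP_e)


def ligand_free_steady_state(params: ParameterSet, k_rec: float | None = None):
    """Ligand-free fixed point of the free pools (per unit F_s).

    With no ligand the occupied pools vanish and the free pools satisfy
    ``F_e* = k_ec F_s* / ((1 - f2) k_rec + f2 k_deg)`` with the synthesis rate
    balancing the degraded flux, ``V_r = k_ec F_s* f2 k_deg / ((1 - f2) k_rec
    + f2 k_deg)``.  Returns ``(F_s*, F_e*)`` for the configured ``V_r``.
    """
    p = params
    kr = p.k_rec if k_rec is None else k_rec
    denom = (1.0 - p.f2) * kr + p.f2 * p.k_deg
    f_s = p.V_r * denom / (p.k_ec * p.f2 * p.k_deg)
    f_e = p.k_ec * f_s / denom
    return f_s, f_e
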