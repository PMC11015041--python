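"""Deterministic verification fixtures: manufactured solutions and 0-D references.

These are correctness oracles, deliberately independent of the production
solvers: the manufactured Darcy case prescribes an analytic pressure field and
the forcing that makes it an exact solution, and the reaction reference
integrates the spatially uniform kinetics with a high-accuracy adaptive
implicit integrator at tight tolerance.  The simulator never imports this
module; tests compare its output against the production code.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .darcy_flow import VoxelMesh
from .params import ParameterSet
from .phantom import Phantom, NORMAL, TUMOR
from .plasma_pk import AdministrationProtocol, plasma_concentration

__all__ = [
    "ManufacturedCase",
    "make_manufactured_darcy",
    "make_reaction_reference",
    "uniform_phantom",
]


def uniform_phantom(half_width: float, spacing: float, tissue: str = "normal") -> Phantom:
    """Single-tissue cube (no embedded tumor); for verification only.

    Skips the tumor-inside-normal structural validation on purpose: uniform
    media are the degenerate cases used by equilibrium and convergence
    checks.
    """
    n = int(round(2.0 * half_width / spacing))
    n += 1 - n % 2
    label = TUMOR if tissue == "tumor" else NORMAL
    labels = np.full((n, n, n), label, dtype=np.int8)
    x0 = -(n // 2) * spacing
    return Phantom(
        labels=labels,
        spacing=(spacing,) * 3,
        origin=(x0,) * 3,
        provenance=f"uniform {tissue} cube, half-width {half_width:g} cm",
    )


@dataclass
class ManufacturedCase:
    """A prescribed pressure field plus the forcing making it exact."""

    phantom: Phantom
    mesh: VoxelMesh
    p_exact: np.ndarray       # Pa, per tissue cell
    forcing: np.ndarray       # 1/s, per tissue cell; pass as extra_source
    description: str


def make_manufactured_darcy(
    params: ParameterSet,
    half_width: float = 0.5,
    spacing: float = 0.05,
    tissue: str = "normal",
    amplitude: float = 500.0,
) -> ManufacturedCase:
    """Smooth manufactured pressure on a uniform cube.

    Prescribes ``p(x, y, z) = amplitude * prod_i cos(pi x_i / (2 W))`` (zero on
    the cube faces, consistent with the outer Dirichlet condition) and
    computes the forcing ``f = -K lap(p) - (phi_B(p) - phi_L(p))`` analytically
    at the voxel centers, so the solver must recover ``p`` up to its
    discretization error.
    """
    phantom = uniform_phantom(half_width, spacing, tissue)
    mesh = VoxelMesh(phantom)
    x = phantom.voxel_centers()
    X, Y, Z = np.meshgrid(*x, indexing="ij")
    # zero of the cosine sits on the true outer faces (half a voxel beyond the
    # outermost centers), matching the Dirichlet plane of the solver
    w_eff = phantom.shape[0] * spacing / 2.0
    w = np.pi / (2.0 * w_eff)
    shape_fn = np.cos(w * X) * np.cos(w * Y) * np.cos(w * Z)
    p_grid = amplitude * shape_fn
    lap = -3.0 * w * w * p_grid

    tf = params.flow(tissue)
    k = tf.K
    a = tf.Lp * tf.S_V * tf.p_equilibrium + tf.lymph_conductance * tf.p_L
    b = tf.Lp * tf.S_V + tf.lymph_conductance

    p_exact = mesh.gather(p_grid)
    forcing = -k * mesh.gather(lap) - (a - b * p_exact)
    return ManufacturedCase(
        phantom=phantom,
        mesh=mesh,
        p_exact=p_exact,
        forcing=forcing,
        description=(
            f"cosine bump, amplitude {amplitude:g} Pa, {tissue} cube "
            f"half-width {half_width:g} cm, spacing {spacing:g} cm"
        ),
    )


def make_reaction_reference(
    params: ParameterSet,
    protocol: AdministrationProtocol,
    t_grid_min: np.ndarray,
    receptor_density: float | None = None,
    k_rec_per_s: float | None = None,
    exchange_diff_per_s: float | None = None,
    exchange_conv_per_s: float = 0.0,
    lymph_per_s: float = 0.0,
    initial: np.ndarray | None = None,
    rtol: float = 1e-11,
    atol: float = 1e-13,
) -> dict[str, np.ndarray]:
    """High-accuracy 0-D trajectories of the coupled kinetics.

    A single well-mixed tissue volume exchanging with plasma: the ten state
    variables are the six ligand species followed by the four receptor pools.
    The right-hand side is written out independently of the production
    stepping code and integrated with LSODA at tight tolerance; the result
    serves as ground truth for the reaction part of the solver.

    ``exchange_diff_per_s`` defaults to the tumor-tissue diffusive exchange
    rate ``P * S/V``; set it (and the convective and lymphatic rates) to zero
    for closed-volume checks.
    """
    p = params
    lam = p.lambda_lu177
    fv = p.FVi / p.FVc
    kr = p.k_rec if k_rec_per_s is None else k_rec_per_s
    dr = p.receptor_density_tumor if receptor_density is None else receptor_density
    s_diff = p.P * p.tumor.S_V if exchange_diff_per_s is None else exchange_diff_per_s
    s_conv = exchange_conv_per_s
    phi_l = lymph_per_s

    def cp(t_s):
        if protocol.amount_total == 0.0:
            return 0.0, 0.0
        h, c = plasma_concentration(protocol, t_s / 60.0)
        return float(h), float(c)

    def rhs(t_s, y):
        CF, CB, CI, CFU, CBU, CIU, Fs, Fe, RPs, RPe = y
        cph, cpc = cp(t_s)
        bind = p.k_on * Fs
        dCF = (
            s_conv * cph + s_diff * (cph - CF) - phi_l * CF
            - lam * CF - bind * CF + p.k_off * CB
        )
        dCB = -lam * CB + bind * CF - (p.k_off + p.k_int) * CB
        dCI = -lam * CI - p.k_rel * CI + fv * p.k_int * CB
        dCFU = (
            s_conv * cpc + s_diff * (cpc - CFU) - phi_l * CFU
            + lam * CF - bind * CFU + p.k_off * CBU
        )
        dCBU = lam * CB + bind * CFU - (p.k_off + p.k_int) * CBU
        dCIU = lam * CI - p.k_rel * CIU + fv * p.k_int * CBU
        L = CF + CFU
        dFs = (
            -p.k_on * Fs * L + p.V_r + (p.k_syn + p.k_off) * RPs
            - p.k_ec * Fs + (1.0 - p.f2) * kr * Fe
        )
        dFe = p.k_ec * Fs - ((1.0 - p.f2) * kr + p.f2 * p.k_deg) * Fe
        dRPs = p.k_on * Fs * L + (1.0 - p.f1) * kr * RPe - (p.k_off + p.k_int) * RPs
        dRPe = -((1.0 - p.f1) * kr + p.f1 * p.k_deg) * RPe + p.k_int * RPs
        return [dCF, dCB, dCI, dCFU, dCBU, dCIU, dFs, dFe, dRPs, dRPe]

    y0 = np.zeros(10)
    y0[6] = dr
    if initial is not None:
        y0 = np.asarray(initial, dtype=float)
    t_s = np.asarray(t_grid_min, dtype=float) * 60.0
    sol = solve_ivp(
        rhs,
        (t_s[0], t_s[-1]),
        y0,
        method="LSODA",
        t_eval=t_s,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"reference integration failed: {sol.message}")
    names = ["C_F", "C_B", "C_I", "C_FU", "C_BU", "C_IU", "F_s", "F_e", "RP_s", "RP_e"]
    out = {name: sol.y[i] for i, name in enumerate(names)}
    out["t_min"] = np.asarray(t_grid_min, dtype=float)
    return out
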