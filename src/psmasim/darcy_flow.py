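"""Steady interstitial fluid flow: Darcy pressure with Starling exchange.

Solves the linear elliptic problem

    -div( K grad p_i ) = phi_B(p_i) - phi_L(p_i)

on the tissue voxels of a phantom, with

    phi_B = Lp (S/V) [ p_B - p_i - sigma_s (pi_B - pi_i) ]   (capillary source)
    phi_L = LpL (S_L/V) [ p_i - p_L ]                        (lymphatic sink,
                                                              normal tissue only)

per-tissue coefficients, pressure and normal-flux continuity at the
tumor/normal interface, and ``p_i = 0`` on the outer boundary of the
normal-tissue box.  Discretization is a cell-centered finite volume scheme on
the voxel grid with harmonic averaging of K at faces, which is conservative
and imposes flux continuity at tissue interfaces by construction.  Because
both Starling terms are linear in ``p_i``, a single symmetric
positive-definite sparse solve suffices.  The interstitial velocity is the
Darcy flux ``v = -K grad p_i`` evaluated on faces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.linalg import cg, spsolve

from .errors import SolverError, ValidationError
from .params import ParameterSet
from .phantom import Phantom, OUTSIDE

__all__ = ["VoxelMesh", "FlowField", "solve_ifp", "starling_fields"]


class VoxelMesh:
    """Face/cell connectivity of the tissue voxels of a phantom.

    Tissue voxels (labels 1 and 2) are flattened into a 1-D index.  Internal
    faces connect pairs of adjacent tissue voxels; boundary faces separate a
    tissue voxel from the outside (array edge or a label-0 voxel) and carry
    the outer Dirichlet condition.
    """

    def __init__(self, phantom: Phantom):
        self.phantom = phantom
        tissue = phantom.tissue_mask
        _, n_comp = ndimage.label(tissue)
        if n_comp != 1:
            raise ValidationError(
                f"tissue region must be connected, found {n_comp} components"
            )
        self.n_cells = int(tissue.sum())
        self.index = np.full(phantom.shape, -1, dtype=np.int64)
        self.index[tissue] = np.arange(self.n_cells)
        self.tumor_cells = phantom.tumor_mask[tissue]   # bool (n_cells,)
        self.cell_volume = phantom.voxel_volume

        sp = phantom.spacing
        self.face_area = tuple(
            float(np.prod([sp[b] for b in range(3) if b != a])) for a in range(3)
        )
        self.face_h = sp

        # internal faces per axis: (left cell, right cell) flat indices
        self.faces = []
        for axis in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(0, -1)
            sl_hi[axis] = slice(1, None)
            both = tissue[tuple(sl_lo)] & tissue[tuple(sl_hi)]
            left = self.index[tuple(sl_lo)][both]
            right = self.index[tuple(sl_hi)][both]
            self.faces.append((left, right))

        # boundary faces: tissue voxel whose neighbor along (axis, sign) is outside
        padded = np.pad(phantom.labels, 1, constant_values=OUTSIDE)
        self.boundary = []
        for axis in range(3):
            for sign in (+1, -1):
                neighbor = np.roll(padded, -sign, axis=axis)[1:-1, 1:-1, 1:-1]
                sel = tissue & (neighbor == OUTSIDE)
                self.boundary.append((axis, sign, self.index[sel]))

    def gather(self, field_3d: np.ndarray) -> np.ndarray:
        """Flatten a full-grid field onto tissue cells."""
        return np.asarray(field_3d)[self.phantom.tissue_mask]

    def scatter(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Expand a per-cell array onto the full grid (``fill`` outside)."""
        out = np.full(self.phantom.shape, fill, dtype=float)
        out[self.phantom.tissue_mask] = values
        return out

    def per_tissue(self, tumor_value: float, normal_value: float) -> np.ndarray:
        """Per-cell array taking one value in tumor and another in normal tissue."""
        return np.where(self.tumor_cells, tumor_value, normal_value)


@dataclass
class FlowField:
    """Interstitial pressure, face velocities, and Starling source/sink fields."""

    mesh: VoxelMesh
    p: np.ndarray                 # Pa, per tissue cell
    phi_B: np.ndarray             # capillary fluid source, 1/s
    phi_L: np.ndarray             # lymphatic fluid sink, 1/s
    face_velocity: list           # per axis: cm/s on internal faces (left->right positive)
    boundary_velocity: list       # per boundary group: outward cm/s
    residual_norm: float

    def cell_velocity(self) -> np.ndarray:
        """Cell-centered velocity vectors (n_cells, 3), cm/s, by face averaging."""
        mesh = self.mesh
        v = np.zeros((mesh.n_cells, 3))
        count = np.zeros((mesh.n_cells, 3))
        for axis, (left, right) in enumerate(mesh.faces):
            vf = self.face_velocity[axis]
            np.add.at(v[:, axis], left, vf)
            np.add.at(v[:, axis], right, vf)
            np.add.at(count[:, axis], left, 1.0)
            np.add.at(count[:, axis], right, 1.0)
        for (axis, sign, cells), vb in zip(mesh.boundary, self.boundary_velocity):
            np.add.at(v[:, axis], cells, sign * vb)
            np.add.at(count[:, axis], cells, 1.0)
        with np.errstate(invalid="ignore"):
            v = np.where(count > 0, v / np.maximum(count, 1.0), 0.0)
        return v

    def speed(self) -> np.ndarray:
        """Cell-centered velocity magnitude, cm/s."""
        return np.linalg.norm(self.cell_velocity(), axis=1)

    def boundary_outflow(self) -> float:
        """Net volumetric outflow through the outer boundary, cm^3/s."""
        total = 0.0
        for (axis, _sign, _cells), vb in zip(self.mesh.boundary, self.boundary_velocity):
            total += float(vb.sum()) * self.mesh.face_area[axis]
        return total

    def net_source(self) -> float:
        """Net Starling fluid production, sum (phi_B - phi_L) * V, cm^3/s."""
        return float((self.phi_B - self.phi_L).sum()) * self.mesh.cell_volume

    def divergence(self) -> np.ndarray:
        """Discrete div(v) per cell, 1/s (should equal phi_B - phi_L)."""
        mesh = self.mesh
        div = np.zeros(mesh.n_cells)
        for axis, (left, right) in enumerate(mesh.faces):
            flux = self.face_velocity[axis] * mesh.face_area[axis]
            np.add.at(div, left, flux)      # leaves left cell
            np.add.at(div, right, -flux)    # enters right cell
        for (axis, _sign, cells), vb in zip(mesh.boundary, self.boundary_velocity):
            np.add.at(div, cells, vb * mesh.face_area[axis])
        return div / mesh.cell_volume


def _starling_coefficients(mesh: VoxelMesh, params: ParameterSet):
    """Per-cell linearization phi_B - phi_L = a - b * p  (a in 1/s, b in 1/(Pa s))."""
    tf, nf = params.tumor, params.normal
    lp_sv = mesh.per_tissue(tf.Lp * tf.S_V, nf.Lp * nf.S_V)
    p_e = mesh.per_tissue(tf.p_equilibrium, nf.p_equilibrium)
    lymph = mesh.per_tissue(tf.lymph_conductance, nf.lymph_conductance)
    p_l = mesh.per_tissue(tf.p_L, nf.p_L)
    a = lp_sv * p_e + lymph * p_l
    b = lp_sv + lymph
    return a, b, lp_sv, p_e, lymph, p_l


def starling_fields(
    p: np.ndarray, params: ParameterSet, phantom_or_mesh
) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise Starling fluid source/sink for a given pressure field.

    ``phi_L`` is structurally zero at tumor cells (no functional lymphatics).
    Returns per-cell arrays in 1/s.
    """
    mesh = (
        phantom_or_mesh
        if isinstance(phantom_or_mesh, VoxelMesh)
        else VoxelMesh(phantom_or_mesh)
    )
    _a, _b, lp_sv, p_e, lymph, p_l = _starling_coefficients(mesh, params)
    phi_B = lp_sv * (p_e - p)
    phi_L = lymph * (p - p_l)
    return phi_B, phi_L


def solve_ifp(
    phantom: Phantom,
    params: ParameterSet,
    extra_source: np.ndarray | None = None,
    rtol: float = 1e-10,
    maxiter: int = 20000,
    mesh: VoxelMesh | None = None,
) -> FlowField:
    """Solve the steady Darcy--Starling pressure problem on a phantom.

    ``extra_source`` is an optional per-cell volumetric source (1/s) added to
    the right-hand side; it is used by manufactured-solution verification
    cases and is zero in physiological runs.
    """
    mesh = mesh or VoxelMesh(phantom)
    K = mesh.per_tissue(params.tumor.K, params.normal.K)
    a, b, *_ = _starling_coefficients(mesh, params)

    rows, cols, vals = [], [], []
    diag = b * mesh.cell_volume
    for axis, (left, right) in enumerate(mesh.faces):
        k_face = 2.0 * K[left] * K[right] / (K[left] + K[right])
        t = k_face * mesh.face_area[axis] / mesh.face_h[axis]
        rows += [left, right, left, right]
        cols += [left, right, right, left]
        vals += [t, t, -t, -t]
    for axis, _sign, cells in mesh.boundary:
        t_b = K[cells] * mesh.face_area[axis] / (0.5 * mesh.face_h[axis])
        rows.append(cells)
        cols.append(cells)
        vals.append(t_b)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    A = coo_matrix((vals, (rows, cols)), shape=(mesh.n_cells,) * 2).tocsr()
    A = A + csr_matrix(
        (diag, (np.arange(mesh.n_cells), np.arange(mesh.n_cells))),
        shape=A.shape,
    )
    rhs = a * mesh.cell_volume
    if extra_source is not None:
        rhs = rhs + np.asarray(extra_source) * mesh.cell_volume

    if mesh.n_cells <= 20000:
        p = spsolve(A.tocsc(), rhs)
        info = 0
    else:
        M = 1.0 / A.diagonal()
        p, info = cg(
            A,
            rhs,
            rtol=rtol,
            atol=0.0,
            maxiter=maxiter,
            M=_diag_operator(M),
        )
    if info != 0:
        raise SolverError(f"pressure solve did not converge (info={info})")
    res = float(np.linalg.norm(A @ p - rhs) / max(np.linalg.norm(rhs), 1e-300))

    phi_B, phi_L = starling_fields(p, params, mesh)
    face_velocity = []
    for axis, (left, right) in enumerate(mesh.faces):
        k_face = 2.0 * K[left] * K[right] / (K[left] + K[right])
        face_velocity.append(-k_face * (p[right] - p[left]) / mesh.face_h[axis])
    boundary_velocity = []
    for axis, _sign, cells in mesh.boundary:
        # outward-positive Darcy flux toward the p = 0 boundary face
        boundary_velocity.append(K[cells] * p[cells] / (0.5 * mesh.face_h[axis]))

    return FlowField(
        mesh=mesh,
        p=p,
        phi_B=phi_B,
        phi_L=phi_L,
        face_velocity=face_velocity,
        boundary_velocity=boundary_velocity,
        residual_norm=res,
    )


def _diag_operator(diag_inv: np.ndarray):
    from scipy.sparse.linalg import LinearOperator

    n = diag_inv.size
    return LinearOperator((n, n), matvec=lambda x: diag_inv * x)
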