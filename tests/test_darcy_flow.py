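import math

import numpy as np
import pytest

from psmasim.darcy_flow import solve_ifp, starling_fields
from psmasim.errors import ValidationError
from psmasim.fixtures import make_manufactured_darcy, uniform_phantom
from psmasim.params import MMHG_TO_PA
from psmasim.phantom import Phantom, make_spherical_phantom

from oracles import radial_two_region_pressure


@pytest.fixture(scope="module")
def sphere_flow(params):
    """Darcy solve on the standard 0.5 cm sphere surrogate (0.05 cm grid)."""
    phantom = make_spherical_phantom(0.5, 1.0, 0.05)
    return phantom, solve_ifp(phantom, params)


class TestEquilibriumLimit:
    def test_uniform_tumor_interior_reaches_starling_plateau(self, params):
        # deep inside a uniform tumor block the pressure equilibrates at
        # p_e = p_B - sigma_s (pi_B - pi_i); the Dirichlet rim only perturbs a
        # thin boundary layer (~0.03 cm here)
        phantom = uniform_phantom(0.5, 0.05, tissue="tumor")
        flow = solve_ifp(phantom, params)
        center = flow.mesh.index[tuple(s // 2 for s in phantom.shape)]
        p_e = params.tumor.p_equilibrium
        assert flow.p[center] == pytest.approx(p_e, rel=1e-6)
        assert p_e == pytest.approx((15.6 - 0.82 * 5.0) * MMHG_TO_PA, rel=1e-12)
        # zero-flow equilibrium: interior velocity vanishes
        speed = flow.speed()
        interior = np.abs(flow.p - p_e) / p_e < 1e-6
        assert np.abs(speed[interior]).max() < 1e-9  # vs ~1e-6 cm/s at the rim

    def test_starling_fields_zero_at_equilibrium(self, params, micro_phantom):
        from psmasim.darcy_flow import VoxelMesh

        mesh = VoxelMesh(micro_phantom)
        p_e = np.where(
            mesh.tumor_cells,
            params.tumor.p_equilibrium,
            params.normal.p_equilibrium,
        )
        phi_B, phi_L = starling_fields(p_e, params, mesh)
        assert np.abs(phi_B).max() < 1e-18
        # lymphatic sink vanishes when p_i = p_L
        p_l = np.where(mesh.tumor_cells, params.tumor.p_L, params.normal.p_L)
        phi_B2, phi_L2 = starling_fields(p_l, params, mesh)
        assert np.abs(phi_L2).max() < 1e-25

    def test_lymphatic_sink_clamped_to_normal_tissue(self, sphere_flow):
        phantom, flow = sphere_flow
        assert np.all(flow.phi_L[flow.mesh.tumor_cells] == 0.0)
        assert np.any(flow.phi_L[~flow.mesh.tumor_cells] > 0.0)

    def test_tumor_voxel_source_arithmetic(self, params, sphere_flow):
        # phi_B at p_i = 1490.8 Pa equals Lp * S/V * (p_e - p_i) evaluated
        # directly in canonical units
        tf = params.tumor
        expected = tf.Lp * tf.S_V * (tf.p_equilibrium - 1490.8)
        manual = (2.8e-7 / MMHG_TO_PA) * 200.0 * ((15.6 - 0.82 * 5.0) * MMHG_TO_PA - 1490.8)
        assert expected == pytest.approx(manual, rel=1e-12)


class TestSphereSolution:
    def test_center_pressure_matches_radial_oracle(self, params, sphere_flow):
        phantom, flow = sphere_flow
        center = flow.mesh.index[tuple(s // 2 for s in phantom.shape)]
        r, p_ref = radial_two_region_pressure(params, 0.5, 1.0)
        assert flow.p[center] == pytest.approx(p_ref[0], rel=0.02)

    def test_center_pressure_near_published_tumor_ifp(self, params, sphere_flow):
        phantom, flow = sphere_flow
        center = flow.mesh.index[tuple(s // 2 for s in phantom.shape)]
        assert flow.p[center] == pytest.approx(1490.8, rel=0.05)

    def test_maximum_principle(self, params, sphere_flow):
        _, flow = sphere_flow
        upper = max(params.tumor.p_equilibrium, params.normal.p_equilibrium)
        assert flow.p.min() >= -1e-9
        assert flow.p.max() <= upper * (1 + 1e-9)

    def test_pressure_peaks_in_core_velocity_at_interface(self, sphere_flow):
        phantom, flow = sphere_flow
        mesh = flow.mesh
        x = phantom.voxel_centers()
        X, Y, Z = np.meshgrid(*x, indexing="ij")
        r = mesh.gather(np.sqrt(X**2 + Y**2 + Z**2))
        speed = flow.speed()
        # IFP highest in the core, dropping across the rim
        assert flow.p[r < 0.2].mean() > 5.0 * flow.p[(r > 0.45) & (r < 0.55)].mean() / 4.0
        assert flow.p[r < 0.2].mean() > flow.p[r > 0.7].mean()
        # velocity magnitude peaks at the tumor-normal interface
        rim = (r > 0.4) & (r < 0.6)
        assert speed[rim].mean() > 10.0 * speed[r < 0.2].mean()
        assert speed[rim].max() == pytest.approx(speed.max())

    def test_global_fluid_balance(self, sphere_flow):
        _, flow = sphere_flow
        net = flow.net_source()
        out = flow.boundary_outflow()
        assert abs(net - out) / abs(out) < 0.005

    def test_discrete_divergence_identity(self, sphere_flow):
        _, flow = sphere_flow
        div = flow.divergence()
        rhs = flow.phi_B - flow.phi_L
        scale = np.abs(rhs).max()
        assert np.abs(div - rhs).max() < 1e-8 * scale

    def test_grid_refinement_changes_center_ifp_by_under_3_percent(self, params):
        vals = []
        for h in (0.1, 0.05):
            phantom = make_spherical_phantom(0.5, 1.0, h)
            flow = solve_ifp(phantom, params)
            center = flow.mesh.index[tuple(s // 2 for s in phantom.shape)]
            vals.append(flow.p[center])
        assert abs(vals[1] - vals[0]) / vals[1] < 0.03


class TestManufacturedSolution:
    def test_constant_equilibrium_forcing_free(self, params):
        case = make_manufactured_darcy(params, amplitude=0.0, spacing=0.1)
        assert np.abs(case.forcing - case.forcing[0]).max() < 1e-18
        flow = solve_ifp(case.phantom, params, extra_source=case.forcing, mesh=case.mesh)
        assert np.abs(flow.p).max() < 1e-9

    def test_second_order_convergence(self, params):
        errs = []
        for h in (0.1, 0.05, 0.025):
            case = make_manufactured_darcy(params, half_width=0.5, spacing=h)
            flow = solve_ifp(
                case.phantom, params, extra_source=case.forcing, mesh=case.mesh
            )
            errs.append(
                np.sqrt(np.mean((flow.p - case.p_exact) ** 2))
                / np.sqrt(np.mean(case.p_exact**2))
            )
        orders = [math.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) > 1.5
        assert orders[-1] > 1.7


class TestErrors:
    def test_disconnected_tissue_rejected(self, params):
        labels = np.zeros((7, 7, 7), dtype=np.int8)
        labels[1:3, 1:3, 1:3] = 1
        labels[4:6, 4:6, 4:6] = 1
        labels[1, 1, 1] = 2
        with pytest.raises(ValidationError, match="connected"):
            solve_ifp(Phantom(labels, (0.1,) * 3), params)
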