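import numpy as np
import pytest

from psmasim.darcy_flow import VoxelMesh, solve_ifp
from psmasim.fixtures import make_reaction_reference, uniform_phantom
from psmasim.plasma_pk import AdministrationProtocol
from psmasim.receptor_traffic import ReceptorState, initial_receptor_state
from psmasim.transport import (
    BatchMember,
    SpeciesState,
    _peclet_factor,
    build_transport_operator,
    run_batch,
    run_simulation,
    solute_exchange,
    transport_rhs,
)


def protocol(params, **kw):
    kw.setdefault("amount_total", 100.0)
    kw.setdefault("plasma_volume", params.plasma_volume)
    kw.setdefault("alpha", params.alpha * 3600.0)
    return AdministrationProtocol(**kw)


def random_state(rng, n):
    return SpeciesState(*(rng.uniform(0.0, 10.0, size=n) for _ in range(6)))


def random_receptors(rng, n):
    return ReceptorState(*(rng.uniform(0.0, 50.0, size=n) for _ in range(4)))


class TestSoluteExchange:
    def test_peclet_factor_limit_and_continuity(self):
        pe = np.array([0.0, 1e-12, 1e-9, 1e-6, 1e-3, 1.0, -1e-3])
        f = _peclet_factor(pe)
        assert f[0] == 1.0
        assert np.allclose(f[:4], 1.0, atol=1e-6)
        assert f[4] == pytest.approx(1e-3 / np.expm1(1e-3), rel=1e-12)
        assert f[6] > 1.0  # negative Pe boosts uptake

    def test_zero_filtration_reduces_to_pure_diffusion(self, params, micro_flow):
        mesh = micro_flow.mesh
        flow = micro_flow
        # force phi_B = 0: exchange must reduce to (P S/V)(C_p - C_F)
        flow_zero = type(flow)(
            mesh=mesh,
            p=flow.p,
            phi_B=np.zeros(mesh.n_cells),
            phi_L=flow.phi_L,
            face_velocity=flow.face_velocity,
            boundary_velocity=flow.boundary_velocity,
            residual_norm=0.0,
        )
        c_f = np.full(mesh.n_cells, 2.0)
        ex = solute_exchange(c_f, c_f, 5.0, 5.0, flow_zero, params)
        ps_v = params.P * mesh.per_tissue(params.tumor.S_V, params.normal.S_V)
        assert np.allclose(ex.phi_B_solute, ps_v * (5.0 - 2.0), rtol=1e-12)
        assert np.all(ex.Pe_transcap == 0.0)
        # and vanishes when plasma equals tissue concentration
        ex2 = solute_exchange(c_f, c_f, 2.0, 2.0, flow_zero, params)
        assert np.abs(ex2.phi_B_solute).max() == 0.0

    def test_lymphatic_solute_sink_zero_in_tumor(self, params, micro_flow):
        mesh = micro_flow.mesh
        c = np.ones(mesh.n_cells)
        ex = solute_exchange(c, c, 1.0, 9.0, micro_flow, params)
        assert np.all(ex.phi_L_solute[mesh.tumor_cells] == 0.0)
        assert np.all(ex.phi_LU_solute[mesh.tumor_cells] == 0.0)

    def test_transcapillary_peclet_is_small(self, params, micro_flow):
        # exchange is diffusion-dominated: |Pe| well below 1 everywhere
        c = np.zeros(micro_flow.mesh.n_cells)
        ex = solute_exchange(c, c, 1.0, 9.0, micro_flow, params)
        assert np.abs(ex.Pe_transcap).max() < 1e-3
        # sign follows the fluid filtration flux
        assert np.all(np.sign(ex.Pe_transcap) == np.sign(micro_flow.phi_B))


class TestRhsIdentities:
    def test_hot_cold_sums_are_decay_free(self, params, micro_flow):
        # the lambda terms cancel pairwise: the summed hot+cold derivatives
        # are identical for different decay constants
        rng = np.random.default_rng(7)
        n = micro_flow.mesh.n_cells
        state = random_state(rng, n)
        rec = random_receptors(rng, n)
        op = build_transport_operator(micro_flow.mesh, params, micro_flow)
        ex = solute_exchange(state.C_F, state.C_FU, 1.0, 9.0, micro_flow, params)
        params2 = params.replace(lambda_lu177=params.lambda_lu177 * 0.9)
        d1 = transport_rhs(state, rec, ex, micro_flow, params, op)
        d2 = transport_rhs(state, rec, ex, micro_flow, params2, op)
        for hot, cold in (("C_F", "C_FU"), ("C_B", "C_BU"), ("C_I", "C_IU")):
            s1 = getattr(d1, hot) + getattr(d1, cold)
            s2 = getattr(d2, hot) + getattr(d2, cold)
            assert np.allclose(s1, s2, rtol=0.0, atol=1e-14)

    def test_internalization_conserves_amounts(self, params, micro_flow):
        # FVi * dC_B + FVc * dC_I carries no k_int contribution: the
        # FVi/FVc factor makes internalized *amounts* conservative
        rng = np.random.default_rng(11)
        n = micro_flow.mesh.n_cells
        state = random_state(rng, n)
        rec = random_receptors(rng, n)
        ex = solute_exchange(
            np.zeros(n), np.zeros(n), 0.0, 0.0, micro_flow, params
        )
        d1 = transport_rhs(state, rec, ex, micro_flow, params, None)
        d2 = transport_rhs(
            state, rec, ex, micro_flow, params.replace(k_int=2.0 * params.k_int), None
        )
        for b_field, i_field in (("C_B", "C_I"), ("C_BU", "C_IU")):
            amt1 = params.FVi * getattr(d1, b_field) + params.FVc * getattr(d1, i_field)
            amt2 = params.FVi * getattr(d2, b_field) + params.FVc * getattr(d2, i_field)
            assert np.allclose(amt1, amt2, rtol=0.0, atol=1e-13)

    def test_binding_exchange_terms_as_written(self, params, micro_flow):
        n = micro_flow.mesh.n_cells
        state = SpeciesState.zeros(n)
        state.C_F[:] = 4.0
        rec = initial_receptor_state(micro_flow.mesh.tumor_cells, params)
        ex = solute_exchange(state.C_F, state.C_FU, 0.0, 0.0, micro_flow, params)
        d = transport_rhs(state, rec, ex, micro_flow, params, None)
        bind = params.k_on * rec.F_s * 4.0
        assert np.allclose(d.C_B, -params.lambda_lu177 * 0.0 + bind, rtol=1e-12)


class TestPureDiffusion:
    def test_gaussian_blob_matches_heat_kernel_with_decay(self, params):
        # zero receptors, zero plasma, v = 0: a Gaussian spreads analytically
        # (sigma^2 grows by 2Dt) and decays by exp(-lambda t)
        h = 0.01
        phantom = uniform_phantom(0.155, h, tissue="normal")
        mesh = VoxelMesh(phantom)
        op = build_transport_operator(mesh, params, flow=None)
        x = phantom.voxel_centers()
        X, Y, Z = np.meshgrid(*x, indexing="ij")
        r2 = mesh.gather(X**2 + Y**2 + Z**2)
        sig0 = 0.03
        c = np.exp(-r2 / (2 * sig0**2))
        lam = params.lambda_lu177
        t_end, dt = 600.0, 4.0
        for _ in range(int(t_end / dt)):
            c = c + dt * (op @ c - lam * c)
        sig_t2 = sig0**2 + 2 * params.D_eff * t_end
        exact = (
            (sig0**2 / sig_t2) ** 1.5
            * np.exp(-r2 / (2 * sig_t2))
            * np.exp(-lam * t_end)
        )
        err = np.abs(c - exact).max() / exact.max()
        assert err < 0.01

    def test_operator_conserves_mass_without_flow(self, params, micro_phantom):
        mesh = VoxelMesh(micro_phantom)
        op = build_transport_operator(mesh, params, flow=None)
        # zero-flux boundaries: column sums vanish (total amount conserved)
        colsum = np.asarray(op.sum(axis=0)).ravel()
        assert np.abs(colsum).max() < 1e-16


class TestRunSimulation:
    def test_zero_amount_stays_identically_zero(self, params, micro_phantom, micro_flow):
        proto = AdministrationProtocol(
            amount_total=0.0, plasma_volume=params.plasma_volume,
            alpha=params.alpha * 3600.0,
        )
        res = run_simulation(
            micro_phantom, params, proto, t_end_h=1.0, dt_min=0.5, flow=micro_flow
        )
        for arr in res.tumor_mean.values():
            assert np.all(arr == 0.0)
        assert res.tia("tumor")[0] == 0.0

    def test_deterministic(self, params, micro_phantom, micro_flow):
        kw = dict(t_end_h=1.0, dt_min=0.5, flow=micro_flow)
        r1 = run_simulation(micro_phantom, params, protocol(params), **kw)
        r2 = run_simulation(micro_phantom, params, protocol(params), **kw)
        for k in r1.tumor_mean:
            assert np.array_equal(r1.tumor_mean[k], r2.tumor_mean[k])

    def test_tumor_means_track_zero_dimensional_reference(
        self, params, micro_phantom, micro_flow
    ):
        # spatial coupling is weak at these parameters: the tumor-averaged
        # engine output must agree closely with the independent high-accuracy
        # 0-D integration of the same kinetics
        proto = protocol(params)
        res = run_simulation(
            micro_phantom, params, proto, t_end_h=6.0, dt_min=0.1,
            output_every_min=30.0, flow=micro_flow,
        )
        ref = make_reaction_reference(params, proto, res.times_min)
        for k in ("C_F", "C_B", "C_I", "C_FU", "C_BU", "C_IU"):
            sim = res.tumor_mean[k][0, -1]
            exact = ref[k][-1]
            assert sim == pytest.approx(exact, rel=0.02, abs=1e-10)

    def test_peak_ordering_free_then_bound_then_internalized(self, reference_run):
        peaks = reference_run.peak_times("tumor")
        assert peaks["C_F"][0] < peaks["C_B"][0] < peaks["C_I"][0]
        assert peaks["C_FU"][0] < peaks["C_BU"][0] < peaks["C_IU"][0]

    def test_tumor_exceeds_normal_after_transient(self, reference_run):
        t = reference_run.times_min
        tumor = reference_run.total_mean("tumor")[0]
        normal = reference_run.total_mean("normal")[0]
        late = t > 60.0
        assert np.all(tumor[late] > normal[late])

    def test_unlabeled_to_labeled_auc_ratio_near_dose_ratio(self, reference_run):
        t = reference_run.times_min
        hot = np.trapezoid(reference_run.total_mean("tumor", labeled=True)[0], t)
        cold = np.trapezoid(reference_run.total_mean("tumor", labeled=False)[0], t)
        assert 7.0 <= cold / hot <= 12.0

    def test_batch_matches_individual_runs(self, params, micro_phantom, micro_flow):
        protos = [protocol(params), protocol(params, amount_total=300.0)]
        batch = run_batch(
            micro_phantom, params, [BatchMember(p) for p in protos],
            t_end_h=0.5, dt_min=0.5, flow=micro_flow,
        )
        single = run_simulation(
            micro_phantom, params, protos[1], t_end_h=0.5, dt_min=0.5, flow=micro_flow
        )
        assert np.allclose(
            batch.tumor_mean["C_F"][1], single.tumor_mean["C_F"][0], rtol=1e-13
        )
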