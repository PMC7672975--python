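import numpy as np
import pytest

import capsim as cs
from capsim.exceptions import ConfigurationError, NumericalInstabilityError
from capsim.fixtures import make_fiber_scenario

from conftest import radial_reference


class TestStableTimestep:
    def test_formula_values(self, small_domain):
        # dx=5, D_max=0.15: dx^2/(4 D_max) = 41.667 s
        assert cs.stable_timestep(small_domain, 1.0) == pytest.approx(
            41.6667, rel=1e-4)
        assert cs.stable_timestep(small_domain, 0.5) == pytest.approx(
            20.8333, rel=1e-4)

    def test_scaling_with_diffusivity(self, small_domain):
        doubled = small_domain.copy()
        doubled.diffusivity = small_domain.diffusivity * 2
        assert cs.stable_timestep(doubled, 1.0) == pytest.approx(
            cs.stable_timestep(small_domain, 1.0) / 2)

    def test_degenerate_domain_rejected(self, small_grid):
        dom = cs.build_domain(small_grid)
        dom.diffusivity = np.zeros(dom.labels.shape)
        with pytest.raises(ConfigurationError):
            cs.stable_timestep(dom)


class TestDiffuseStep:
    def test_uniform_field_unchanged(self, small_domain, transport):
        C = np.full(small_domain.labels.shape, transport.C_inj)
        out = cs.diffuse_step(C, small_domain, 10.0, transport)
        np.testing.assert_allclose(out, C, atol=1e-12)

    def test_matches_bruteforce_stencil(self, small_grid, transport):
        """Vectorized update equals a per-node loop with interface means."""
        dom = cs.init_diffusivity(cs.build_domain(small_grid), transport)
        rng = np.random.default_rng(0)
        C = rng.uniform(0, 13, size=dom.labels.shape)
        C[dom.exterior_mask] = transport.C_inj
        dt, dx = 5.0, small_grid.dx
        out = cs.diffuse_step(C, dom, dt, transport)
        D = dom.diffusivity
        n = small_grid.nodes_per_side

        def harm(a, b):
            return 0.0 if a + b == 0 else 2 * a * b / (a + b)

        interior = ~dom.exterior_mask
        for i, j in zip(*np.nonzero(interior)):
            acc = 0.0
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < n and 0 <= nj < n:
                    acc += harm(D[i, j], D[ni, nj]) * (C[ni, nj] - C[i, j])
            expected = C[i, j] + dt / dx**2 * acc
            assert out[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_diffusivity_face_blocks_flux(self, small_grid, transport):
        dom = cs.build_domain(small_grid)
        dom.labels[30, 30] = cs.Label.FIBER
        dom = cs.init_diffusivity(dom, transport)
        C = np.zeros(dom.labels.shape)
        C[dom.exterior_mask] = transport.C_inj
        C[30, 31] = 5.0  # hot neighbor of the fiber node
        out = cs.diffuse_step(C, dom, 10.0, transport)
        assert out[30, 30] == 0.0  # fiber node receives nothing

    def test_flux_balance_to_machine_precision(self, small_domain, transport):
        """Interior mass change equals the net flux across the
        interior/exterior interface (conservative stencil)."""
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 13, size=small_domain.labels.shape)
        ext = small_domain.exterior_mask
        C[ext] = transport.C_inj
        dt, dx = 10.0, small_domain.grid.dx
        out = cs.diffuse_step(C, small_domain, dt, transport)
        dm = (out[~ext] - C[~ext]).sum() * dx**2

        D = small_domain.diffusivity
        from capsim.engine import _interface_diffusivities
        f0, f1 = _interface_diffusivities(D, "harmonic")
        boundary_flux = 0.0
        n = small_domain.grid.nodes_per_side
        for i, j in zip(*np.nonzero(~ext)):
            for (di, dj) in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = i + di, j + dj
                if 0 <= ni < n and 0 <= nj < n and ext[ni, nj]:
                    f = f0[min(i, ni), j] if di else f1[i, min(j, nj)]
                    boundary_flux += f * (C[ni, nj] - C[i, j])
        assert dm == pytest.approx(dt * boundary_flux, rel=1e-10, abs=1e-10)

    def test_instability_flagged(self, small_domain, transport):
        C = np.zeros(small_domain.labels.shape)
        C[small_domain.exterior_mask] = transport.C_inj
        huge_dt = 100 * cs.stable_timestep(small_domain, 1.0)
        with pytest.raises(NumericalInstabilityError):
            for _ in range(50):
                C = cs.diffuse_step(C, small_domain, huge_dt, transport)


class TestSaturationStep:
    def test_zero_concentration_leaves_D_unchanged(self, small_domain):
        C = np.zeros(small_domain.labels.shape)
        D = small_domain.diffusivity
        out = cs.saturation_step(C, D, small_domain,
                                 cs.SaturationParams(1, 1, 1), 120.0)
        np.testing.assert_array_equal(out, D)

    def test_reference_multiplier(self, small_grid, transport):
        """a=n=p=1, C_norm=0.5, dt=dt_ref: multiplier is exp(-1)."""
        dom = cs.build_domain(small_grid)
        dom.labels[30, 30] = cs.Label.FIBROBLAST
        dom = cs.init_diffusivity(dom, transport)
        C = np.zeros(dom.labels.shape)
        C[30, 30] = 0.5 * transport.C_inj * 0.01
        out = cs.saturation_step(C, dom.diffusivity, dom,
                                 cs.SaturationParams(1, 1, 1), 120.0,
                                 transport)
        assert out[30, 30] == pytest.approx(0.0015 * np.exp(-1.0))

    def test_saturating_concentration_kills_diffusivity(self, small_grid,
                                                        transport):
        dom = cs.build_domain(small_grid)
        dom.labels[30, 30] = cs.Label.CANCER
        dom = cs.init_diffusivity(dom, transport)
        C = np.full(dom.labels.shape, transport.C_inj * 0.01)
        out = cs.saturation_step(C, dom.diffusivity, dom,
                                 cs.SaturationParams(1, 1, 1), 120.0,
                                 transport)
        assert out[30, 30] < 1e-9 * 0.0015

    def test_only_cell_nodes_touched(self, small_domain, transport):
        C = np.full(small_domain.labels.shape, transport.C_inj * 0.005)
        D = small_domain.diffusivity
        out = cs.saturation_step(C, D, small_domain,
                                 cs.SaturationParams(2, 1, 1), 120.0,
                                 transport)
        untouched = ~small_domain.cell_mask
        np.testing.assert_array_equal(out[untouched], D[untouched])
        assert np.all(out[small_domain.cell_mask]
                      < D[small_domain.cell_mask])

    def test_never_increases(self, small_domain, transport):
        rng = np.random.default_rng(3)
        C = rng.uniform(0, 13, size=small_domain.labels.shape)
        D = small_domain.diffusivity
        out = cs.saturation_step(C, D, small_domain,
                                 cs.SaturationParams(0.5, 2.0, 0.3), 60.0,
                                 transport)
        assert np.all(out <= D + 1e-15)


class TestRunSimulation:
    def test_initial_and_boundary_conditions(self, small_run, small_domain,
                                             transport):
        first = small_run.concentration[0]
        ext = small_domain.exterior_mask
        assert np.all(first[~ext] == 0.0)
        # exterior reads exactly 13 ug/mL at every frame
        assert np.all(small_run.concentration[:, ext] == transport.C_inj)

    def test_maximum_principle(self, small_run, transport):
        assert small_run.concentration.min() >= 0.0
        assert small_run.concentration.max() <= transport.C_inj

    def test_temporal_monotonicity(self, small_domain, transport):
        """With zero initial condition, a fixed exterior source and
        time-constant diffusivity, concentration is non-decreasing at every
        node (discrete comparison principle).  Only holds as a theorem for
        constant coefficients: saturation collapses cellular diffusivity over
        time and can reroute flux, producing genuine small local decreases."""
        sim = cs.SimulationConfig(total_time_min=60,
                                  saturation_enabled=False,
                                  store_diffusivity=False)
        res = cs.run_simulation(small_domain, sim, transport=transport)
        assert np.diff(res.concentration, axis=0).min() >= -1e-12

    def test_diffusivity_monotone_at_cells_constant_at_medium(
            self, small_run, small_domain):
        frames = small_run.diffusivity_frames
        assert frames is None  # short_sim does not store D; rerun storing it
        sim = cs.SimulationConfig(total_time_min=20, store_diffusivity=True)
        res = cs.run_simulation(small_domain, sim,
                                cs.SaturationParams(1, 1, 1))
        D = res.diffusivity_frames
        cells = small_domain.cell_mask
        assert np.all(np.diff(D[:, cells], axis=0) <= 1e-18)
        medium = small_domain.labels == cs.Label.MEDIUM
        assert np.all(D[:, medium] == D[0, medium])

    def test_four_fold_symmetry(self, small_grid, transport):
        dom = cs.init_diffusivity(cs.build_domain(small_grid), transport)
        sim = cs.SimulationConfig(total_time_min=20,
                                  saturation_enabled=False,
                                  store_diffusivity=False)
        res = cs.run_simulation(dom, sim)
        for frame in res.concentration:
            np.testing.assert_allclose(frame, np.rot90(frame), atol=1e-12)

    def test_fiber_loop_isolation_is_exact(self, transport):
        grid = cs.GridSpec(nodes_per_side=100, side_length=500,
                           capsule_radius=175)
        dom = cs.build_domain(grid)
        dom.labels[40:61, 40] = cs.Label.FIBER
        dom.labels[40:61, 60] = cs.Label.FIBER
        dom.labels[40, 40:61] = cs.Label.FIBER
        dom.labels[60, 40:61] = cs.Label.FIBER
        dom = cs.init_diffusivity(dom, transport)
        sim = cs.SimulationConfig(total_time_min=60,
                                  saturation_enabled=False,
                                  store_diffusivity=False)
        res = cs.run_simulation(dom, sim)
        assert np.all(res.concentration[:, 41:60, 41:60] == 0.0)

    def test_matches_radial_reference(self, transport):
        """Empty capsule vs an independent fine 1-D radial solution.

        The 2-D scheme pins the bath at exterior node centers, so its
        effective Dirichlet boundary sits at R + dx/2.
        """
        grid = cs.GridSpec(nodes_per_side=100, side_length=500,
                           capsule_radius=175)
        dom = cs.init_diffusivity(cs.build_domain(grid), transport)
        sim = cs.SimulationConfig(total_time_min=180,
                                  saturation_enabled=False,
                                  store_diffusivity=False)
        res = cs.run_simulation(dom, sim)
        r_ref, c_ref = radial_reference(175 + grid.dx / 2, 0.15, 13.0,
                                        180 * 60, dr=grid.dx / 4)
        rmap = grid.radius_map()
        inside = rmap <= 175
        ref_at = np.interp(rmap[inside], r_ref, c_ref)
        rel = np.linalg.norm(res.final_frame()[inside] - ref_at) \
            / np.linalg.norm(ref_at)
        assert rel < 0.02

    def test_dt_refinement_converges(self, small_domain, transport):
        """Halving dt changes the final frame by < 0.1% relative L2
        (saturation exponent is dt-scaled)."""
        sat = cs.SaturationParams(1, 1, 1)
        res = [cs.run_simulation(
            small_domain,
            cs.SimulationConfig(total_time_min=60, dt=dt,
                                store_diffusivity=False),
            sat, transport) for dt in (20.0, 10.0)]
        rel = np.linalg.norm(res[0].final_frame() - res[1].final_frame()) \
            / np.linalg.norm(res[1].final_frame())
        assert rel < 1e-3

    def test_excessive_dt_rejected(self, small_domain):
        sim = cs.SimulationConfig(total_time_min=10, dt=60.0)
        with pytest.raises(ConfigurationError):
            cs.run_simulation(small_domain, sim)

    def test_fiber_shielding_lowers_cluster_concentration(self):
        grid = cs.GridSpec(nodes_per_side=100, side_length=500,
                           capsule_radius=175)
        nofib, fib, rois = make_fiber_scenario(grid)
        sim = cs.SimulationConfig(total_time_min=60,
                                  saturation_enabled=False,
                                  store_diffusivity=False)
        ra = cs.run_simulation(nofib, sim)
        rb = cs.run_simulation(fib, sim)
        roi = rois["cluster3"]
        a = cs.extract_profile(ra, roi).values[-1]
        b = cs.extract_profile(rb, roi).values[-1]
        assert b < a

    def test_uninitialized_domain_rejected(self, small_grid):
        with pytest.raises(ConfigurationError):
            cs.run_simulation(cs.build_domain(small_grid))
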