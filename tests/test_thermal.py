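"""Bioheat transient: flow profiles, Joule source, analytic benchmarks."""

import numpy as np
import pytest

from pfasim import scenario as sc
from pfasim import thermal as th
from pfasim import electrics as el


def uniform_block(dims=(20, 20, 20), spacing=0.5, label=sc.MYOCARDIUM):
    labels = np.full(dims, label, dtype=np.int8)
    grid = sc.ScenarioGrid(spacing_mm=spacing, labels=labels)
    sc.assign_materials(grid)
    return grid


class TestFlowField:
    def test_zero_peak_gives_zero_field(self):
        grid = sc.build_pv_ostium(13.0, 3.0, 0.5)
        f = th.make_flow_field(grid, 0.0)
        assert not f.velocity.any()

    def test_no_slip_and_centerline(self):
        grid = sc.build_pv_ostium(13.0, 3.0, 0.5)
        f = th.make_flow_field(grid, 0.16, "poiseuille")
        blood = grid.labels == sc.BLOOD
        tissueish = ~blood
        # no velocity outside blood, none in the wall-adjacent layer
        assert not f.velocity[tissueish].any()
        from scipy import ndimage

        near_wall = blood & ndimage.binary_dilation(tissueish)
        assert not f.velocity[near_wall].any()
        assert f.velocity.max() == pytest.approx(0.16, rel=0.01)

    def test_poiseuille_mean_is_half_peak(self):
        """Parabolic profile in a cylinder: cross-section mean = peak/2."""
        grid = sc.build_pv_ostium(13.0, 3.0, 0.25)
        f = th.make_flow_field(grid, 0.16, "poiseuille")
        x, y, _ = grid.coords_mm()
        cx, cy = grid.meta["lumen_center_mm"]
        r = np.broadcast_to(np.sqrt((x - cx) ** 2 + (y - cy) ** 2), grid.labels.shape)
        lumen = (grid.labels == sc.BLOOD) & (r < grid.meta["lumen_radius_mm"])
        sl = lumen[:, :, 2]
        mean = f.velocity[:, :, 2][sl].mean()
        assert mean == pytest.approx(0.08, rel=0.05)

    def test_no_blood_rejected(self):
        grid = uniform_block()
        with pytest.raises(ValueError, match="blood"):
            th.make_flow_field(grid, 0.1)


class TestJouleSource:
    def test_direct_formula(self, atrial_coarse):
        """q = duty * sigma * |E|^2; spot-checked at sigma = 0.5 S/m,
        |E| = 1e4 V/m, duty 0.5 -> 2.5e7 W/m^3."""
        grid = uniform_block(dims=(6, 6, 6))
        grid.materials.sigma[:] = 0.5
        sol_like = type("S", (), {})()
        sol_like.e_mag = np.full((6, 6, 6), 100.0)  # 100 V/cm = 1e4 V/m
        q = th.joule_source(sol_like, grid, 0.5)
        assert np.allclose(q, 2.5e7)

    def test_zero_duty_zero_source(self, atrial_coarse):
        grid, sol, _ = atrial_coarse
        assert not th.joule_source(sol, grid, 0.0).any()

    def test_dead_in_insulator_and_electrodes(self, atrial_coarse):
        grid, sol, _ = atrial_coarse
        q = th.joule_source(sol, grid, 0.5)
        dead = (
            (grid.labels == sc.INSULATOR)
            | (grid.labels == sc.ELECTRODE_LINE)
            | (grid.labels == sc.ELECTRODE_NEUTRAL)
        )
        assert not q[dead].any()


class TestTransient:
    def test_zero_source_stays_at_baseline(self):
        grid = uniform_block(dims=(10, 10, 10))
        tr = th.simulate_transient(
            grid, np.zeros((10, 10, 10)), burst_s=1e-4, relax_s=0.02
        )
        assert np.allclose(tr.final_temp, 37.0, atol=1e-12)
        assert np.allclose(tr.probes["domain_max"], 37.0, atol=1e-12)

    def test_heat_kernel_1d(self):
        """Gaussian excess on a rod spreads per the analytic diffusion
        kernel; L2 error of the profile <= 1%."""
        s = 0.25
        n = 200
        grid = uniform_block(dims=(n, 1, 1), spacing=s)
        mat = grid.materials
        alpha = mat.k[0, 0, 0] / (mat.rho[0, 0, 0] * mat.c_p[0, 0, 0])
        x = (np.arange(n) + 0.5) * s * 1e-3
        x0 = x[n // 2]
        sig0 = 6 * s * 1e-3
        excess0 = 5.0 * np.exp(-((x - x0) ** 2) / (2 * sig0**2))
        t_end = 2.0
        tr = th.simulate_transient(
            grid,
            np.zeros(grid.labels.shape),
            burst_s=0.0,
            relax_s=t_end,
            dt_relax=0.05,
            boundary="adiabatic",
            initial_excess=excess0.reshape(n, 1, 1),
        )
        sig_t = np.sqrt(sig0**2 + 2 * alpha * t_end)
        exact = 37.0 + 5.0 * sig0 / sig_t * np.exp(-((x - x0) ** 2) / (2 * sig_t**2))
        num = tr.final_temp[:, 0, 0]
        l2 = np.linalg.norm(num - exact) / np.linalg.norm(exact - 37.0)
        assert l2 < 0.01

    def test_energy_consistency_adiabatic(self):
        """No flow, adiabatic walls: enthalpy gain equals source energy
        within 2%."""
        grid = uniform_block()
        q = np.zeros(grid.labels.shape)
        q[8:12, 8:12, 8:12] = 1e8
        tr = th.simulate_transient(
            grid, q, burst_s=100e-6, relax_s=0.01, boundary="adiabatic"
        )
        vol = (0.5e-3) ** 3
        gained = np.sum(
            grid.materials.rho * grid.materials.c_p * (tr.final_temp - 37.0) * vol
        )
        expected = q.sum() * vol * 100e-6
        assert gained == pytest.approx(expected, rel=0.02)

    def test_post_burst_monotone_cooling(self, atrial_coarse):
        """Without flow the probe series never rises after the burst ends."""
        grid, sol, q = atrial_coarse
        tr = th.simulate_transient(grid, q, burst_s=100e-6, relax_s=0.05)
        post = tr.probes["domain_max"][tr.times_s >= 100e-6 - 1e-12]
        assert np.all(np.diff(post) <= 1e-12)

    def test_voltage_doubling_quadruples_rise_rate(self, atrial_coarse):
        """q scales with V^2, so the initial temperature-rise rate does too."""
        grid, sol, _ = atrial_coarse
        sol2 = el.solve_potential(grid, 450.0)
        q1 = th.joule_source(sol2, grid, 0.5)
        sol3 = el.solve_potential(grid, 900.0)
        q2 = th.joule_source(sol3, grid, 0.5)
        kw = dict(burst_s=2e-6, relax_s=0.0, dt_burst=1e-6)
        t1 = th.simulate_transient(grid, q1, **kw)
        t2 = th.simulate_transient(grid, q2, **kw)
        rise1 = t1.probes["domain_max"][-1] - 37.0
        rise2 = t2.probes["domain_max"][-1] - 37.0
        assert rise2 == pytest.approx(4.0 * rise1, rel=1e-3)

    def test_unstable_dt_rejected(self):
        grid = uniform_block(dims=(10, 10, 10), spacing=0.25)
        with pytest.raises(ValueError, match="stability"):
            th.simulate_transient(
                grid, np.zeros((10, 10, 10)), burst_s=0.0, relax_s=1.0, dt_relax=1.0
            )

    def test_cfl_violation_rejected(self):
        grid = sc.build_pv_ostium(13.0, 3.0, 0.5)
        sc.assign_materials(grid)
        flow = th.make_flow_field(grid, 1.0)
        with pytest.raises(ValueError, match="CFL"):
            th.simulate_transient(
                grid,
                np.zeros(grid.labels.shape),
                flow=flow,
                burst_s=0.0,
                relax_s=0.01,
                dt_relax=1e-3,
            )


class TestAdvectiveCooling:
    def test_washout_monotone_with_shrinking_marginal_effect(self):
        """A heated plume in moving blood washes out monotonically with
        velocity, and the marginal effect of doubling the velocity
        shrinks (convective cooling saturates)."""
        labels = np.full((60, 8, 8), sc.BLOOD, dtype=np.int8)
        grid = sc.ScenarioGrid(spacing_mm=0.5, labels=labels, meta={"flow_axis": 0})
        sc.assign_materials(grid)
        exc = np.zeros(labels.shape)
        exc[8:14, 2:6, 2:6] = 10.0
        peaks = {}
        for v in (0.0, 0.08, 0.16):
            flow = th.make_flow_field(grid, v, "plug")
            tr = th.simulate_transient(
                grid,
                np.zeros(labels.shape),
                flow=flow,
                burst_s=0.0,
                relax_s=0.12,
                dt_relax=1e-3,
                boundary="fixed",
                initial_excess=exc,
            )
            peaks[v] = float(tr.final_temp.max())
        assert peaks[0.0] > peaks[0.08] > peaks[0.16]
        d1 = peaks[0.0] - peaks[0.08]
        d2 = peaks[0.08] - peaks[0.16]
        assert d1 > d2 > 0
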