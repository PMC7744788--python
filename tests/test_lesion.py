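"""Lesion metrics: decay fits, threshold radii, gaps, alignment CV."""

import numpy as np
import pytest
from scipy import ndimage

from pfasim import scenario as sc
from pfasim import electrics as el
from pfasim import lesion as le
from pfasim import synthetic as syn

from conftest import SPHERE_A_MM, SPHERE_B_MM, SPHERE_VOLTS


class TestDecayFit:
    def test_noiseless_recovery(self):
        """Exact recovery of the tissue decay parameters (A = 7.6 C,
        tau = 9.22 ms) from a clean exponential."""
        t, y = syn.gen_decay_series(7.6, 9.22, 37.0, 0.0)
        fit = le.fit_exponential_decay(t, y)
        assert fit.amplitude_c == pytest.approx(7.6, rel=1e-3)
        assert fit.tau_ms == pytest.approx(9.22, rel=1e-3)
        assert fit.baseline_c == pytest.approx(37.0, abs=0.05)
        assert fit.r_squared > 0.9999

    def test_one_percent_noise_recovery(self):
        t, y = syn.gen_decay_series(7.6, 9.22, 37.0, 0.01, seed=11)
        fit = le.fit_exponential_decay(t, y)
        assert fit.tau_ms == pytest.approx(9.22, rel=0.05)

    def test_median_recovery_over_seeds(self):
        """Across 100 seeded 1%-noise replicates the median tau error
        stays within 2%."""
        errs = []
        for seed in range(100):
            t, y = syn.gen_decay_series(7.6, 9.22, 37.0, 0.01, seed=seed)
            fit = le.fit_exponential_decay(t, y)
            errs.append(abs(fit.tau_ms - 9.22) / 9.22)
        assert np.median(errs) <= 0.02

    def test_four_tau_residual(self):
        """Remaining excess at t = 4 tau is e^-4 ~ 1.8% of the amplitude."""
        t, y = syn.gen_decay_series(7.6, 9.22, 37.0, 0.0, dt_ms=0.01, duration_ms=50.0)
        fit = le.fit_exponential_decay(t, y)
        t4 = 4.0 * fit.tau_ms * 1e-3
        i4 = int(np.argmin(np.abs(t - t4)))
        excess = y[i4] - fit.baseline_c
        assert excess / fit.amplitude_c == pytest.approx(np.exp(-4.0), rel=0.01)

    def test_constant_series_rejected(self):
        t = np.linspace(0, 0.05, 100)
        with pytest.raises(ValueError, match="constant"):
            le.fit_exponential_decay(t, np.full(100, 37.0))

    def test_non_decaying_series_rejected(self):
        t = np.linspace(0, 0.05, 100)
        with pytest.raises(ValueError, match="decay"):
            le.fit_exponential_decay(t, 37.0 + 5.0 * t / t.max())


class TestEffectiveFieldRadius:
    def test_spherical_electrode_closed_form(self, spheres_fine):
        """The super-threshold radius around a spherical electrode matches
        the closed form r_th = sqrt(C / E_th), C = V / (1/a - 1/b), within
        one voxel."""
        grid, r, sol = spheres_fine
        c_vmm = SPHERE_VOLTS / (1.0 / SPHERE_A_MM - 1.0 / SPHERE_B_MM)  # V mm
        e_th_v_per_mm = 40.0  # 400 V/cm
        r_th = np.sqrt(c_vmm / e_th_v_per_mm)
        expected_from_surface = r_th - SPHERE_A_MM
        measured = le.effective_field_radius(sol, grid, 400.0, "electrode_surface")
        assert abs(measured - expected_from_surface) <= grid.spacing_mm

    def test_threshold_above_max_gives_zero(self, spheres_fine):
        grid, _, sol = spheres_fine
        huge = sol.e_mag.max() * 10.0
        assert le.effective_field_radius(sol, grid, huge) == 0.0

    def test_matches_brute_force_scan(self, atrial_coarse):
        grid, sol, _ = atrial_coarse
        measured = le.effective_field_radius(sol, grid, 400.0)
        mask = (sol.e_mag >= 400.0) & (grid.labels == sc.MYOCARDIUM)
        elec = (grid.labels == sc.ELECTRODE_LINE) | (
            grid.labels == sc.ELECTRODE_NEUTRAL
        )
        d = ndimage.distance_transform_edt(~elec) * grid.spacing_mm
        assert measured == float(d[mask].max())

    def test_monotone_in_voltage_and_threshold(self, atrial_coarse):
        grid, sol, _ = atrial_coarse
        lo = el.solve_potential(grid, 450.0)
        r_lo = le.effective_field_radius(lo, grid, 400.0)
        r_hi = le.effective_field_radius(sol, grid, 400.0)
        assert r_hi >= r_lo
        assert le.effective_field_radius(sol, grid, 800.0) <= r_hi

    def test_inter_electrode_not_larger_than_surface(self, atrial_coarse):
        """Between adjacent electrodes the treatable depth sags below the
        radius at the electrode surface."""
        grid, sol, _ = atrial_coarse
        r_surf = le.effective_field_radius(sol, grid, 400.0, "electrode_surface")
        r_mid = le.effective_field_radius(sol, grid, 400.0, "inter_electrode")
        assert 0.0 < r_mid <= r_surf


class TestUntreatedGap:
    def test_zero_threshold_gives_zero_gap(self, septal_solutions):
        grid, sol = septal_solutions["aligned"]
        assert le.untreated_gap(sol, grid, 1e-12) == 0.0

    def test_misalignment_widens_gap(self, septal_solutions):
        """At equal voltage the sub-threshold span grows when the catheters
        are misaligned."""
        g_a, s_a = septal_solutions["aligned"]
        g_o, s_o = septal_solutions["offset"]
        thr = 700.0  # V/cm, chosen so both configurations leave a gap
        gap_a = le.untreated_gap(s_a, g_a, thr)
        gap_o = le.untreated_gap(s_o, g_o, thr)
        assert gap_o >= gap_a > 0.0

    def test_matches_brute_force_line_scan(self, septal_solutions):
        grid, sol = septal_solutions["offset"]
        thr = 700.0
        gap = le.untreated_gap(sol, grid, thr)
        # independent scan: sample the centroid-to-centroid segment directly
        s = grid.spacing_mm
        p0 = (np.argwhere(grid.labels == sc.ELECTRODE_LINE).mean(axis=0) + 0.5) * s
        p1 = (np.argwhere(grid.labels == sc.ELECTRODE_NEUTRAL).mean(axis=0) + 0.5) * s
        n = 4000
        pts = p0 + np.linspace(0, 1, n)[:, None] * (p1 - p0)
        idx = np.clip(
            np.floor(pts / s).astype(int), 0, np.array(grid.labels.shape) - 1
        )
        lab = grid.labels[idx[:, 0], idx[:, 1], idx[:, 2]]
        e = sol.e_mag[idx[:, 0], idx[:, 1], idx[:, 2]]
        sub = (lab == sc.MYOCARDIUM) & (e < thr)
        best = run = 0
        for f in sub:
            run = run + 1 if f else 0
            best = max(best, run)
        step = np.linalg.norm(p1 - p0) / (n - 1)
        assert gap == pytest.approx(best * step, abs=2 * step + s)

    def test_axis_missing_tissue_rejected(self, septal_solutions):
        grid, sol = septal_solutions["aligned"]
        corner = (np.zeros(3), np.array([1.0, 1.0, 1.0]))
        with pytest.raises(ValueError, match="myocardium"):
            le.untreated_gap(sol, grid, 400.0, axis_mm=corner)


class TestAlignmentSensitivity:
    def test_identical_values_give_zero(self):
        assert le.alignment_sensitivity([5.0, 5.0, 5.0]) == 0.0

    def test_hand_computed_examples(self):
        assert le.alignment_sensitivity([1.0, 2.0, 3.0]) == pytest.approx(50.0)
        assert le.alignment_sensitivity([5.0, 5.5, 4.5, 5.0]) == pytest.approx(
            8.1649658, rel=1e-6
        )

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            le.alignment_sensitivity([5.0])
        with pytest.raises(ValueError, match="mean"):
            le.alignment_sensitivity([-1.0, 1.0])


class TestLesionReport:
    def test_septal_report_structure(self, septal_solutions):
        grid, sol = septal_solutions["aligned"]
        rep = le.build_lesion_report(sol, grid)
        d = rep.to_dict()
        for key in (
            "applied_volts",
            "e_field_max_kv_per_cm",
            "e_field_mean_v_per_cm",
            "j_mean_ka_per_m2",
            "j_max_ka_per_m2",
            "t_interface_max_c",
            "effective_radius_mm",
            "untreated_gap_mm",
        ):
            assert key in d
        assert d["untreated_gap_mm"] is not None  # septal: gap is reported
        assert d["effective_radius_mm"] >= 0.0
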