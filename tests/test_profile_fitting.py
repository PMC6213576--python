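"""TOF and BVG fits, background-threshold search, 3D scaling, intensity."""

import numpy as np
import pytest
from dataclasses import replace

from tofprofile.geometry import q_to_spherical
from tofprofile.histogramming import build_grid, smooth_grid
from tofprofile.moderator import BroadeningParams, ICParams, ic_convolved, initial_guess
from tofprofile.profile_fitting import (
    BVGParams,
    InsufficientCountsError,
    UnfittablePeakError,
    assemble_and_scale,
    bvg_density,
    find_background_threshold,
    fit_bvg,
    fit_tof,
    integrate_intensity,
)
from tofprofile.synthetic import SyntheticPeakSpec, default_instrument, generate_events

IC = ICParams(alpha=1.0, beta=0.05, R=0.3, t0=0.0)


def peak_scene(rng_seed, true_counts, background_rate, peak=None, table_ic=None):
    """One synthetic peak on the default instrument, with truth labels."""
    ub, geom = default_instrument()
    peak = peak or (7, 2, 6)
    ic = table_ic or ICParams(alpha=0.18, beta=0.0095, R=0.5, t0=2.3)
    spec = SyntheticPeakSpec(peak=peak, true_counts=true_counts, ic=ic,
                             sigma_phi=0.005, sigma_2theta=0.004, rho=0.2,
                             background_rate=background_rate)
    events, truth = generate_events([spec], ub, geom, seed=rng_seed)
    return ub, geom, events, truth, spec


class TestFitTOF:
    def setup_histogram(self, n_counts, seed=5, sigma_g=4.0, pulse=6.0):
        rng = np.random.default_rng(seed)
        t = np.arange(10.0, 620.0, 5.0)
        ic = ICParams(alpha=0.9, beta=0.04, R=0.35, t0=60.0)
        b = BroadeningParams(sigma_g=sigma_g, pulse_width=pulse,
                             scale=n_counts, background=0.5)
        expect = ic_convolved(t, ic, b)
        return t, rng.poisson(expect).astype(float), ic, b

    def test_parameter_recovery_within_3se(self):
        t, counts, ic, b = self.setup_histogram(50000)
        seed_ic = replace(ic, alpha=ic.alpha * 1.2, beta=ic.beta * 0.9, t0=ic.t0 + 5)
        seed_b = replace(b, scale=counts.sum(), background=1.0)
        fit = fit_tof(t, counts, seed_ic, seed_b)
        assert 0.5 < fit.chi2 < 1.5
        for name, truth in [("alpha", ic.alpha), ("beta", ic.beta), ("R", ic.R),
                            ("t0", ic.t0)]:
            got = getattr(fit.ic, name)
            se = fit.stderr[name]
            assert abs(got - truth) < 3 * max(se, 1e-9), name

    def test_scale_recovered_within_2pct_at_1e4(self):
        t, counts, ic, b = self.setup_histogram(10000)
        fit = fit_tof(t, counts, ic, replace(b, scale=counts.sum()))
        assert fit.broad.scale == pytest.approx(10000, rel=0.02)

    def test_zero_count_histogram_rejected(self):
        t = np.arange(0.0, 100.0, 5.0)
        with pytest.raises(UnfittablePeakError):
            fit_tof(t, np.zeros_like(t), IC, BroadeningParams())

    def test_fitted_curve_nonnegative(self):
        t, counts, ic, b = self.setup_histogram(2000)
        fit = fit_tof(t, counts, ic, replace(b, scale=counts.sum()))
        assert np.all(ic_convolved(t, fit.ic, fit.broad) >= 0)


class TestFitBVG:
    grid_1d = np.linspace(-0.025, 0.025, 50)

    def eval_bvg(self, p):
        pp, tt = np.meshgrid(self.grid_1d, 1.0 + self.grid_1d, indexing="ij")
        cell = (self.grid_1d[1] - self.grid_1d[0]) ** 2
        return p.amplitude * bvg_density(pp, tt, p) * cell + p.background2d

    def test_noiseless_exact_recovery(self):
        truth = BVGParams(mu_phi=0.002, mu_2theta=1.003, sigma_phi=0.005,
                          sigma_2theta=0.004, rho=0.3, amplitude=5000.0,
                          background2d=0.2)
        counts = self.eval_bvg(truth)
        fit = fit_bvg(self.grid_1d, 1.0 + self.grid_1d, counts, (0.0, 1.0))
        assert fit.chi2 < 1e-6
        assert fit.params.sigma_phi == pytest.approx(truth.sigma_phi, rel=1e-4)
        assert fit.params.rho == pytest.approx(truth.rho, abs=1e-4)

    def test_zero_rho_symmetric_peak(self, rng):
        truth = BVGParams(mu_phi=0.0, mu_2theta=1.0, sigma_phi=0.005,
                          sigma_2theta=0.004, rho=0.0, amplitude=10000.0)
        counts = rng.poisson(self.eval_bvg(truth)).astype(float)
        fit = fit_bvg(self.grid_1d, 1.0 + self.grid_1d, counts, (0.0, 1.0))
        assert abs(fit.params.rho) < 0.05

    def test_sampled_recovery_within_3se(self, rng):
        truth = BVGParams(mu_phi=0.0, mu_2theta=1.0, sigma_phi=0.004,
                          sigma_2theta=0.003, rho=0.4, amplitude=5000.0)
        counts = rng.poisson(self.eval_bvg(truth)).astype(float)
        fit = fit_bvg(self.grid_1d, 1.0 + self.grid_1d, counts, (0.0, 1.0))
        for name, val in [("sigma_phi", truth.sigma_phi),
                          ("sigma_2theta", truth.sigma_2theta), ("rho", truth.rho)]:
            assert abs(getattr(fit.params, name) - val) < 3 * fit.stderr[name], name

    def test_insufficient_cells_flagged(self):
        counts = np.zeros((50, 50))
        counts[20:24, 20:26] = 1.0  # 24 occupied cells
        with pytest.raises(InsufficientCountsError):
            fit_bvg(self.grid_1d, 1.0 + self.grid_1d, counts, (0.0, 1.0))


class TestBackgroundThreshold:
    def run_threshold(self, events, truth, ub, geom, table_ic):
        from tofprofile.geometry import TOF_COEF

        peak = tuple(int(v) for v in truth.iloc[0][["h", "k", "l"]])
        grid = build_grid(events, peak, ub)
        sm = smooth_grid(grid)
        qr0, _, tth0 = q_to_spherical(grid.q_center)
        L = geom.flight_path_for(grid.q_center)
        broad = BroadeningParams(sigma_g=8.0, pulse_width=10.0,
                                 sigma_vox=grid.radial_voxel_sigma(L))
        t_b = TOF_COEF * L * np.sin(tth0 / 2.0) / qr0
        ic_seed = replace(table_ic, t0=t_b + table_ic.t0)
        return grid, find_background_threshold(grid, sm, ic_seed, broad, L)

    def test_pure_peak_lowest_level_keeps_counts(self):
        ic = ICParams(alpha=0.18, beta=0.0095, R=0.5, t0=2.3)
        ub, geom, events, truth, spec = peak_scene(3, 3000, 0.0, table_ic=ic)
        grid, thr = self.run_threshold(events, truth, ub, geom, ic)
        # no background to exclude: the mask keeps essentially all counts
        assert grid.counts[thr.mask].sum() >= 0.99 * grid.counts.sum()

    def test_pure_background_never_significant_peak(self):
        # background-only boxes must never yield a significant profile
        # intensity at the study background rate
        from tofprofile.config import IntegrationConfig
        from tofprofile.peak_library import LibraryEntry, StrongPeakLibrary
        from tofprofile.pipeline import fit_peak_profile

        ub, geom = default_instrument()
        ic = ICParams(alpha=0.18, beta=0.0095, R=0.5, t0=2.3)
        qr0, phi0, tth0 = q_to_spherical(ub.hkl_to_q(np.array([7., 2., 6.])))
        lib = StrongPeakLibrary(entries=[LibraryEntry(
            phi_az=phi0, two_theta=tth0, sigma_phi=0.005, sigma_2theta=0.004,
            rho=0.2, n_events=1000, peak=(1, 1, 1))])
        for seed in range(1, 6):
            spec = SyntheticPeakSpec(peak=(7, 2, 6), true_counts=0.0, ic=ic,
                                     sigma_phi=0.005, sigma_2theta=0.004,
                                     rho=0.2, background_rate=0.02)
            events, _ = generate_events([spec], ub, geom, seed=seed)
            res = fit_peak_profile(events, (7, 2, 6), ub, geom,
                                   __import__("tofprofile").default_table(),
                                   IntegrationConfig(), library=lib)
            assert (res.rejected or not np.isfinite(res.I)
                    or res.I / res.sigma_I < 1.0), seed

    def test_mask_quality_on_peak_with_flat_background(self):
        # IC-shaped peak of ~2000 counts over a flat background of 0.2
        # neutrons per voxel; decay constants scaled to the instrument's
        # radial resolution with the canonical fast/slow ratio alpha/beta = 20
        ub, geom = default_instrument()
        ic = ICParams(alpha=0.18, beta=0.009, R=0.3, t0=2.3)
        base = dict(peak=(7, 2, 6), ic=ic, sigma_phi=0.005,
                    sigma_2theta=0.004, rho=0.2)
        peak_spec = SyntheticPeakSpec(true_counts=2000.0, background_rate=0.0, **base)
        bg_spec = SyntheticPeakSpec(true_counts=0.0, background_rate=0.2, **base)
        ev_peak, _ = generate_events([peak_spec], ub, geom, seed=8)
        ev_bg, _ = generate_events([bg_spec], ub, geom, seed=9)
        g_peak = build_grid(ev_peak, (7, 2, 6), ub)
        g_bg = build_grid(ev_bg, (7, 2, 6), ub)
        combined = build_grid(np.vstack([ev_peak, ev_bg]), (7, 2, 6), ub)
        sm = smooth_grid(combined)
        qr0, _, tth0 = q_to_spherical(combined.q_center)
        L = geom.flight_path_for(combined.q_center)
        from tofprofile.geometry import TOF_COEF
        t_b = TOF_COEF * L * np.sin(tth0 / 2) / qr0
        ic_seed = replace(ic, t0=t_b + ic.t0)
        broad = BroadeningParams(sigma_g=8.0, pulse_width=10.0,
                                 sigma_vox=combined.radial_voxel_sigma(L))
        thr = find_background_threshold(combined, sm, ic_seed, broad, L)
        peak_kept = g_peak.counts[thr.mask].sum() / g_peak.counts.sum()
        assert peak_kept >= 0.90
        # voxels empty even in a 100x brighter replica lie far outside the
        # true peak region.  Thresholding a 3x3x3-smoothed histogram always
        # carries a one-voxel halo around the peak support, so a small
        # background fringe is inherent to the construction; it must stay a
        # minor fraction of the mask.
        ref_spec = SyntheticPeakSpec(true_counts=200000.0, background_rate=0.0, **base)
        ev_ref, _ = generate_events([ref_spec], ub, geom, seed=10)
        g_ref = build_grid(ev_ref, (7, 2, 6), ub)
        far_bg = g_ref.counts == 0
        assert (thr.mask & far_bg).sum() <= 0.15 * thr.mask.sum()


class TestAssembleAndIntegrate:
    def make_shape(self, seed=1):
        """A realistic fitted-profile scaffold on a small synthetic grid."""
        ic = ICParams(alpha=0.18, beta=0.0095, R=0.5, t0=2.3)
        ub, geom, events, truth, spec = peak_scene(seed, 4000, 0.02, table_ic=ic)
        peak = tuple(int(v) for v in truth.iloc[0][["h", "k", "l"]])
        grid = build_grid(events, peak, ub)
        L = geom.flight_path_for(grid.q_center)
        from tofprofile.geometry import TOF_COEF
        qr0, phi0, tth0 = q_to_spherical(grid.q_center)
        t_b = TOF_COEF * L * np.sin(tth0 / 2) / qr0
        from tofprofile.profile_fitting import TOFFitResult
        tof_fit = TOFFitResult(
            ic=replace(ic, t0=t_b + ic.t0),
            broad=BroadeningParams(sigma_g=8.0, pulse_width=10.0,
                                   sigma_vox=grid.radial_voxel_sigma(L)),
            chi2=1.0,
        )
        bvg = BVGParams(mu_phi=phi0, mu_2theta=tth0, sigma_phi=0.005,
                        sigma_2theta=0.004, rho=0.2)
        return grid, tof_fit, bvg, L

    def test_exact_linear_recovery(self):
        grid, tof_fit, bvg, L = self.make_shape()
        scale = assemble_and_scale(grid, tof_fit, bvg, L)
        S = scale.shape
        grid.counts = 7.0 * S  # noiseless model input
        again = assemble_and_scale(grid, tof_fit, bvg, L)
        assert again.A == pytest.approx(7.0, abs=1e-9)
        assert again.B == pytest.approx(0.0, abs=1e-9)
        assert again.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_pure_background_recovery(self):
        grid, tof_fit, bvg, L = self.make_shape()
        grid.counts = np.full_like(grid.counts, 3.0)
        scale = assemble_and_scale(grid, tof_fit, bvg, L)
        assert scale.A == pytest.approx(0.0, abs=1e-9)
        assert scale.B == pytest.approx(3.0, abs=1e-9)

    def test_poisson_coverage_of_sigma_A(self, rng):
        grid, tof_fit, bvg, L = self.make_shape()
        S = assemble_and_scale(grid, tof_fit, bvg, L).shape
        a_true, b_true = 2000.0, 0.2
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            grid.counts = rng.poisson(a_true * S + b_true).astype(float)
            sc = assemble_and_scale(grid, tof_fit, bvg, L)
            if abs(sc.A - a_true) < 3 * sc.sigma_A:
                hits += 1
        assert hits >= 95

    def test_intensity_definition_and_peak_set(self):
        grid, tof_fit, bvg, L = self.make_shape()
        scale = assemble_and_scale(grid, tof_fit, bvg, L)
        S = scale.shape
        grid.counts = 1000.0 * S
        sc = assemble_and_scale(grid, tof_fit, bvg, L)
        mask = S > 0.5 * S.max()
        res = integrate_intensity(grid, mask, sc)
        P = S > 0.05 * S.max()
        assert res.I == pytest.approx(sc.A * S[P].sum(), rel=1e-9)
        assert res.n_peak_voxels == int(P.sum())

    def test_machine_precision_inverse_for_noiseless_input(self):
        grid, tof_fit, bvg, L = self.make_shape()
        S = assemble_and_scale(grid, tof_fit, bvg, L).shape
        a_true, b_true = 1234.5, 0.75
        grid.counts = a_true * S + b_true
        sc = assemble_and_scale(grid, tof_fit, bvg, L)
        assert sc.A == pytest.approx(a_true, rel=1e-9)
        assert sc.B == pytest.approx(b_true, rel=1e-9)

    def test_degenerate_design_rejected(self):
        grid, tof_fit, bvg, L = self.make_shape()
        # a single accessible voxel cannot determine two parameters
        single = np.zeros_like(grid.counts, dtype=bool)
        single[0, 0, 0] = True
        with pytest.raises(UnfittablePeakError):
            assemble_and_scale(grid, tof_fit, bvg, L, accessible=single)
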