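"""Per-peak orchestration: from an event list to fitted intensities.

The run proceeds in two passes.  Pass one integrates every peak that is
neither weak nor on a detector edge, fitting the angular profile freely, and
collects the strong-peak library (> 500 spherical events, acceptable fits).
Pass two integrates the weak and edge peaks with their angular shape frozen
to the nearest library entry; the TOF direction is always fitted from the
moderator characterization.  Spherical integration runs alongside for every
peak so the two methods can be filtered symmetrically.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np

from .config import IntegrationConfig
from .filtering import apply_filters
from .geometry import DetectorGeometry, UBMatrix, edge_distance, q_to_spherical, wavelength_from_q
from .histogramming import (
    EmptyGridError,
    build_grid,
    smooth_grid,
    tof_histogram,
)
from .moderator import ModeratorTable, ic_convolved_density, initial_guess
from .peak_library import EmptyLibraryError, StrongPeakLibrary, build_library, classify_peak
from .profile_fitting import (
    InsufficientCountsError,
    PeakFitResult,
    UnfittablePeakError,
    assemble_and_scale,
    find_background_threshold,
    fit_bvg_voxel,
    fit_tof,
    integrate_intensity,
)
from .spherical import integrate_spherical

__all__ = ["group_events_by_peak", "fit_peak_profile", "integrate_peaks", "IntegrationRun"]

log = logging.getLogger("tofprofile")


def group_events_by_peak(events_q, ub: UBMatrix, peaks, eta: float):
    """Split one event list into per-peak boxes by rounding fractional hkl.

    Valid for eta <= 0.5 (boxes cannot overlap); events whose nearest integer
    hkl is not a requested peak are dropped.
    """
    events_q = np.atleast_2d(np.asarray(events_q, dtype=float))
    wanted = {tuple(int(v) for v in p): i for i, p in enumerate(peaks)}
    out = {k: [] for k in wanted}
    if events_q.size:
        frac = ub.q_to_hkl(events_q)
        nearest = np.round(frac).astype(int)
        off = np.abs(frac - nearest)
        inbox = np.all(off <= eta, axis=1)
        for idx in np.where(inbox)[0]:
            key = tuple(nearest[idx])
            if key in out:
                out[key].append(idx)
    return {k: events_q[v] if v else np.empty((0, 3)) for k, v in out.items()}


def _accessible_voxels(grid, geom: DetectorGeometry, edge_px: int, margin: int = 40):
    """Which voxels of the box land on a panel; skip the ray tracing for
    peaks far from every edge."""
    if edge_px >= margin:
        return np.ones_like(grid.counts, dtype=bool)
    q = grid.voxel_q.reshape(-1, 3)
    return geom.on_detector(q).reshape(grid.counts.shape)


def fit_peak_profile(
    box_events,
    peak,
    ub: UBMatrix,
    geom: DetectorGeometry,
    table: ModeratorTable,
    config: IntegrationConfig,
    library: StrongPeakLibrary | None = None,
) -> PeakFitResult:
    """Run the full profile-fitting chain for one peak.

    Never raises for per-peak data problems: failures are recorded as
    ``rejected:<reason>`` flags on the returned result.
    """
    peak = tuple(int(v) for v in peak)
    res = PeakFitResult(peak=peak)
    q0 = ub.hkl_to_q(np.asarray(peak, dtype=float))
    qr0, phi0, tth0 = q_to_spherical(q0)
    res.q_r, res.phi_az, res.two_theta = float(qr0), float(phi0), float(tth0)
    res.wavelength = float(wavelength_from_q(qr0, tth0))
    ed = edge_distance(q0, geom)
    res.edge_px = -1 if ed is None else int(ed)
    if ed is None:
        res.flags.append("rejected:off_detector")
        return res
    length = geom.flight_path_for(q0)

    sph = integrate_spherical(box_events, q0, config.spherical)
    res.n_events_spherical = sph.n_events
    res.I_spherical, res.sigma_spherical = sph.I, sph.sigma_I
    res.classification = classify_peak(
        sph.n_events, res.edge_px,
        weak_max_events=config.weak_max_events,
        strong_min_events=config.strong_min_events,
        edge_max_pixels=config.edge_max_pixels,
    )

    try:
        grid = build_grid(box_events, peak, ub, eta=config.eta,
                          voxels_per_side=config.voxels_per_side)
    except EmptyGridError:
        res.flags.append("rejected:empty_grid")
        return res
    smoothed = smooth_grid(grid)
    ic_seed, broad_seed = initial_guess(qr0, tth0, length, table)
    broad_seed = replace(broad_seed, sigma_g=config.sigma_g,
                         pulse_width=config.pulse_width,
                         sigma_vox=grid.radial_voxel_sigma(length))

    try:
        thr = find_background_threshold(
            grid, smoothed, ic_seed, broad_seed, length,
            n_levels=config.n_bg_levels,
            quantile_range=config.bg_quantile_range,
            n_tof_bins=config.n_tof_bins,
        )
    except UnfittablePeakError as exc:
        res.flags.append(f"rejected:unfittable_tof({exc})")
        return res
    res.bg_level = thr.level
    mask = thr.mask

    # final TOF fit: bounded shape refinement on the chosen mask
    centers, counts = tof_histogram(grid, mask, length, n_bins=config.n_tof_bins)
    seed_broad = replace(
        broad_seed,
        sigma_g=thr.tof_fit.broad.sigma_g,
        scale=max(float(counts.sum()), 1.0),
        background=thr.tof_fit.broad.background,
    )
    try:
        tof_fit = fit_tof(centers, counts, replace(ic_seed, t0=thr.tof_fit.ic.t0),
                          seed_broad, fit_shape=True)
    except UnfittablePeakError:
        tof_fit = thr.tof_fit
        res.flags.append("tof_refinement_failed")
    res.chi2_tof = tof_fit.chi2
    res.ic, res.broad = tof_fit.ic, tof_fit.broad
    res.tof_stderr = tof_fit.stderr

    use_library = res.classification in ("weak", "edge", "weak+edge")
    bvg = None
    if not use_library:
        # radial profile mass per voxel (with the q-space Jacobians), from
        # the fitted TOF model: the angular fit matches the marginal of the
        # voxelized 3D model, which a cell-center analytic BVG aliases
        qr_v, _, tth_v3 = grid.voxel_spherical
        tof_v = grid.voxel_tof(length)
        s_r = ic_convolved_density(tof_v.ravel(), tof_fit.ic, tof_fit.broad)
        s_r = s_r * tof_v.ravel() ** 2 / (qr_v.ravel() ** 2 * np.sin(tth_v3.ravel()))
        try:
            bvg_fit = fit_bvg_voxel(
                grid, mask, s_r, center_seed=(phi0, tth0),
                n_phi=config.n_phi_bins, n_two_theta=config.n_two_theta_bins,
                min_occupied=config.min_occupied_cells,
            )
            bvg = bvg_fit.params
            res.chi2_bvg = bvg_fit.chi2
            res.bvg_stderr = bvg_fit.stderr
        except InsufficientCountsError:
            use_library = True
            res.flags.append("bvg_insufficient_counts")
        except UnfittablePeakError as exc:
            res.flags.append(f"rejected:unfittable_bvg({exc})")
            return res
    if use_library:
        if library is None or len(library) == 0:
            res.flags.append("rejected:no_library_for_transfer")
            return res
        entry = library.lookup_nearest(phi0, tth0)
        bvg = entry.shape(mu_phi=phi0, mu_2theta=tth0)
        if "weak" in res.classification or "bvg_insufficient_counts" in res.flags:
            res.flags.append("weak_profile_forced")
        if "edge" in res.classification:
            res.flags.append("edge_profile_forced")
    res.bvg = bvg

    accessible = _accessible_voxels(grid, geom, res.edge_px)
    try:
        scale = assemble_and_scale(grid, tof_fit, bvg, length, accessible=accessible)
        intensity = integrate_intensity(grid, mask, scale,
                                        model_fraction=config.model_fraction)
    except UnfittablePeakError as exc:
        res.flags.append(f"rejected:unfittable_3d({exc})")
        return res
    res.A, res.B = scale.A, scale.B
    res.sigma_A = scale.sigma_A
    res.chi2_3d = scale.chi2
    res.I, res.sigma_I = intensity.I, intensity.sigma_I
    res.I_masked = intensity.I_masked
    res.b_est = intensity.b_est
    if res.B > 0 and intensity.b_est > 0 and (
        res.B / intensity.b_est > 3.0 or intensity.b_est / res.B > 3.0
    ):
        res.flags.append("background_mismatch")
    return res


class IntegrationRun:
    """Container for one full integration: results, library, filters."""

    def __init__(self, results, library, accepted, reasons):
        self.results = results
        self.library = library
        self.accepted = accepted
        self.reasons = reasons

    @property
    def accepted_results(self):
        acc = set(self.accepted)
        return [r for r in self.results if tuple(r.peak) in acc]


def integrate_peaks(
    events_q,
    peaks,
    ub: UBMatrix,
    geom: DetectorGeometry,
    table: ModeratorTable,
    config: IntegrationConfig | None = None,
    library: StrongPeakLibrary | None = None,
) -> IntegrationRun:
    """Integrate an event list over a predicted peak list (both methods).

    Pass one: free fits for non-weak, non-edge peaks; builds the strong-peak
    library (unless one is supplied, in which case new entries are appended
    to a copy).  Pass two: weak and edge peaks via library transfer.  The
    rejection rules are then applied symmetrically to the profile and
    spherical results.
    """
    config = config or IntegrationConfig()
    peaks = [tuple(int(v) for v in p) for p in peaks]
    boxes = group_events_by_peak(events_q, ub, peaks, config.eta)
    results: list[PeakFitResult] = []
    deferred = []
    for peak in peaks:
        box = boxes[peak]
        q0 = ub.hkl_to_q(np.asarray(peak, dtype=float))
        sph = integrate_spherical(box, q0, config.spherical)
        ed = edge_distance(q0, geom)
        cls = classify_peak(
            sph.n_events, -1 if ed is None else int(ed),
            weak_max_events=config.weak_max_events,
            strong_min_events=config.strong_min_events,
            edge_max_pixels=config.edge_max_pixels,
        )
        if cls in ("weak", "edge", "weak+edge"):
            deferred.append(peak)
        else:
            results.append(
                fit_peak_profile(box, peak, ub, geom, table, config, library=None)
            )
    lib = build_library(
        results, chi2_max=config.rules.chi2_max,
        strong_min_events=config.strong_min_events,
    )
    if library is not None:
        lib.entries = list(library.entries) + lib.entries
    if deferred and len(lib) == 0:
        raise EmptyLibraryError(
            f"{len(deferred)} weak/edge peaks need profile transfer but the "
            "strong-peak library is empty; integrate a strong data set first "
            "or pass a library file"
        )
    for peak in deferred:
        results.append(
            fit_peak_profile(boxes[peak], peak, ub, geom, table, config, library=lib)
        )
        log.info("peak %s: %s", peak, results[-1].classification)
    order = {p: i for i, p in enumerate(peaks)}
    results.sort(key=lambda r: order[tuple(r.peak)])

    spherical_results = []
    for r in results:
        s = PeakFitResult(peak=r.peak, method="spherical")
        s.q_r, s.phi_az, s.two_theta = r.q_r, r.phi_az, r.two_theta
        s.wavelength = r.wavelength
        s.edge_px = r.edge_px
        s.n_events_spherical = r.n_events_spherical
        s.classification = r.classification
        s.I, s.sigma_I = r.I_spherical, r.sigma_spherical
        s.I_spherical, s.sigma_spherical = r.I_spherical, r.sigma_spherical
        # chi^2 filters act on the profile fit; copy for symmetric filtering
        s.chi2_tof, s.chi2_bvg, s.chi2_3d = r.chi2_tof, r.chi2_bvg, r.chi2_3d
        s.bvg = r.bvg
        s.flags = list(r.flags)
        spherical_results.append(s)
    accepted, reasons = apply_filters(results, spherical_results, config.rules)
    n_rej = len(reasons)
    log.info("accepted %d peaks, rejected %d", len(accepted), n_rej)
    return IntegrationRun(results=results, library=lib, accepted=accepted,
                          reasons=reasons)
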