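"""Core fitting: background-threshold search, TOF and BVG fits, 3D scaling.

The (2+1)-dimensional strategy: the radial (TOF) direction is fitted with the
moderator emission model (Ikeda-Carpenter convolved with Gaussian and
top-hat), the two angular directions with a bivariate Gaussian (BVG), and the
full 3D model psi = A * (psi_IC x psi_BVG) + B is then scaled to the voxel
histogram by a two-parameter weighted linear least squares.

The background threshold is found by scanning candidate levels (quantiles of
the nearest-neighbors-smoothed histogram): at each level the masked TOF
profile is fitted with the *expected* profile (shape frozen at the moderator
seed, only scale/background/position/broadening free) and the level whose
reduced chi^2 is closest to 1 is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .histogramming import (
    EmptyGridError,
    EmptyMaskError,
    VoxelGrid,
    angular_histogram,
    threshold_mask,
    tof_histogram,
)
from .moderator import (
    BroadeningParams,
    ICParams,
    _fine_grid,
    ic_convolved,
    ic_convolved_density,
)

__all__ = [
    "BVGParams",
    "TOFFitResult",
    "BVGFitResult",
    "ThresholdResult",
    "ScaleResult",
    "IntensityResult",
    "PeakFitResult",
    "UnfittablePeakError",
    "InsufficientCountsError",
    "find_background_threshold",
    "fit_tof",
    "fit_bvg",
    "bvg_density",
    "assemble_and_scale",
    "integrate_intensity",
]


class UnfittablePeakError(RuntimeError):
    """No candidate background level yields a convergent TOF fit."""


class InsufficientCountsError(RuntimeError):
    """Too few occupied angular cells for a free BVG fit."""


@dataclass(frozen=True)
class BVGParams:
    """Bivariate Gaussian angular profile of a peak.

    Means and widths in radians; ``rho`` is the phi/2theta correlation that
    sets the peak's orientation on the detector.  ``amplitude`` is the
    integrated angular count and ``background2d`` a flat per-cell background.
    """

    mu_phi: float
    mu_2theta: float
    sigma_phi: float
    sigma_2theta: float
    rho: float
    amplitude: float = 1.0
    background2d: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_phi > 0 and self.sigma_2theta > 0):
            raise ValueError("BVG widths must be positive")
        if not abs(self.rho) < 1.0:
            raise ValueError("|rho| must be < 1")


def bvg_density(phi, two_theta, p: BVGParams) -> np.ndarray:
    """Unit-normalized bivariate Gaussian density at (phi, two_theta)."""
    x = (np.asarray(phi, float) - p.mu_phi) / p.sigma_phi
    y = (np.asarray(two_theta, float) - p.mu_2theta) / p.sigma_2theta
    omr2 = 1.0 - p.rho**2
    z = (x**2 - 2.0 * p.rho * x * y + y**2) / omr2
    norm = 2.0 * np.pi * p.sigma_phi * p.sigma_2theta * np.sqrt(omr2)
    return np.exp(-0.5 * z) / norm


def _poisson_sigma(counts: np.ndarray) -> np.ndarray:
    return np.maximum(1.0, np.sqrt(np.maximum(counts, 0.0)))


# ------------------------------------------------------------------ TOF fit


@dataclass(frozen=True)
class TOFFitResult:
    ic: ICParams
    broad: BroadeningParams
    chi2: float
    stderr: dict = field(default_factory=dict)
    converged: bool = True


def fit_tof(
    tof_centers: np.ndarray,
    counts: np.ndarray,
    ic_seed: ICParams,
    broad_seed: BroadeningParams,
    fit_shape: bool = True,
    bounds_frac: float = 0.5,
    t0_window: float | None = None,
    max_nfev: int = 200,
) -> TOFFitResult:
    """Weighted least-squares fit of the broadened IC profile to a TOF
    histogram (Poisson weights, sigma = max(1, sqrt(N))).

    ``ic_seed.t0`` is the absolute seed position (nominal Bragg TOF plus
    moderator offset).  With ``fit_shape`` the decay parameters alpha, beta
    and R vary within +/- ``bounds_frac`` of the seed; otherwise only
    position, Gaussian broadening, scale and background are free — the shape
    is the predicted moderator profile, as used during the background scan.
    The proton-pulse width is an instrument constant and is never fitted.
    """
    t = np.asarray(tof_centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    nonempty = int(np.count_nonzero(counts))
    if nonempty < 8:
        raise UnfittablePeakError(
            f"TOF histogram has only {nonempty} non-empty bins (need >= 8)"
        )
    bin_w = t[1] - t[0]
    sigma = _poisson_sigma(counts)
    if t0_window is None:
        t0_window = 3.0 * bin_w + 5.0
    scale0 = max(float(broad_seed.scale), 1.0)
    bg0 = max(float(broad_seed.background), 0.0)
    sg0 = max(float(broad_seed.sigma_g), 1e-3)

    names = ["t0", "sigma_g", "scale", "background"]
    x0 = [ic_seed.t0, sg0, scale0, bg0]
    lo = [ic_seed.t0 - t0_window, 1e-3, 0.0, 0.0]
    hi = [ic_seed.t0 + t0_window, max(4.0 * bin_w, 4.0 * sg0), np.inf, np.inf]
    if fit_shape:
        names = ["alpha", "beta", "R"] + names
        x0 = [ic_seed.alpha, ic_seed.beta, ic_seed.R] + x0
        lo = [
            ic_seed.alpha * (1 - bounds_frac),
            ic_seed.beta * (1 - bounds_frac),
            max(ic_seed.R * (1 - bounds_frac), 0.0),
        ] + lo
        hi = [
            ic_seed.alpha * (1 + bounds_frac),
            ic_seed.beta * (1 + bounds_frac),
            min(ic_seed.R * (1 + bounds_frac), 1.0),
        ] + hi

    def unpack(x):
        d = dict(zip(names, x))
        alpha = d.get("alpha", ic_seed.alpha)
        beta = d.get("beta", ic_seed.beta)
        if alpha <= beta * 1.0001:
            return None, None
        ic = ICParams(alpha=alpha, beta=beta, R=d.get("R", ic_seed.R), t0=d["t0"])
        br = BroadeningParams(
            sigma_g=d["sigma_g"],
            pulse_width=broad_seed.pulse_width,
            sigma_vox=broad_seed.sigma_vox,
            scale=d["scale"],
            background=d["background"],
        )
        return ic, br

    # freeze the oversampled grid across evaluations so the model stays
    # smooth in its parameters (a per-call grid makes the numerical jacobian
    # noisy and the reported errors meaningless)
    grid_ic = replace(ic_seed, alpha=ic_seed.alpha * (1 + bounds_frac))
    grid_b = replace(broad_seed, sigma_g=max(hi[names.index("sigma_g")], sg0))
    fine = _fine_grid(t, grid_ic, grid_b)

    def resid(x):
        ic, br = unpack(x)
        if ic is None:
            return np.full(t.size, 1e6)
        return (ic_convolved(t, ic, br, fine_grid=fine) - counts) / sigma

    def make_resid(sig):
        def resid2(x):
            ic, br = unpack(x)
            if ic is None:
                return np.full(t.size, 1e6)
            return (ic_convolved(t, ic, br, fine_grid=fine) - counts) / sig
        return resid2

    try:
        res = least_squares(
            resid, x0, bounds=(lo, hi), x_scale="jac", max_nfev=max_nfev,
            ftol=1e-8, xtol=1e-8,
        )
        if fit_shape:
            # refinement pass with model-based Poisson weights: weighting by
            # observed counts overweights downward fluctuations and shifts
            # the position/shape parameters at high counts
            ic1, br1 = unpack(res.x)
            if ic1 is not None:
                sig2 = np.sqrt(np.maximum(ic_convolved(t, ic1, br1, fine_grid=fine), 1.0))
                res = least_squares(
                    make_resid(sig2), res.x, bounds=(lo, hi), x_scale="jac",
                    max_nfev=max_nfev, ftol=1e-8, xtol=1e-8,
                )
    except Exception as exc:  # pragma: no cover - defensive
        raise UnfittablePeakError(f"TOF fit failed: {exc}") from exc
    ic, br = unpack(res.x)
    if ic is None or not np.all(np.isfinite(res.x)):
        raise UnfittablePeakError("TOF fit did not converge to valid parameters")
    dof = max(t.size - len(res.x), 1)
    chi2 = float(2.0 * res.cost / dof)
    stderr = {}
    try:
        jtj = res.jac.T @ res.jac
        cov = np.linalg.inv(jtj)
        stderr = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except np.linalg.LinAlgError:
        pass
    return TOFFitResult(ic=ic, broad=br, chi2=chi2, stderr=stderr,
                        converged=bool(res.success))


# ------------------------------------------------------------ threshold scan


@dataclass(frozen=True)
class ThresholdResult:
    level: float
    mask: np.ndarray
    chi2: float
    tof_fit: TOFFitResult


def find_background_threshold(
    grid: VoxelGrid,
    smoothed: np.ndarray,
    ic_seed: ICParams,
    broad_seed: BroadeningParams,
    flight_path: float,
    n_levels: int = 16,
    quantile_range: tuple = (0.5, 0.995),
    n_tof_bins: int | None = None,
) -> ThresholdResult:
    """Scan candidate background levels; keep the one whose masked TOF
    profile is best described by the predicted moderator profile
    (reduced chi^2 closest to 1)."""
    qs = np.linspace(quantile_range[0], quantile_range[1], n_levels)
    levels = np.unique(np.quantile(smoothed.ravel(), qs))
    best = None
    for level in levels:
        try:
            mask = threshold_mask(smoothed, float(level), grid.center_index)
        except EmptyMaskError:
            continue
        centers, counts = tof_histogram(grid, mask, flight_path, n_bins=n_tof_bins)
        if np.count_nonzero(counts) < 8:
            continue
        seed_broad = replace(
            broad_seed,
            scale=max(float(counts.sum()), 1.0),
            background=float(np.mean(np.concatenate([counts[:2], counts[-2:]]))),
        )
        try:
            fit = fit_tof(
                centers, counts, ic_seed, seed_broad,
                fit_shape=False, max_nfev=80,
            )
        except UnfittablePeakError:
            continue
        score = abs(fit.chi2 - 1.0)
        if best is None or score < best[0]:
            best = (score, float(level), mask, fit)
    if best is None:
        raise UnfittablePeakError(
            "no background level produced a fittable TOF profile"
        )
    _, level, mask, fit = best
    # the predicted profile describes a peak: a scale consistent with zero
    # means there is nothing above background to integrate
    scale_err = fit.stderr.get("scale", 0.0)
    if scale_err > 0 and fit.broad.scale < 2.0 * scale_err:
        raise UnfittablePeakError(
            "fitted profile scale is consistent with zero (background only)"
        )
    return ThresholdResult(level=level, mask=mask, chi2=fit.chi2, tof_fit=fit)


# ------------------------------------------------------------------ BVG fit


@dataclass(frozen=True)
class BVGFitResult:
    params: BVGParams
    chi2: float
    stderr: dict = field(default_factory=dict)


def fit_bvg(
    phi_centers: np.ndarray,
    tth_centers: np.ndarray,
    counts2d: np.ndarray,
    center_seed: tuple,
    footprint: np.ndarray | None = None,
    exposure: np.ndarray | None = None,
    bg_cover: np.ndarray | None = None,
    min_occupied: int = 25,
    max_nfev: int = 300,
) -> BVGFitResult:
    """Least-squares fit of amplitude * BVG + background to a 2D angular
    histogram.  Raises :class:`InsufficientCountsError` when fewer than
    ``min_occupied`` cells are occupied — the trigger for the strong-peak
    library transfer path.

    ``footprint`` restricts the fit to the cells actually covered by the
    voxel mask that built the histogram; cells outside it are empty by
    construction and would clip the Gaussian tails if treated as data.
    ``exposure`` (per-cell fraction of the radial profile mass the mask
    captures, from the TOF fit) and ``bg_cover`` (masked voxels per cell)
    refine the model of a masked histogram to
    ``amp * BVG * cell * exposure + bg2d * bg_cover``; without them the
    background is per cell and the exposure is unity.
    """
    phi_c = np.asarray(phi_centers, float)
    tth_c = np.asarray(tth_centers, float)
    counts = np.asarray(counts2d, float)
    if footprint is None:
        footprint = np.ones_like(counts, dtype=bool)
    expo = np.ones_like(counts) if exposure is None else np.asarray(exposure, float)
    bgc = np.ones_like(counts) if bg_cover is None else np.asarray(bg_cover, float)
    occupied = int(np.count_nonzero(counts[footprint]))
    if occupied < min_occupied:
        raise InsufficientCountsError(
            f"only {occupied} occupied angular cells (need >= {min_occupied})"
        )
    pp, tt = np.meshgrid(phi_c, tth_c, indexing="ij")
    cell = (phi_c[1] - phi_c[0]) * (tth_c[1] - tth_c[0])
    sigma = _poisson_sigma(counts)

    total = counts[footprint].sum()
    w = np.where(footprint, counts, 0.0) / total
    mu_phi0 = float((w * pp).sum())
    mu_tth0 = float((w * tt).sum())
    var_phi = max(float((w * (pp - mu_phi0) ** 2).sum()), (phi_c[1] - phi_c[0]) ** 2 / 4)
    var_tth = max(float((w * (tt - mu_tth0) ** 2).sum()), (tth_c[1] - tth_c[0]) ** 2 / 4)
    cov0 = float((w * (pp - mu_phi0) * (tt - mu_tth0)).sum())
    rho0 = np.clip(cov0 / np.sqrt(var_phi * var_tth), -0.9, 0.9)
    if center_seed is not None:
        # moment means can be dragged by background; start between the two
        mu_phi0 = 0.5 * (mu_phi0 + center_seed[0])
        mu_tth0 = 0.5 * (mu_tth0 + center_seed[1])

    phi_span = phi_c[-1] - phi_c[0]
    tth_span = tth_c[-1] - tth_c[0]
    x0 = [mu_phi0, mu_tth0, np.sqrt(var_phi), np.sqrt(var_tth), rho0, total, 0.0]
    lo = [phi_c[0], tth_c[0], (phi_c[1] - phi_c[0]) / 4.0,
          (tth_c[1] - tth_c[0]) / 4.0, -0.98, 0.0, 0.0]
    hi = [phi_c[-1], tth_c[-1], phi_span, tth_span, 0.98, np.inf, np.inf]
    x0 = np.clip(x0, lo, hi)

    def model(x):
        p = BVGParams(
            mu_phi=x[0], mu_2theta=x[1], sigma_phi=x[2], sigma_2theta=x[3],
            rho=x[4], amplitude=x[5], background2d=x[6],
        )
        return x[5] * bvg_density(pp, tt, p) * cell * expo + x[6] * bgc, p

    fp = footprint.ravel()

    def make_resid(sig):
        def resid(x):
            m, _ = model(x)
            return (((m - counts) / sig).ravel())[fp]
        return resid

    res = least_squares(make_resid(sigma), x0, bounds=(lo, hi), x_scale="jac",
                        max_nfev=max_nfev, ftol=1e-8, xtol=1e-8)
    # second pass with model-based Poisson weights: observed-count weights
    # overweight downward fluctuations and bias the widths low
    m1, _ = model(res.x)
    sigma = np.sqrt(np.maximum(m1, 1.0))
    res = least_squares(make_resid(sigma), res.x, bounds=(lo, hi), x_scale="jac",
                        max_nfev=max_nfev, ftol=1e-8, xtol=1e-8)
    _, params = model(res.x)
    dof = max(int(fp.sum()) - 7, 1)
    chi2 = float(2.0 * res.cost / dof)
    stderr = {}
    names = ["mu_phi", "mu_2theta", "sigma_phi", "sigma_2theta", "rho",
             "amplitude", "background2d"]
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac)
        stderr = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except np.linalg.LinAlgError:
        pass
    return BVGFitResult(params=params, chi2=chi2, stderr=stderr)


def fit_bvg_voxel(
    grid: VoxelGrid,
    mask: np.ndarray,
    radial_weight: np.ndarray,
    center_seed: tuple,
    n_phi: int = 50,
    n_two_theta: int = 50,
    min_occupied: int = 25,
    max_nfev: int = 120,
) -> BVGFitResult:
    """BVG fit against the angular marginal of the *voxelized* peak model.

    Events are histogrammed to voxel centers before any marginal is built, so
    the observed angular histogram is the BVG filtered through the voxel
    grid; the voxel angular footprint (typically larger than an angular
    cell) aliases a cell-center analytic model and inflates chi^2.  Here the
    per-cell model is the exact marginal of the 3D model: the BVG evaluated
    at voxel centers, weighted by the fitted radial profile mass
    ``radial_weight`` and binned with the data's own cells.  The data are
    full radial column sums (no mask truncation, no fluctuation selection);
    the background scales with the voxel count per cell; the fit is windowed
    to the mask's angular footprint.

    The ``min_occupied`` rule is evaluated on the *masked* histogram — the
    quantity that decides whether a weak peak can support a free angular fit.
    """
    phi_c, tth_c, ang_masked, fp_mask, _ = angular_histogram(
        grid, mask, n_phi=n_phi, n_two_theta=n_two_theta
    )
    occupied = int(np.count_nonzero(ang_masked[fp_mask]))
    if occupied < min_occupied:
        raise InsufficientCountsError(
            f"only {occupied} occupied angular cells (need >= {min_occupied})"
        )
    _, _, ang_full, _, cover_full = angular_histogram(
        grid, None, n_phi=n_phi, n_two_theta=n_two_theta
    )
    _, phi_v, tth_v = grid.voxel_spherical
    pv, tv = phi_v.ravel(), tth_v.ravel()
    phi_edges = np.linspace(pv.min(), pv.max(), n_phi + 1)
    tth_edges = np.linspace(tv.min(), tv.max(), n_two_theta + 1)
    ci = (
        np.clip(np.digitize(pv, phi_edges) - 1, 0, n_phi - 1) * n_two_theta
        + np.clip(np.digitize(tv, tth_edges) - 1, 0, n_two_theta - 1)
    )
    w_r = np.asarray(radial_weight, dtype=float).ravel()
    if not np.any(w_r > 0):
        raise UnfittablePeakError("radial weight carries no profile mass")
    data = ang_full.ravel()
    cover = cover_full.ravel()
    fpr = fp_mask.ravel()
    ncells = n_phi * n_two_theta

    # moment seeds from the masked histogram
    pp, tt = np.meshgrid(phi_c, tth_c, indexing="ij")
    tot_m = max(ang_masked.sum(), 1.0)
    wm = ang_masked / tot_m
    mu_p0 = 0.5 * (float((wm * pp).sum()) + center_seed[0])
    mu_t0 = 0.5 * (float((wm * tt).sum()) + center_seed[1])
    sp0 = max(np.sqrt(max(float((wm * (pp - mu_p0) ** 2).sum()), 0.0)),
              (phi_c[1] - phi_c[0]) / 2.0)
    st0 = max(np.sqrt(max(float((wm * (tt - mu_t0) ** 2).sum()), 0.0)),
              (tth_c[1] - tth_c[0]) / 2.0)
    amp0 = float(tot_m)
    bg0 = max(float((data.sum() - amp0) / max(cover.sum(), 1.0)), 0.0)

    def cellmodel(x):
        mu_p, mu_t, sp, st, rho, amp, bg = x
        xn = (pv - mu_p) / sp
        yn = (tv - mu_t) / st
        dens = np.exp(-0.5 * (xn * xn - 2.0 * rho * xn * yn + yn * yn)
                      / (1.0 - rho * rho))
        ker = np.bincount(ci, weights=dens * w_r, minlength=ncells)
        tot = ker.sum()
        if tot <= 0:
            return np.full(ncells, np.inf)
        return amp * ker / tot + bg * cover

    x0 = np.array([mu_p0, mu_t0, sp0, st0, 0.0, amp0, bg0])
    lo = [phi_c[0], tth_c[0], (phi_c[1] - phi_c[0]) / 4.0,
          (tth_c[1] - tth_c[0]) / 4.0, -0.98, 0.0, 0.0]
    hi = [phi_c[-1], tth_c[-1], phi_c[-1] - phi_c[0], tth_c[-1] - tth_c[0],
          0.98, np.inf, np.inf]
    x0 = np.clip(x0, lo, hi)

    def make_resid(sig):
        def resid(x):
            return ((cellmodel(x) - data) / sig)[fpr]
        return resid

    sig = _poisson_sigma(data)
    res = least_squares(make_resid(sig), x0, bounds=(lo, hi), x_scale="jac",
                        max_nfev=max_nfev, ftol=1e-8, xtol=1e-8)
    sig = np.sqrt(np.maximum(cellmodel(res.x), 1.0))
    res = least_squares(make_resid(sig), res.x, bounds=(lo, hi), x_scale="jac",
                        max_nfev=max_nfev, ftol=1e-8, xtol=1e-8)
    x = res.x
    params = BVGParams(
        mu_phi=x[0], mu_2theta=x[1], sigma_phi=x[2], sigma_2theta=x[3],
        rho=x[4], amplitude=x[5], background2d=x[6],
    )
    dof = max(int(fpr.sum()) - 7, 1)
    chi2 = float(2.0 * res.cost / dof)
    stderr = {}
    names = ["mu_phi", "mu_2theta", "sigma_phi", "sigma_2theta", "rho",
             "amplitude", "background2d"]
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac)
        stderr = dict(zip(names, np.sqrt(np.maximum(np.diag(cov), 0.0))))
    except np.linalg.LinAlgError:
        pass
    return BVGFitResult(params=params, chi2=chi2, stderr=stderr)


# --------------------------------------------------------------- 3D scaling


@dataclass(frozen=True)
class ScaleResult:
    A: float
    B: float
    sigma_A: float
    sigma_B: float
    chi2: float
    shape: np.ndarray      # normalized 3D profile S, unit sum over the box
    accessible: np.ndarray


def assemble_and_scale(
    grid: VoxelGrid,
    tof_fit: TOFFitResult,
    bvg: BVGParams,
    flight_path: float,
    accessible: np.ndarray | None = None,
) -> ScaleResult:
    """Build the normalized 3D profile S = psi_IC(t(v)) * psi_BVG(angles(v))
    (with the proper q-space Jacobians) and solve counts ~= A*S + B by
    weighted linear least squares over the detector-accessible voxels.

    A and B are clipped to be nonnegative: if the closed-form solution turns
    one negative it is pinned to zero and the other refitted.
    """
    counts = grid.counts
    qr, phi, tth = grid.voxel_spherical
    tof = grid.voxel_tof(flight_path)
    dens_t = ic_convolved_density(tof.ravel(), tof_fit.ic, tof_fit.broad).reshape(tof.shape)
    # map densities to per-voxel expected mass: equal-q-volume voxels, so
    # S ∝ p(t)|dt/dq_r| * p(phi,2theta) / (q_r^2 sin 2theta); |dt/dq_r| ∝ t^2
    shape_p = bvg_density(phi, tth, bvg)
    S = dens_t * tof**2 * shape_p / (qr**2 * np.sin(tth))
    tot = S.sum()
    if not np.isfinite(tot) or tot <= 0:
        raise UnfittablePeakError("degenerate 3D profile (no shape mass in box)")
    S = S / tot
    if accessible is None:
        accessible = np.ones_like(counts, dtype=bool)
    s = S[accessible].ravel()
    y = counts[accessible].ravel()
    if s.max() - s.min() < 1e-15:
        raise UnfittablePeakError("degenerate design: constant profile over box")
    # iteratively reweighted linear LS: Poisson variance taken from the
    # *model* (floored at 1), so high-count voxels are not overweighted on
    # downward fluctuations — observed-count weights bias A low
    w = 1.0 / _poisson_sigma(y) ** 2
    A = B = 0.0
    cov_AA = cov_BB = np.inf
    for _ in range(3):
        sw, s2w = (w * s).sum(), (w * s * s).sum()
        yw, syw = (w * y).sum(), (w * s * y).sum()
        wsum = w.sum()
        det = s2w * wsum - sw * sw
        if det <= 0:
            raise UnfittablePeakError("degenerate design in 3D scaling")
        A = (syw * wsum - sw * yw) / det
        B = (s2w * yw - sw * syw) / det
        if A < 0:
            A, B = 0.0, yw / wsum
        if B < 0:
            B, A = 0.0, syw / s2w
        cov_AA = wsum / det
        cov_BB = s2w / det
        w = 1.0 / np.maximum(A * s + B, 1.0)
    resid = (y - A * s - B) * np.sqrt(w)
    dof = max(y.size - 2, 1)
    chi2 = float((resid**2).sum() / dof)
    return ScaleResult(
        A=float(A), B=float(B),
        sigma_A=float(np.sqrt(cov_AA)), sigma_B=float(np.sqrt(cov_BB)),
        chi2=chi2, shape=S, accessible=accessible,
    )


# -------------------------------------------------------------- integration


@dataclass(frozen=True)
class IntensityResult:
    I: float
    sigma_I: float
    b_est: float
    n_peak_voxels: int
    I_masked: float
    sigma_masked: float


def integrate_intensity(
    grid: VoxelGrid,
    mask: np.ndarray,
    scale: ScaleResult,
    model_fraction: float = 0.05,
) -> IntensityResult:
    """Profile-fitted intensity and its variance.

    The peak-voxel set P holds the voxels whose background-subtracted model
    exceeds ``model_fraction`` of its maximum (the 5%-of-max rule);
    I = sum_P A*S(v).  The per-voxel background estimate ``b_est`` is the
    mean count over detector-accessible voxels outside the peak mask, and
    sigma^2(I) = sum_P (N_obs + b_est) + sigma_A^2 (sum_P S)^2.

    Also reports the plain masked summation (counts in the threshold mask
    minus background), the comparator that underestimates truncated peaks.
    """
    S, A = scale.shape, scale.A
    acc = scale.accessible
    P = S > model_fraction * S.max()
    if not np.any(P):
        raise UnfittablePeakError("empty peak-voxel set at the 5% model cut")
    outside = acc & ~mask
    b_est = float(grid.counts[outside].mean()) if np.any(outside) else 0.0
    frac = float(S[P].sum())
    I = A * frac
    pa = P & acc
    var = float(grid.counts[pa].sum()) + b_est * int(pa.sum())
    var_fit = scale.sigma_A**2 * frac**2
    sigma_I = float(np.sqrt(max(var + var_fit, 0.0)))
    ma = mask & acc
    n_masked = int(ma.sum())
    i_masked = float(grid.counts[ma].sum()) - b_est * n_masked
    sigma_masked = float(np.sqrt(max(grid.counts[ma].sum() + b_est * n_masked, 0.0)))
    return IntensityResult(
        I=float(I), sigma_I=sigma_I, b_est=b_est, n_peak_voxels=int(P.sum()),
        I_masked=i_masked, sigma_masked=sigma_masked,
    )


# ------------------------------------------------------------- result record


@dataclass
class PeakFitResult:
    """Everything the pipeline knows about one fitted peak."""

    peak: tuple
    q_r: float = np.nan
    phi_az: float = np.nan
    two_theta: float = np.nan
    wavelength: float = np.nan
    n_events_spherical: int = 0
    edge_px: int = -1
    classification: str = ""
    method: str = "profile"
    A: float = np.nan
    sigma_A: float = np.nan
    B: float = np.nan
    I: float = np.nan
    sigma_I: float = np.nan
    I_masked: float = np.nan
    I_spherical: float = np.nan
    sigma_spherical: float = np.nan
    chi2_tof: float = np.nan
    chi2_bvg: float = np.nan
    chi2_3d: float = np.nan
    bg_level: float = np.nan
    b_est: float = np.nan
    ic: ICParams | None = None
    broad: BroadeningParams | None = None
    bvg: BVGParams | None = None
    bvg_stderr: dict = field(default_factory=dict)
    tof_stderr: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)

    @property
    def rejected(self) -> bool:
        return any(f.startswith("rejected") for f in self.flags)

    @property
    def i_over_sigma(self) -> float:
        if self.sigma_I > 0:
            return self.I / self.sigma_I
        return np.nan
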