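"""Per-peak reciprocal-space voxel histograms and their marginals.

Each predicted peak (h, k, l) gets a cubic box in fractional-hkl space from
(h - eta, k - eta, l - eta) to (h + eta, k + eta, l + eta), histogrammed on an
odd number of voxels per side so the predicted position is a voxel center.
All downstream fitting operates on this grid and on two marginals under a
voxel mask: a 1D TOF histogram (radial direction) and a 2D angular histogram
in (phi_az, two_theta).

The TOF coordinate of a voxel is computed with the *peak's* Bragg angle held
fixed, t(v) = coef * L * sin(theta_peak) / |q_v|, so the TOF axis is a pure
|q| coordinate and the angular extent of the peak does not smear the TOF
profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import TOF_COEF, UBMatrix, q_to_spherical

__all__ = [
    "VoxelGrid",
    "EmptyGridError",
    "build_grid",
    "smooth_grid",
    "threshold_mask",
    "tof_histogram",
    "angular_histogram",
]


class EmptyGridError(ValueError):
    """No events fell inside the peak's reciprocal-space box."""


@dataclass
class VoxelGrid:
    """3D event histogram over one peak's reciprocal-space box."""

    counts: np.ndarray
    peak: tuple
    eta: float
    ub: UBMatrix
    _cache: dict = field(default_factory=dict, repr=False)

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def frac_axes(self):
        """Voxel-center coordinates along each axis, in fractional hkl."""
        if "frac_axes" not in self._cache:
            n = self.n
            step = 2.0 * self.eta / n
            offs = -self.eta + (np.arange(n) + 0.5) * step
            self._cache["frac_axes"] = tuple(
                np.asarray(self.peak)[i] + offs for i in range(3)
            )
        return self._cache["frac_axes"]

    @property
    def center_index(self) -> tuple:
        c = (self.n - 1) // 2
        return (c, c, c)

    @property
    def q_center(self) -> np.ndarray:
        return self.ub.hkl_to_q(np.asarray(self.peak, dtype=float))

    @property
    def voxel_q(self) -> np.ndarray:
        """(n, n, n, 3) array of voxel-center q-vectors."""
        if "voxel_q" not in self._cache:
            ax = self.frac_axes
            frac = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
            self._cache["voxel_q"] = 2.0 * np.pi * frac @ self.ub.matrix.T
        return self._cache["voxel_q"]

    @property
    def voxel_spherical(self):
        """(q_r, phi_az, two_theta) arrays of shape (n, n, n)."""
        if "voxel_sph" not in self._cache:
            self._cache["voxel_sph"] = q_to_spherical(self.voxel_q)
        return self._cache["voxel_sph"]

    def radial_voxel_sigma(self, flight_path: float) -> float:
        """Gaussian-equivalent TOF smearing (us) of one voxel's radial extent.

        Events anywhere in a voxel share the voxel-center TOF, which smears
        the radial profile by the voxel's extent along the q direction; the
        top-hat window is summarized as a Gaussian of width extent/sqrt(12).
        """
        q0 = self.q_center
        qr0 = float(np.linalg.norm(q0))
        qhat = q0 / qr0
        basis = 2.0 * np.pi * self.ub.matrix  # columns: q per unit h,k,l
        step = 2.0 * self.eta / self.n
        dq = float(np.abs(qhat @ basis).sum()) * step
        _, _, tth0 = q_to_spherical(q0)
        t0 = TOF_COEF * flight_path * np.sin(tth0 / 2.0) / qr0
        return t0 * dq / qr0 / np.sqrt(12.0)

    def voxel_tof(self, flight_path: float) -> np.ndarray:
        """Radial TOF coordinate (us) of each voxel, peak Bragg angle frozen."""
        key = ("voxel_tof", flight_path)
        if key not in self._cache:
            qr, _, _ = self.voxel_spherical
            _, _, tth0 = q_to_spherical(self.q_center)
            self._cache[key] = (
                TOF_COEF * flight_path * np.sin(tth0 / 2.0) / qr
            )
        return self._cache[key]


def build_grid(
    events_q: np.ndarray,
    peak,
    ub: UBMatrix,
    eta: float = 0.25,
    voxels_per_side: int = 31,
) -> VoxelGrid:
    """Histogram events into the peak's (h +/- eta, k +/- eta, l +/- eta) box.

    ``events_q`` is an (N, 3) array of q-vectors (Angstrom^-1).  Every event
    whose fractional hkl falls in the closed box is counted exactly once.
    """
    if not (0.1 <= eta <= 1.0):
        raise ValueError(f"eta must lie in [0.1, 1.0], got {eta}")
    if voxels_per_side % 2 != 1 or voxels_per_side < 3:
        raise ValueError("voxels_per_side must be odd and >= 3")
    peak = tuple(float(v) for v in np.asarray(peak, dtype=float))
    events_q = np.atleast_2d(np.asarray(events_q, dtype=float))
    if events_q.size == 0:
        raise EmptyGridError(f"no events in box around peak {peak}")
    off = ub.q_to_hkl(events_q) - np.asarray(peak)
    inbox = np.all(np.abs(off) <= eta, axis=1)
    if not np.any(inbox):
        raise EmptyGridError(f"no events in box around peak {peak}")
    edges = np.linspace(-eta, eta, voxels_per_side + 1)
    counts, _ = np.histogramdd(off[inbox], bins=(edges, edges, edges))
    return VoxelGrid(counts=counts, peak=peak, eta=eta, ub=ub)


def smooth_grid(grid) -> np.ndarray:
    """Nearest-neighbors smoothing: mean over each voxel's 3x3x3 neighborhood.

    Edge voxels average over their truncated neighborhood, so a constant
    grid maps to itself everywhere.  Accepts a VoxelGrid or a bare array.
    """
    counts = grid.counts if isinstance(grid, VoxelGrid) else np.asarray(grid, float)
    if counts.sum() == 0:
        raise EmptyGridError("cannot smooth an empty grid")
    kernel_sum = ndimage.uniform_filter(counts.astype(float), size=3, mode="constant") * 27.0
    nbrs = ndimage.uniform_filter(np.ones_like(counts, dtype=float), size=3, mode="constant") * 27.0
    return kernel_sum / nbrs


class EmptyMaskError(ValueError):
    """The threshold level leaves no voxel above it."""


def threshold_mask(smoothed: np.ndarray, level: float, center_index=None) -> np.ndarray:
    """Boolean peak mask: voxels with ``smoothed > level``, restricted to the
    26-connected component containing (or nearest to) the predicted center.

    Ties between equidistant components are broken toward the component with
    the larger total smoothed mass.
    """
    if level < 0:
        raise ValueError("threshold level must be >= 0")
    smoothed = np.asarray(smoothed, dtype=float)
    above = smoothed > level
    if not np.any(above):
        raise EmptyMaskError(f"no voxel above level {level}")
    if center_index is None:
        c = (smoothed.shape[0] - 1) // 2
        center_index = (c,) * smoothed.ndim
    labels, n_comp = ndimage.label(above, structure=np.ones((3,) * smoothed.ndim))
    if n_comp == 1:
        return above
    center_label = labels[tuple(center_index)]
    if center_label > 0:
        return labels == center_label
    # center not above threshold: nearest component, mass-weighted tie-break
    idx = np.argwhere(above)
    d2 = np.sum((idx - np.asarray(center_index)) ** 2, axis=1)
    lab_at = labels[above]
    best, best_key = None, None
    for lab in range(1, n_comp + 1):
        sel = lab_at == lab
        key = (d2[sel].min(), -smoothed[labels == lab].sum())
        if best_key is None or key < best_key:
            best, best_key = lab, key
    return labels == best


def angular_capture(
    grid: VoxelGrid,
    mask,
    radial_weight: np.ndarray,
    n_phi: int = 50,
    n_two_theta: int = 50,
) -> np.ndarray:
    """Fraction of the radial profile mass the mask captures, per angular cell.

    ``radial_weight`` is a per-voxel model of the radial (TOF) profile mass;
    the capture fraction is the masked share of its per-cell column sum.
    Cells with no model mass report 0.
    """
    _, phi, tth = grid.voxel_spherical
    phi_edges = np.linspace(phi.min(), phi.max(), n_phi + 1)
    tth_edges = np.linspace(tth.min(), tth.max(), n_two_theta + 1)
    w = np.asarray(radial_weight, float)
    total, _, _ = np.histogram2d(phi.ravel(), tth.ravel(),
                                 bins=(phi_edges, tth_edges), weights=w.ravel())
    if mask is None:
        return np.where(total > 0, 1.0, 0.0)
    got, _, _ = np.histogram2d(phi[mask].ravel(), tth[mask].ravel(),
                               bins=(phi_edges, tth_edges), weights=w[mask].ravel())
    with np.errstate(invalid="ignore", divide="ignore"):
        cap = np.where(total > 0, got / np.maximum(total, 1e-300), 0.0)
    return cap


def tof_histogram(
    grid: VoxelGrid,
    mask,
    flight_path: float,
    n_bins: int | None = None,
):
    """1D TOF marginal of the (masked) voxel counts.

    Bin edges are uniform and span the full box's voxel TOF range regardless
    of the mask, so histograms at different background levels share one grid.
    Returns (bin centers us, counts).
    """
    if grid.counts.sum() == 0:
        raise EmptyGridError("empty grid")
    tof = grid.voxel_tof(flight_path)
    if n_bins is None:
        n_bins = grid.n
    lo, hi = float(tof.min()), float(tof.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    weights = grid.counts if mask is None else np.where(mask, grid.counts, 0.0)
    idx = np.clip(np.digitize(tof.ravel(), edges) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, weights=weights.ravel(), minlength=n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts


def angular_histogram(
    grid: VoxelGrid,
    mask,
    n_phi: int = 50,
    n_two_theta: int = 50,
):
    """2D angular marginal over (phi_az, two_theta), summing the radial axis.

    The binning spans the box's full angular extent.  Returns
    (phi centers, two_theta centers, counts[n_phi, n_two_theta], footprint,
    cover): ``cover`` counts the masked voxels contributing to each cell and
    ``footprint = cover > 0`` flags the cells the mask reaches — cells
    outside it carry no information (they are empty because the mask
    excludes them, not because no neutrons arrived) and should not enter a
    fit as observed zeros.
    """
    if grid.counts.sum() == 0:
        raise EmptyGridError("empty grid")
    _, phi, tth = grid.voxel_spherical
    phi_edges = np.linspace(phi.min(), phi.max(), n_phi + 1)
    tth_edges = np.linspace(tth.min(), tth.max(), n_two_theta + 1)
    weights = grid.counts if mask is None else np.where(mask, grid.counts, 0.0)
    hist, _, _ = np.histogram2d(
        phi.ravel(), tth.ravel(), bins=(phi_edges, tth_edges), weights=weights.ravel()
    )
    if mask is None:
        cover, _, _ = np.histogram2d(phi.ravel(), tth.ravel(),
                                     bins=(phi_edges, tth_edges))
    else:
        cover, _, _ = np.histogram2d(
            phi[mask].ravel(), tth[mask].ravel(), bins=(phi_edges, tth_edges)
        )
    footprint = cover > 0
    phi_c = 0.5 * (phi_edges[:-1] + phi_edges[1:])
    tth_c = 0.5 * (tth_edges[:-1] + tth_edges[1:])
    return phi_c, tth_c, hist, footprint, cover
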