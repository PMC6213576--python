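"""Spherical peak-minus-background integration.

The traditional comparator to profile fitting: sum events inside a sphere of
radius ``r_peak`` around the predicted q position, subtract the local
background measured in a surrounding shell with the geometric volume scaling
``f = r_peak^3 / (r_bg_outer^3 - r_bg_inner^3)``::

    I        = N_pk - f * N_shell
    sigma^2  = N_pk + f^2 * N_shell

Counts are exact integers when operating on raw events; ``n_events`` (used by
the 250/500-event weak/strong classification) is the raw in-sphere count
before background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SphericalConfig", "SphericalResult", "integrate_spherical"]


@dataclass(frozen=True)
class SphericalConfig:
    """Integration radii (Angstrom^-1): 0 < r_peak <= r_bg_inner < r_bg_outer.

    Defaults follow common practice for medium-resolution macromolecular
    data (0.021 / 0.022 / 0.026); ``alternate()`` gives the tighter preset
    (0.018 / 0.019 / 0.022) used for smaller peaks.
    """

    r_peak: float = 0.021
    r_bg_inner: float = 0.022
    r_bg_outer: float = 0.026

    def __post_init__(self) -> None:
        if not (0.0 < self.r_peak <= self.r_bg_inner < self.r_bg_outer):
            raise ValueError(
                "radii must satisfy 0 < r_peak <= r_bg_inner < r_bg_outer"
            )

    @classmethod
    def alternate(cls) -> "SphericalConfig":
        return cls(r_peak=0.018, r_bg_inner=0.019, r_bg_outer=0.022)

    @property
    def bg_scale(self) -> float:
        return self.r_peak**3 / (self.r_bg_outer**3 - self.r_bg_inner**3)


@dataclass(frozen=True)
class SphericalResult:
    I: float
    sigma_I: float
    n_events: int
    n_shell: int


def integrate_spherical(events_q, q_center, cfg: SphericalConfig = SphericalConfig()) -> SphericalResult:
    """Integrate a peak from raw events (N, 3 q-vectors) or from a VoxelGrid
    (voxel-center membership decides the voxel case)."""
    from .histogramming import VoxelGrid

    q_center = np.asarray(q_center, dtype=float)
    if isinstance(events_q, VoxelGrid):
        pts = events_q.voxel_q.reshape(-1, 3)
        wts = events_q.counts.ravel()
    else:
        pts = np.atleast_2d(np.asarray(events_q, dtype=float))
        wts = None
    if pts.size == 0:
        return SphericalResult(I=0.0, sigma_I=0.0, n_events=0, n_shell=0)
    d2 = np.sum((pts - q_center) ** 2, axis=1)
    in_peak = d2 <= cfg.r_peak**2
    in_shell = (d2 >= cfg.r_bg_inner**2) & (d2 <= cfg.r_bg_outer**2)
    if wts is None:
        n_pk = int(np.count_nonzero(in_peak))
        n_sh = int(np.count_nonzero(in_shell))
    else:
        n_pk = int(wts[in_peak].sum())
        n_sh = int(wts[in_shell].sum())
    f = cfg.bg_scale
    intensity = n_pk - f * n_sh
    sigma = float(np.sqrt(n_pk + f**2 * n_sh)) if (n_pk or n_sh) else 0.0
    return SphericalResult(I=float(intensity), sigma_I=sigma, n_events=n_pk, n_shell=n_sh)
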