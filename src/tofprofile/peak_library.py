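"""Strong-peak profile library and transfer to weak / detector-edge peaks.

Bright reflections (> 500 events by spherical integration) donate their
fitted angular shapes (sigma_phi, sigma_2theta, rho) to a library indexed by
position on the sphere (phi_az, two_theta).  Peaks too weak to support a free
bivariate-Gaussian fit (< 250 events) and peaks predicted within 15 pixels of
a detector edge borrow the shape of their nearest library neighbor; the TOF
direction is always fitted directly from the moderator characterization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .profile_fitting import BVGParams

__all__ = [
    "LibraryEntry",
    "StrongPeakLibrary",
    "EmptyLibraryError",
    "classify_peak",
    "build_library",
]

STRONG_MIN_EVENTS = 500
WEAK_MAX_EVENTS = 250
EDGE_MAX_PIXELS = 15


class EmptyLibraryError(RuntimeError):
    """Weak/edge peaks need a profile library but none is available."""


@dataclass(frozen=True)
class LibraryEntry:
    phi_az: float
    two_theta: float
    sigma_phi: float
    sigma_2theta: float
    rho: float
    n_events: int
    peak: tuple

    def shape(self, mu_phi: float, mu_2theta: float) -> BVGParams:
        """The stored shape re-centered on a target peak position."""
        return BVGParams(
            mu_phi=mu_phi, mu_2theta=mu_2theta,
            sigma_phi=self.sigma_phi, sigma_2theta=self.sigma_2theta,
            rho=self.rho,
        )


@dataclass
class StrongPeakLibrary:
    entries: list = field(default_factory=list)
    strong_min_events: int = STRONG_MIN_EVENTS
    weak_max_events: int = WEAK_MAX_EVENTS
    edge_max_pixels: int = EDGE_MAX_PIXELS

    def __post_init__(self) -> None:
        if not (0 < self.weak_max_events < self.strong_min_events):
            raise ValueError("thresholds must satisfy 0 < weak_max < strong_min")
        if self.edge_max_pixels <= 0:
            raise ValueError("edge_max_pixels must be positive")

    def __len__(self) -> int:
        return len(self.entries)

    def lookup_nearest(self, phi_az: float, two_theta: float) -> LibraryEntry:
        """Entry minimizing Euclidean distance in (phi_az, two_theta), with
        azimuthal wrap-around; ties break to larger n_events, then
        lexicographic hkl."""
        if not self.entries:
            raise EmptyLibraryError(
                "strong-peak library is empty: run (or load) a strong-peak "
                "pass before integrating weak or edge peaks"
            )
        dphi = np.array([e.phi_az for e in self.entries]) - phi_az
        dphi = np.mod(dphi + np.pi, 2.0 * np.pi) - np.pi
        dtth = np.array([e.two_theta for e in self.entries]) - two_theta
        d2 = dphi**2 + dtth**2
        order = sorted(
            range(len(self.entries)),
            key=lambda i: (d2[i], -self.entries[i].n_events, self.entries[i].peak),
        )
        return self.entries[order[0]]

    # ------------------------------------------------------------------ io
    def to_json(self, path) -> None:
        doc = {
            "format": "tofprofile-peak-library",
            "version": 1,
            "thresholds": {
                "strong_min_events": self.strong_min_events,
                "weak_max_events": self.weak_max_events,
                "edge_max_pixels": self.edge_max_pixels,
            },
            "entries": [
                {
                    "peak": list(e.peak),
                    "phi_az": e.phi_az,
                    "two_theta": e.two_theta,
                    "sigma_phi": e.sigma_phi,
                    "sigma_2theta": e.sigma_2theta,
                    "rho": e.rho,
                    "n_events": e.n_events,
                }
                for e in self.entries
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "StrongPeakLibrary":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "tofprofile-peak-library":
            raise ValueError(f"{path!r} is not a peak-library file")
        th = doc.get("thresholds", {})
        lib = cls(
            strong_min_events=th.get("strong_min_events", STRONG_MIN_EVENTS),
            weak_max_events=th.get("weak_max_events", WEAK_MAX_EVENTS),
            edge_max_pixels=th.get("edge_max_pixels", EDGE_MAX_PIXELS),
        )
        for e in doc["entries"]:
            lib.entries.append(
                LibraryEntry(
                    phi_az=e["phi_az"], two_theta=e["two_theta"],
                    sigma_phi=e["sigma_phi"], sigma_2theta=e["sigma_2theta"],
                    rho=e["rho"], n_events=e["n_events"], peak=tuple(e["peak"]),
                )
            )
        return lib


def classify_peak(
    n_events_spherical: int,
    edge_px: int,
    weak_max_events: int = WEAK_MAX_EVENTS,
    strong_min_events: int = STRONG_MIN_EVENTS,
    edge_max_pixels: int = EDGE_MAX_PIXELS,
) -> str:
    """Route a peak: 'weak' (< 250 events), 'edge' (<= 15 px from a panel
    edge, any brightness), 'weak+edge', 'strong' (> 500 events, off-edge,
    library-eligible) or 'intermediate' (250-500 events: free fit, never
    enters the library).  ``edge_px < 0`` means off-detector."""
    weak = n_events_spherical < weak_max_events
    edge = 0 <= edge_px <= edge_max_pixels
    if weak and edge:
        return "weak+edge"
    if weak:
        return "weak"
    if edge:
        return "edge"
    if n_events_spherical > strong_min_events:
        return "strong"
    return "intermediate"


def build_library(
    results,
    chi2_max: float = 50.0,
    strong_min_events: int = STRONG_MIN_EVENTS,
) -> StrongPeakLibrary:
    """Collect every accepted strong peak (> strong_min_events spherical
    events, off-edge, convergent BVG fit with acceptable chi^2) into a
    shape-only library."""
    lib = StrongPeakLibrary(strong_min_events=strong_min_events)
    for r in results:
        if r.bvg is None or r.classification != "strong":
            continue
        if not (r.n_events_spherical > strong_min_events):
            continue
        if not np.isfinite(r.chi2_bvg) or r.chi2_bvg > chi2_max:
            continue
        if any(f.startswith("rejected") for f in r.flags):
            continue
        lib.entries.append(
            LibraryEntry(
                phi_az=r.phi_az, two_theta=r.two_theta,
                sigma_phi=r.bvg.sigma_phi, sigma_2theta=r.bvg.sigma_2theta,
                rho=r.bvg.rho, n_events=int(r.n_events_spherical),
                peak=tuple(int(v) for v in r.peak),
            )
        )
    return lib
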