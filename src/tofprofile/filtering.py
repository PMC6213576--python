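"""Rejection filters and reflection-file output.

A reflection survives only if all three per-stage goodness-of-fit values
(TOF, BVG, 3D scaling) are at most ``chi2_max``, its I/sigma(I) reaches
``i_over_sigma_min`` under *both* integration methods (profile fitting and
spherical integration), and its center is at least ``min_edge_px`` pixels
from a detector edge.  Filtering is method-symmetric: both output files carry
the identical reflection set, differing only in intensities and errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RejectionRules", "apply_filters", "write_reflections", "results_table"]


@dataclass(frozen=True)
class RejectionRules:
    chi2_max: float = 50.0
    i_over_sigma_min: float = 1.0
    min_edge_px: int = 2  # reject centers <= 1 pixel from the edge

    def __post_init__(self) -> None:
        if self.chi2_max <= 0 or self.i_over_sigma_min <= 0 or self.min_edge_px <= 0:
            raise ValueError("all rejection thresholds must be positive")


def _profile_reasons(r, rules: RejectionRules) -> list:
    reasons = []
    for name, val in (("tof", r.chi2_tof), ("bvg", r.chi2_bvg), ("3d", r.chi2_3d)):
        if not np.isfinite(val):
            # chi2_bvg is undefined on the library-transfer path: not a defect
            if name == "bvg" and r.bvg is not None:
                continue
            reasons.append(f"chi2_{name}_undefined")
        elif val > rules.chi2_max:
            reasons.append(f"chi2_{name}>{rules.chi2_max:g}")
    if not (np.isfinite(r.I) and np.isfinite(r.sigma_I) and r.sigma_I > 0):
        reasons.append("profile_fit_failed")
    elif r.I / r.sigma_I < rules.i_over_sigma_min:
        reasons.append(f"profile_i_over_sigma<{rules.i_over_sigma_min:g}")
    if r.edge_px >= 0 and r.edge_px < rules.min_edge_px:
        reasons.append(f"edge_px<{rules.min_edge_px}")
    for f in r.flags:
        if f.startswith("rejected:"):
            reasons.append(f.split(":", 1)[1])
    return reasons


def apply_filters(
    results_profile,
    results_spherical,
    rules: RejectionRules = RejectionRules(),
):
    """Apply the rejection rules to paired profile/spherical results.

    Both sequences must cover the identical peak set.  Returns
    ``(accepted_peaks, reasons)`` where ``reasons`` maps each rejected peak
    to the list of rules it violated (a machine-readable partition of the
    rejected set).
    """
    prof = {tuple(r.peak): r for r in results_profile}
    sph = {tuple(r.peak): r for r in results_spherical}
    if set(prof) != set(sph):
        raise ValueError(
            "profile and spherical result sets cover different peaks"
        )
    accepted, reasons = [], {}
    for peak in sorted(prof):
        r, s = prof[peak], sph[peak]
        why = _profile_reasons(r, rules)
        if not (np.isfinite(s.I) and np.isfinite(s.sigma_I) and s.sigma_I > 0):
            why.append("spherical_no_counts")
        elif s.I / s.sigma_I < rules.i_over_sigma_min:
            why.append(f"spherical_i_over_sigma<{rules.i_over_sigma_min:g}")
        if why:
            reasons[peak] = why
        else:
            accepted.append(peak)
    return accepted, reasons


def write_reflections(results, accepted, path, fmt: str = "hkl") -> None:
    """Write accepted reflections.

    ``fmt='hkl'``: SHELX-style fixed-width lines ``h(4) k(4) l(4) I(8.1f)
    sigma(8.1f)``.  ``fmt='tsv'``: full diagnostics (intensities, background,
    per-stage chi^2, angles, wavelength, classification, flags).
    """
    by_peak = {tuple(r.peak): r for r in results}
    rows = [by_peak[tuple(p)] for p in accepted]
    if fmt == "hkl":
        with open(path, "w") as fh:
            for r in rows:
                h, k, l = (int(round(v)) for v in r.peak)
                fh.write(f"{h:4d}{k:4d}{l:4d}{r.I:8.1f}{r.sigma_I:8.1f}\n")
    elif fmt == "tsv":
        results_table(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")
    else:
        raise ValueError(f"unknown reflection format {fmt!r}")


def results_table(results) -> pd.DataFrame:
    """Tabulate fit results (one row per peak) for reports and diagnostics."""
    recs = []
    for r in results:
        h, k, l = (int(round(v)) for v in r.peak)
        recs.append(
            {
                "h": h, "k": k, "l": l,
                "method": r.method,
                "I": r.I, "sigma_I": r.sigma_I,
                "I_masked": r.I_masked,
                "I_spherical": r.I_spherical,
                "sigma_spherical": r.sigma_spherical,
                "A": r.A, "B": r.B, "b_est": r.b_est,
                "chi2_tof": r.chi2_tof, "chi2_bvg": r.chi2_bvg,
                "chi2_3d": r.chi2_3d,
                "q_r": r.q_r, "phi_az": r.phi_az, "two_theta": r.two_theta,
                "wavelength": r.wavelength,
                "n_events": r.n_events_spherical, "edge_px": r.edge_px,
                "classification": r.classification,
                "flags": ";".join(r.flags),
            }
        )
    return pd.DataFrame.from_records(recs)
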