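"""Run configuration for the integration pipeline."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields

from .filtering import RejectionRules
from .spherical import SphericalConfig

__all__ = ["IntegrationConfig"]


@dataclass
class IntegrationConfig:
    """Everything the pipeline needs besides the data itself.

    eta: reciprocal-space box half-width in fractional hkl (working value
    0.25; anywhere in 0.2-0.5 changes intensities little).
    voxels_per_side: odd voxel count per box edge (31 keeps >= 5 voxels
    across a typical peak FWHM).  sigma_g / pulse_width are instrument
    timing constants (us) seeding the TOF fit.
    """

    eta: float = 0.25
    voxels_per_side: int = 31
    n_bg_levels: int = 16
    bg_quantile_range: tuple = (0.5, 0.995)
    n_tof_bins: int | None = None
    n_phi_bins: int = 50
    n_two_theta_bins: int = 50
    min_occupied_cells: int = 25
    sigma_g: float = 8.0
    pulse_width: float = 10.0
    model_fraction: float = 0.05
    strong_min_events: int = 500
    weak_max_events: int = 250
    edge_max_pixels: int = 15
    seed: int = 0
    spherical: SphericalConfig = field(default_factory=SphericalConfig)
    rules: RejectionRules = field(default_factory=RejectionRules)

    @classmethod
    def from_toml(cls, path) -> "IntegrationConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        kwargs = {}
        simple = {f.name for f in fields(cls)} - {"spherical", "rules"}
        for key, val in doc.get("integration", {}).items():
            if key not in simple:
                raise ValueError(f"unknown integration option {key!r}")
            kwargs[key] = tuple(val) if key == "bg_quantile_range" else val
        if "spherical" in doc:
            kwargs["spherical"] = SphericalConfig(**doc["spherical"])
        if "rejection" in doc:
            kwargs["rules"] = RejectionRules(**doc["rejection"])
        return cls(**kwargs)
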