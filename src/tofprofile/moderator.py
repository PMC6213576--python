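"""Moderator emission model: Ikeda-Carpenter profile, broadening, Pade tables.

The emission-time density of a pulsed-source moderator is modelled by the
Ikeda-Carpenter (IC) function with a fast (storage) term decaying at rate
``alpha`` and a slow term at rate ``beta`` carrying a fraction ``R`` of the
neutrons::

    psi(t') = (1 - R) * (alpha^3 t'^2 / 2) exp(-alpha t')
            + R * alpha^3 beta / (alpha - beta)^3
              * { exp(-beta t')
                  - exp(-alpha t') [1 + (alpha-beta) t' + (alpha-beta)^2 t'^2 / 2] }

with ``t' = t - t0`` and ``psi = 0`` for ``t' <= 0``.  The density is
normalized: its integral over t' in [0, inf) is exactly 1 for any valid
parameter set.

Energy dependence of (alpha, beta, R, t0) is carried by fourth-order Pade
approximants in ``x = log10(E / eV)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ICParams",
    "BroadeningParams",
    "PadeSeries",
    "ModeratorTable",
    "default_table",
    "fit_pade",
    "ic_profile",
    "ic_convolved",
    "ic_convolved_density",
    "initial_guess",
]


@dataclass(frozen=True)
class ICParams:
    """Ikeda-Carpenter parameters.

    alpha, beta in 1/us (alpha > beta > 0), R in [0, 1], t0 in us.
    """

    alpha: float
    beta: float
    R: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError("alpha and beta must be positive")
        if self.alpha <= self.beta:
            raise ValueError(
                f"IC function requires alpha > beta (got alpha={self.alpha}, "
                f"beta={self.beta}); alpha = beta is singular"
            )
        if not (0.0 <= self.R <= 1.0):
            raise ValueError("R must lie in [0, 1]")


@dataclass(frozen=True)
class BroadeningParams:
    """Gaussian / top-hat broadening of the emission profile.

    sigma_g: Gaussian width (us) for detector time resolution;
    pulse_width: full width (us) of the proton-pulse top-hat;
    sigma_vox: Gaussian equivalent (us) of the radial voxel window when the
    profile is evaluated on voxelized data — a discretization term, never
    fitted;
    scale: integrated profile amplitude (counts);
    background: flat TOF background (counts per bin).
    """

    sigma_g: float = 0.0
    pulse_width: float = 0.0
    sigma_vox: float = 0.0
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_g, self.pulse_width, self.sigma_vox, self.scale) < 0:
            raise ValueError("sigma_g, pulse_width, sigma_vox, scale must be >= 0")

    @property
    def sigma_eff(self) -> float:
        """Total Gaussian smearing: timing jitter plus voxel window."""
        return float(np.hypot(self.sigma_g, self.sigma_vox))


def ic_profile(tprime, p: ICParams) -> np.ndarray:
    """Normalized IC emission density evaluated at ``t' = t - t0`` (1/us).

    ``tprime`` is measured from the absolute time origin: the shift by
    ``p.t0`` is applied internally, i.e. the density is zero for
    ``tprime <= p.t0``.
    """
    t = np.asarray(tprime, dtype=float) - p.t0
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    a, b, r = p.alpha, p.beta, p.R
    fast = (a**3 * tp**2 / 2.0) * np.exp(-a * tp)
    d = a - b
    slow = (a**3 * b / d**3) * (
        np.exp(-b * tp)
        - np.exp(-a * tp) * (1.0 + d * tp + 0.5 * d**2 * tp**2)
    )
    out[pos] = (1.0 - r) * fast + r * slow
    return out


def _fine_grid(t, p: ICParams, b: BroadeningParams):
    """Oversampled uniform grid spanning the bin grid plus kernel margins."""
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two bin centers")
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("convolution requires a uniform bin grid")
    width = dt[0]
    # resolve both the IC rise (~1/alpha) and the broadening kernels
    step = width / 4.0
    step = min(step, 0.5 / p.alpha)
    sig = b.sigma_eff
    if sig > 0:
        step = min(step, sig / 3.0)
    if b.pulse_width > 0:
        step = min(step, b.pulse_width / 4.0)
    step = max(step, width / 64.0)  # cap the grid size
    margin = 6.0 * sig + b.pulse_width + 2.0 * width
    lo = t[0] - width / 2.0 - margin
    hi = t[-1] + width / 2.0 + margin
    n = int(np.ceil((hi - lo) / step)) + 1
    return np.linspace(lo, hi, n), width


def _convolved_fine(tf, step, p: ICParams, b: BroadeningParams):
    y = ic_profile(tf, p)
    sig = b.sigma_eff
    if sig > 0:
        half = int(np.ceil(6.0 * sig / step))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) * step / sig) ** 2)
        y = np.convolve(y, k / k.sum(), mode="same")
    if b.pulse_width > 0:
        # symmetric top-hat: odd length, fractional end weights so the
        # kernel width is exactly pulse_width/step samples
        w = b.pulse_width / step
        half = int(np.floor((w - 1.0) / 2.0)) if w > 1.0 else 0
        k = np.ones(2 * half + 3)
        k[0] = k[-1] = max((w - (2 * half + 1)) / 2.0, 0.0)
        y = np.convolve(y, k / k.sum(), mode="same")
    return y


def ic_convolved(t, p: ICParams, b: BroadeningParams, fine_grid=None) -> np.ndarray:
    """Expected counts per bin of the broadened IC profile.

    ``scale * mean_over_bin(psi_IC (x) Gaussian (x) TopHat) * bin_width +
    background``, evaluated on the uniform bin grid ``t`` (bin centers).  The
    counts above background sum to ``scale`` up to discretization and the
    profile mass outside the grid.  With ``sigma_g = pulse_width = 0`` this
    reduces to ``scale * ic_profile(t) * bin_width + background`` exactly.

    ``fine_grid`` (as returned by an earlier call's grid construction) pins
    the oversampled evaluation grid, which keeps the model smooth in its
    parameters during fitting; by default the grid is rebuilt per call.
    """
    t = np.asarray(t, dtype=float)
    if b.sigma_eff == 0.0 and b.pulse_width == 0.0:
        if t.size > 1:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("convolution requires a uniform bin grid")
            width = dt[0]
        else:
            raise ValueError("need at least two bin centers")
        return b.scale * ic_profile(t, p) * width + b.background
    if fine_grid is None:
        tf, width = _fine_grid(t, p, b)
    else:
        tf, width = fine_grid
    step = tf[1] - tf[0]
    y = _convolved_fine(tf, step, p, b)
    # average the fine samples falling inside each bin
    edges = np.concatenate([t - width / 2.0, [t[-1] + width / 2.0]])
    idx = np.digitize(tf, edges) - 1
    ok = (idx >= 0) & (idx < t.size)
    sums = np.bincount(idx[ok], weights=y[ok], minlength=t.size)
    cnts = np.bincount(idx[ok], minlength=t.size)
    mean = np.where(cnts > 0, sums / np.maximum(cnts, 1), 0.0)
    return b.scale * mean * width + b.background


def ic_convolved_density(t_eval, p: ICParams, b: BroadeningParams) -> np.ndarray:
    """Broadened IC *density* (1/us) at arbitrary times, via interpolation
    on an oversampled grid.  Ignores ``scale`` and ``background``."""
    t_eval = np.asarray(t_eval, dtype=float)
    lo, hi = float(np.min(t_eval)), float(np.max(t_eval))
    if b.sigma_eff == 0.0 and b.pulse_width == 0.0:
        return ic_profile(t_eval, p)
    span = max(hi - lo, 1.0)
    step = min(span / 2000.0, 0.5 / p.alpha)
    sig = b.sigma_eff
    if sig > 0:
        step = min(step, sig / 3.0)
    step = max(step, span / 60000.0)
    margin = 6.0 * sig + b.pulse_width
    tf = np.arange(lo - margin, hi + margin + step, step)
    y = _convolved_fine(tf, step, p, b)
    return np.interp(t_eval, tf, y)


# --------------------------------------------------------------------- Pade


@dataclass(frozen=True)
class PadeSeries:
    """Fourth-order Pade approximant P(x) = N4(x) / (1 + b1 x + ... + b4 x^4)."""

    a: tuple  # a0..a4
    b: tuple  # b1..b4

    def __post_init__(self) -> None:
        if len(self.a) != 5 or len(self.b) != 4:
            raise ValueError("PadeSeries needs 5 numerator and 4 denominator coefficients")

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        num = sum(c * x**i for i, c in enumerate(self.a))
        den = 1.0 + sum(c * x ** (i + 1) for i, c in enumerate(self.b))
        return num / den


def fit_pade(x, y) -> PadeSeries:
    """Fit a fourth-order Pade approximant by linearized least squares.

    Solves ``y * (1 + sum b_j x^j) = sum a_i x^i`` for (a, b); adequate for
    the smooth, pole-free parameter curves this package tabulates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cols = [x**i for i in range(5)] + [-y * x**j for j in range(1, 5)]
    design = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return PadeSeries(a=tuple(coef[:5]), b=tuple(coef[5:]))


class EnergyRangeError(ValueError):
    """Energy outside the moderator table's valid range."""


@dataclass(frozen=True)
class ModeratorTable:
    """Energy-dependent IC parameters as Pade approximants in log10(E/eV)."""

    alpha: PadeSeries
    beta: PadeSeries
    R: PadeSeries
    t0: PadeSeries
    e_min: float
    e_max: float

    def evaluate(self, energy_ev: float) -> ICParams:
        if not (self.e_min * (1 - 1e-12) <= energy_ev <= self.e_max * (1 + 1e-12)):
            raise EnergyRangeError(
                f"energy {energy_ev:g} eV outside the table's valid range "
                f"[{self.e_min:g}, {self.e_max:g}] eV"
            )
        x = np.log10(energy_ev)
        try:
            return ICParams(
                alpha=float(self.alpha(x)),
                beta=float(self.beta(x)),
                R=float(self.R(x)),
                t0=float(self.t0(x)),
            )
        except ValueError as exc:
            raise ValueError(f"corrupt moderator table: {exc}") from exc

    # ------------------------------------------------------------------ io
    def to_json(self, path) -> None:
        doc = {
            "format": "tofprofile-moderator-table",
            "version": 1,
            "energy_range_ev": [self.e_min, self.e_max],
            "parameters": {
                name: {"numerator": list(ser.a), "denominator": list(ser.b)}
                for name, ser in (
                    ("alpha", self.alpha),
                    ("beta", self.beta),
                    ("R", self.R),
                    ("t0", self.t0),
                )
            },
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ModeratorTable":
        with open(path) as fh:
            doc = json.load(fh)
        if doc.get("format") != "tofprofile-moderator-table":
            raise ValueError(f"{path!r} is not a moderator table file")
        pars = {
            name: PadeSeries(
                a=tuple(blk["numerator"]), b=tuple(blk["denominator"])
            )
            for name, blk in doc["parameters"].items()
        }
        lo, hi = doc["energy_range_ev"]
        return cls(
            alpha=pars["alpha"], beta=pars["beta"], R=pars["R"], t0=pars["t0"],
            e_min=lo, e_max=hi,
        )


def default_table() -> ModeratorTable:
    """The package's shipped moderator characterization (synthetic).

    A physically shaped stand-in for an instrument-specific table: the fast
    decay rate alpha rises with energy (shorter pulses for hotter neutrons),
    the slow fraction R falls with energy, and beta/t0 drift gently.  The
    curves are themselves rational in x = log10(E/eV), so the Pade
    coefficients are exact.  Replace via a JSON table for a real instrument.
    """
    return ModeratorTable(
        alpha=PadeSeries(a=(0.35, 0.12, 0.018, 0.0, 0.0), b=(0.0, 0.0, 0.0, 0.0)),
        beta=PadeSeries(a=(0.012, 0.0012, 0.0, 0.0, 0.0), b=(0.0, 0.0, 0.0, 0.0)),
        R=PadeSeries(a=(0.45, 0.0, 0.0, 0.0, 0.0), b=(0.08, 0.015, 0.0, 0.0)),
        t0=PadeSeries(a=(2.0, -0.15, 0.0, 0.0, 0.0), b=(0.0, 0.0, 0.0, 0.0)),
        e_min=1e-5,
        e_max=100.0,
    )


def initial_guess(
    q_r: float,
    two_theta: float,
    flight_path: float,
    table: ModeratorTable,
    tof_counts=None,
):
    """Seed (ICParams, BroadeningParams) for a peak's TOF fit.

    The peak's energy follows from |q| and the Bragg angle via de Broglie;
    the IC shape comes from the Pade table.  ``t0`` is returned as an
    *absolute* time: nominal Bragg TOF plus the moderator emission offset.
    ``tof_counts``, when given, seeds the scale (total counts) and the flat
    background (mean of the outer bins).
    """
    from .geometry import TOF_COEF, energy_from_q

    energy = energy_from_q(q_r, two_theta)
    p = table.evaluate(energy)
    t_nominal = TOF_COEF * flight_path * np.sin(two_theta / 2.0) / q_r
    p = replace(p, t0=t_nominal + p.t0)
    scale = 1.0
    background = 0.0
    if tof_counts is not None:
        counts = np.asarray(tof_counts, dtype=float)
        edge = np.concatenate([counts[:2], counts[-2:]])
        background = float(np.mean(edge))
        scale = float(max(counts.sum() - background * counts.size, 1.0))
    broad = BroadeningParams(scale=scale, background=background)
    return p, broad
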