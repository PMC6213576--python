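"""Reciprocal-space and detector coordinate conventions.

Conventions used throughout the package (recorded once, applied uniformly):

* physics convention ``|q| = 2*pi/d``; ``q = 2*pi * UB @ (h, k, l)``;
* the incident beam travels along +z; ``two_theta`` is the polar angle of a
  q-vector measured from +z and ``phi_az`` the azimuth in the laboratory xy
  plane (``atan2(qy, qx)``);
* time of flight is ``t = (4*pi*m_n/h) * L * sin(theta) / |q|`` with
  ``theta = two_theta/2`` the Bragg half-angle, equivalent to the de Broglie
  relation ``t = m_n * L * lambda / h`` with ``lambda = 2 d sin(theta)``;
* detector panels are flat rectangles with 0-based (row, col) pixel indices,
  row 0 / col 0 at the panel corner ``origin``.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MN_OVER_H",
    "TOF_COEF",
    "UBMatrix",
    "Panel",
    "DetectorGeometry",
    "q_to_spherical",
    "spherical_to_q",
    "wavelength_from_q",
    "energy_from_q",
    "q_to_tof",
    "edge_distance",
]

#: neutron mass over Planck constant, s / m^2  (m_n = 1.67492749804e-27 kg,
#: h = 6.62607015e-34 J s)
MN_OVER_H = 1.67492749804e-27 / 6.62607015e-34

#: TOF coefficient: t [us] = TOF_COEF * L [m] * sin(theta) / |q| [1/Angstrom]
#: t = m_n L lambda / h,  lambda = 4 pi sin(theta)/|q|  (|q| = 2 pi / d)
TOF_COEF = 4.0 * np.pi * MN_OVER_H * 1.0e-10 * 1.0e6


class SingularUBError(ValueError):
    """Raised when an orientation matrix is not invertible."""


@dataclass(frozen=True)
class UBMatrix:
    """Orientation matrix mapping Miller indices to reciprocal space.

    ``q = 2 pi * UB @ hkl`` (Angstrom^-1).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"UB matrix must be 3x3, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise SingularUBError("UB matrix contains non-finite entries")
        if abs(np.linalg.det(m)) < 1e-300:
            raise SingularUBError("UB matrix is singular (det = 0)")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "_inv", np.linalg.inv(m))

    def hkl_to_q(self, hkl) -> np.ndarray:
        """Map (fractional) Miller indices to q-vectors, |q| = 2 pi / d.

        Accepts a length-3 triple or an (N, 3) array; a null (0,0,0) index is
        rejected for the single-triple form since it has no scattering vector.
        """
        h = np.asarray(hkl, dtype=float)
        single = h.ndim == 1
        if single and np.all(h == 0.0):
            raise ValueError("hkl = (0, 0, 0) has no scattering vector")
        q = 2.0 * np.pi * h @ self.matrix.T
        return q

    def q_to_hkl(self, q) -> np.ndarray:
        """Inverse map: fractional Miller indices of q-vectors."""
        q = np.asarray(q, dtype=float)
        return q @ self._inv.T / (2.0 * np.pi)

    @classmethod
    def from_file(cls, path) -> "UBMatrix":
        """Read a UB matrix from plain text.

        Plain format: three rows of three whitespace-separated reals.  An
        ISAW-style ``.mat`` file (UB rows followed by lattice-constant and
        error rows) is accepted; only the first three rows are used.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) < 3:
                    continue
                try:
                    vals = [float(p) for p in parts[:3]]
                except ValueError:
                    continue
                rows.append(vals)
                if len(rows) == 3:
                    break
        if len(rows) != 3:
            raise ValueError(f"could not read a 3x3 UB matrix from {path!r}")
        return cls(np.array(rows))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.matrix:
                fh.write("  ".join(f"{v: .10f}" for v in row) + "\n")


def q_to_spherical(q):
    """(qx, qy, qz) -> (q_r, phi_az, two_theta).

    ``two_theta`` is the angle from +z (beam axis), ``phi_az`` the azimuth in
    the xy plane; for a vector on the beam axis ``phi_az`` is 0 by
    convention.  Works on a single vector or an (..., 3) array.
    """
    q = np.asarray(q, dtype=float)
    qr = np.linalg.norm(q, axis=-1)
    if np.any(qr == 0.0):
        raise ValueError("zero q-vector has no spherical representation")
    two_theta = np.arccos(np.clip(q[..., 2] / qr, -1.0, 1.0))
    phi = np.arctan2(q[..., 1], q[..., 0])
    phi = np.where(phi <= -np.pi, np.pi, phi)  # keep phi in (-pi, pi]
    return qr, phi, two_theta


def spherical_to_q(q_r, phi_az, two_theta):
    """Inverse of :func:`q_to_spherical`; broadcasts over array inputs."""
    q_r = np.asarray(q_r, dtype=float)
    st = np.sin(two_theta)
    out = np.stack(
        [
            q_r * st * np.cos(phi_az),
            q_r * st * np.sin(phi_az),
            q_r * np.cos(two_theta),
        ],
        axis=-1,
    )
    return out


def wavelength_from_q(q_r, two_theta):
    """de Broglie wavelength (Angstrom): lambda = 2 d sin(theta) = 4 pi sin(theta)/|q|."""
    return 4.0 * np.pi * np.sin(np.asarray(two_theta) / 2.0) / np.asarray(q_r)


def energy_from_q(q_r, two_theta):
    """Neutron energy (eV) from |q| and scattering angle: E = h^2/(2 m lambda^2)."""
    lam = wavelength_from_q(q_r, two_theta)
    # h^2 / (2 m_n e) in eV Angstrom^2
    return 0.081804209605 / lam**2


@dataclass(frozen=True)
class Panel:
    """A flat rectangular detector panel.

    ``origin`` is the laboratory position (m) of the corner of pixel
    (row 0, col 0); ``u_hat`` is the in-plane unit vector along increasing
    column, ``v_hat`` along increasing row.  ``flight_path`` is the total
    moderator-to-detector distance L (m) used for TOF on this panel.
    """

    name: str
    origin: np.ndarray
    u_hat: np.ndarray
    v_hat: np.ndarray
    n_rows: int
    n_cols: int
    pitch: float
    flight_path: float

    def __post_init__(self) -> None:
        for attr in ("origin", "u_hat", "v_hat"):
            v = np.asarray(getattr(self, attr), dtype=float)
            object.__setattr__(self, attr, v)
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("panel pixel counts must be >= 1")
        u, v = self.u_hat, self.v_hat
        n = np.cross(u, v)
        if np.linalg.norm(n) < 1e-12:
            raise ValueError("panel basis vectors are parallel")
        object.__setattr__(self, "u_hat", u / np.linalg.norm(u))
        object.__setattr__(self, "v_hat", v / np.linalg.norm(v))
        object.__setattr__(self, "_normal", n / np.linalg.norm(n))

    @classmethod
    def tangent(
        cls,
        name: str,
        two_theta: float,
        phi_az: float,
        distance: float,
        n_rows: int = 1024,
        n_cols: int = 1024,
        pitch: float = 0.0004,
        l1: float = 30.0,
    ) -> "Panel":
        """Panel tangent to a sphere of ``distance`` m, centered on the given
        direction, with columns along increasing azimuth and rows along
        increasing scattering angle."""
        d_hat = spherical_to_q(1.0, phi_az, two_theta)
        # local angular basis: e_phi (azimuth), e_tth (polar)
        e_tth = spherical_to_q(1.0, phi_az, two_theta + np.pi / 2.0)
        e_phi = np.cross(e_tth, d_hat)
        center = distance * d_hat
        origin = center - e_phi * (n_cols * pitch / 2.0) - e_tth * (n_rows * pitch / 2.0)
        return cls(
            name=name,
            origin=origin,
            u_hat=e_phi,
            v_hat=e_tth,
            n_rows=n_rows,
            n_cols=n_cols,
            pitch=pitch,
            flight_path=l1 + distance,
        )

    def intersect(self, directions: np.ndarray):
        """Intersect rays from the sample at the given unit directions.

        Returns float (row, col) coordinates and a boolean hit mask.
        """
        d = np.asarray(directions, dtype=float)
        n = self._normal
        denom = d @ n
        p0n = float(self.origin @ n)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = p0n / denom
        ok = (denom * np.sign(p0n) > 1e-12) & (t > 0)
        x = t[..., None] * d - self.origin
        col = (x @ self.u_hat) / self.pitch
        row = (x @ self.v_hat) / self.pitch
        inside = ok & (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class DetectorGeometry:
    """A collection of flat panels plus a default flight path."""

    panels: list = field(default_factory=list)
    l_default: float = 30.0

    def locate(self, q):
        """Map q-vectors to (panel index, row, col); -1 panel index = off-detector.

        The scattered-ray direction is taken as the direction of q itself
        (the package's laboratory-frame plumbing convention).  ``q`` may be a
        single vector or an (N, 3) array.
        """
        q = np.asarray(q, dtype=float)
        single = q.ndim == 1
        qa = q[None, :] if single else q
        norm = np.linalg.norm(qa, axis=-1, keepdims=True)
        d = qa / np.where(norm == 0.0, 1.0, norm)
        n = qa.shape[0]
        panel_idx = np.full(n, -1, dtype=int)
        rows = np.full(n, -1, dtype=int)
        cols = np.full(n, -1, dtype=int)
        for i, p in enumerate(self.panels):
            todo = panel_idx < 0
            if not np.any(todo):
                break
            r, c, inside = p.intersect(d[todo])
            hit = np.where(todo)[0][inside]
            panel_idx[hit] = i
            rows[hit] = np.floor(r[inside]).astype(int)
            cols[hit] = np.floor(c[inside]).astype(int)
        if single:
            return panel_idx[0], rows[0], cols[0]
        return panel_idx, rows, cols

    def on_detector(self, q):
        idx, _, _ = self.locate(q)
        return np.asarray(idx) >= 0

    def flight_path_for(self, q) -> float:
        """Flight path L (m) of the panel a q-vector lands on, else the default."""
        idx, _, _ = self.locate(q)
        if np.ndim(idx) == 0:
            return self.panels[idx].flight_path if idx >= 0 else self.l_default
        out = np.full(len(idx), self.l_default)
        for i, p in enumerate(self.panels):
            out[idx == i] = p.flight_path
        return out

    # ------------------------------------------------------------------ io
    def to_file(self, path) -> None:
        cp = configparser.ConfigParser()
        cp["geometry"] = {"l_default": repr(float(self.l_default))}
        for p in self.panels:
            sec = f"panel {p.name}"
            cp[sec] = {
                "origin": " ".join(repr(float(v)) for v in p.origin),
                "u_hat": " ".join(repr(float(v)) for v in p.u_hat),
                "v_hat": " ".join(repr(float(v)) for v in p.v_hat),
                "n_rows": str(int(p.n_rows)),
                "n_cols": str(int(p.n_cols)),
                "pitch": repr(float(p.pitch)),
                "flight_path": repr(float(p.flight_path)),
            }
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path) -> "DetectorGeometry":
        cp = configparser.ConfigParser()
        with open(path) as fh:
            cp.read_file(fh)
        geom = cls(l_default=float(cp["geometry"].get("l_default", "30.0")))
        for sec in cp.sections():
            if not sec.startswith("panel "):
                continue
            s = cp[sec]
            geom.panels.append(
                Panel(
                    name=sec[len("panel "):],
                    origin=np.array([float(v) for v in s["origin"].split()]),
                    u_hat=np.array([float(v) for v in s["u_hat"].split()]),
                    v_hat=np.array([float(v) for v in s["v_hat"].split()]),
                    n_rows=int(s["n_rows"]),
                    n_cols=int(s["n_cols"]),
                    pitch=float(s["pitch"]),
                    flight_path=float(s["flight_path"]),
                )
            )
        return geom


def q_to_tof(q, geom_or_l, two_theta=None):
    """Time of flight (us) of a Bragg peak at q.

    ``geom_or_l`` may be a :class:`DetectorGeometry` (the panel flight path of
    the peak is used) or a flight path in meters.  When ``two_theta`` is
    given, it overrides the polar angle of q in the Bragg-angle factor — this
    is how per-box radial TOF coordinates with a frozen peak angle are built.
    A peak at theta = 0 returns 0, which is unphysical for a Bragg peak and
    should be treated by the caller as a skip condition.
    """
    q = np.asarray(q, dtype=float)
    qr = np.linalg.norm(q, axis=-1)
    if np.any(qr == 0.0):
        raise ValueError("zero q-vector has no TOF")
    if two_theta is None:
        two_theta = np.arccos(np.clip(q[..., 2] / qr, -1.0, 1.0))
    if isinstance(geom_or_l, DetectorGeometry):
        length = geom_or_l.flight_path_for(q)
    else:
        length = float(geom_or_l)
    if np.any(np.asarray(length) <= 0):
        raise ValueError("flight path must be positive")
    return TOF_COEF * length * np.sin(np.asarray(two_theta) / 2.0) / qr


def edge_distance(q, geom: DetectorGeometry):
    """Distance (whole pixels) from the projected peak to the nearest panel edge.

    0 means the outermost pixel row/column; ``None`` means the peak does not
    intersect any panel (off-detector).  Vectorized input returns -1 for
    off-detector entries.
    """
    idx, row, col = geom.locate(q)
    if np.ndim(idx) == 0:
        if idx < 0:
            return None
        p = geom.panels[idx]
        return int(min(row, col, p.n_rows - 1 - row, p.n_cols - 1 - col))
    out = np.full(len(idx), -1, dtype=int)
    for i, p in enumerate(geom.panels):
        m = idx == i
        out[m] = np.minimum.reduce(
            [row[m], col[m], p.n_rows - 1 - row[m], p.n_cols - 1 - col[m]]
        )
    return out
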