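"""Event-list readers and writers.

The standard event file is a columnar table with a header, one row per
detected neutron, and either reciprocal-space columns ``qx, qy, qz``
(Angstrom^-1) or detector columns ``panel, row, col, tof_us``.  Text files
are CSV (gzip-transparent via the ``.gz`` suffix); an HDF5 variant stores the
same column names as datasets under the root group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .geometry import TOF_COEF, DetectorGeometry, q_to_spherical

__all__ = ["read_events", "write_events", "pixel_events_to_q"]

_Q_COLS = ["qx", "qy", "qz"]
_PIX_COLS = ["panel", "row", "col", "tof_us"]


def pixel_events_to_q(df: pd.DataFrame, geom: DetectorGeometry) -> np.ndarray:
    """Convert (panel, row, col, tof_us) records to q-vectors.

    The scattered direction is the pixel-center direction; the magnitude
    follows from the measured TOF via |q| = coef * L * sin(theta) / t.
    """
    q = np.empty((len(df), 3))
    panel_ids = df["panel"].to_numpy()
    for i, p in enumerate(geom.panels):
        m = panel_ids == i
        if not np.any(m):
            continue
        pos = (
            p.origin
            + np.outer((df.loc[m, "col"].to_numpy() + 0.5) * p.pitch, p.u_hat)
            + np.outer((df.loc[m, "row"].to_numpy() + 0.5) * p.pitch, p.v_hat)
        )
        d = pos / np.linalg.norm(pos, axis=1, keepdims=True)
        _, _, tth = q_to_spherical(d)
        qr = TOF_COEF * p.flight_path * np.sin(tth / 2.0) / df.loc[m, "tof_us"].to_numpy()
        q[m] = d * qr[:, None]
    return q


def read_events(path, geom: DetectorGeometry | None = None) -> np.ndarray:
    """Read an event file into an (N, 3) array of q-vectors.

    CSV (optionally .gz) or HDF5 (.h5/.hdf5, requires h5py).  Pixel-format
    files need ``geom`` for the conversion.
    """
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            cols = set(fh.keys())
            if set(_Q_COLS) <= cols:
                return np.stack([fh[c][...] for c in _Q_COLS], axis=1)
            df = pd.DataFrame({c: fh[c][...] for c in _PIX_COLS})
    else:
        df = pd.read_csv(path)
        if set(_Q_COLS) <= set(df.columns):
            return df[_Q_COLS].to_numpy(dtype=float)
    if not set(_PIX_COLS) <= set(df.columns):
        raise ValueError(
            f"{path!r} has neither {_Q_COLS} nor {_PIX_COLS} columns"
        )
    if geom is None:
        raise ValueError("pixel-format event files need a detector geometry")
    return pixel_events_to_q(df, geom)


def write_events(path, events_q: np.ndarray) -> None:
    """Write q-vector events as CSV (gzip if the path ends in .gz) or HDF5."""
    path = str(path)
    events_q = np.atleast_2d(np.asarray(events_q, dtype=float))
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            for i, c in enumerate(_Q_COLS):
                fh.create_dataset(c, data=events_q[:, i])
        return
    pd.DataFrame(events_q, columns=_Q_COLS).to_csv(path, index=False)
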