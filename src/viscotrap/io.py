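"""Trajectory and result file I/O.

Trajectories are plain delimited text (comma, tab or whitespace), either two
columns ``time, position`` with a uniform time grid or a single position
column with ``dt`` supplied.  Positions are converted to meters on read;
supported units are ``m``, ``um``, ``nm`` and ``px`` (the latter requires a
``calib`` factor in pixels per meter).  Results serialize to versioned JSON
with full float precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np

from .model import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_acf_table",
    "write_acf_table",
    "write_results",
]

RESULTS_SCHEMA_VERSION = 1

_UNIT_SCALE = {"m": 1.0, "um": 1e-6, "nm": 1e-9}

#: Allowed relative jitter of the time grid.
_TIME_JITTER_TOL = 1e-6


class TrajectoryFormatError(ValueError):
    pass


def _load_columns(path) -> np.ndarray:
    """Load a 1- or 2-column delimited text file, tolerating a header line."""
    path = Path(path)
    text = path.read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise TrajectoryFormatError(f"{path} is empty")

    def parse(line: str) -> Optional[list]:
        for sep in (",", "\t", None):
            parts = line.split(sep) if sep else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) in (1, 2):
                try:
                    return [float(p) for p in parts]
                except ValueError:
                    continue
        return None

    first = parse(lines[0])
    rows = lines[1:] if first is None else lines
    data = []
    for ln in rows:
        vals = parse(ln)
        if vals is None:
            raise TrajectoryFormatError(f"unparseable line in {path}: {ln!r}")
        data.append(vals)
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (1, 2):
        raise TrajectoryFormatError(f"{path}: expected 1 or 2 columns")
    return arr


def read_trajectory(
    path,
    dt: Optional[float] = None,
    units: str = "m",
    calib: Optional[float] = None,
) -> Trajectory:
    """Read a probe trajectory from delimited text.

    Parameters
    ----------
    path : path-like
        One position column (requires ``dt``) or two columns time/position.
    dt : float, optional
        Sampling step in seconds; required for one-column files and ignored
        (but cross-checked) for two-column files.
    units : {'m', 'um', 'nm', 'px'}
        Units of the position column.  ``px`` requires ``calib``.
    calib : float, optional
        Pixels per meter, for ``units='px'``.
    """
    arr = _load_columns(path)
    if arr.shape[1] == 2:
        t, pos = arr[:, 0], arr[:, 1]
        steps = np.diff(t)
        if steps.size == 0:
            raise TrajectoryFormatError("need at least 2 samples")
        dt_file = float(np.median(steps))
        if dt_file <= 0 or np.any(
            np.abs(steps - dt_file) > _TIME_JITTER_TOL * dt_file
        ):
            raise TrajectoryFormatError(
                "time column is not uniform within the allowed jitter "
                f"({_TIME_JITTER_TOL:g} relative)"
            )
        if dt is not None and abs(dt - dt_file) > _TIME_JITTER_TOL * dt_file:
            raise TrajectoryFormatError(
                f"supplied dt {dt!r} disagrees with the file's {dt_file!r}"
            )
        dt = dt_file
    else:
        pos = arr[:, 0]
        if dt is None:
            raise TrajectoryFormatError(
                "one-column trajectory requires dt to be supplied"
            )
    if units == "px":
        if calib is None or calib <= 0:
            raise ValueError("units='px' requires a positive calib (px per m)")
        pos = pos / calib
    elif units in _UNIT_SCALE:
        pos = pos * _UNIT_SCALE[units]
    else:
        raise ValueError(f"unknown units {units!r}")
    return Trajectory(dt=float(dt), x=pos)


def write_trajectory(path, traj: Trajectory, header: bool = True) -> None:
    """Write a trajectory as 'time,position' CSV in SI units, full precision."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write("time,position\n")
        for i, xi in enumerate(traj.x):
            fh.write(f"{i * traj.dt:.17g},{xi:.17g}\n")


def read_acf_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column (lag s, acf m^2) delimited text table."""
    arr = _load_columns(path)
    if arr.shape[1] != 2:
        raise TrajectoryFormatError("ACF table must have two columns")
    return arr[:, 0], arr[:, 1]


def write_acf_table(path, lags: np.ndarray, values: np.ndarray) -> None:
    with Path(path).open("w") as fh:
        fh.write("lag,acf\n")
        for lag, val in zip(lags, values):
            fh.write(f"{lag:.17g},{val:.17g}\n")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
            if not f.name.startswith("_")
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "to_dict"):  # pandas
        return _jsonable(obj.to_dict(orient="records"))
    return obj


def write_results(path, result, seed: Optional[int] = None, **extra) -> None:
    """Serialize a result object to versioned JSON.

    Floats keep full (17 significant digit) precision via Python's repr-based
    JSON encoder.  ``seed`` and any extra metadata are stored alongside.
    """
    from . import __version__

    payload = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "software": {"name": "viscotrap", "version": __version__},
        "units": {
            "position": "m", "time": "s", "viscosity": "Pa s",
            "stiffness": "N/m", "temperature": "K",
        },
        "seed": seed,
        "result": _jsonable(result),
    }
    payload.update(_jsonable(extra))
    with Path(path).open("w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
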