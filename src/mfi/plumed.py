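"""Reading and writing the PLUMED COLVAR and HILLS text dialects.

Only the ``#! FIELDS`` header and the numeric body are honored.  ``#! SET``
lines are parsed; variants this package cannot represent (multivariate,
non-diagonal hills) raise an explicit "unsupported dialect" error rather
than being silently misread.  Restart-duplicated time blocks are
deduplicated keeping the later block, with a loud warning.  All output is
written at full double precision so round trips are bit-faithful.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .grid import CVTrajectory
from .metad import HillsLog

__all__ = [
    "ColvarTable",
    "read_colvar",
    "write_colvar",
    "read_hills",
    "write_hills",
    "colvar_to_trajectory",
    "trajectory_to_colvar",
    "PlumedParseError",
]

log = logging.getLogger(__name__)


class PlumedParseError(ValueError):
    pass


@dataclass
class ColvarTable:
    """A parsed PLUMED-style table: column names and a float matrix."""

    names: list
    data: np.ndarray

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise PlumedParseError("duplicate column names in FIELDS header")
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[1] != len(self.names):
            raise PlumedParseError("row width does not match header width")
        if "time" not in self.names:
            raise PlumedParseError("a 'time' column is mandatory")

    def column(self, name: str) -> np.ndarray:
        return self.data[:, self.names.index(name)]


def _parse_table(path) -> tuple[list, list, np.ndarray]:
    names: list[str] = []
    sets: list[tuple[str, str]] = []
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#!"):
                parts = line[2:].split()
                if not parts:
                    continue
                if parts[0] == "FIELDS":
                    if names:
                        raise PlumedParseError(f"{path}:{lineno}: repeated FIELDS header")
                    names = parts[1:]
                elif parts[0] == "SET":
                    sets.append((parts[1] if len(parts) > 1 else "", " ".join(parts[2:])))
                continue
            if not names:
                raise PlumedParseError(f"{path}:{lineno}: data before FIELDS header")
            vals = line.split()
            if len(vals) != len(names):
                raise PlumedParseError(
                    f"{path}:{lineno}: expected {len(names)} columns, found {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise PlumedParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not names:
        raise PlumedParseError(f"{path}: missing '#! FIELDS' header")
    if not rows:
        raise PlumedParseError(f"{path}: empty data section")
    for key, _ in sets:
        if key.startswith("multivariate") and sets_true(dict(sets).get(key, "")):
            raise PlumedParseError(f"{path}: unsupported dialect: multivariate hills")
    return names, sets, np.asarray(rows, dtype=float)


def sets_true(v: str) -> bool:
    return v.strip().lower() in ("true", "yes", "1")


def _dedup_restarts(names, data, path) -> np.ndarray:
    """Keep the later block wherever a restart rewound the time column."""
    t = data[:, names.index("time")]
    keep = np.ones(len(t), dtype=bool)
    drops = np.flatnonzero(np.diff(t) <= 0)
    for b in drops:
        t_restart = t[b + 1]
        overlap = keep[: b + 1] & (t[: b + 1] >= t_restart)
        if overlap.any():
            keep[: b + 1] &= ~overlap
            msg = (
                f"{path}: restart overlap detected at t={t_restart}; "
                f"dropping {int(overlap.sum())} earlier rows (keeping later block)"
            )
            log.warning(msg)
            warnings.warn(msg, stacklevel=3)
    return data[keep]


def read_colvar(path) -> ColvarTable:
    """Parse a COLVAR file; restart-overlapping blocks keep the later rows."""
    names, _, data = _parse_table(path)
    data = _dedup_restarts(names, data, path)
    return ColvarTable(names, data)


def write_colvar(table: ColvarTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(table.names) + "\n")
        for row in table.data:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


_CV = ("s1", "s2")


def colvar_to_trajectory(table: ColvarTable, cv_names=None) -> CVTrajectory:
    names = list(cv_names) if cv_names else [n for n in table.names if n != "time"]
    t = table.column("time")
    samples = np.stack([table.column(n) for n in names], axis=1)
    stride = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    return CVTrajectory(t, samples, stride)


def trajectory_to_colvar(traj: CVTrajectory, cv_names=None) -> ColvarTable:
    names = list(cv_names) if cv_names else list(_CV[: traj.ndim])
    data = np.column_stack([traj.times, traj.samples])
    return ColvarTable(["time"] + names, data)


def read_hills(path, kT: float = 1.0) -> HillsLog:
    """Parse a HILLS file into a :class:`HillsLog`.

    The bias factor is taken from a ``biasf`` column when present: values
    > 1 mark a well-tempered run; absent or <= 1 means plain metadynamics.
    """
    names, _, data = _parse_table(path)
    data = _dedup_restarts(names, data, path)
    cvs = [n for n in names if n not in ("time", "height", "biasf") and not n.startswith("sigma_")]
    if not 1 <= len(cvs) <= 2:
        raise PlumedParseError(f"{path}: expected 1 or 2 CV columns, found {cvs}")
    ndim = len(cvs)
    t = data[:, names.index("time")]
    centers = np.stack([data[:, names.index(c)] for c in cvs], axis=1)
    try:
        sigmas = np.stack([data[:, names.index(f"sigma_{c}")] for c in cvs], axis=1)
    except ValueError:
        raise PlumedParseError(f"{path}: missing sigma_<cv> column(s)") from None
    heights = data[:, names.index("height")]
    bad = np.flatnonzero(sigmas.min(axis=1) <= 0)
    if bad.size:
        raise PlumedParseError(f"{path}: nonpositive sigma in data row {bad[0] + 1}")
    bias_factor = None
    if "biasf" in names:
        bf = data[:, names.index("biasf")]
        if bf[0] > 1:
            bias_factor = float(bf[0])
    return HillsLog(ndim, centers, sigmas, heights, t, bias_factor=bias_factor, kT=kT,
                    pace_time=float(np.median(np.diff(t))) if len(t) > 1 else None)


def write_hills(log: HillsLog, path, cv_names=None) -> None:
    names = list(cv_names) if cv_names else list(_CV[: log.ndim])
    cols = ["time"] + names + [f"sigma_{n}" for n in names] + ["height"]
    mat = [log.times] + [log.centers[:, a] for a in range(log.ndim)] + [
        log.sigmas[:, a] for a in range(log.ndim)
    ] + [log.heights]
    if log.bias_factor is not None:
        cols.append("biasf")
        mat.append(np.full(len(log.times), log.bias_factor))
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(cols) + "\n")
        for row in zip(*mat):
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")
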