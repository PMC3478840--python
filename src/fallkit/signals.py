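"""Data model and file I/O for tri-axial accelerometer recordings.

Traces are uniformly sampled series of (ax, ay, az) in g units.  Files
are plain delimited text (comma or whitespace, auto-detected), with
optional ``#`` comment lines; an optional leading time column is
validated against the sampling rate.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "AccelTrace",
    "TrialManifest",
    "ManifestEntry",
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
]

#: Default sampling rate of the target hardware, Hz.
DEFAULT_FS = 200.0

#: Falling ADL class ids (catalog numbering 1..21; 1-10 fall, 11-21 not).
FALL_ADL_IDS = frozenset(range(1, 11))
NONFALL_ADL_IDS = frozenset(range(11, 22))

ADL_NAMES = {
    1: "Slip and ascending stairs",
    2: "Slip and descending stairs",
    3: "Forward fall",
    4: "Backward fall",
    5: "Falling down from bed",
    6: "Fall down from wheelchair",
    7: "Rolling down from bed",
    8: "Lateral fall",
    9: "Falling down to bed",
    10: "Fall for the weak leg",
    11: "Ascending stairs",
    12: "Descending stairs",
    13: "Sitting down on bed",
    14: "Standing up from bed",
    15: "Sitting down in wheelchair",
    16: "Standing up from wheelchair",
    17: "Walking",
    18: "Lying down",
    19: "Lying up",
    20: "Squatting down",
    21: "Standing up",
}


class TraceParseError(ValueError):
    """Raised when a trace or manifest file cannot be parsed."""


@dataclass
class AccelTrace:
    """Uniformly sampled tri-axial acceleration in g units.

    Attributes
    ----------
    t : ndarray
        Sample times in seconds, a uniform grid with step ``1/fs``.
    ax, ay, az : ndarray
        Per-axis acceleration in g.
    fs : float
        Sampling rate in Hz.
    meta : dict
        Free-form provenance (subject id, ADL id, trial index, ...).
    """

    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    fs: float = DEFAULT_FS
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ax = np.asarray(self.ax, dtype=float)
        self.ay = np.asarray(self.ay, dtype=float)
        self.az = np.asarray(self.az, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.t)
        if not (len(self.ax) == len(self.ay) == len(self.az) == n):
            raise ValueError("t, ax, ay, az must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) > 1e-9):
                raise ValueError("time grid is not uniform at 1/fs (tol 1e-9 s)")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xyz(self) -> np.ndarray:
        """(n, 3) array of the three axes."""
        return np.column_stack([self.ax, self.ay, self.az])

    @classmethod
    def from_samples(
        cls, xyz: np.ndarray, fs: float = DEFAULT_FS, t0: float = 0.0, meta: dict | None = None
    ) -> "AccelTrace":
        """Build a trace from an (n, 3) sample block, synthesizing the grid."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ValueError("xyz must be an (n, 3) array")
        t = t0 + np.arange(xyz.shape[0]) / fs
        return cls(t, xyz[:, 0], xyz[:, 1], xyz[:, 2], fs=fs, meta=meta or {})


@dataclass(frozen=True)
class ManifestEntry:
    path: str
    subject: str
    adl_id: int
    trial: int
    is_fall: bool


@dataclass
class TrialManifest:
    """Catalog of trial recordings: one entry per recorded file."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            if not 1 <= e.adl_id <= 21:
                raise ValueError(f"adl_id out of range 1..21: {e.adl_id}")
            expected = e.adl_id in FALL_ADL_IDS
            if e.is_fall != expected:
                raise ValueError(
                    f"is_fall={e.is_fall} inconsistent with adl_id={e.adl_id}"
                )
            key = (e.subject, e.adl_id, e.trial)
            if key in seen:
                raise ValueError(f"duplicate (subject, ADL, trial) triple: {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def subjects(self) -> list[str]:
        return sorted({e.subject for e in self.entries})

    def filter(self, **kwargs) -> "TrialManifest":
        """Subset by field equality, e.g. ``filter(is_fall=True)``."""
        kept = [
            e
            for e in self.entries
            if all(getattr(e, k) == v for k, v in kwargs.items())
        ]
        return TrialManifest(kept)


def _detect_delimiter(line: str) -> str | None:
    return "," if "," in line else None  # None -> whitespace split


def _parse_delimited(path: str | Path) -> tuple[list[list[str]], list[int], list[str]]:
    """Split a text file into token rows, skipping comments and blanks.

    Returns (rows, original line numbers, comment lines).
    """
    rows, linenos, comments = [], [], []
    delim = None
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line[1:].strip())
                continue
            if delim is None:
                delim = _detect_delimiter(line)
            rows.append(line.split(delim) if delim else line.split())
            linenos.append(lineno)
    return rows, linenos, comments


def read_trace(path: str | Path, fs: float = DEFAULT_FS) -> AccelTrace:
    """Read a trace from delimited text.

    The file may have 3 columns (ax, ay, az; grid synthesized from *fs*)
    or 4 columns (t, ax, ay, az; timestamps validated against *fs*).
    A non-numeric header row is tolerated and skipped.

    Raises
    ------
    TraceParseError
        On non-numeric data rows, inconsistent column counts, or
        non-uniform explicit timestamps; the message names the row.
    """
    rows, linenos, comments = _parse_delimited(path)
    meta: dict = {}
    for c in comments:
        if "=" in c:
            k, _, v = c.partition("=")
            meta[k.strip()] = v.strip()
    if rows:
        # tolerate one non-numeric header row
        try:
            [float(v) for v in rows[0]]
        except ValueError:
            rows = rows[1:]
            linenos = linenos[1:]
    if not rows:
        return AccelTrace.from_samples(np.empty((0, 3)), fs=fs, meta=meta)
    ncol = len(rows[0])
    if ncol not in (3, 4):
        raise TraceParseError(
            f"{path}: expected 3 or 4 columns, found {ncol} at line {linenos[0]}"
        )
    data = np.empty((len(rows), ncol))
    for i, (row, lineno) in enumerate(zip(rows, linenos)):
        if len(row) != ncol:
            raise TraceParseError(
                f"{path}: inconsistent column count at line {lineno} "
                f"(expected {ncol}, got {len(row)})"
            )
        try:
            data[i] = [float(v) for v in row]
        except ValueError:
            raise TraceParseError(
                f"{path}: non-numeric value at line {lineno}: {row!r}"
            ) from None
    if ncol == 3:
        return AccelTrace.from_samples(data, fs=fs, meta=meta)
    t = data[:, 0]
    if len(t) >= 2:
        dt = np.diff(t)
        bad = np.nonzero(np.abs(dt - 1.0 / fs) > 1e-6)[0]
        if bad.size:
            raise TraceParseError(
                f"{path}: non-uniform timestamp at line {linenos[bad[0] + 1]} "
                f"(dt={dt[bad[0]]:.9f}, expected {1.0 / fs:.9f})"
            )
    trace = AccelTrace.from_samples(data[:, 1:], fs=fs, t0=t[0] if len(t) else 0.0, meta=meta)
    return trace


def write_trace(trace: AccelTrace, path: str | Path) -> Path:
    """Write a trace as 4-column CSV with a header; meta as '#' comments."""
    path = Path(path)
    buf = io.StringIO()
    for k, v in trace.meta.items():
        buf.write(f"# {k} = {v}\n")
    buf.write("t,ax,ay,az\n")
    for ti, x, y, z in zip(trace.t, trace.ax, trace.ay, trace.az):
        buf.write(f"{ti:.6f},{x:.6f},{y:.6f},{z:.6f}\n")
    path.write_text(buf.getvalue())
    return path


def read_manifest(path: str | Path) -> TrialManifest:
    """Read a trial manifest: columns path, subject, adl_id, trial, is_fall."""
    rows, linenos, _ = _parse_delimited(path)
    if rows and rows[0][0].strip().lower() == "path":
        rows, linenos = rows[1:], linenos[1:]
    entries = []
    for row, lineno in zip(rows, linenos):
        if len(row) != 5:
            raise TraceParseError(
                f"{path}: manifest row at line {lineno} needs 5 fields, got {len(row)}"
            )
        p, subj, adl, trial, is_fall = (v.strip() for v in row)
        try:
            entries.append(
                ManifestEntry(
                    path=p,
                    subject=subj,
                    adl_id=int(adl),
                    trial=int(trial),
                    is_fall=is_fall.lower() in ("1", "true", "yes"),
                )
            )
        except ValueError:
            raise TraceParseError(
                f"{path}: bad manifest row at line {lineno}: {row!r}"
            ) from None
    return TrialManifest(entries)


def write_manifest(manifest: TrialManifest, path: str | Path) -> Path:
    path = Path(path)
    lines = ["path,subject,adl_id,trial,is_fall"]
    for e in manifest:
        lines.append(f"{e.path},{e.subject},{e.adl_id},{e.trial},{int(e.is_fall)}")
    path.write_text("\n".join(lines) + "\n")
    return path
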