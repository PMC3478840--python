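"""Per-sample action parameters computed from a tri-axial trace.

Four features drive classification:

* ``sv_total`` -- Euclidean magnitude of the three axes (static +
  dynamic), ~1 g at rest.
* ``cv_fast`` -- root-sum-square over axes of (max - min) within a
  causal 0.1 s sliding window; the impact-sensitivity feature.
* ``va`` -- signed vertical acceleration recovered from the magnitudes
  by the law of cosines, ``(sv_total^2 - sv_d^2 - |G|^2) / (2 |G|)``,
  where ``sv_d`` is the magnitude of the high-pass-filtered axes.
* ``phi_z`` -- posture angle in degrees between the low-pass gravity
  estimate and the upright reference direction.

All filters are causal (Butterworth, state initialized at the first
sample's steady state so a constant input produces zero transient).
Feature series have exactly the length of the source trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from fallkit.signals import AccelTrace

__all__ = [
    "FeatureSeries",
    "FeatureConfig",
    "sv_total",
    "cv_fast",
    "sv_d",
    "vertical_acceleration",
    "posture_angle",
    "extract_features",
    "read_features",
    "write_features",
]

PARAM_NAMES = ("sv_total", "cv_fast", "va", "phi_z")

#: Gravity magnitude in g units.
G_MAG = 1.0

#: Upright gravity direction in the sensor frame (wearer standing).
UPRIGHT = np.array([0.0, 0.0, 1.0])


@dataclass(frozen=True)
class FeatureConfig:
    """Settings for feature extraction."""

    window_s: float = 0.1
    hp_cutoff_hz: float = 0.3
    hp_order: int = 4
    lp_cutoff_hz: float = 0.3
    lp_order: int = 2
    g_mag: float = G_MAG


@dataclass
class FeatureSeries:
    """The four per-sample action parameters aligned to a trace timeline."""

    t: np.ndarray
    sv_total: np.ndarray
    cv_fast: np.ndarray
    va: np.ndarray
    phi_z: np.ndarray
    fs: float
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.t)

    def matrix(self, params: tuple[str, ...] = PARAM_NAMES) -> np.ndarray:
        """(n, k) matrix of the requested parameters, in the given order."""
        unknown = set(params) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        return np.column_stack([getattr(self, p) for p in params])


def _causal_filter(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # steady-state init at x[0]: a constant signal passes with no transient
    zi = sps.sosfilt_zi(sos) * x[0] if len(x) else sps.sosfilt_zi(sos)
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def sv_total(trace: AccelTrace) -> np.ndarray:
    """Total sum vector: per-sample Euclidean norm of (ax, ay, az), in g."""
    return np.sqrt(trace.ax**2 + trace.ay**2 + trace.az**2)


def cv_fast(trace: AccelTrace, window_s: float = 0.1) -> np.ndarray:
    """Fast changed vector over a causal sliding window, in g.

    Per sample, ``sqrt(sum_axis (max - min)^2)`` over the window of
    ``ceil(window_s * fs)`` samples ending at that sample; the first
    windows are partial.
    """
    w = int(np.ceil(window_s * trace.fs))
    if w < 2:
        raise ValueError(
            f"window of {window_s} s at fs={trace.fs} spans {w} sample(s); need >= 2"
        )
    if len(trace) == 0:
        return np.empty(0)
    total = np.zeros(len(trace))
    for axis in (trace.ax, trace.ay, trace.az):
        s = pd.Series(axis)
        rng = s.rolling(w, min_periods=1).max() - s.rolling(w, min_periods=1).min()
        total += rng.to_numpy() ** 2
    return np.sqrt(total)


def sv_d(
    trace: AccelTrace, hp_cutoff_hz: float = 0.3, hp_order: int = 4
) -> np.ndarray:
    """Dynamic sum vector: magnitude of the high-pass-filtered axes, in g."""
    if not 0 < hp_cutoff_hz < trace.fs / 2:
        raise ValueError(
            f"hp_cutoff_hz must be in (0, fs/2)=(0, {trace.fs / 2}), got {hp_cutoff_hz}"
        )
    if len(trace) == 0:
        return np.empty(0)
    sos = sps.butter(hp_order, hp_cutoff_hz, btype="highpass", fs=trace.fs, output="sos")
    total = np.zeros(len(trace))
    for axis in (trace.ax, trace.ay, trace.az):
        total += _causal_filter(sos, axis) ** 2
    return np.sqrt(total)


def vertical_acceleration(
    sv_total: np.ndarray, sv_d: np.ndarray, g_mag: float = G_MAG
) -> np.ndarray:
    """Signed vertical acceleration from the two magnitudes, in g.

    ``va = (sv_total^2 - sv_d^2 - g_mag^2) / (2 g_mag)``.  Zero at rest,
    negative during free fall (-g_mag in the ideal drop).
    """
    sv_total = np.asarray(sv_total, dtype=float)
    sv_d = np.asarray(sv_d, dtype=float)
    if sv_total.shape != sv_d.shape:
        raise ValueError(
            f"length mismatch: sv_total has {sv_total.shape}, sv_d has {sv_d.shape}"
        )
    return (sv_total**2 - sv_d**2 - g_mag**2) / (2.0 * g_mag)


def posture_angle(
    trace: AccelTrace,
    lp_cutoff_hz: float = 0.3,
    lp_order: int = 2,
    upright: np.ndarray = UPRIGHT,
    literal: bool = False,
) -> np.ndarray:
    """Posture angle in degrees, in [0, 180].

    Default mode: angle between the low-pass-filtered acceleration
    vector (gravity estimate) and the upright reference direction.
    Samples where the gravity estimate has zero magnitude carry the
    previous sample's angle forward (0 deg at the start).

    ``literal=True`` returns the degenerate scalar form: 0 deg where the
    vertical acceleration estimate is non-negative, 180 deg where it is
    negative.
    """
    if not 0 < lp_cutoff_hz < trace.fs / 2:
        raise ValueError(
            f"lp_cutoff_hz must be in (0, fs/2)=(0, {trace.fs / 2}), got {lp_cutoff_hz}"
        )
    if len(trace) == 0:
        return np.empty(0)
    sos = sps.butter(lp_order, lp_cutoff_hz, btype="lowpass", fs=trace.fs, output="sos")
    g_est = np.column_stack([_causal_filter(sos, a) for a in (trace.ax, trace.ay, trace.az)])
    if literal:
        va = vertical_acceleration(sv_total(trace), sv_d(trace))
        return np.where(va < 0, 180.0, 0.0)
    upright = np.asarray(upright, dtype=float)
    upright = upright / np.linalg.norm(upright)
    norms = np.linalg.norm(g_est, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (g_est @ upright) / norms
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    # carry forward over zero-magnitude gravity estimates
    dead = norms <= 1e-12
    if dead.any():
        angles[dead] = np.nan
        filled = pd.Series(angles).ffill().fillna(0.0)
        angles = filled.to_numpy()
    return angles


def extract_features(trace: AccelTrace, cfg: FeatureConfig | None = None) -> FeatureSeries:
    """Bundle the four action parameters on the trace's timeline."""
    cfg = cfg or FeatureConfig()
    svt = sv_total(trace)
    svd = sv_d(trace, cfg.hp_cutoff_hz, cfg.hp_order)
    return FeatureSeries(
        t=trace.t.copy(),
        sv_total=svt,
        cv_fast=cv_fast(trace, cfg.window_s),
        va=vertical_acceleration(svt, svd, cfg.g_mag),
        phi_z=posture_angle(trace, cfg.lp_cutoff_hz, cfg.lp_order),
        fs=trace.fs,
        meta=dict(trace.meta),
    )


def write_features(feats: FeatureSeries, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# fs = {feats.fs}"]
    lines += [f"# {k} = {v}" for k, v in feats.meta.items()]
    lines.append("t,sv_total,cv_fast,va,phi_z")
    for row in zip(feats.t, feats.sv_total, feats.cv_fast, feats.va, feats.phi_z):
        lines.append(",".join(f"{v:.6f}" for v in row))
    path.write_text("\n".join(lines) + "\n")
    return path


def read_features(path: str | Path) -> FeatureSeries:
    from fallkit.signals import _parse_delimited

    rows, linenos, comments = _parse_delimited(path)
    meta = {}
    for c in comments:
        if "=" in c:
            k, _, v = c.partition("=")
            meta[k.strip()] = v.strip()
    fs = float(meta.pop("fs", 200.0))
    if rows and rows[0][0].strip().lower() == "t":
        rows = rows[1:]
    data = np.array([[float(v) for v in row] for row in rows]) if rows else np.empty((0, 5))
    if data.size and data.shape[1] != 5:
        raise ValueError(f"{path}: feature files need 5 columns, got {data.shape[1]}")
    return FeatureSeries(
        t=data[:, 0] if data.size else np.empty(0),
        sv_total=data[:, 1] if data.size else np.empty(0),
        cv_fast=data[:, 2] if data.size else np.empty(0),
        va=data[:, 3] if data.size else np.empty(0),
        phi_z=data[:, 4] if data.size else np.empty(0),
        fs=fs,
        meta=meta,
    )
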