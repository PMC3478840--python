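"""Boxplot-threshold comparator for trial-level fall classification.

For each parameter, every fall trial contributes its upper peak (trial
max) and lower peak (trial min).  The upper falling threshold is the
lower boxplot whisker of the upper-peak distribution (smallest peak at
or above Q1 - whisker*IQR); the lower falling threshold is the upper
whisker of the lower-peak distribution.  A trial is called a fall when
its upper peak reaches the upper threshold or its lower peak reaches the
lower threshold, for one chosen parameter or for any of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from fallkit.features import PARAM_NAMES, FeatureSeries

__all__ = [
    "ThresholdModel",
    "trial_peaks",
    "fit_thresholds",
    "classify_threshold",
    "save_thresholds",
    "load_thresholds",
]


@dataclass
class ThresholdModel:
    """Per-parameter upper/lower falling thresholds plus the peak tables."""

    upper: dict[str, float]
    lower: dict[str, float]
    peak_table: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    whisker: float = 1.5

    def params(self) -> tuple[str, ...]:
        return tuple(self.upper)


def trial_peaks(feats: FeatureSeries, param: str) -> tuple[float, float]:
    """(max, min) of one parameter over a trial."""
    if param not in PARAM_NAMES:
        raise ValueError(f"unknown parameter {param!r}; expected one of {PARAM_NAMES}")
    series = getattr(feats, param)
    if len(series) == 0:
        raise ValueError("empty feature series")
    return float(np.max(series)), float(np.min(series))


def _lower_whisker(values: np.ndarray, whisker: float) -> float:
    """Smallest value at or above Q1 - whisker*IQR."""
    q1, q3 = np.percentile(values, [25, 75])
    fence = q1 - whisker * (q3 - q1)
    return float(values[values >= fence].min())


def _upper_whisker(values: np.ndarray, whisker: float) -> float:
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + whisker * (q3 - q1)
    return float(values[values <= fence].max())


def fit_thresholds(
    fall_peaks: dict[str, list[tuple[float, float]]], whisker: float = 1.5
) -> ThresholdModel:
    """Derive the falling thresholds from fall-trial peak tables.

    *fall_peaks* maps parameter name -> list of (upper, lower) peaks,
    one pair per fall trial.  ``whisker=inf`` reduces to plain min/max.
    """
    if not fall_peaks:
        raise ValueError("empty peak table")
    upper, lower = {}, {}
    for param, peaks in fall_peaks.items():
        if not peaks:
            raise ValueError(f"no fall-trial peaks for parameter {param!r}")
        ups = np.array([p[0] for p in peaks], dtype=float)
        los = np.array([p[1] for p in peaks], dtype=float)
        if np.isinf(whisker):
            upper[param] = float(ups.min())
            lower[param] = float(los.max())
        else:
            upper[param] = _lower_whisker(ups, whisker)
            lower[param] = _upper_whisker(los, whisker)
    return ThresholdModel(
        upper=upper, lower=lower, peak_table=dict(fall_peaks), whisker=whisker
    )


def classify_threshold(
    feats: FeatureSeries,
    model: ThresholdModel,
    rule: str = "any_param",
    param: str | None = None,
    sides: str = "both",
) -> bool:
    """Trial-level fall decision; True means fall.

    ``single_param`` applies one parameter's thresholds (named via
    *param*); ``any_param`` is the OR over all fitted parameters.
    *sides* selects which thresholds fire: ``upper`` (impact side),
    ``lower`` (free-fall side), or ``both``.  Lower thresholds of
    parameters that rest at their minimum (cv_fast, phi_z when trials
    start upright) sit at the noise floor and flag almost everything;
    ``sides='upper'`` gives the usable comparator.
    """
    if sides not in ("both", "upper", "lower"):
        raise ValueError(f"sides must be 'both', 'upper' or 'lower', got {sides!r}")
    if rule == "single_param":
        if param is None:
            raise ValueError("single_param rule requires param=")
        if param not in model.upper:
            raise ValueError(f"parameter {param!r} not in fitted model")
        up, lo = trial_peaks(feats, param)
        hit_up = sides != "lower" and up >= model.upper[param]
        hit_lo = sides != "upper" and lo <= model.lower[param]
        return hit_up or hit_lo
    if rule == "any_param":
        return any(
            classify_threshold(feats, model, rule="single_param", param=p, sides=sides)
            for p in model.params()
        )
    raise ValueError(f"unknown rule {rule!r}; use 'any_param' or 'single_param'")


def save_thresholds(model: ThresholdModel, path: str | Path) -> Path:
    path = Path(path)
    lines = [f"# whisker = {model.whisker}", "param,upper_fall_threshold,lower_fall_threshold"]
    for p in model.params():
        lines.append(f"{p},{model.upper[p]!r},{model.lower[p]!r}")
    path.write_text("\n".join(lines) + "\n")
    return path


def load_thresholds(path: str | Path) -> ThresholdModel:
    path = Path(path)
    whisker = 1.5
    upper, lower = {}, {}
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "whisker" in line and "=" in line:
                whisker = float(line.split("=", 1)[1])
            continue
        if line.startswith("param,"):
            continue
        p, up, lo = line.split(",")
        upper[p] = float(up)
        lower[p] = float(lo)
    if not upper:
        raise ValueError(f"{path}: no thresholds found")
    return ThresholdModel(upper=upper, lower=lower, whisker=whisker)
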