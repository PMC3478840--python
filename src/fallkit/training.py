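"""Labeled frame-set construction for detector training.

Frames from fall trials are labeled +1 where ``cv_fast`` reaches a
per-trial threshold (a fixed fraction of the trial's maximum, default
0.87) and -1 elsewhere; frames from non-fall trials are all -1.
Training selects a fixed number of trials per (subject, ADL) cell, and
two-fold splits are available by trial (within subject) or by subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from fallkit.features import PARAM_NAMES, FeatureSeries
from fallkit.signals import ManifestEntry, TrialManifest

__all__ = [
    "LabeledFrameSet",
    "fall_frame_threshold",
    "label_trial",
    "select_training_trials",
    "assemble_training_set",
    "split_cv",
]


@dataclass
class LabeledFrameSet:
    """Feature matrix with +/-1 labels and per-row provenance.

    ``X`` is (m, n) with one column per selected parameter; ``D`` is the
    length-m label vector; ``provenance`` holds one
    (subject, adl_id, trial, sample_index) tuple per row.
    """

    X: np.ndarray
    D: np.ndarray
    param_names: tuple[str, ...]
    provenance: list[tuple] = field(default_factory=list)
    n_fall_trials: int = 0
    n_nonfall_trials: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.D = np.asarray(self.D, dtype=int)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.D.shape[0]:
            raise ValueError("X and D row counts differ")
        if self.X.shape[1] != len(self.param_names):
            raise ValueError("X column count does not match param_names")
        bad = set(np.unique(self.D)) - {1, -1}
        if bad:
            raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.D)

    @property
    def n_selected_trials(self) -> int:
        return self.n_fall_trials + self.n_nonfall_trials


def fall_frame_threshold(cv_fast: np.ndarray, factor: float = 0.87) -> float:
    """Per-trial fall threshold: *factor* times the trial's cv_fast peak."""
    cv_fast = np.asarray(cv_fast, dtype=float)
    if cv_fast.size == 0:
        raise ValueError("empty cv_fast series")
    peak = float(cv_fast.max())
    if peak <= 0:
        raise ValueError("cv_fast is identically zero: no fall signature in trial")
    return factor * peak


def label_trial(
    feats: FeatureSeries, is_fall: bool, threshold: float | None = None
) -> np.ndarray:
    """Per-sample labels for one trial.

    Fall trials get +1 where ``cv_fast >= threshold`` (so the peak frame
    is always positive) and -1 elsewhere; non-fall trials are all -1.
    """
    n = len(feats)
    if not is_fall:
        return np.full(n, -1, dtype=int)
    if threshold is None:
        raise ValueError("fall trial requires a threshold (see fall_frame_threshold)")
    return np.where(feats.cv_fast >= threshold, 1, -1)


def _cells(manifest: TrialManifest) -> dict[tuple[str, int], list[ManifestEntry]]:
    cells: dict[tuple[str, int], list[ManifestEntry]] = {}
    for e in manifest:
        cells.setdefault((e.subject, e.adl_id), []).append(e)
    # canonical within-cell order -> row-order invariance
    for v in cells.values():
        v.sort(key=lambda e: e.trial)
    return cells


def select_training_trials(
    manifest: TrialManifest, select: int = 5, seed: int = 0
) -> TrialManifest:
    """Randomly pick *select* trials per (subject, ADL) cell, seeded."""
    if select <= 0:
        raise ValueError(f"select must be >= 1, got {select}")
    rng = np.random.default_rng(seed)
    chosen: list[ManifestEntry] = []
    cells = _cells(manifest)
    for key in sorted(cells):
        trials = cells[key]
        if len(trials) < select:
            raise ValueError(
                f"(subject, ADL) cell {key} has {len(trials)} trials; need {select}"
            )
        idx = rng.choice(len(trials), size=select, replace=False)
        chosen.extend(trials[i] for i in sorted(idx))
    return TrialManifest(chosen)


def assemble_training_set(
    manifest: TrialManifest,
    load_features: Callable[[ManifestEntry], FeatureSeries],
    select: int = 5,
    params: tuple[str, ...] = PARAM_NAMES,
    factor: float = 0.87,
    seed: int = 0,
    frame_stride: int = 1,
    neg_keep: float = 1.0,
) -> LabeledFrameSet:
    """Build the labeled frame matrix from a seeded trial selection.

    Parameters
    ----------
    load_features
        Maps a manifest entry to its FeatureSeries (file loader or
        in-memory extractor).
    frame_stride
        Keep every k-th frame of each trial (1 = all frames).  Positive
        frames of fall trials are always kept regardless of stride.
    neg_keep
        Fraction of negative frames retained (seeded subsample); 1.0
        keeps all.  Class-imbalance knob, off by default.
    """
    if not 0 < neg_keep <= 1.0:
        raise ValueError(f"neg_keep must be in (0, 1], got {neg_keep}")
    if frame_stride < 1:
        raise ValueError(f"frame_stride must be >= 1, got {frame_stride}")
    selected = select_training_trials(manifest, select=select, seed=seed)
    rng = np.random.default_rng(seed + 1)
    blocks_X, blocks_D, prov = [], [], []
    n_fall = n_nonfall = 0
    for e in selected:
        feats = load_features(e)
        if e.is_fall:
            thr = fall_frame_threshold(feats.cv_fast, factor=factor)
            labels = label_trial(feats, True, thr)
            n_fall += 1
        else:
            labels = label_trial(feats, False)
            n_nonfall += 1
        keep = np.zeros(len(feats), dtype=bool)
        keep[::frame_stride] = True
        keep |= labels == 1  # never drop positive frames
        if neg_keep < 1.0:
            neg = keep & (labels == -1)
            drop = rng.random(len(feats)) > neg_keep
            keep &= ~(neg & drop)
        idx = np.nonzero(keep)[0]
        blocks_X.append(feats.matrix(params)[idx])
        blocks_D.append(labels[idx])
        prov.extend((e.subject, e.adl_id, e.trial, int(i)) for i in idx)
    return LabeledFrameSet(
        X=np.vstack(blocks_X),
        D=np.concatenate(blocks_D),
        param_names=tuple(params),
        provenance=prov,
        n_fall_trials=n_fall,
        n_nonfall_trials=n_nonfall,
    )


def split_cv(
    manifest: TrialManifest, mode: str = "by_trial", seed: int = 0
) -> tuple[TrialManifest, TrialManifest]:
    """Two-fold split: disjoint halves, union equals the input.

    ``by_trial`` halves the trials within every (subject, ADL) cell;
    ``by_subject`` assigns whole subjects to one half or the other.
    """
    rng = np.random.default_rng(seed)
    if mode == "by_trial":
        first: list[ManifestEntry] = []
        second: list[ManifestEntry] = []
        cells = _cells(manifest)
        for key in sorted(cells):
            trials = cells[key]
            if len(trials) < 2:
                raise ValueError(f"cell {key} has {len(trials)} trial(s); cannot split")
            perm = rng.permutation(len(trials))
            half = len(trials) // 2
            first.extend(trials[i] for i in sorted(perm[:half]))
            second.extend(trials[i] for i in sorted(perm[half:]))
        return TrialManifest(first), TrialManifest(second)
    if mode == "by_subject":
        subjects = manifest.subjects()
        if len(subjects) < 2:
            raise ValueError("need >= 2 subjects for a by_subject split")
        perm = rng.permutation(len(subjects))
        half = len(subjects) // 2
        train_subj = {subjects[i] for i in perm[:half]}
        first = [e for e in manifest if e.subject in train_subj]
        second = [e for e in manifest if e.subject not in train_subj]
        return TrialManifest(first), TrialManifest(second)
    raise ValueError(f"unknown split mode {mode!r}; use 'by_trial' or 'by_subject'")
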