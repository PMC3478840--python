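"""Seeded synthetic waist-accelerometer traces for 21 ADL classes.

Each ADL is a phase script (static, gait oscillation, posture tilt,
sit/stand magnitude dip+bump, free fall, impact, post-impact slump)
rendered onto a rotating gravity direction, then degraded with the
acquisition model: Gaussian noise (sigma 0.02 g), 12-bit quantization
over +/-2 g, clipping at +/-2 g.

Fall classes 1-10 contain a free-fall dip followed by an impact spike;
hard falls peak at 1.75-2.0 g, soft falls (bed/wheelchair classes 5, 6,
7, 9) at 1.2-1.6 g so they overlap the sit-down bump range of non-fall
classes — the deliberately marginal regime.  Non-fall classes contain
no free-fall phase of 0.15 s or more and no spike reaching 1.7 g.

All kinematic ranges are invented defaults, exposed on the profile
objects so they can be overridden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from fallkit.signals import (
    ADL_NAMES,
    FALL_ADL_IDS,
    AccelTrace,
    ManifestEntry,
    TrialManifest,
    write_manifest,
    write_trace,
)

__all__ = [
    "AdlProfile",
    "Phase",
    "FallAnnotation",
    "SessionScript",
    "Protocol",
    "default_profiles",
    "generate_trial",
    "generate_protocol",
    "generate_session",
    "write_annotations",
    "read_annotations",
]

#: Acquisition model constants: sensor range and resolution.
CLIP_G = 2.0
QUANT_BITS = 12
NOISE_SIGMA = 0.02

#: Spike magnitude separating fall impacts from ordinary-activity bumps.
IMPACT_FLOOR = 1.7

HARD_IMPACT = (1.75, 2.0)
SOFT_IMPACT = (1.2, 1.6)
HARD_FREEFALL_DUR = (0.3, 0.5)
SOFT_FREEFALL_DUR = (0.2, 0.35)

SOFT_FALL_IDS = frozenset({5, 6, 7, 9})

POSTURES = {
    "upright": np.array([0.0, 0.0, 1.0]),
    "lying_front": np.array([1.0, 0.0, 0.0]),
    "lying_back": np.array([-1.0, 0.0, 0.0]),
    "lying_left": np.array([0.0, 1.0, 0.0]),
    "lying_right": np.array([0.0, -1.0, 0.0]),
}


@dataclass(frozen=True)
class Phase:
    """One motion segment; all ranges are (lo, hi) drawn uniformly."""

    kind: str  # static | walk | tilt | dipbump | bumpdip | free_fall | impact | slump
    dur: tuple[float, float]
    amp: tuple[float, float] = (0.0, 0.0)  # oscillation amp / impact peak / bump peak
    freq: tuple[float, float] = (0.0, 0.0)
    level: tuple[float, float] = (1.0, 1.0)  # dip depth or free-fall target magnitude
    orient: str | None = None  # posture at end of phase


@dataclass(frozen=True)
class AdlProfile:
    adl_id: int
    name: str
    is_fall: bool
    phases: tuple[Phase, ...]
    severity: str | None = None  # 'hard' | 'soft' for falls
    start_posture: str = "upright"


@dataclass(frozen=True)
class FallAnnotation:
    start_s: float
    end_s: float
    adl_id: int
    is_fall: bool = True


@dataclass
class SessionScript:
    """Ground truth for a continuous session."""

    total_s: float
    fs: float
    activities: list[tuple[float, int]] = field(default_factory=list)  # (start_s, adl_id)
    falls: list[FallAnnotation] = field(default_factory=list)


@dataclass
class Protocol:
    """In-memory result of a multi-subject recording protocol."""

    manifest: TrialManifest
    traces: dict[str, AccelTrace]
    annotations: dict[str, FallAnnotation | None]


def _walk(dur, amp, freq):
    return Phase("walk", dur=dur, amp=amp, freq=freq)


def _fall_phases(
    pre: Phase,
    orient: str,
    impact: tuple[float, float],
    ff_dur: tuple[float, float],
    ff_level: tuple[float, float] = (0.2, 0.5),
) -> tuple[Phase, ...]:
    return (
        pre,
        Phase("free_fall", dur=ff_dur, level=ff_level, orient=orient),
        Phase("impact", dur=(0.03, 0.08), amp=impact),
        Phase("slump", dur=(0.4, 0.8), orient=orient),
        Phase("static", dur=(1.0, 1.5)),
    )


def default_profiles() -> dict[int, AdlProfile]:
    """The built-in catalog of 21 activity profiles."""
    stair = _walk((1.0, 1.8), (0.25, 0.42), (1.4, 2.0))
    stand = Phase("static", dur=(0.6, 1.0))
    p: dict[int, AdlProfile] = {}

    hard = [
        (1, stair, "lying_front"),
        (2, stair, "lying_back"),
        (3, _walk((0.8, 1.5), (0.2, 0.4), (1.6, 2.2)), "lying_front"),
        (4, stand, "lying_back"),
        (8, stand, "lying_left"),
        (10, stand, "lying_front"),
    ]
    for adl_id, pre, orient in hard:
        p[adl_id] = AdlProfile(
            adl_id,
            ADL_NAMES[adl_id],
            True,
            _fall_phases(pre, orient, HARD_IMPACT, HARD_FREEFALL_DUR),
            severity="hard",
        )
    soft = [
        (5, "upright", "lying_left"),  # slipping off the bedside
        (6, "upright", "lying_back"),  # slipping off the wheelchair
        (7, "lying_left", "lying_right"),  # rolling off the bed
        (9, "upright", "lying_back"),  # falling onto the bed
    ]
    for adl_id, start, orient in soft:
        p[adl_id] = AdlProfile(
            adl_id,
            ADL_NAMES[adl_id],
            True,
            _fall_phases(
                stand, orient, SOFT_IMPACT, SOFT_FREEFALL_DUR, ff_level=(0.3, 0.55)
            ),
            severity="soft",
            start_posture=start,
        )

    sit_down = (
        Phase("static", dur=(0.8, 1.2)),
        Phase("dipbump", dur=(0.9, 1.5), level=(0.62, 0.78), amp=(1.0, 1.35)),
        Phase("static", dur=(0.8, 1.2)),
    )
    stand_up = (
        Phase("static", dur=(0.8, 1.2)),
        Phase("bumpdip", dur=(0.8, 1.3), level=(0.75, 0.9), amp=(1.05, 1.3)),
        Phase("static", dur=(0.8, 1.2)),
    )
    nonfall: dict[int, tuple[Phase, ...]] = {
        11: (_walk((3.0, 5.0), (0.2, 0.42), (1.4, 2.0)),),
        12: (_walk((3.0, 5.0), (0.25, 0.42), (1.4, 2.0)),),
        13: sit_down,
        14: stand_up,
        15: sit_down,
        16: stand_up,
        17: (_walk((4.0, 6.0), (0.2, 0.42), (1.6, 2.4)),),
        18: (
            Phase("static", dur=(0.8, 1.2)),
            Phase("tilt", dur=(1.5, 3.0), orient="lying_left"),
            Phase("static", dur=(1.0, 1.5)),
        ),
        19: (
            Phase("static", dur=(0.8, 1.2)),
            Phase("tilt", dur=(1.5, 3.0), orient="upright"),
            Phase("static", dur=(0.8, 1.2)),
        ),
        20: (
            Phase("static", dur=(0.8, 1.2)),
            Phase("dipbump", dur=(1.0, 1.6), level=(0.6, 0.8), amp=(1.0, 1.0)),
            Phase("static", dur=(0.8, 1.2)),
        ),
        21: (
            Phase("static", dur=(0.8, 1.2)),
            Phase("bumpdip", dur=(0.8, 1.3), level=(0.85, 0.95), amp=(1.1, 1.3)),
            Phase("static", dur=(0.8, 1.2)),
        ),
    }
    for adl_id, phases in nonfall.items():
        p[adl_id] = AdlProfile(
            adl_id,
            ADL_NAMES[adl_id],
            False,
            phases,
            start_posture="lying_left" if adl_id == 19 else "upright",
        )
    return p


_PROFILES = default_profiles()


def _slerp(u: np.ndarray, v: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Spherical interpolation rows between unit vectors u and v."""
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    theta = math.acos(dot)
    if theta < 1e-9:
        return np.tile(u, (len(frac), 1))
    if theta > math.pi - 1e-6:
        # antiparallel: rotate through a perpendicular waypoint
        w, _ = _perp_basis(u)
        first = frac <= 0.5
        out = np.empty((len(frac), 3))
        out[first] = _slerp(u, w, frac[first] * 2.0)
        out[~first] = _slerp(w, v, (frac[~first] - 0.5) * 2.0)
        return out
    s = math.sin(theta)
    a = np.sin((1.0 - frac) * theta) / s
    b = np.sin(frac * theta) / s
    return a[:, None] * u + b[:, None] * v


def _perp_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    return e1, np.cross(u, e1)


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _taper(n: int, fs: float, ramp_s: float = 0.25) -> np.ndarray:
    env = np.ones(n)
    r = min(int(ramp_s * fs), n // 2)
    if r > 0:
        edge = 0.5 * (1.0 - np.cos(np.pi * np.arange(r) / r))
        env[:r] = edge
        env[-r:] = edge[::-1]
    return env


def _synth_profile(
    profile: AdlProfile,
    fs: float,
    rng: np.random.Generator,
    amp_scale: float = 1.0,
    dur_scale: float = 1.0,
    severity: str | None = None,
) -> tuple[np.ndarray, FallAnnotation | None]:
    """Render a profile to a clean (n, 3) signal plus its fall interval."""
    g_dir = POSTURES[profile.start_posture].copy()
    mag = 1.0
    segs: list[np.ndarray] = []
    t_cursor = 0.0
    ff_start = imp_end = None
    for phase in profile.phases:
        amp_rng, level_rng, dur_rng = phase.amp, phase.level, phase.dur
        if severity and phase.kind == "impact":
            amp_rng = HARD_IMPACT if severity == "hard" else SOFT_IMPACT
        if severity and phase.kind == "free_fall":
            dur_rng = HARD_FREEFALL_DUR if severity == "hard" else SOFT_FREEFALL_DUR
        dur = rng.uniform(*dur_rng) * dur_scale
        n = max(2, int(round(dur * fs)))
        tloc = np.arange(n) / fs
        frac = tloc / (n / fs)
        if phase.kind == "static":
            seg = np.tile(g_dir * mag, (n, 1))
        elif phase.kind == "walk":
            amp = min(rng.uniform(*amp_rng) * amp_scale, 0.48)
            f = rng.uniform(*phase.freq)
            e1, e2 = _perp_basis(g_dir)
            env = _taper(n, fs)
            vert = 1.0 + amp * env * np.sin(2 * np.pi * f * tloc + rng.uniform(0, 2 * np.pi))
            lat1 = 0.3 * amp * env * np.sin(2 * np.pi * f * tloc + rng.uniform(0, 2 * np.pi))
            lat2 = 0.2 * amp * env * np.sin(np.pi * f * tloc + rng.uniform(0, 2 * np.pi))
            seg = vert[:, None] * g_dir + lat1[:, None] * e1 + lat2[:, None] * e2
        elif phase.kind == "tilt":
            target = POSTURES[phase.orient]
            dirs = _slerp(g_dir, target, _smoothstep(frac))
            wob = 1.0 + 0.04 * amp_scale * np.sin(2 * np.pi * 1.5 * tloc)
            seg = dirs * wob[:, None]
            g_dir = target.copy()
        elif phase.kind in ("dipbump", "bumpdip"):
            dip = rng.uniform(*level_rng)
            bump = rng.uniform(*amp_rng) * (1.0 + 0.3 * (amp_scale - 1.0))
            m = np.ones(n)
            t1 = 0.55 * dur
            w = min(0.25 * dur, 0.25)
            first = tloc < t1
            m[first] += (dip - 1.0) * np.sin(np.pi * tloc[first] / t1)
            second = (tloc >= t1) & (tloc < t1 + w)
            m[second] += (bump - 1.0) * np.sin(np.pi * (tloc[second] - t1) / w)
            if phase.kind == "bumpdip":
                m = m[::-1].copy()
            seg = np.outer(m, g_dir)
        elif phase.kind == "free_fall":
            target_mag = rng.uniform(*level_rng)
            m = 1.0 + (target_mag - 1.0) * _smoothstep(frac / 0.8)
            if phase.orient is not None:
                dirs = _slerp(g_dir, POSTURES[phase.orient], 0.3 * _smoothstep(frac))
                dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            else:
                dirs = np.tile(g_dir, (n, 1))
            seg = dirs * m[:, None]
            mag = target_mag
            ff_start = t_cursor
        elif phase.kind == "impact":
            peak = rng.uniform(*amp_rng)
            base = mag
            gap = rng.uniform(0.02, 0.04)
            d2 = rng.uniform(0.04, 0.07)
            n = max(2, int(round((dur + gap + d2) * fs)))
            tloc = np.arange(n) / fs
            e1, _ = _perp_basis(g_dir)
            m = np.full(n, 0.8)
            in1 = tloc < dur
            m[in1] = base + (peak - base) * np.sin(np.pi * tloc[in1] / dur)
            m[min(int(round(dur / 2 * fs)), n - 1)] = peak  # sample the crest exactly
            in2 = tloc >= dur + gap
            p2 = 0.8 + rng.uniform(0.6, 0.75) * (peak - 0.8)
            m[in2] = 0.8 + (p2 - 0.8) * np.sin(np.pi * (tloc[in2] - dur - gap) / d2)
            jolt = 0.35 * np.sin(np.pi * np.clip(tloc / dur, 0, 1))
            dirs = g_dir[None, :] + jolt[:, None] * e1
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            seg = dirs * m[:, None]
            mag = 0.8
            imp_end = t_cursor + n / fs
        elif phase.kind == "slump":
            target = POSTURES[phase.orient] if phase.orient else g_dir
            dirs = _slerp(g_dir, target, _smoothstep(frac))
            wob = 1.0 + 0.2 * np.exp(-tloc / 0.25) * np.sin(2 * np.pi * 5.0 * tloc)
            m = mag + (1.0 - mag) * _smoothstep(frac / 0.3)
            seg = dirs * (m * wob)[:, None]
            g_dir = target.copy()
            mag = 1.0
        else:
            raise ValueError(f"unknown phase kind {phase.kind!r}")
        segs.append(seg)
        t_cursor += len(seg) / fs
    xyz = np.vstack(segs)
    annotation = None
    if profile.is_fall:
        if ff_start is None or imp_end is None:
            raise RuntimeError(f"fall profile {profile.adl_id} missing fall phases")
        annotation = FallAnnotation(ff_start, imp_end, profile.adl_id)
    return xyz, annotation


def _acquire(xyz: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply sensor noise, 12-bit quantization over +/-2 g, and clipping."""
    noisy = xyz + rng.normal(0.0, NOISE_SIGMA, size=xyz.shape)
    step = 2.0 * CLIP_G / (2**QUANT_BITS)
    return np.clip(np.round(noisy / step) * step, -CLIP_G, CLIP_G)


def generate_trial(
    adl_id: int,
    fs: float = 200.0,
    seed: int | np.random.SeedSequence = 0,
    severity: str | None = None,
    amp_scale: float = 1.0,
    dur_scale: float = 1.0,
    profiles: dict[int, AdlProfile] | None = None,
) -> tuple[AccelTrace, FallAnnotation | None]:
    """One seeded trial of an ADL class; deterministic given (id, seed)."""
    profiles = profiles or _PROFILES
    if adl_id not in profiles:
        raise ValueError(f"unknown adl_id {adl_id}; expected 1..21")
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if severity not in (None, "hard", "soft"):
        raise ValueError(f"severity must be 'hard' or 'soft', got {severity!r}")
    rng = np.random.default_rng(seed)
    profile = profiles[adl_id]
    xyz, annotation = _synth_profile(
        profile, fs, rng, amp_scale=amp_scale, dur_scale=dur_scale, severity=severity
    )
    trace = AccelTrace.from_samples(
        _acquire(xyz, rng),
        fs=fs,
        meta={"adl_id": adl_id, "adl_name": profile.name, "is_fall": int(profile.is_fall)},
    )
    return trace, annotation


def generate_protocol(
    subjects: int,
    trials_per_adl: int,
    fs: float = 200.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    amp_scale: float = 1.0,
) -> Protocol:
    """subjects x 21 ADLs x trials recordings with per-subject variation.

    If *out_dir* is given, traces and a manifest are written there;
    otherwise everything stays in memory keyed by a synthetic path.
    """
    if subjects < 1 or trials_per_adl < 1:
        raise ValueError("subjects and trials_per_adl must be >= 1")
    entries: list[ManifestEntry] = []
    traces: dict[str, AccelTrace] = {}
    annotations: dict[str, FallAnnotation | None] = {}
    for s in range(1, subjects + 1):
        subj_rng = np.random.default_rng(np.random.SeedSequence([seed, 7919, s]))
        subj_amp = amp_scale * float(np.exp(subj_rng.normal(0.0, 0.1)))
        subj_dur = float(subj_rng.uniform(0.8, 1.2))
        for adl_id in range(1, 22):
            for trial in range(1, trials_per_adl + 1):
                key = f"S{s:02d}_A{adl_id:02d}_T{trial:02d}.csv"
                trace, ann = generate_trial(
                    adl_id,
                    fs=fs,
                    seed=np.random.SeedSequence([seed, s, adl_id, trial]),
                    amp_scale=subj_amp,
                    dur_scale=subj_dur,
                )
                trace.meta.update({"subject": f"S{s:02d}", "trial": trial})
                entries.append(
                    ManifestEntry(
                        path=key,
                        subject=f"S{s:02d}",
                        adl_id=adl_id,
                        trial=trial,
                        is_fall=adl_id in FALL_ADL_IDS,
                    )
                )
                traces[key] = trace
                annotations[key] = ann
    manifest = TrialManifest(entries)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, trace in traces.items():
            write_trace(trace, out_dir / key)
        manifest = TrialManifest(
            [replace(e, path=str(out_dir / e.path)) for e in entries]
        )
        write_manifest(manifest, out_dir / "manifest.csv")
    return Protocol(manifest=manifest, traces=traces, annotations=annotations)


#: Non-fall activities that start and end upright, safe to chain.
_SESSION_POOL = (17, 11, 12, 20, 13, 14, 21, 0)  # 0 = standing still


def generate_session(
    duration_s: float,
    embed_falls: int = 0,
    fs: float = 200.0,
    seed: int = 0,
    min_fall_gap_s: float = 20.0,
) -> tuple[AccelTrace, SessionScript]:
    """Continuous unscripted activity with optional embedded falls."""
    if duration_s < 60:
        raise ValueError(f"session duration must be >= 60 s, got {duration_s}")
    if embed_falls < 0:
        raise ValueError("embed_falls must be >= 0")
    needed = embed_falls * (min_fall_gap_s + 10.0)
    if embed_falls and duration_s < needed:
        raise ValueError(
            f"duration {duration_s} s too short for {embed_falls} falls "
            f">= {min_fall_gap_s} s apart"
        )
    rng = np.random.default_rng(seed)
    fall_times: list[float] = []
    if embed_falls:
        lo, hi = 15.0, duration_s - 15.0
        slot = (hi - lo) / embed_falls
        fall_times = [
            lo + i * slot + rng.uniform(0.0, max(slot - min_fall_gap_s, 1.0))
            for i in range(embed_falls)
        ]
    script = SessionScript(total_s=duration_s, fs=fs)
    segs: list[np.ndarray] = []
    t_cursor = 0.0
    next_fall = 0
    n_target = int(round(duration_s * fs))
    n_done = 0
    while n_done < n_target:
        if next_fall < len(fall_times) and t_cursor >= fall_times[next_fall]:
            fall_id = int(rng.choice(sorted(FALL_ADL_IDS)))
            profile = _PROFILES[fall_id]
            xyz, ann = _synth_profile(profile, fs, rng)
            script.activities.append((t_cursor, fall_id))
            script.falls.append(
                FallAnnotation(t_cursor + ann.start_s, t_cursor + ann.end_s, fall_id)
            )
            segs.append(xyz)
            n_done += len(xyz)
            t_cursor = n_done / fs
            # recovery: get up from the post-fall lying posture
            recovery = AdlProfile(
                adl_id=19,
                name="recovery",
                is_fall=False,
                phases=(
                    Phase("static", dur=(2.0, 4.0)),
                    Phase("tilt", dur=(2.0, 3.0), orient="upright"),
                    Phase("static", dur=(1.0, 2.0)),
                ),
                start_posture=_last_posture(profile),
            )
            xyz, _ = _synth_profile(recovery, fs, rng)
            segs.append(xyz)
            n_done += len(xyz)
            t_cursor = n_done / fs
            next_fall += 1
            continue
        adl_id = int(rng.choice(_SESSION_POOL))
        if adl_id == 0:
            n = int(round(rng.uniform(3.0, 10.0) * fs))
            xyz = np.tile(POSTURES["upright"], (n, 1))
            script.activities.append((t_cursor, 0))
        else:
            xyz, _ = _synth_profile(_PROFILES[adl_id], fs, rng)
            script.activities.append((t_cursor, adl_id))
        segs.append(xyz)
        n_done += len(xyz)
        t_cursor = n_done / fs
    xyz = np.vstack(segs)[:n_target]
    trace = AccelTrace.from_samples(
        _acquire(xyz, rng), fs=fs, meta={"session_s": duration_s, "falls": embed_falls}
    )
    return trace, script


def _last_posture(profile: AdlProfile) -> str:
    for phase in reversed(profile.phases):
        if phase.orient is not None:
            return phase.orient
    return profile.start_posture


def write_annotations(events: list[FallAnnotation], path: str | Path) -> Path:
    path = Path(path)
    lines = ["start_s,end_s,adl_id,is_fall"]
    for e in events:
        lines.append(f"{e.start_s:.3f},{e.end_s:.3f},{e.adl_id},{int(e.is_fall)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_annotations(path: str | Path) -> list[FallAnnotation]:
    events = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("start_s"):
            continue
        start, end, adl, is_fall = line.split(",")
        events.append(
            FallAnnotation(float(start), float(end), int(adl), bool(int(is_fall)))
        )
    return events
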