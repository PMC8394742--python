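"""Synthetic accelerometer trace generator for ADLs and falls.

Emulates the structure that waist-worn fall-detection datasets share:
activities of daily living in three intensity categories and falls built
from a free-fall dip, a short impact spike and a post-impact rest phase.
Every trace is gravity (1 g along a slowly varying orientation unit
vector) plus an activity component plus white Gaussian sensor noise.

The generator is not a biomechanical simulator; it reproduces the
qualitative signal properties the downstream analysis relies on — falls
carry the global acceleration peak inside the impact, ADL intensity
categories are ordered in SMV variability, and per-subject amplitude
heterogeneity makes subject-blind folding meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datamodel import (
    Manifest, ManifestEntry, Trace, ValidationError,
    entry_for, write_manifest, write_trace,
)

ADL_CATEGORIES = ("basic", "standard", "sporting")

#: representative activity names per category, cycled over generated traces
ACTIVITY_NAMES = {
    "basic": ("standing", "sitting_down", "lying", "getting_up"),
    "standard": ("walking", "climbing_stairs", "squatting", "picking_object"),
    "sporting": ("running", "jogging", "hopping", "walking_fast"),
}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults describe a mid-range waist sensor: 100 Hz sampling, 15 s
    traces, 0.03 g white noise, 20 ADLs per intensity category and 30
    falls spread over 8 subjects.  Fall-phase parameter ranges (free-fall
    floor 0.1-0.4 g over 0.3-0.5 s, half-sine impact peaking at 3-6 g
    within 0.5 s) bracket the values the peak/valley features are meant
    to capture.
    """

    fs: float = 100.0             # Hz
    duration: float = 15.0        # s per trace
    noise_sd: float = 0.03        # g, per axis
    n_subjects: int = 8
    n_basic: int = 20
    n_standard: int = 20
    n_sporting: int = 20
    n_falls: int = 30
    seed: int = 0
    free_fall_floor: tuple[float, float] = (0.1, 0.4)      # g
    free_fall_duration: tuple[float, float] = (0.3, 0.5)   # s
    impact_peak: tuple[float, float] = (3.0, 6.0)          # g
    impact_duration: tuple[float, float] = (0.1, 0.4)      # s
    basic_transition_prob: float = 0.5
    subject_amp_range: tuple[float, float] = (0.8, 1.2)

    def __post_init__(self) -> None:
        if not (self.fs > 0 and self.duration > 0):
            raise ValidationError("fs and duration must be > 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        for name in ("free_fall_floor", "free_fall_duration",
                     "impact_peak", "impact_duration", "subject_amp_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise ValidationError(f"{name}: range must satisfy lo <= hi")
            if lo <= 0 and name != "free_fall_floor":
                raise ValidationError(f"{name}: bounds must be > 0")
        if self.impact_duration[1] > 0.5:
            raise ValidationError("impact duration must not exceed 0.5 s")
        lo, hi = self.free_fall_duration
        if lo < 0.2 or hi > 0.6:
            raise ValidationError("free-fall duration must lie in [0.2, 0.6] s")


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-12:        # pragma: no cover - astronomically unlikely
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _slerp(u: np.ndarray, v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Spherical interpolation between unit vectors; t in [0, 1], shape (T,)."""
    dot = float(np.clip(np.dot(u, v), -1.0, 1.0))
    omega = np.arccos(dot)
    if omega < 1e-8:
        return np.outer(np.ones_like(t), u)
    s = np.sin(omega)
    return (np.outer(np.sin((1 - t) * omega) / s, u)
            + np.outer(np.sin(t * omega) / s, v))


def _raised_cosine(n: int) -> np.ndarray:
    """Smooth unit bump of n samples (0 at both ends, 1 in the middle)."""
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / max(n - 1, 1)))


def _band_limited(rng, t, total_amp, f_lo, f_hi, n_components=3):
    """Sum of a few random sinusoids with absolute amplitudes summing to total_amp."""
    freqs = rng.uniform(f_lo, f_hi, n_components)
    phases = rng.uniform(0, 2 * np.pi, n_components)
    weights = rng.uniform(0.5, 1.0, n_components)
    weights = weights / weights.sum() * total_amp
    out = np.zeros_like(t)
    for f, p, w in zip(freqs, phases, weights):
        out += w * np.sin(2 * np.pi * f * t + p)
    return out


def _periodic(rng, t, f0, amplitude):
    """Fundamental plus one harmonic, rescaled so the peak equals amplitude."""
    ph1, ph2 = rng.uniform(0, 2 * np.pi, 2)
    raw = (np.sin(2 * np.pi * f0 * t + ph1)
           + 0.15 * np.sin(4 * np.pi * f0 * t + ph2))
    return amplitude * raw / np.abs(raw).max()


def generate_adl(category: str, config: GeneratorConfig,
                 rng: np.random.Generator, *, trace_id: str = "adl0",
                 subject_id: str = "s0", orientation: np.ndarray | None = None,
                 activity_type: str | None = None, amp: float = 1.0) -> Trace:
    """Generate one ADL trace of the given intensity category.

    basic    — gravity plus a 0.02-0.08 g band-limited fluctuation, with at
               most one smooth posture transition (slerped orientation and a
               <= 0.2 g transient bump, keeping peak SMV <= 1.3 g);
    standard — a periodic component, fundamental 1.5-2.5 Hz, amplitude
               0.2-0.5 g, plus one harmonic at 0.15 of the fundamental;
    sporting — fundamental 2.5-3.5 Hz, amplitude 0.8-2.0 g, plus sporadic
               short spikes reaching up to roughly 4 g SMV.
    """
    if category not in ADL_CATEGORIES:
        raise ValueError(f"unknown ADL category {category!r}; "
                         f"expected one of {ADL_CATEGORIES}")
    n = int(round(config.fs * config.duration))
    t = np.arange(n) / config.fs
    orient = _unit(rng) if orientation is None else np.asarray(orientation, float)
    gravity = np.outer(np.ones(n), orient)
    direction = _unit(rng)
    activity = np.zeros((n, 3))

    if category == "basic":
        a_tot = rng.uniform(0.02, 0.08) * amp
        activity += np.outer(
            _band_limited(rng, t, a_tot, 0.3, 1.0), direction)
        if rng.random() < config.basic_transition_prob and config.duration > 4:
            # smooth posture change: rotate gravity, add a small transient
            new_orient = _unit(rng)
            t0 = rng.uniform(1.0, config.duration - 3.0)
            i0, i1 = int(t0 * config.fs), int((t0 + 2.0) * config.fs)
            frac = np.linspace(0.0, 1.0, i1 - i0)
            gravity[i0:i1] = _slerp(orient, new_orient, frac)
            gravity[i1:] = new_orient
            bump = rng.uniform(0.05, 0.2) * amp
            activity[i0:i1] += np.outer(
                bump * _raised_cosine(i1 - i0), _unit(rng))
    elif category == "standard":
        f0 = rng.uniform(1.5, 2.5)
        a = rng.uniform(0.2, 0.5) * amp
        wave = _periodic(rng, t, f0, a)
        activity += np.outer(wave, direction)
    else:  # sporting
        f0 = rng.uniform(2.5, 3.5)
        a = rng.uniform(0.8, 2.0) * amp
        wave = _periodic(rng, t, f0, a)
        activity += np.outer(wave, direction)
        n_spikes = rng.poisson(0.3 * config.duration)
        for _ in range(n_spikes):
            width = int(rng.uniform(0.08, 0.16) * config.fs)
            width = max(width, 3)
            start = rng.integers(0, max(n - width, 1))
            spike_amp = rng.uniform(0.3, 1.2) * amp
            activity[start:start + width] += np.outer(
                spike_amp * _raised_cosine(width), _unit(rng))

    samples = gravity + activity
    if config.noise_sd > 0:
        samples = samples + rng.normal(0, config.noise_sd, (n, 3))
    names = ACTIVITY_NAMES[category]
    return Trace(
        trace_id=trace_id, samples=samples, fs=config.fs, label="ADL",
        activity_type=activity_type if activity_type is not None
        else names[0],
        category=category, subject_id=subject_id)


def generate_fall(config: GeneratorConfig, rng: np.random.Generator, *,
                  trace_id: str = "fall0", subject_id: str = "s0",
                  orientation: np.ndarray | None = None, amp: float = 1.0,
                  return_info: bool = False):
    """Generate one fall trace with four consecutive phases.

    (1) pre-fall quiet ADL-like segment; (2) free-fall where the SMV decays
    smoothly from 1 g to a floor drawn from ``free_fall_floor``; (3) impact:
    a half-sine SMV spike peaking at a value drawn from ``impact_peak``
    over a duration drawn from ``impact_duration``; (4) rest at a new fixed
    orientation under reduced noise.  The global SMV maximum is the impact
    peak by construction (impact peaks >= 3 g dominate the <= ~1.3 g
    pre-fall activity).

    With ``return_info=True`` also returns a dict of the drawn phase
    parameters and the sample ranges of each phase.
    """
    fs = config.fs
    n = int(round(fs * config.duration))
    floor = rng.uniform(*config.free_fall_floor)
    peak = rng.uniform(*config.impact_peak)
    t_ff = rng.uniform(*config.free_fall_duration)
    t_imp = rng.uniform(*config.impact_duration)

    n_ff = max(int(round(t_ff * fs)), 2)
    n_imp = max(int(round(t_imp * fs)), 3)
    if n_imp % 2 == 0:          # odd length so one sample hits the exact peak
        n_imp += 1
    n_pre_min = max(int(round(0.5 * fs)), 2)
    n_rest_min = max(int(round(0.5 * fs)), 2)
    if n_pre_min + n_ff + n_imp + n_rest_min > n:
        raise ValidationError(
            "trace duration too short to contain pre-fall, free-fall, "
            "impact and rest phases")

    # place the impact centre at 45-70% of the trace, clamped to fit
    center = int(rng.uniform(0.45, 0.70) * n)
    i_imp = center - n_imp // 2
    i_imp = int(np.clip(i_imp, n_pre_min + n_ff, n - n_rest_min - n_imp))
    i_ff = i_imp - n_ff
    i_rest = i_imp + n_imp

    o1 = _unit(rng) if orientation is None else np.asarray(orientation, float)
    o_imp = _unit(rng)
    o2 = _unit(rng)

    t_pre = np.arange(i_ff) / fs
    mag = np.empty(n)
    direction = np.empty((n, 3))
    # pre-fall: quiet upright activity
    pre_fluct = _band_limited(rng, t_pre, rng.uniform(0.02, 0.05) * amp,
                              0.3, 1.0)
    mag[:i_ff] = 1.0 + pre_fluct
    direction[:i_ff] = o1
    # free-fall: smooth monotone decay 1 -> floor
    k = np.arange(n_ff)
    mag[i_ff:i_imp] = floor + (1.0 - floor) * 0.5 * (
        1 + np.cos(np.pi * k / (n_ff - 1)))
    direction[i_ff:i_imp] = o1
    # impact: half-sine floor -> peak -> floor, exact peak at the midpoint
    k = np.arange(n_imp)
    mag[i_imp:i_rest] = floor + (peak - floor) * np.sin(
        np.pi * k / (n_imp - 1))
    direction[i_imp:i_rest] = o_imp
    # rest: lying still at a new orientation
    mag[i_rest:] = 1.0
    direction[i_rest:] = o2

    samples = mag[:, None] * direction
    if config.noise_sd > 0:
        noise = rng.normal(0, config.noise_sd, (n, 3))
        noise[i_rest:] *= 0.3   # post-impact stillness
        samples = samples + noise

    trace = Trace(trace_id=trace_id, samples=samples, fs=fs, label="FALL",
                  activity_type="fall", category="none",
                  subject_id=subject_id)
    if return_info:
        info = {"floor": floor, "peak": peak,
                "free_fall": (i_ff, i_imp), "impact": (i_imp, i_rest),
                "rest": (i_rest, n), "pre": (0, i_ff)}
        return trace, info
    return trace


def generate_traces(config: GeneratorConfig) -> list[Trace]:
    """Generate the full labeled trace set for ``config`` (in memory).

    Deterministic in ``config.seed``.  Subjects are assigned round-robin;
    each subject carries a fixed orientation and a single multiplicative
    amplitude factor drawn once from ``subject_amp_range``.
    """
    total = config.n_basic + config.n_standard + config.n_sporting + config.n_falls
    if total <= 0:
        raise ValidationError("zero traces requested")
    if config.n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    rng = np.random.default_rng(config.seed)
    subjects = []
    for s in range(config.n_subjects):
        subjects.append({
            "id": f"s{s:02d}",
            "orientation": _unit(rng),
            "amp": rng.uniform(*config.subject_amp_range)})

    traces: list[Trace] = []
    cursor = 0

    def next_subject():
        nonlocal cursor
        s = subjects[cursor % len(subjects)]
        cursor += 1
        return s

    counts = {"basic": config.n_basic, "standard": config.n_standard,
              "sporting": config.n_sporting}
    for category in ADL_CATEGORIES:
        names = ACTIVITY_NAMES[category]
        for i in range(counts[category]):
            subj = next_subject()
            traces.append(generate_adl(
                category, config, rng,
                trace_id=f"{category}_{i:03d}", subject_id=subj["id"],
                orientation=subj["orientation"],
                activity_type=names[i % len(names)], amp=subj["amp"]))
    for i in range(config.n_falls):
        subj = next_subject()
        traces.append(generate_fall(
            config, rng, trace_id=f"fall_{i:03d}", subject_id=subj["id"],
            orientation=subj["orientation"], amp=subj["amp"]))
    return traces


def generate_dataset(config: GeneratorConfig, out_dir: str | Path) -> Manifest:
    """Generate traces, write them under ``out_dir`` and return the manifest.

    Layout: ``out_dir/traces/<trace_id>.csv`` plus ``out_dir/manifest.csv``.
    Byte-identical across runs for a fixed config (including seed).
    """
    out_dir = Path(out_dir)
    trace_dir = out_dir / "traces"
    trace_dir.mkdir(parents=True, exist_ok=True)
    traces = generate_traces(config)
    entries = []
    for trace in traces:
        path = trace_dir / f"{trace.trace_id}.csv"
        write_trace(trace, path)
        entries.append(entry_for(trace, path))
    manifest = Manifest(entries)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
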