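"""Peak-centered window extraction and the twelve candidate statistics.

Every trace is reduced to a single 2-s observation window centered on the
global maximum of the signal magnitude vector (SMV), the acceleration peak
a fall impact produces.  Twelve physically interpretable statistics are
computed from that window and identified by letters A-L:

==  ==========  =========================================================
ID  Symbol      Description (units)
==  ==========  =========================================================
A   muSMV       mean SMV (g)
B   Adiffmax    max magnitude of the change between consecutive
                acceleration vectors (g)
C   sigmaSMV    sample standard deviation of SMV (g)
D   muTheta     mean rotation angle between consecutive acceleration
                vectors (rad)
E   muSMVdiff   mean absolute first difference of SMV (g)
F   muAp        mean magnitude of the acceleration component parallel to
                the floor plane, i.e. orthogonal to the window-mean
                gravity direction (g)
G   SMVMax      SMV maximum — the violence of the impact (g)
H   SMVMin      SMV minimum — the free-fall valley (g)
I   gammaSMV    sample skewness g1 of SMV (dimensionless)
J   SMA         signal magnitude area: mean of |ax|+|ay|+|az| (g)
K   E           energy: sum of squared SMV over the window (g^2 * samples)
L   muR         mean of the biased normalized autocorrelation of the
                mean-removed SMV over all positive lags (dimensionless)
==  ==========  =========================================================

The named presets ``BCDFGIK`` (seven features) and ``ABCDEFGHIJKL`` (all
twelve, alias ``ALL12``) are the two input sets the classifiers consume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import Trace, ValidationError

WINDOW_SECONDS = 2.0
FEATURE_IDS = tuple("ABCDEFGHIJKL")
FEATURE_SETS = {
    "BCDFGIK": tuple("BCDFGIK"),
    "ABCDEFGHIJKL": FEATURE_IDS,
    "ALL12": FEATURE_IDS,
}


def resolve_feature_set(spec) -> tuple[str, ...]:
    """Turn a preset name or an iterable of feature IDs into an ID tuple."""
    if isinstance(spec, str):
        if spec in FEATURE_SETS:
            return FEATURE_SETS[spec]
        ids = tuple(spec)
    else:
        ids = tuple(spec)
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate feature IDs in {ids}")
    unknown = [i for i in ids if i not in FEATURE_IDS]
    if unknown:
        raise ValidationError(f"unknown feature IDs: {unknown}")
    return ids


def smv(samples) -> np.ndarray | float:
    """Signal magnitude vector: Euclidean norm of an acceleration triple.

    Accepts a single (3,) triple or an (N, 3) array.
    """
    arr = np.asarray(samples, dtype=float)
    return np.linalg.norm(arr, axis=-1)


@dataclass
class Window:
    """The N_W-sample segment centered on the SMV peak of a trace."""

    samples: np.ndarray          # (N_W, 3) in g
    fs: float
    peak_index_in_trace: int

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def smv(self) -> np.ndarray:
        return np.linalg.norm(self.samples, axis=1)


def window_length(fs: float, t_w: float = WINDOW_SECONDS) -> int:
    """N_W = round(fs * t_w), the sample count of the observation window."""
    return int(round(fs * t_w))


def extract_window(trace: Trace) -> Window:
    """Cut the 2-s observation window centered on the global SMV peak.

    The peak index i_o is the first occurrence of the SMV maximum.  The
    window spans ``[i_o - N_W//2, i_o - N_W//2 + N_W)``; when that range
    overflows a trace edge it is shifted to fit, and traces shorter than
    N_W are edge-replicated up to N_W samples.  The window always contains
    the global peak.
    """
    samples = trace.samples
    n = samples.shape[0]
    if n == 0:
        raise ValidationError("empty trace")
    magnitudes = np.linalg.norm(samples, axis=1)
    i_o = int(np.argmax(magnitudes))   # first occurrence on ties
    n_w = window_length(trace.fs)
    if n >= n_w:
        start = i_o - n_w // 2
        start = int(np.clip(start, 0, n - n_w))
        segment = samples[start:start + n_w]
    else:
        pad_left = (n_w - n) // 2
        pad_right = n_w - n - pad_left
        segment = np.pad(samples, ((pad_left, pad_right), (0, 0)),
                         mode="edge")
    return Window(samples=segment, fs=trace.fs, peak_index_in_trace=i_o)


def _mean_autocorr(x: np.ndarray) -> float:
    """Mean over lags 1..N-1 of the biased normalized autocorrelation."""
    x = x - x.mean()
    c0 = float(np.dot(x, x))
    if c0 < 1e-24:
        return 0.0
    full = np.correlate(x, x, mode="full")
    pos = full[len(x):]                 # lags 1..N-1
    return float(np.mean(pos / c0))


def _rotation_angles(samples: np.ndarray) -> np.ndarray:
    """Angle between consecutive acceleration vectors; zero-norm pairs -> 0."""
    a, b = samples[:-1], samples[1:]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 1e-12) & (nb > 1e-12)
    cosang = np.zeros(len(a))
    cosang[ok] = np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok])
    angles = np.where(ok, np.arccos(np.clip(cosang, -1.0, 1.0)), 0.0)
    return angles


def compute_features(window: Window, spec="ABCDEFGHIJKL") -> np.ndarray:
    """Compute the selected statistics of a window, in spec order."""
    ids = resolve_feature_set(spec)
    a = window.samples
    if a.shape[0] < 2:
        raise ValidationError("window must contain at least 2 samples")
    mag = np.linalg.norm(a, axis=1)
    sd = float(mag.std(ddof=1))
    values = {}
    if "A" in ids:
        values["A"] = float(mag.mean())
    if "B" in ids:
        values["B"] = float(np.linalg.norm(np.diff(a, axis=0), axis=1).max())
    if "C" in ids:
        values["C"] = sd
    if "D" in ids:
        values["D"] = float(_rotation_angles(a).mean())
    if "E" in ids:
        values["E"] = float(np.abs(np.diff(mag)).mean())
    if "F" in ids:
        g_mean = a.mean(axis=0)
        norm = np.linalg.norm(g_mean)
        if norm > 1e-12:
            g_hat = g_mean / norm
            parallel = a - np.outer(a @ g_hat, g_hat)
            values["F"] = float(np.linalg.norm(parallel, axis=1).mean())
        else:
            values["F"] = 0.0
    if "G" in ids:
        values["G"] = float(mag.max())
    if "H" in ids:
        values["H"] = float(mag.min())
    if "I" in ids:
        values["I"] = float(stats.skew(mag, bias=True)) if sd > 1e-12 else 0.0
    if "J" in ids:
        values["J"] = float(np.abs(a).sum(axis=1).mean())
    if "K" in ids:
        values["K"] = float(np.square(mag).sum())
    if "L" in ids:
        values["L"] = _mean_autocorr(mag) if sd > 1e-12 else 0.0
    return np.array([values[i] for i in ids], dtype=float)


def features_frame(traces, spec="ABCDEFGHIJKL") -> pd.DataFrame:
    """Feature matrix for a trace collection.

    Returns a DataFrame indexed by trace_id with ``label``, ``category``
    and ``activity_type`` metadata columns followed by one column per
    feature ID in spec order.
    """
    ids = resolve_feature_set(spec)
    rows = []
    for trace in traces:
        window = extract_window(trace)
        feats = compute_features(window, ids)
        row = {"trace_id": trace.trace_id, "label": trace.label,
               "category": trace.category,
               "activity_type": trace.activity_type}
        row.update(dict(zip(ids, feats)))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("trace_id")
    return df


@dataclass
class Normalizer:
    """Per-feature z-score statistics learned from a training matrix.

    Columns whose training standard deviation is below 1e-12 are mapped
    with sd = 1 so constant features normalize to zero instead of
    dividing by zero.
    """

    mean_: np.ndarray
    sd_: np.ndarray

    def transform(self, matrix) -> np.ndarray:
        x = np.asarray(matrix, dtype=float)
        if x.ndim != 2 or x.shape[1] != self.mean_.shape[0]:
            raise ValidationError(
                f"matrix has {x.shape[1] if x.ndim == 2 else '?'} columns, "
                f"normalizer was fitted on {self.mean_.shape[0]}")
        return (x - self.mean_) / self.sd_


def fit_normalizer(train_matrix) -> Normalizer:
    """Learn z-score statistics from the training rows only."""
    x = np.asarray(train_matrix, dtype=float)
    if x.size == 0 or x.ndim != 2:
        raise ValidationError("training matrix must be non-empty and 2-D")
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return Normalizer(mean_=mean, sd_=sd)


def apply_normalizer(normalizer: Normalizer, matrix) -> np.ndarray:
    return normalizer.transform(matrix)
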