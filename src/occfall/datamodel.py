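"""Trace/manifest data model and plain-CSV I/O.

A *trace* is a single labeled recording of a waist-worn triaxial
accelerometer: an (N, 3) array of acceleration components in g, a sampling
rate, a class label (``ADL`` or ``FALL``) and activity metadata.  Traces
live one-per-file as tiny CSVs; a *manifest* CSV is the single source of
labels and ties trace files to their metadata, mirroring how public fall
repositories separate signal files from annotation tables.

Canonical internal unit is g (1 g = 9.80665 m/s²); files recorded in m/s²
are converted at read time and never touched again.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: m/s² per g; divisor applied when a manifest entry declares unit "m/s2".
GRAVITY_MS2 = 9.80665

LABELS = ("ADL", "FALL")
CATEGORIES = ("basic", "standard", "sporting", "none")
UNITS = ("g", "m/s2")
MANIFEST_COLUMNS = [
    "trace_id", "path", "label", "activity_type",
    "category", "subject_id", "fs", "unit",
]
TRACE_COLUMNS = ["ax", "ay", "az"]


class FormatError(ValueError):
    """A file does not conform to the documented CSV layout."""


class ValidationError(ValueError):
    """Contents are well-formed but violate a data-model invariant."""


@dataclass
class Trace:
    """One labeled triaxial acceleration recording.

    Parameters
    ----------
    trace_id : str
        Unique identifier within a dataset.
    samples : ndarray of shape (N, 3)
        Acceleration components (ax, ay, az) in g, N >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    label : {"ADL", "FALL"}
    activity_type : str
        Dataset-specific movement name (e.g. "walking").
    category : {"basic", "standard", "sporting", "none"}
        ADL intensity category; falls always carry "none".
    subject_id : str
    """

    trace_id: str
    samples: np.ndarray
    fs: float
    label: str
    activity_type: str = ""
    category: str = "none"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValidationError(
                f"trace {self.trace_id!r}: samples must be (N, 3), "
                f"got {self.samples.shape}")
        if self.samples.shape[0] < 2:
            raise ValidationError(
                f"trace {self.trace_id!r}: needs at least 2 samples")
        if not np.isfinite(self.samples).all():
            raise ValidationError(
                f"trace {self.trace_id!r}: non-finite acceleration values")
        if not self.fs > 0:
            raise ValidationError(
                f"trace {self.trace_id!r}: sampling rate must be > 0")
        if self.label not in LABELS:
            raise ValidationError(
                f"trace {self.trace_id!r}: label must be one of {LABELS}")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"trace {self.trace_id!r}: unknown category {self.category!r}")
        if self.label == "FALL" and self.category != "none":
            raise ValidationError(
                f"trace {self.trace_id!r}: falls carry no ADL category")

    @property
    def n_samples(self) -> int:
        return int(self.samples.shape[0])

    def smv(self) -> np.ndarray:
        """Signal magnitude vector per sample, in g."""
        return np.linalg.norm(self.samples, axis=1)


@dataclass
class ManifestEntry:
    trace_id: str
    path: Path
    label: str
    activity_type: str
    category: str
    subject_id: str
    fs: float
    unit: str

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.label not in LABELS:
            raise ValidationError(
                f"entry {self.trace_id!r}: label must be one of {LABELS}")
        if self.category not in CATEGORIES:
            raise ValidationError(
                f"entry {self.trace_id!r}: unknown category {self.category!r}")
        if self.unit not in UNITS:
            raise ValidationError(
                f"entry {self.trace_id!r}: unit must be one of {UNITS}")
        if not float(self.fs) > 0:
            raise ValidationError(
                f"entry {self.trace_id!r}: fs must be > 0")


@dataclass
class Manifest:
    """Validated list of manifest entries with resolved file paths."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [e.trace_id for e in self.entries]
        dupes = {t for t in ids if ids.count(t) > 1}
        if dupes:
            raise ValidationError(f"duplicate trace_id(s): {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def adls(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.label == "ADL"]

    def falls(self) -> list[ManifestEntry]:
        return [e for e in self.entries if e.label == "FALL"]


def read_manifest(path: str | Path) -> Manifest:
    """Read and validate a manifest CSV.

    Relative trace paths are resolved against the manifest's directory.
    Raises :class:`FormatError` when a documented column is missing and
    :class:`ValidationError` on duplicate ids or missing trace files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"manifest {path}: missing column {col!r}")
    entries = []
    for _, row in df.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = path.parent / p
        entries.append(ManifestEntry(
            trace_id=row["trace_id"], path=p, label=row["label"],
            activity_type=row["activity_type"] or "",
            category=row["category"], subject_id=row["subject_id"] or "",
            fs=float(row["fs"]), unit=row["unit"]))
    manifest = Manifest(entries)
    for e in manifest:
        if not e.path.exists():
            raise ValidationError(
                f"entry {e.trace_id!r}: trace file not found: {e.path}")
    return manifest


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    """Write a manifest CSV; trace paths are stored relative when possible."""
    path = Path(path)
    rows = []
    for e in manifest:
        p = e.path
        try:
            p = p.relative_to(path.parent)
        except ValueError:
            pass
        rows.append({
            "trace_id": e.trace_id, "path": str(p), "label": e.label,
            "activity_type": e.activity_type, "category": e.category,
            "subject_id": e.subject_id, "fs": e.fs, "unit": e.unit})
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_trace(entry: ManifestEntry) -> Trace:
    """Load one trace file and return a :class:`Trace` in g units."""
    df = pd.read_csv(entry.path, dtype=str)
    for col in TRACE_COLUMNS:
        if col not in df.columns:
            raise FormatError(
                f"trace file {entry.path}: missing column {col!r}")
    numeric = df[TRACE_COLUMNS].apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        idx = int(numeric.isna().any(axis=1).idxmax())
        raise FormatError(
            f"trace file {entry.path}: non-numeric value at row {idx}")
    samples = numeric.to_numpy(dtype=float)
    if samples.shape[0] < 2:
        raise ValidationError(
            f"trace file {entry.path}: needs at least 2 samples")
    if entry.unit == "m/s2":
        samples = samples / GRAVITY_MS2
    return Trace(
        trace_id=entry.trace_id, samples=samples, fs=float(entry.fs),
        label=entry.label, activity_type=entry.activity_type,
        category=entry.category, subject_id=entry.subject_id)


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as a ``ax,ay,az`` CSV, lossless to well below 1e-9 g."""
    path = Path(path)
    buf = io.StringIO()
    buf.write("ax,ay,az\n")
    for row in trace.samples:
        buf.write(f"{row[0]:.12e},{row[1]:.12e},{row[2]:.12e}\n")
    path.write_text(buf.getvalue())


def entry_for(trace: Trace, path: str | Path) -> ManifestEntry:
    """Manifest entry describing an on-disk trace written by this package."""
    return ManifestEntry(
        trace_id=trace.trace_id, path=Path(path), label=trace.label,
        activity_type=trace.activity_type, category=trace.category,
        subject_id=trace.subject_id, fs=trace.fs, unit="g")


def load_traces(manifest: Manifest) -> list[Trace]:
    return [read_trace(e) for e in manifest]
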