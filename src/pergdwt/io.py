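"""Cohort CSV I/O, cohort filters and trace preprocessing.

The canonical on-disk layout is one row per recording: the metadata
columns ``participant_id, visit, eye, diagnosis, age, sex, va_logmar``
followed by the sample columns ``s0 ... s{n-1}`` (µV).  Native traces are
255 samples (150 ms at 1700 Hz); preprocessing removes the DC offset
(zero-order detrend, no slope fit) and repeats the final sample so every
analysed trace is exactly 256 samples (dyadic length).

Missing visual acuity is an empty field, never zero: 0.0 is a valid
logMAR value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dwt import DURATION_MS, FS_HZ, N_SAMPLES

EYES = ("RE", "LE")
DIAGNOSES = ("normal", "CRD", "MD", "STGD")
#: macular-predominant inherited retinal disease labels
MPIRD_DIAGNOSES = frozenset({"CRD", "MD", "STGD"})

METADATA_COLUMNS = (
    "participant_id",
    "visit",
    "eye",
    "diagnosis",
    "age",
    "sex",
    "va_logmar",
)


def group_label(diagnosis: str) -> str:
    """Analysis group of a diagnosis: 'normal' or 'mpird'."""
    if diagnosis == "normal":
        return "normal"
    if diagnosis in MPIRD_DIAGNOSES:
        return "mpird"
    raise ValueError(f"diagnosis {diagnosis!r} belongs to no analysis group")


@dataclass
class PergRecording:
    """One PERG trace with its participant/visit/eye metadata."""

    participant_id: str
    visit: int
    eye: str
    diagnosis: str
    age: float
    sex: str
    va_logmar: float  # NaN when missing
    samples: np.ndarray
    fs: float = FS_HZ
    duration_ms: float = DURATION_MS

    @property
    def group(self) -> str:
        return group_label(self.diagnosis)

    @property
    def has_va(self) -> bool:
        return np.isfinite(self.va_logmar)


@dataclass(frozen=True)
class CohortFilterRules:
    """The cohort restrictions applied before any analysis."""

    allowed_diagnoses: frozenset[str] = frozenset(DIAGNOSES)
    first_visit_only: bool = True
    require_va: bool = True

    def __post_init__(self):
        if not self.allowed_diagnoses:
            raise ValueError("allowed_diagnoses must be non-empty")


def sample_columns(n_samples: int) -> list[str]:
    return [f"s{i}" for i in range(n_samples)]


def write_cohort(recordings: Sequence[PergRecording], path: str | Path) -> None:
    """Write recordings in the canonical CSV layout (pinned float format)."""
    if not recordings:
        raise ValueError("nothing to write")
    n = len(recordings[0].samples)
    rows = []
    for rec in recordings:
        if len(rec.samples) != n:
            raise ValueError("all recordings must have the same trace length")
        row = {
            "participant_id": rec.participant_id,
            "visit": rec.visit,
            "eye": rec.eye,
            "diagnosis": rec.diagnosis,
            "age": rec.age,
            "sex": rec.sex,
            "va_logmar": rec.va_logmar if np.isfinite(rec.va_logmar) else None,
        }
        row.update(zip(sample_columns(n), rec.samples))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_cohort(path: str | Path, n_samples: int = N_SAMPLES) -> list[PergRecording]:
    """Read recordings from the canonical CSV layout.

    ``n_samples`` declares the native trace length the file must carry
    (255 for unpadded hardware traces, 256 for padded ones); rows with a
    different number of sample columns are a schema error, not silently
    padded.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    for col in METADATA_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    scols = sample_columns(n_samples)
    missing = [c for c in scols if c not in frame.columns]
    if missing:
        raise ValueError(
            f"missing sample column {missing[0]!r}: expected {n_samples} samples"
        )
    extra = [c for c in frame.columns if c.startswith("s") and c[1:].isdigit()
             and int(c[1:]) >= n_samples]
    if extra:
        raise ValueError(
            f"unexpected sample column {extra[0]!r}: expected {n_samples} samples"
        )
    recordings = []
    for idx, row in frame.iterrows():
        try:
            samples = np.asarray([float(row[c]) for c in scols])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric sample in row {idx}: {exc}") from exc
        if not np.all(np.isfinite(samples)):
            raise ValueError(f"non-finite sample in row {idx}")
        va = row["va_logmar"]
        recordings.append(
            PergRecording(
                participant_id=str(row["participant_id"]),
                visit=int(row["visit"]),
                eye=str(row["eye"]),
                diagnosis=str(row["diagnosis"]),
                age=float(row["age"]),
                sex=str(row["sex"]),
                va_logmar=float(va) if pd.notna(va) else float("nan"),
                samples=samples,
            )
        )
    return recordings


def filter_cohort(
    recordings: Iterable[PergRecording],
    rules: CohortFilterRules = CohortFilterRules(),
) -> list[PergRecording]:
    """Apply the cohort restrictions.

    Drops recordings outside the allowed diagnosis set, recordings without
    a visual-acuity measure (if required), and — per participant — every
    visit after the first retained one.  An empty result is a warning, not
    an error.
    """
    kept = [r for r in recordings if r.diagnosis in rules.allowed_diagnoses]
    if rules.require_va:
        kept = [r for r in kept if r.has_va]
    if rules.first_visit_only:
        first_visit: dict[str, int] = {}
        for r in kept:
            prev = first_visit.get(r.participant_id)
            if prev is None or r.visit < prev:
                first_visit[r.participant_id] = r.visit
        kept = [r for r in kept if r.visit == first_visit[r.participant_id]]
    if not kept:
        warnings.warn("cohort filter produced an empty cohort", stacklevel=2)
    return kept


def preprocess_trace(raw: Sequence[float], native_length: int | None = None) -> np.ndarray:
    """DC-detrend a native trace and pad it to 256 samples.

    Subtracts the mean of the raw trace (zero-order detrend — any linear
    drift is deliberately preserved), then, if the trace is 255 samples
    long, repeats the final detrended sample to reach dyadic length.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D trace")
    if native_length is not None and len(x) != native_length:
        raise ValueError(f"expected {native_length} samples, got {len(x)}")
    if len(x) not in (N_SAMPLES - 1, N_SAMPLES):
        raise ValueError(
            f"trace length must be {N_SAMPLES - 1} or {N_SAMPLES}, got {len(x)}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    x = x - x.mean()
    if len(x) == N_SAMPLES - 1:
        x = np.append(x, x[-1])
    return x


def preprocess_cohort(recordings: Iterable[PergRecording]) -> list[PergRecording]:
    """Preprocess every trace in a cohort (returns new recording objects)."""
    return [replace(r, samples=preprocess_trace(r.samples)) for r in recordings]
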