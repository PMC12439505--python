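"""Minimal inverse-DWT reconstruction of the canonical PERG peaks.

Each canonical component is measured as the signed extremum of the trace
inside a search window bracketing its nominal latency: N35 is the
minimum on 20-45 ms, P50 the maximum on 40-70 ms, N95 the minimum on
75-130 ms (ties resolve to the earliest time).  A candidate index set is
scored by reconstructing every trace of the (normal) cohort from only
those coefficients and comparing the peak against the original trace:

* voltage MAE — mean |amplitude difference| (µV),
* time MAE — mean |implicit-time difference| (ms),
* weighted MAE — their product (µV × ms), the selection criterion.

The greedy selection scores every single index drawn from the sub-100 Hz
levels (D4, D5, D6 and the deepest approximation for sym2), keeps the
best one, and then tries pairing it with each of the remaining top-5
singles; a pair replaces the single only when it lowers the weighted MAE
by at least 40%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dwt import (
    FS_HZ,
    IndexAddress,
    WaveletSpec,
    decompose,
    format_address,
    reconstruct_subset,
    time_grid,
)
from .io import PergRecording

#: search windows (ms) bracketing the canonical latencies ~35/50/95 ms
PEAK_SEARCH_WINDOWS_MS: dict[str, tuple[float, float]] = {
    "N35": (20.0, 45.0),
    "P50": (40.0, 70.0),
    "N95": (75.0, 130.0),
}
PEAK_POLARITY = {"N35": -1, "P50": +1, "N95": -1}
PEAKS = tuple(PEAK_SEARCH_WINDOWS_MS)


@dataclass(frozen=True)
class PeakMeasurement:
    """Signed amplitude (µV) and implicit time (ms) of one component."""

    amplitude: float
    implicit_time_ms: float
    found: bool = True


def measure_peaks(
    samples: Sequence[float],
    windows: Mapping[str, tuple[float, float]] | None = None,
    fs: float = FS_HZ,
) -> dict[str, PeakMeasurement]:
    """Extrema of the trace inside each peak's search window."""
    x = np.asarray(samples, dtype=float)
    t = time_grid(x.size, fs)
    windows = dict(PEAK_SEARCH_WINDOWS_MS, **(windows or {}))
    out: dict[str, PeakMeasurement] = {}
    for peak, (lo, hi) in windows.items():
        mask = (t >= lo) & (t <= hi)
        if not mask.any():
            out[peak] = PeakMeasurement(0.0, lo, found=False)
            continue
        seg = x[mask]
        # argmin/argmax return the first occurrence: earliest-time tie rule
        k = int(np.argmax(seg)) if PEAK_POLARITY[peak] > 0 else int(np.argmin(seg))
        out[peak] = PeakMeasurement(float(seg[k]), float(t[mask][k]))
    return out


@dataclass(frozen=True)
class ReconstructionError:
    """MAE of one peak over a cohort, for one index set."""

    peak: str
    indices: tuple[IndexAddress, ...]
    v_mae: float  # µV
    t_mae: float  # ms
    weighted: float  # µV × ms

    @property
    def label(self) -> str:
        return ", ".join(format_address(a) for a in self.indices)


def _trace_of(obj) -> np.ndarray:
    return obj.samples if isinstance(obj, PergRecording) else np.asarray(obj, float)


class _ReconstructionScorer:
    """Caches decompositions and one-index reconstructions per trace.

    Subset reconstruction is linear, so any index set is scored by
    summing the cached single-index reconstructions.
    """

    def __init__(self, cohort, wavelet: str, windows=None):
        self.spec = WaveletSpec.from_name(wavelet)
        self.windows = windows
        self.traces = [_trace_of(r) for r in cohort]
        if not self.traces:
            raise ValueError("empty cohort")
        self.decomps = [decompose(tr, self.spec) for tr in self.traces]
        self.original_peaks = [measure_peaks(tr, windows) for tr in self.traces]
        self._singles: dict[IndexAddress, list[np.ndarray]] = {}

    def _single(self, address: IndexAddress) -> list[np.ndarray]:
        if address not in self._singles:
            self._singles[address] = [
                reconstruct_subset(d, [address]) for d in self.decomps
            ]
        return self._singles[address]

    def error(self, indices: Iterable[IndexAddress], peak: str) -> ReconstructionError:
        indices = tuple(indices)
        parts = [self._single(a) for a in indices]
        dv = np.empty(len(self.traces))
        dt = np.empty(len(self.traces))
        for i in range(len(self.traces)):
            recon = sum(p[i] for p in parts) if parts else np.zeros_like(self.traces[i])
            m = measure_peaks(recon, self.windows)[peak]
            orig = self.original_peaks[i][peak]
            dv[i] = abs(m.amplitude - orig.amplitude)
            dt[i] = abs(m.implicit_time_ms - orig.implicit_time_ms)
        v_mae = float(dv.mean())
        t_mae = float(dt.mean())
        return ReconstructionError(peak, indices, v_mae, t_mae, v_mae * t_mae)


def reconstruction_error(
    cohort,
    wavelet: str,
    index_set: Iterable[IndexAddress],
    peak: str,
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> ReconstructionError:
    """Peak MAE of one index-set reconstruction over a cohort of traces."""
    if peak not in PEAK_SEARCH_WINDOWS_MS and (windows is None or peak not in windows):
        raise ValueError(f"unknown peak {peak!r}")
    return _ReconstructionScorer(cohort, wavelet, windows).error(index_set, peak)


@dataclass(frozen=True)
class SelectionResult:
    """Greedy selection outcome for one peak."""

    peak: str
    indices: tuple[IndexAddress, ...]
    error: ReconstructionError
    augmented: bool
    singles: pd.DataFrame  # ranked single-index scores (top candidates)


def default_candidate_levels(wavelet: str) -> list[tuple[str, int]]:
    """The sub-100 Hz levels: D4, D5, D6 (as available) plus the deepest A."""
    spec = WaveletSpec.from_name(wavelet)
    levels: list[tuple[str, int]] = [
        ("D", lvl) for lvl in (4, 5, 6) if lvl <= spec.max_level
    ]
    levels.append(("A", spec.max_level))
    return levels


def _sort_key(err: ReconstructionError):
    # the weighted MAE is a product, so it collapses to zero whenever either
    # factor does; break those ties on the factors before falling back to
    # the positional rule (lower level, detail first, lower position)
    band, level, position = err.indices[-1]
    return (err.weighted, err.v_mae, err.t_mae, level, 0 if band == "D" else 1, position)


def select_minimal_indices(
    cohort,
    wavelet: str = "sym2",
    candidate_levels: Sequence[tuple[str, int]] | None = None,
    improvement: float = 0.40,
    n_top: int = 5,
    peaks: Sequence[str] = PEAKS,
    windows: Mapping[str, tuple[float, float]] | None = None,
) -> dict[str, SelectionResult]:
    """Smallest index set preserving each canonical peak.

    Per peak: every single index from the candidate levels is scored by
    weighted MAE; the best single is retained; each of the remaining
    top-``n_top`` singles is then tried alongside it, and the best pair
    replaces the single only if it lowers the weighted MAE by at least
    ``improvement`` (strictly).  Ties break toward lower level, detail
    before approximation, then lower position.
    """
    scorer = _ReconstructionScorer(cohort, wavelet, windows)
    if candidate_levels is None:
        candidate_levels = default_candidate_levels(wavelet)
    addresses: list[IndexAddress] = []
    for band, level in candidate_levels:
        n_coef = len(scorer.decomps[0].coefficients(band, level))
        addresses.extend((band, level, k + 1) for k in range(n_coef))

    results: dict[str, SelectionResult] = {}
    for peak in peaks:
        singles = sorted((scorer.error([a], peak) for a in addresses), key=_sort_key)
        best = singles[0]
        chosen, augmented = best, False
        candidates = singles[1:n_top]
        if candidates and best.weighted > 0:
            pairs = sorted(
                (scorer.error(best.indices + c.indices, peak) for c in candidates),
                key=_sort_key,
            )
            if pairs[0].weighted <= (1.0 - improvement) * best.weighted:
                chosen, augmented = pairs[0], True
        table = pd.DataFrame(
            [
                {
                    "index": s.label,
                    "v_mae": s.v_mae,
                    "t_mae": s.t_mae,
                    "weighted": s.weighted,
                }
                for s in singles[: max(n_top, 1)]
            ]
        )
        results[peak] = SelectionResult(peak, chosen.indices, chosen, augmented, table)
    return results


def selection_report(results: Mapping[str, SelectionResult]) -> pd.DataFrame:
    """Per-peak selected indices and their errors, one row per peak."""
    rows = []
    for peak, sel in results.items():
        rows.append(
            {
                "peak": peak,
                "indices": sel.error.label,
                "v_mae": sel.error.v_mae,
                "t_mae": sel.error.t_mae,
                "weighted": sel.error.weighted,
                "augmented": sel.augmented,
            }
        )
    return pd.DataFrame(rows)
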