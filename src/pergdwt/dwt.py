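"""Multilevel discrete wavelet transform of PERG traces.

All decompositions are orthogonal and periodized ("per" extension): the
256-sample trace is treated as circular, which is the natural boundary
model for a steady-state pattern-reversal response and is what makes the
coefficient counts exactly dyadic (level ``d`` holds ``256 / 2**d``
coefficients) and Parseval / perfect reconstruction exact.  Other
extension modes are deliberately not supported.

Every coefficient is addressed as ``(band, level, position)`` with band
``"A"`` (approximation, lowpass) or ``"D"`` (detail, bandpass), and a
1-based position, matching the conventional "D6-2" naming.  Squaring a
coefficient gives the energy of its time-frequency cell; the cell's
nominal window is computed by :func:`index_window`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pywt

from . import _fejer_korovkin

#: pipeline constants: ISCEV-style PERG acquisition, padded to dyadic length
N_SAMPLES = 256
FS_HZ = 1700.0
DURATION_MS = 150.0

#: the 20 candidate mother wavelets screened by the energy-to-entropy ratio
SUPPORTED_WAVELETS = (
    "haar",
    "db2", "db3", "db4", "db5", "db6", "db7", "db8",
    "sym2", "sym3", "sym4", "sym5", "sym6", "sym7", "sym8",
    "coif1", "coif2",
    "fk4", "fk6", "fk8",
)

#: haar is decomposed to level 7 so that D7 splits the trace into a P50
#: (0-75 ms) and an N95 (75-150 ms) half, rather than its admissible level 8
HAAR_MAX_LEVEL = 7

IndexAddress = tuple[str, int, int]


def time_grid(n_samples: int = N_SAMPLES, fs: float = FS_HZ) -> np.ndarray:
    """Sample times in ms (0 ... 150 ms at 1700 Hz for the default trace)."""
    return np.arange(n_samples) / fs * 1000.0


def get_wavelet(name: str) -> pywt.Wavelet:
    """The pywt filter bank for a supported mother wavelet name."""
    if name not in SUPPORTED_WAVELETS:
        raise ValueError(
            f"unknown wavelet {name!r}; supported: {', '.join(SUPPORTED_WAVELETS)}"
        )
    if name in _fejer_korovkin.FK_LENGTHS:
        return _fejer_korovkin.wavelet(name)
    return pywt.Wavelet(name)


def max_level(name: str, n_samples: int = N_SAMPLES) -> int:
    """Maximum admissible decomposition depth: floor(log2(n / (L - 1))).

    The haar wavelet is capped at 7 (see :data:`HAAR_MAX_LEVEL`).
    """
    filt = get_wavelet(name).dec_len
    level = int(math.floor(math.log2(n_samples / (filt - 1))))
    if name == "haar":
        level = min(HAAR_MAX_LEVEL, level)
    if level < 1:
        raise ValueError(f"{name}: filter too long for {n_samples} samples")
    return level


@dataclass(frozen=True)
class WaveletSpec:
    """A mother wavelet together with its filter length and admissible depth."""

    name: str
    filter_length: int
    max_level: int

    @classmethod
    def from_name(cls, name: str, n_samples: int = N_SAMPLES) -> "WaveletSpec":
        return cls(name, get_wavelet(name).dec_len, max_level(name, n_samples))


@dataclass(frozen=True)
class TimeFreqWindow:
    """Nominal time/frequency cell of one coefficient (unrounded bounds)."""

    t_lo: float
    t_hi: float
    f_lo: float
    f_hi: float

    @property
    def t_center(self) -> float:
        return 0.5 * (self.t_lo + self.t_hi)

    @property
    def f_center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)

    # integer bounds as conventionally printed: time rounds half to even,
    # frequency half away from zero
    @property
    def t_lo_ms(self) -> int:
        return int(round(self.t_lo))

    @property
    def t_hi_ms(self) -> int:
        return int(round(self.t_hi))

    @property
    def f_lo_hz(self) -> int:
        return int(math.floor(self.f_lo + 0.5))

    @property
    def f_hi_hz(self) -> int:
        return int(math.floor(self.f_hi + 0.5))

    def overlaps_time(self, lo_ms: float, hi_ms: float) -> bool:
        return self.t_lo < hi_ms and self.t_hi > lo_ms


def index_window(
    band: str,
    level: int,
    position: int,
    n_samples: int = N_SAMPLES,
    duration_ms: float = DURATION_MS,
    fs: float = FS_HZ,
) -> TimeFreqWindow:
    """Time/frequency window of coefficient ``position`` in band ``band``/``level``.

    Time: level-``d`` coefficients tile the ``duration_ms`` window into
    ``n_samples / 2**d`` equal cells; position ``k`` (1-based) covers
    ``[(k-1) w, k w]`` with ``w = duration_ms * 2**d / n_samples``.
    Frequency: detail level ``d`` spans the ideal dyadic band
    ``[fs / 2**(d+1), fs / 2**d]``; the approximation spans
    ``[0, fs / 2**(d+1)]``.
    """
    if band not in ("A", "D"):
        raise ValueError(f"band must be 'A' or 'D', got {band!r}")
    if level < 1 or 2**level > n_samples:
        raise ValueError(f"level {level} out of range for {n_samples} samples")
    n_cells = n_samples // 2**level
    if not 1 <= position <= n_cells:
        raise ValueError(
            f"position {position} out of range 1..{n_cells} at level {level}"
        )
    width = duration_ms * 2**level / n_samples
    t_lo = (position - 1) * width
    t_hi = position * width
    if band == "D":
        f_lo, f_hi = fs / 2 ** (level + 1), fs / 2**level
    else:
        f_lo, f_hi = 0.0, fs / 2 ** (level + 1)
    return TimeFreqWindow(t_lo, t_hi, f_lo, f_hi)


@dataclass(frozen=True)
class EnergyIndex:
    """One addressable time-frequency cell with its energy (µV²)."""

    wavelet: str
    band: str
    level: int
    position: int
    energy: float
    window: TimeFreqWindow

    @property
    def name(self) -> str:
        return f"{self.wavelet}-{self.band}{self.level}-{self.position}"


@dataclass
class WaveletDecomposition:
    """Per-level coefficient arrays of one trace under one mother wavelet."""

    wavelet: WaveletSpec
    level: int
    approximation: np.ndarray
    details: dict[int, np.ndarray]
    n_samples: int

    def coefficients(self, band: str, level: int) -> np.ndarray:
        if band == "A":
            if level != self.level:
                raise ValueError(
                    f"approximation exists only at level {self.level}, not {level}"
                )
            return self.approximation
        if band == "D":
            try:
                return self.details[level]
            except KeyError:
                raise ValueError(f"no detail level {level} in this decomposition")
        raise ValueError(f"band must be 'A' or 'D', got {band!r}")

    def coefficient(self, address: IndexAddress) -> float:
        band, level, position = address
        arr = self.coefficients(band, level)
        if not 1 <= position <= len(arr):
            raise ValueError(f"position out of range in {address}")
        return float(arr[position - 1])

    def energy(self, address: IndexAddress) -> float:
        return self.coefficient(address) ** 2

    def addresses(self) -> list[IndexAddress]:
        out: list[IndexAddress] = []
        for level in sorted(self.details):
            out.extend(("D", level, k + 1) for k in range(len(self.details[level])))
        out.extend(("A", self.level, k + 1) for k in range(len(self.approximation)))
        return out


def decompose(
    samples: Sequence[float],
    wavelet: str | WaveletSpec,
    level: int | None = None,
) -> WaveletDecomposition:
    """Periodized orthogonal DWT of a dyadic-length trace.

    ``level`` defaults to the wavelet's admissible maximum.  Parseval holds
    exactly: the sum of squared coefficients equals the sum of squared
    samples (to round-off).
    """
    spec = wavelet if isinstance(wavelet, WaveletSpec) else WaveletSpec.from_name(wavelet)
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D trace")
    n = x.size
    if n == 0 or n & (n - 1):
        raise ValueError(f"trace length must be a power of two, got {n}")
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite samples")
    if level is None:
        level = spec.max_level
    if not 1 <= level <= spec.max_level:
        raise ValueError(f"level must be in 1..{spec.max_level} for {spec.name}")
    coeffs = pywt.wavedec(x, get_wavelet(spec.name), mode="periodization", level=level)
    details = {level - i + 1: np.asarray(coeffs[i]) for i in range(1, level + 1)}
    return WaveletDecomposition(
        wavelet=spec,
        level=level,
        approximation=np.asarray(coeffs[0]),
        details=details,
        n_samples=n,
    )


def energy_map(
    decomp: WaveletDecomposition,
    duration_ms: float = DURATION_MS,
    fs: float = FS_HZ,
) -> list[EnergyIndex]:
    """One EnergyIndex (squared coefficient + window) per coefficient."""
    out = []
    for band, level, position in decomp.addresses():
        out.append(
            EnergyIndex(
                wavelet=decomp.wavelet.name,
                band=band,
                level=level,
                position=position,
                energy=decomp.energy((band, level, position)),
                window=index_window(
                    band, level, position, decomp.n_samples, duration_ms, fs
                ),
            )
        )
    return out


def scalogram_table(decomp: WaveletDecomposition) -> pd.DataFrame:
    """Long-format scalogram: wavelet, band, level, position, window, energy."""
    rows = [
        {
            "wavelet": e.wavelet,
            "band": e.band,
            "level": e.level,
            "position": e.position,
            "t_lo": e.window.t_lo,
            "t_hi": e.window.t_hi,
            "f_lo": e.window.f_lo,
            "f_hi": e.window.f_hi,
            "energy": e.energy,
        }
        for e in energy_map(decomp)
    ]
    return pd.DataFrame(rows)


def _validate_addresses(
    decomp: WaveletDecomposition, kept: Iterable[IndexAddress]
) -> set[IndexAddress]:
    addresses = set()
    for addr in kept:
        decomp.coefficient(addr)  # raises on invalid
        addresses.add(tuple(addr))
    return addresses


def reconstruct_subset(
    decomp: WaveletDecomposition, kept: Iterable[IndexAddress]
) -> np.ndarray:
    """Inverse DWT with every coefficient outside ``kept`` zeroed.

    Linear in the kept set: disjoint sets reconstruct additively.
    """
    addresses = _validate_addresses(decomp, kept)
    approx = np.zeros_like(decomp.approximation)
    details = {lvl: np.zeros_like(arr) for lvl, arr in decomp.details.items()}
    for band, level, position in addresses:
        if band == "A":
            approx[position - 1] = decomp.approximation[position - 1]
        else:
            details[level][position - 1] = decomp.details[level][position - 1]
    coeffs = [approx] + [details[lvl] for lvl in sorted(details, reverse=True)]
    rec = pywt.waverec(coeffs, get_wavelet(decomp.wavelet.name), mode="periodization")
    return np.asarray(rec[: decomp.n_samples])


def single_index_signal(
    wavelet: str,
    address: IndexAddress,
    value: float = 1.0,
    n_samples: int = N_SAMPLES,
    level: int | None = None,
) -> np.ndarray:
    """The trace whose decomposition is a single coefficient of given value."""
    decomp = decompose(np.zeros(n_samples), wavelet, level=level)
    band, lvl, position = address
    arr = decomp.coefficients(band, lvl)
    if not 1 <= position <= len(arr):
        raise ValueError(f"position out of range in {address}")
    arr[position - 1] = value
    return reconstruct_subset(decomp, [address])


def parse_address(text: str) -> IndexAddress:
    """Parse 'D6-2' / 'A6-3' style coefficient labels."""
    band = text[0].upper()
    level_s, _, pos_s = text[1:].partition("-")
    if band not in ("A", "D") or not level_s.isdigit() or not pos_s.isdigit():
        raise ValueError(f"cannot parse coefficient address {text!r}")
    return band, int(level_s), int(pos_s)


def format_address(address: IndexAddress) -> str:
    band, level, position = address
    return f"{band}{level}-{position}"
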