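"""Energy-to-entropy screening of candidate mother wavelets.

For a set of DWT coefficients ``c_i`` the energy is ``E = sum c_i²`` and
the Shannon entropy of the normalised energies ``p_i = c_i²/E`` is
``H = -sum p_i ln p_i`` (natural log; the argmax over wavelets is
base-invariant).  A wavelet that concentrates signal power into few
coefficients has high E and low H, so the ratio E·H⁻¹ rewards compact,
physiologically faithful decompositions.

The ratio is computed per recording, averaged within participant and then
across participants (two-stage averaging avoids biasing toward
participants with many recordings); 95% bootstrap confidence intervals
resample participants by default.  The retention rule keeps, for each
scope (a band/level, e.g. D6, or "overall"), the wavelet with the highest
mean ratio, plus any forced inclusions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dwt import WaveletSpec, decompose
from .io import PergRecording

#: the per-level scopes screened in addition to nothing else by default:
#: the detail levels below 100 Hz and the two deepest shared approximations
DEFAULT_SCOPES = (("D", 4), ("D", 5), ("D", 6), ("A", 5), ("A", 6))

Scope = str | tuple[str, int]


class ZeroEntropyError(ValueError):
    """All energy in a single coefficient: E/H is undefined."""


def energy(coeffs: Sequence[float]) -> float:
    """E = sum of squared coefficients (µV²)."""
    c = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("coefficients must be finite")
    return float(np.sum(c**2))


def shannon_entropy(coeffs: Sequence[float]) -> float:
    """H = -sum p_i ln p_i of the normalised coefficient energies (nats)."""
    c = np.asarray(coeffs, dtype=float)
    e = energy(c)
    if e == 0.0:
        raise ValueError("entropy undefined for all-zero coefficients")
    p = c**2 / e
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _scope_coefficients(samples, wavelet: str, scope: Scope) -> np.ndarray:
    spec = WaveletSpec.from_name(wavelet)
    if scope == "overall":
        decomp = decompose(samples, spec)
        parts = [decomp.approximation] + [decomp.details[l] for l in sorted(decomp.details)]
        return np.concatenate(parts)
    band, level = scope
    if band == "D":
        if level > spec.max_level:
            raise ValueError(f"{wavelet} has no detail level {level}")
        return decompose(samples, spec).details[level]
    if band == "A":
        if level > spec.max_level:
            raise ValueError(f"{wavelet} has no approximation level {level}")
        return decompose(samples, spec, level=level).approximation
    raise ValueError(f"invalid scope {scope!r}")


def energy_entropy_ratio(samples, wavelet: str, scope: Scope = "overall") -> float:
    """E·H⁻¹ of one trace for one wavelet, overall or restricted to a level."""
    coeffs = _scope_coefficients(samples, wavelet, scope)
    e = energy(coeffs)
    if e == 0.0:
        raise ZeroEntropyError("all-zero coefficients")
    h = shannon_entropy(coeffs)
    if h == 0.0:
        raise ZeroEntropyError("point-mass energy distribution, H = 0")
    return e / h


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the mean (resampling the given units)."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, v.size, size=(n_boot, v.size))
    means = v[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass(frozen=True)
class ScreeningResult:
    """Mean E·H⁻¹ of one wavelet at one scope, with bootstrap CI."""

    wavelet: str
    scope: Scope
    mean_ratio: float
    ci_lo: float
    ci_hi: float
    n_participants: int
    retained: bool = False


def _scope_name(scope: Scope) -> str:
    return scope if scope == "overall" else f"{scope[0]}{scope[1]}"


def screening_table(results: Iterable[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "wavelet": r.wavelet,
                "scope": _scope_name(r.scope),
                "mean_ratio": r.mean_ratio,
                "ci_lo": r.ci_lo,
                "ci_hi": r.ci_hi,
                "n_participants": r.n_participants,
                "retained": r.retained,
            }
            for r in results
        ]
    )


def screen_wavelets(
    cohort: Sequence[PergRecording],
    candidates: Sequence[str],
    scopes: Sequence[Scope] = DEFAULT_SCOPES,
    forced: Sequence[str] = (),
    n_boot: int = 10_000,
    seed: int = 0,
    resample_unit: str = "participant",
) -> tuple[list[ScreeningResult], list[str]]:
    """Screen candidate wavelets and return (results, retained wavelets).

    Retention: per scope, the wavelet with the highest participant-mean
    ratio (ties broken by shorter filter, then name), plus every wavelet
    in ``forced``.  A wavelet that cannot produce a scope (insufficient
    decomposition depth) simply does not compete there.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if resample_unit not in ("participant", "recording"):
        raise ValueError("resample_unit must be 'participant' or 'recording'")
    rng = np.random.default_rng(seed)
    results: list[ScreeningResult] = []
    best: dict[str, tuple] = {}
    for wavelet in candidates:
        spec = WaveletSpec.from_name(wavelet)
        for scope in scopes:
            if scope != "overall" and scope[1] > spec.max_level:
                continue
            per_recording: dict[str, list[float]] = {}
            all_ratios: list[float] = []
            for rec in cohort:
                try:
                    ratio = energy_entropy_ratio(rec.samples, wavelet, scope)
                except ZeroEntropyError:
                    continue
                per_recording.setdefault(rec.participant_id, []).append(ratio)
                all_ratios.append(ratio)
            if not per_recording:
                raise ValueError(f"no decomposable recordings for {wavelet}/{scope}")
            participant_means = np.array(
                [np.mean(v) for v in per_recording.values()]
            )
            mean_ratio = float(participant_means.mean())
            units = participant_means if resample_unit == "participant" else np.asarray(all_ratios)
            ci_lo, ci_hi = bootstrap_ci(units, n_boot=n_boot, seed=rng)
            results.append(
                ScreeningResult(
                    wavelet, scope, mean_ratio, ci_lo, ci_hi, len(participant_means)
                )
            )
            key = _scope_name(scope)
            cand = (-mean_ratio, spec.filter_length, wavelet)
            if key not in best or cand < best[key]:
                best[key] = cand
    winners = {entry[2] for entry in best.values()}
    retained = [w for w in candidates if w in winners or w in forced]
    results = [
        ScreeningResult(
            r.wavelet, r.scope, r.mean_ratio, r.ci_lo, r.ci_hi,
            r.n_participants, r.wavelet in retained,
        )
        for r in results
    ]
    return results, retained
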