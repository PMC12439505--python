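"""Participant-level energy features and group-comparison statistics.

Feature construction mirrors the screening's physiological constraints:
detail levels D1-D3 carry only content above 100 Hz — outside the
hardware band-pass — and are dropped; of the approximations only the
deepest level is kept (shallower approximations duplicate the frequency
content of the retained details).  Each remaining coefficient index of
each retained wavelet contributes one energy feature, named
``<wavelet>-<band><level>-<position>`` (e.g. ``sym2-D6-2``); recordings
are averaged within participant so every participant contributes one row
regardless of how many eyes/repeats were recorded.

Group separation (normal vs mpIRD) is tested with the Mann–Whitney U
test (U oriented as "normal greater", asymptotic z with midrank tie
correction, no continuity correction), the false discovery rate is
controlled with Benjamini–Hochberg, and two effect sizes are reported:

* ``r_es = |z| / sqrt(N)`` — the Mann–Whitney effect size;
* ``CLES = U / (n_normal * n_mpird)`` — the probability that a random
  normal observation exceeds a random mpIRD observation (identical to
  the ROC AUC).

Redundant features (participant-level Spearman |rho| > 0.9) are pruned
greedily in descending r_es order, dropping the weaker of each pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dwt import IndexAddress, WaveletSpec, decompose, format_address, index_window, parse_address
from .io import PergRecording

logger = logging.getLogger(__name__)

#: the six wavelets the energy-to-entropy screen retains at this geometry
RETAINED_WAVELETS_DEFAULT = ("haar", "sym2", "sym4", "db4", "coif1", "fk4")

MIN_DETAIL_LEVEL = 4


def feature_addresses(wavelet: str) -> list[IndexAddress]:
    """Retained addresses for one wavelet: D4..Dmax plus the deepest A."""
    spec = WaveletSpec.from_name(wavelet)
    n = 256
    out: list[IndexAddress] = []
    for level in range(MIN_DETAIL_LEVEL, spec.max_level + 1):
        out.extend(("D", level, k + 1) for k in range(n // 2**level))
    out.extend(
        ("A", spec.max_level, k + 1) for k in range(n // 2**spec.max_level)
    )
    return out


def feature_name(wavelet: str, address: IndexAddress) -> str:
    return f"{wavelet}-{format_address(address)}"


def parse_feature_name(name: str) -> tuple[str, IndexAddress]:
    wavelet, _, addr = name.partition("-")
    return wavelet, parse_address(addr)


def feature_window(name: str):
    """Time/frequency window of a named feature."""
    _, (band, level, position) = parse_feature_name(name)
    return index_window(band, level, position)


@dataclass
class FeatureTable:
    """Participants × energy features, with the group label per participant."""

    values: pd.DataFrame  # index: participant_id; columns: feature names
    groups: pd.Series  # index: participant_id; 'normal' / 'mpird'

    @property
    def n_normal(self) -> int:
        return int((self.groups == "normal").sum())

    @property
    def n_mpird(self) -> int:
        return int((self.groups == "mpird").sum())

    def group_values(self, feature: str) -> tuple[np.ndarray, np.ndarray]:
        col = self.values[feature]
        return (
            col[self.groups == "normal"].to_numpy(),
            col[self.groups == "mpird"].to_numpy(),
        )


def build_feature_table(
    cohort: Sequence[PergRecording],
    wavelets: Sequence[str] = RETAINED_WAVELETS_DEFAULT,
) -> FeatureTable:
    """Per-recording energies averaged within participant.

    Column order is deterministic: wavelets in the given order, details
    by ascending level then position, then the deepest approximation.
    """
    if not cohort:
        raise ValueError("empty cohort")
    columns: list[str] = []
    per_wavelet_addresses = {}
    for w in wavelets:
        addrs = feature_addresses(w)
        per_wavelet_addresses[w] = addrs
        columns.extend(feature_name(w, a) for a in addrs)

    sums: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    groups: dict[str, str] = {}
    for rec in cohort:
        energies = []
        for w in wavelets:
            decomp = decompose(rec.samples, w)
            energies.extend(decomp.energy(a) for a in per_wavelet_addresses[w])
        vec = np.asarray(energies)
        pid = rec.participant_id
        if pid in sums:
            sums[pid] += vec
            counts[pid] += 1
        else:
            sums[pid] = vec
            counts[pid] = 1
            groups[pid] = rec.group
    values = pd.DataFrame(
        {pid: sums[pid] / counts[pid] for pid in sums}, index=columns
    ).T
    values.index.name = "participant_id"
    return FeatureTable(values=values, groups=pd.Series(groups, name="group"))


def mann_whitney(
    values_normal: Sequence[float], values_mpird: Sequence[float]
) -> tuple[float, float, float]:
    """(U, z, p): U oriented "normal greater"; asymptotic two-sided p.

    U counts cross pairs won by the normal group (ties 0.5).  z uses the
    normal approximation with the midrank tie correction and no
    continuity correction; with zero variance (all values tied) z = 0.
    """
    x = np.asarray(values_normal, dtype=float)
    y = np.asarray(values_mpird, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u = float(stats.mannwhitneyu(x, y, alternative="two-sided").statistic)
    n1, n2 = x.size, y.size
    n = n1 + n2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    if n > 1:
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    else:  # pragma: no cover - groups of one element each handled above
        sigma2 = 0.0
    if sigma2 <= 0:
        return u, 0.0, 1.0
    z = (u - n1 * n2 / 2.0) / np.sqrt(sigma2)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return u, float(z), min(p, 1.0)


def effect_sizes(u: float, z: float, n_normal: int, n_mpird: int) -> tuple[float, float]:
    """(r_es, CLES) from the Mann–Whitney statistics."""
    if min(n_normal, n_mpird) < 1:
        raise ValueError("group sizes must be >= 1")
    r_es = abs(z) / np.sqrt(n_normal + n_mpird)
    cles = u / (n_normal * n_mpird)
    return float(r_es), float(cles)


def bh_adjust(p_values: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


def compute_feature_stats(table: FeatureTable, alpha: float = 0.05) -> pd.DataFrame:
    """Mann–Whitney + effect sizes + BH adjustment for every feature."""
    n1, n2 = table.n_normal, table.n_mpird
    rows = []
    for feature in table.values.columns:
        x, y = table.group_values(feature)
        u, z, p = mann_whitney(x, y)
        r_es, cles = effect_sizes(u, z, n1, n2)
        rows.append(
            {"feature": feature, "U": u, "z": z, "p": p, "r_es": r_es, "cles": cles}
        )
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adj"], out["reject"] = bh_adjust(out["p"].to_numpy(), alpha=alpha)
    out["n_normal"] = n1
    out["n_mpird"] = n2
    return out


def rank_features(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Descending r_es, stable (ties keep the table's column order)."""
    return stats_table.sort_values("r_es", ascending=False, kind="stable")


def prune_correlated(
    table: FeatureTable,
    stats_table: pd.DataFrame,
    threshold: float = 0.9,
) -> list[str]:
    """Greedy redundancy pruning by participant-level Spearman correlation.

    Features are visited in descending r_es (ties: descending CLES, then
    name); a feature is kept iff its |rho| with every already-kept
    feature is <= threshold.  A constant feature has undefined rho and is
    treated as uncorrelated (|rho| = 0).
    """
    order = stats_table.assign(_name=stats_table.index).sort_values(
        ["r_es", "cles", "_name"], ascending=[False, False, True], kind="stable"
    )
    features = list(order.index)
    data = table.values
    constant = data.std(ddof=0) == 0
    if constant.any():
        logger.info(
            "constant features treated as uncorrelated in pruning: %s",
            list(data.columns[constant]),
        )
    rho = data[features].corr(method="spearman").to_numpy()
    rho = np.nan_to_num(rho, nan=0.0)  # constants: undefined -> uncorrelated
    pos = {f: i for i, f in enumerate(features)}
    kept: list[str] = []
    for f in features:
        if all(abs(rho[pos[f], pos[k]]) <= threshold for k in kept):
            kept.append(f)
    # report in the original column order for determinism
    return [f for f in data.columns if f in set(kept)]


def stats_report(
    stats_table: pd.DataFrame, kept: Sequence[str] | None = None
) -> pd.DataFrame:
    """Ranked stats with the printed-window columns, optionally pruned."""
    ranked = rank_features(stats_table)
    if kept is not None:
        ranked = ranked.loc[[f for f in ranked.index if f in set(kept)]]
    windows = [feature_window(f) for f in ranked.index]
    ranked = ranked.copy()
    ranked["time_range_ms"] = [f"{w.t_lo_ms}-{w.t_hi_ms}" for w in windows]
    ranked["frequency_band_hz"] = [f"{w.f_lo_hz}-{w.f_hi_hz}" for w in windows]
    return ranked
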