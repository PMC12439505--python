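"""Benchmarking wavelet indices against clinical time-domain markers.

The conventional macular-cone marker is the trough-to-peak amplitude
|P50−N35| and the retinal-ganglion-cell marker is |N95−P50|.  Each
retained wavelet index (and each selected index pair, summarised by the
mean of its two energies) is compared against these markers three ways,
at the participant level:

* Tukey five-number summaries per group (type-7 linear-interpolation
  quartiles — the fences depend on this convention);
* ROC AUC for normal-vs-mpIRD discrimination (AUC is identical to the
  common-language effect size);
* Mann–Whitney effect size r_es;

plus Pearson correlations between index energies and the clinical
markers across normal participants.  Recordings whose index value lies
more than ``k`` standard deviations above the mean of the *remaining*
normal recordings (leave-one-out, one-sided, default k = 4) are omitted
from the correlation analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .dwt import IndexAddress, decompose, format_address
from .features import effect_sizes, mann_whitney
from .io import PergRecording
from .reconstruction import PeakMeasurement, measure_peaks


@dataclass(frozen=True)
class ClinicalMarkers:
    """Trough-to-peak amplitudes (µV) of the two canonical responses."""

    p50_n35: float
    n95_p50: float


def clinical_markers(peaks: Mapping[str, PeakMeasurement]) -> ClinicalMarkers:
    return ClinicalMarkers(
        p50_n35=abs(peaks["P50"].amplitude - peaks["N35"].amplitude),
        n95_p50=abs(peaks["N95"].amplitude - peaks["P50"].amplitude),
    )


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson r on participant-level values (requires >= 3 pairs)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def roc_auc(values: Sequence[float], labels: Sequence[str], positive: str = "normal") -> float:
    """P(random positive value > random negative value), ties 0.5."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(y, values))


def outlier_filter(values: Sequence[float], k: float = 4.0) -> np.ndarray:
    """Boolean keep-mask: drop values > leave-one-out mean + k·SD.

    Mean and SD are computed on the remaining values (the value under
    test excluded), matching the "greater than the mean of the remaining
    cohort" phrasing; the rule is one-sided.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need >= 2 values")
    keep = np.ones(v.size, dtype=bool)
    for i in range(v.size):
        rest = np.delete(v, i)
        sd = rest.std(ddof=1) if rest.size > 1 else 0.0
        if v[i] > rest.mean() + k * sd:
            keep[i] = False
    return keep


@dataclass(frozen=True)
class TukeySummary:
    """Five-number box summary with 1.5·IQR whiskers."""

    q1: float
    median: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple[float, ...]


def tukey_summary(values: Sequence[float]) -> TukeySummary:
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 1:
        raise ValueError("need >= 1 value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # type-7 linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = v[(v < lo_fence) | (v > hi_fence)]
    return TukeySummary(
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=tuple(float(o) for o in outliers),
    )


def combined_index_value(
    energies: Mapping[IndexAddress, float], pair: Sequence[IndexAddress]
) -> float:
    """Arithmetic mean of two indices' energies (a paired-index metric)."""
    a, b = pair
    return 0.5 * (energies[a] + energies[b])


def _metric_label(indices: tuple[IndexAddress, ...], wavelet: str) -> str:
    return " + ".join(f"{wavelet}-{format_address(a)}" for a in indices)


@dataclass
class BenchmarkReport:
    """Group discrimination and marker correlations for selected metrics."""

    discrimination: pd.DataFrame  # metric × (auc, r_es, U, p)
    boxes: dict[str, dict[str, TukeySummary]]  # metric -> group -> summary
    correlations: pd.DataFrame  # metric × clinical marker (Pearson r, normals)
    n_outlier_recordings: int = 0


def run_benchmark(
    cohort: Sequence[PergRecording],
    wavelet: str = "sym2",
    index_sets: Sequence[Sequence[IndexAddress]] = ((("D", 6, 2),),),
    outlier_k: float = 4.0,
) -> BenchmarkReport:
    """Participant-level benchmark of wavelet metrics vs clinical markers.

    Each entry of ``index_sets`` is one metric: a single address, or a
    pair whose energies are averaged.  Discrimination (AUC, r_es, Tukey
    boxes) uses all participants; Pearson correlations use normal
    participants only, after the leave-one-out outlier filter has been
    applied per metric to the normal recordings.
    """
    if not cohort:
        raise ValueError("empty cohort")
    index_sets = [tuple(tuple(a) for a in s) for s in index_sets]

    rows = []
    for rec in cohort:
        decomp = decompose(rec.samples, wavelet)
        markers = clinical_markers(measure_peaks(rec.samples))
        row = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "p50_n35": markers.p50_n35,
            "n95_p50": markers.n95_p50,
        }
        energies = {a: decomp.energy(a) for s in index_sets for a in s}
        for s in index_sets:
            label = _metric_label(s, wavelet)
            row[label] = (
                energies[s[0]] if len(s) == 1 else combined_index_value(energies, s)
            )
        rows.append(row)
    recordings = pd.DataFrame(rows)
    metric_labels = [_metric_label(s, wavelet) for s in index_sets]
    all_metrics = metric_labels + ["p50_n35", "n95_p50"]

    participants = recordings.groupby("participant_id").agg(
        {**{m: "mean" for m in all_metrics}, "group": "first"}
    )

    disc_rows = []
    boxes: dict[str, dict[str, TukeySummary]] = {}
    labels = participants["group"].to_numpy()
    for metric in all_metrics:
        values = participants[metric].to_numpy()
        auc = roc_auc(values, labels)
        u, z, p = mann_whitney(values[labels == "normal"], values[labels == "mpird"])
        r_es, _ = effect_sizes(
            u, z, int((labels == "normal").sum()), int((labels == "mpird").sum())
        )
        disc_rows.append({"metric": metric, "auc": auc, "r_es": r_es, "U": u, "p": p})
        boxes[metric] = {
            g: tukey_summary(values[labels == g]) for g in ("normal", "mpird")
        }
    discrimination = pd.DataFrame(disc_rows).set_index("metric")

    # correlations: normal recordings, outlier-filtered per metric,
    # averaged within participant
    normal = recordings[recordings["group"] == "normal"]
    corr_rows = []
    n_outliers = 0
    for metric in metric_labels:
        keep = outlier_filter(normal[metric].to_numpy(), k=outlier_k)
        n_outliers += int((~keep).sum())
        per_part = normal[keep].groupby("participant_id")[
            [metric, "p50_n35", "n95_p50"]
        ].mean()
        corr_rows.append(
            {
                "metric": metric,
                "r_p50_n35": pearson_corr(per_part[metric], per_part["p50_n35"]),
                "r_n95_p50": pearson_corr(per_part[metric], per_part["n95_p50"]),
            }
        )
    correlations = pd.DataFrame(corr_rows).set_index("metric")
    return BenchmarkReport(discrimination, boxes, correlations, n_outliers)


def plot_benchmark(report: BenchmarkReport, path: str) -> None:
    """Boxplot + bar chart of the benchmark (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = list(report.boxes)
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    positions, heights, labels = [], [], []
    for i, metric in enumerate(metrics):
        for j, group in enumerate(("normal", "mpird")):
            s = report.boxes[metric][group]
            axes[0].bxp(
                [
                    {
                        "med": s.median,
                        "q1": s.q1,
                        "q3": s.q3,
                        "whislo": s.whisker_lo,
                        "whishi": s.whisker_hi,
                        "fliers": list(s.outliers),
                    }
                ],
                positions=[2 * i + j],
                widths=0.7,
            )
            labels.append(f"{metric}\n{group}")
            positions.append(2 * i + j)
    axes[0].set_xticks(positions, labels, rotation=45, fontsize=6)
    axes[0].set_ylabel("value")
    report.discrimination["auc"].plot.bar(ax=axes[1], ylabel="ROC AUC", rot=45)
    axes[1].axhline(0.5, color="grey", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
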