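"""End-to-end PERG wavelet analysis as a model/results pair.

:class:`PergDwtAnalysis` is constructed from a cohort of recordings (or a
CSV, or a synthetic-cohort configuration); ``fit()`` runs the full
analysis — preprocess → wavelet screening → feature table → group
statistics → redundancy pruning → minimal reconstruction selection →
clinical benchmarking — and returns a :class:`PergDwtResults` carrying
every intermediate table, a text ``summary()`` and a ``save()`` that
writes the CSV/JSON report bundle with a reproducibility manifest.
"""

from __future__ import annotations

import json
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, benchmark, features, io, reconstruction, screening, synthetic
from .dwt import SUPPORTED_WAVELETS, format_address

EYE_PARTITIONS = ("all", "RE", "LE", "worst_va", "worst_p50n35")

_FLOAT_FORMAT = "%.10g"


@dataclass
class PipelineConfig:
    """Everything that determines one analysis run."""

    input_csv: str | None = None
    n_samples: int = 256
    synthetic: synthetic.CohortConfig | None = None
    candidate_wavelets: tuple[str, ...] = SUPPORTED_WAVELETS
    forced_wavelets: tuple[str, ...] = ("haar", "coif1")
    scopes: tuple = screening.DEFAULT_SCOPES
    screen_n_boot: int = 10_000
    resample_unit: str = "participant"
    prune_threshold: float = 0.9
    alpha: float = 0.05
    reconstruction_wavelet: str = "sym2"
    improvement: float = 0.40
    n_top: int = 5
    eye_partition: str = "all"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prune_threshold <= 1:
            raise ValueError("prune_threshold must lie in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.improvement < 1:
            raise ValueError("improvement must lie in (0, 1)")
        if self.eye_partition not in EYE_PARTITIONS:
            raise ValueError(f"eye_partition must be one of {EYE_PARTITIONS}")

    def to_dict(self) -> dict:
        out = asdict(self)
        if self.synthetic is not None:
            out["synthetic"]["base_params"] = asdict(self.synthetic.base_params)
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        data = dict(data)
        syn = data.get("synthetic")
        if syn is not None:
            syn = dict(syn)
            base = syn.pop("base_params", None)
            if base is not None:
                syn["base_params"] = synthetic.WaveformParams(**base)
            data["synthetic"] = synthetic.CohortConfig(**syn)
        for key in ("candidate_wavelets", "forced_wavelets"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "scopes" in data:
            data["scopes"] = tuple(
                s if isinstance(s, str) else (s[0], int(s[1])) for s in data["scopes"]
            )
        return cls(**data)


def eye_partition_view(
    recordings: Sequence[io.PergRecording], partition: str
) -> list[io.PergRecording]:
    """Cohort view for the eye-specific sensitivity analyses.

    ``worst_va`` keeps, per participant, the eye with the higher (worse)
    mean logMAR VA; ``worst_p50n35`` the eye with the smaller mean
    |P50−N35| amplitude.  Ties keep the right eye.
    """
    if partition == "all":
        return list(recordings)
    if partition in ("RE", "LE"):
        return [r for r in recordings if r.eye == partition]
    per_eye: dict[tuple[str, str], list[float]] = {}
    for r in recordings:
        if partition == "worst_va":
            value = r.va_logmar
        else:
            peaks = reconstruction.measure_peaks(r.samples)
            value = benchmark.clinical_markers(peaks).p50_n35
        per_eye.setdefault((r.participant_id, r.eye), []).append(value)
    worst: dict[str, str] = {}
    for pid in {k[0] for k in per_eye}:
        eyes = {
            eye: float(np.nanmean(per_eye[(pid, eye)]))
            for eye in io.EYES
            if (pid, eye) in per_eye
        }
        if partition == "worst_va":
            worst[pid] = max(sorted(eyes), key=lambda e: eyes[e])
        else:
            worst[pid] = min(sorted(eyes), key=lambda e: eyes[e])
    return [r for r in recordings if worst.get(r.participant_id) == r.eye]


class PergDwtAnalysis:
    """The full DWT biomarker analysis of one PERG cohort.

    Parameters
    ----------
    recordings
        Preprocessed or raw recordings; traces of 255 samples are
        DC-detrended and padded to 256 on entry.
    config
        A :class:`PipelineConfig`; keyword overrides are applied on top.
    """

    def __init__(
        self,
        recordings: Sequence[io.PergRecording],
        config: PipelineConfig | None = None,
        **overrides,
    ):
        base = (config or PipelineConfig()).to_dict()
        syn = overrides.pop("synthetic", None)
        base.update(overrides)
        if isinstance(syn, synthetic.CohortConfig):
            base.pop("synthetic", None)
            self.config = PipelineConfig.from_dict(base)
            self.config.synthetic = syn
        else:
            if syn is not None:
                base["synthetic"] = syn
            self.config = PipelineConfig.from_dict(base)
        if not recordings:
            raise ValueError("empty cohort")
        self.recordings = io.preprocess_cohort(recordings)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        rules: io.CohortFilterRules = io.CohortFilterRules(),
        n_samples: int = 256,
        **overrides,
    ) -> "PergDwtAnalysis":
        raw = io.read_cohort(path, n_samples=n_samples)
        model = cls(io.filter_cohort(raw, rules), input_csv=str(path),
                    n_samples=n_samples, **overrides)
        return model

    @classmethod
    def from_synthetic(
        cls, cohort_config: synthetic.CohortConfig | None = None, **overrides
    ) -> "PergDwtAnalysis":
        cohort_config = cohort_config or synthetic.CohortConfig()
        recs = synthetic.generate_cohort(cohort_config)
        return cls(recs, synthetic=cohort_config, **overrides)

    def fit(self) -> "PergDwtResults":
        cfg = self.config
        cohort = eye_partition_view(self.recordings, cfg.eye_partition)
        if not cohort:
            raise ValueError(f"eye partition {cfg.eye_partition!r} left no recordings")

        screen_results, retained = screening.screen_wavelets(
            cohort,
            candidates=cfg.candidate_wavelets,
            scopes=cfg.scopes,
            forced=cfg.forced_wavelets,
            n_boot=cfg.screen_n_boot,
            seed=cfg.seed,
            resample_unit=cfg.resample_unit,
        )

        table = features.build_feature_table(cohort, retained)
        stats_table = features.compute_feature_stats(table, alpha=cfg.alpha)
        kept = features.prune_correlated(table, stats_table, cfg.prune_threshold)
        ranked = features.stats_report(stats_table, kept)

        normal_recordings = [r for r in cohort if r.group == "normal"]
        selection = reconstruction.select_minimal_indices(
            normal_recordings,
            wavelet=cfg.reconstruction_wavelet,
            improvement=cfg.improvement,
            n_top=cfg.n_top,
        )

        index_sets: list[tuple] = []
        for sel in selection.values():
            for addr in sel.indices:
                if (addr,) not in index_sets:
                    index_sets.append((addr,))
            if len(sel.indices) > 1 and tuple(sel.indices) not in index_sets:
                index_sets.append(tuple(sel.indices))
        top_feature = ranked.index[0] if len(ranked) else None
        if top_feature is not None:
            wname, addr = features.parse_feature_name(top_feature)
            if wname == cfg.reconstruction_wavelet and (addr,) not in index_sets:
                index_sets.insert(0, (addr,))
        bench = benchmark.run_benchmark(
            cohort, wavelet=cfg.reconstruction_wavelet, index_sets=index_sets
        )

        return PergDwtResults(
            model=self,
            screening=screening.screening_table(screen_results),
            retained_wavelets=retained,
            feature_table=table,
            feature_stats=stats_table,
            kept_features=kept,
            ranked_features=ranked,
            selection=selection,
            benchmark=bench,
        )


@dataclass
class PergDwtResults:
    """Fitted artefacts of one :class:`PergDwtAnalysis` run."""

    model: PergDwtAnalysis
    screening: pd.DataFrame
    retained_wavelets: list[str]
    feature_table: features.FeatureTable
    feature_stats: pd.DataFrame
    kept_features: list[str]
    ranked_features: pd.DataFrame
    selection: dict[str, reconstruction.SelectionResult]
    benchmark: benchmark.BenchmarkReport

    @property
    def top_feature(self) -> str:
        return str(self.ranked_features.index[0])

    def summary(self, n_features: int = 8) -> str:
        cfg = self.model.config
        lines = [
            "PERG discrete-wavelet-transform analysis",
            "=" * 40,
            f"cohort: {len(self.model.recordings)} recordings, "
            f"{self.feature_table.values.shape[0]} participants "
            f"({self.feature_table.n_normal} normal / {self.feature_table.n_mpird} mpIRD), "
            f"eye partition: {cfg.eye_partition}",
            f"retained wavelets: {', '.join(self.retained_wavelets)}",
            f"features: {self.feature_table.values.shape[1]} candidates, "
            f"{len(self.kept_features)} after |rho|>{cfg.prune_threshold} pruning",
            "",
            f"top features (by Mann-Whitney effect size r_es, BH alpha={cfg.alpha}):",
        ]
        cols = ["r_es", "cles", "p_adj", "time_range_ms", "frequency_band_hz"]
        lines.append(
            self.ranked_features[cols].head(n_features).to_string(
                float_format=lambda v: f"{v:.3f}"
            )
        )
        lines += ["", f"minimal {cfg.reconstruction_wavelet} reconstruction per peak:"]
        lines.append(
            reconstruction.selection_report(self.selection).to_string(
                index=False, float_format=lambda v: f"{v:.3f}"
            )
        )
        lines += ["", "participant-level benchmark vs clinical markers:"]
        lines.append(
            self.benchmark.discrimination[["auc", "r_es"]].to_string(
                float_format=lambda v: f"{v:.3f}"
            )
        )
        lines += ["", "Pearson r vs |P50-N35| / |N95-P50| (normal participants):"]
        lines.append(
            self.benchmark.correlations.to_string(float_format=lambda v: f"{v:.3f}")
        )
        return "\n".join(lines)

    def manifest(self) -> dict:
        return {
            "package_version": __version__,
            "python": sys.version.split()[0],
            "config": self.model.config.to_dict(),
            "n_recordings": len(self.model.recordings),
            "retained_wavelets": self.retained_wavelets,
            "top_feature": self.top_feature,
        }

    def save(self, outdir: str | Path) -> Path:
        """Write the report bundle (CSV/JSON, pinned float formatting)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.screening.to_csv(out / "screening.csv", index=False, float_format=_FLOAT_FORMAT)
        table = self.feature_table.values.copy()
        table.insert(0, "group", self.feature_table.groups)
        table.to_csv(out / "feature_table.csv", float_format=_FLOAT_FORMAT)
        self.feature_stats.to_csv(out / "feature_stats.csv", float_format=_FLOAT_FORMAT)
        self.ranked_features.to_csv(out / "ranked_features.csv", float_format=_FLOAT_FORMAT)
        reconstruction.selection_report(self.selection).to_csv(
            out / "selection.csv", index=False, float_format=_FLOAT_FORMAT
        )
        chosen = {
            peak: [format_address(a) for a in sel.indices]
            for peak, sel in self.selection.items()
        }
        (out / "selection.json").write_text(json.dumps(chosen, indent=2, sort_keys=True))
        self.benchmark.discrimination.to_csv(
            out / "benchmark_discrimination.csv", float_format=_FLOAT_FORMAT
        )
        self.benchmark.correlations.to_csv(
            out / "benchmark_correlations.csv", float_format=_FLOAT_FORMAT
        )
        (out / "manifest.json").write_text(
            json.dumps(self.manifest(), indent=2, sort_keys=True, default=str)
        )
        (out / "summary.txt").write_text(self.summary() + "\n")
        return out


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> PergDwtResults:
    """Run the full pipeline from a config; optionally save the bundle."""
    if config.input_csv is not None:
        model = PergDwtAnalysis.from_csv(config.input_csv, n_samples=config.n_samples,
                                         **_non_input(config))
    elif config.synthetic is not None:
        model = PergDwtAnalysis.from_synthetic(config.synthetic, **_non_input(config))
    else:
        raise ValueError("config needs input_csv or a synthetic cohort spec")
    results = model.fit()
    if outdir is not None:
        results.save(outdir)
    return results


def _non_input(config: PipelineConfig) -> dict:
    skip = {"input_csv", "synthetic", "n_samples"}
    return {k: v for k, v in config.to_dict().items() if k not in skip}
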