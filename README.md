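# pergdwt

Discrete-wavelet-transform (DWT) biomarkers for pattern electroretinogram
(PERG) recordings.

The transient PERG — the retina's response to a reversing checkerboard —
carries three canonical components: a negative deflection near 35 ms
(N35), a positive peak near 50 ms (P50, the macular cone marker) and a
negative deflection near 95 ms (N95, the retinal ganglion cell marker).
In macular-predominant inherited retinal diseases (cone-rod dystrophy,
macular dystrophy, Stargardt disease — collectively "mpIRD"), P50 is
selectively attenuated, but conventional amplitude markers such as
|P50−N35| overlap between patients and controls. This package implements
a time-frequency alternative for clinical electrophysiologists and
methods researchers: orthogonal multilevel DWT energies of the trace,
addressed as `wavelet-D<level>-<position>` cells with physical time/
frequency windows (e.g. `sym2-D6-2` ≙ 38–75 ms, 13–27 Hz), screened,
ranked and benchmarked end to end.

## What it computes

Traces are 256-sample, 150-ms windows sampled at 1700 Hz and band-limited
to 1–100 Hz. For a trace `s`, the periodized orthogonal DWT yields
coefficients `c_i` per dyadic band; the pipeline then runs:

1. **Mother-wavelet screening.** For each of 20 candidate wavelets
   (haar, db2–db8, sym2–sym8, coif1–2, fk4/6/8 — the Fejér–Korovkin
   filter banks are constructed in-package), the energy `E = Σ c_i²` and
   Shannon entropy `H = −Σ p_i ln p_i` with `p_i = c_i²/E` are combined
   into the ratio `E·H⁻¹` per recording, averaged within and then across
   participants (95% bootstrap CIs, 10 000 participant-level resamples).
   The best wavelet per sub-band (D4, D5, D6, A5, A6) is retained.
2. **Feature statistics.** Each coefficient energy of the retained
   wavelets (details D4..Dmax plus the deepest approximation; 192
   features for the canonical six wavelets) is averaged per participant
   and tested with the Mann–Whitney U test; effect sizes are
   `r_es = |Z|/√N` and the common-language effect size
   `CLES = U/(n_normal·n_mpIRD)` (= ROC AUC); Benjamini–Hochberg FDR at
   α = 0.05; redundant features (Spearman |ρ| > 0.9) pruned greedily in
   descending `r_es` order.
3. **Minimal reconstruction.** A greedy search over one-index inverse
   DWTs (sym2; levels D4/D5/D6/A6) finds, per canonical peak, the index
   minimising the weighted MAE — voltage MAE (µV) × implicit-time MAE
   (ms) — and augments it with a second index only when that lowers the
   weighted MAE by ≥ 40%.
4. **Benchmarking.** Selected indices are compared with |P50−N35| and
   |N95−P50| by Tukey boxplots, ROC AUC, `r_es` and participant-level
   Pearson correlations (with a leave-one-out 4-SD outlier filter).

A synthetic cohort generator (three Gaussian bumps + noise, shared
per-participant gain, multiplicative P50/N95 attenuation for the disease
group) makes every stage runnable and testable without any data
download; a CSV reader ingests real cohorts in a simple one-row-per-
recording layout.

## Worked example

```python
import pergdwt as pg

cfg = pg.CohortConfig(n_normal=20, n_mpird=20, recordings_per_participant=4, seed=1)
results = pg.PergDwtAnalysis.from_synthetic(cfg).fit()
print(results.summary())
```

prints (abridged):

```text
PERG discrete-wavelet-transform analysis
========================================
cohort: 160 recordings, 40 participants (20 normal / 20 mpIRD), eye partition: all
retained wavelets: haar, db2, coif1, fk4, fk8
features: 160 candidates, 77 after |rho|>0.9 pruning

minimal sym2 reconstruction per peak:
peak    indices  v_mae  t_mae  weighted  augmented
 N35       D4-4  0.167  2.154     0.359      False
 P50 D4-6, D6-2  1.253  1.426     1.787       True
 N95 D6-3, A6-4  0.874  1.507     1.318       True

participant-level benchmark vs clinical markers:
                        auc  r_es
sym2-D6-2             1.000 0.855
p50_n35               0.997 0.851

Pearson r vs |P50-N35| / |N95-P50| (normal participants):
sym2-D6-2                  0.991      0.994
```

Reading this: on a simulated cohort with P50 attenuated to 30% in the
disease group, the central-time D6 energy separates the groups at least
as well as the clinical amplitude marker (AUC 1.000 vs 0.997), the
greedy reconstruction pairs `D6-3` with `A6-4` to preserve N95 (the
approximation index fixes the amplitude, the detail index the timing),
and `sym2-D6-2` tracks |P50−N35| almost perfectly (r = 0.99) across
normal participants. The same pipeline runs on real cohorts via
`PergDwtAnalysis.from_csv("cohort.csv")`.

A CLI mirrors the library:

```bash
pergdwt simulate --n-normal 20 --n-mpird 20 --seed 1 --out cohort.csv
pergdwt run-all --input cohort.csv --seed 1 --out results/
```

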