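# Methods

## Signal model and preprocessing

Analysed traces are 256-sample vectors covering a 150-ms post-reversal
window at 1700 Hz, band-limited 1–100 Hz by the acquisition hardware.
Native 255-sample traces are DC-detrended (the mean is subtracted; a
linear drift, if present, is deliberately preserved — the detrend is
zero-order) and the final detrended sample is repeated once to reach
dyadic length. Preprocessing is idempotent up to the padded sample's
contribution to the mean. Cohort filters (diagnosis whitelist,
visual-acuity requirement, first-visit-per-participant) are generic
rules, not hard-coded exclusion lists; missing visual acuity is an empty
CSV field because 0.0 logMAR is a valid measurement.

## Discrete wavelet transform

All decompositions are orthogonal, periodized ("per" extension) DWTs:
the trace is treated as circular, which suits a steady-state
pattern-reversal response, makes level *d* hold exactly 256/2^d
coefficients, and renders Parseval and perfect reconstruction exact (the
tests demand 1e-8 relative error; the filters deliver ~1e-12, limited
only by published-coefficient precision). Other extension modes are
rejected rather than silently accepted, because every downstream count,
window and invariant depends on periodization.

The admissible depth is floor(log2(256/(L−1))) for an L-tap filter. Haar
is capped at level 7 instead of its admissible 8 so that D7 splits the
trace into a 0–75 ms (P50) and a 75–150 ms (N95) half — two
physiologically aligned cells rather than four.

Coefficients are addressed `(band, level, position)` with 1-based
positions ("D6-2"). The nominal window of a coefficient uses the 150-ms
linear grid: position *k* at level *d* covers [(k−1)·w, k·w] ms with
w = 150·2^d/256; detail level *d* spans the ideal dyadic band
[fs/2^(d+1), fs/2^d] and the approximation [0, fs/2^(d+1)]. Reported
integer bounds round half-to-even in time and half-away-from-zero in
frequency — the one combination that reproduces every printed window
(37.5→38, 75→75, 112.5→112, 56.25→56; 13.28→13, 26.56→27, 53.125→53)
simultaneously. Window centres are midpoints of the unrounded bands.

### Fejér–Korovkin filters

PyWavelets (1.8) does not ship the Fejér–Korovkin family, so
`_fejer_korovkin.py` constructs fk4/fk6/fk8 from their definition
(Nielsen 2001): the ideal half-band response smoothed by the
Fejér–Korovkin positive kernel — the smallest kernel order ≥ N−1 that
keeps the half-band polynomial nonnegative — followed by spectral
factorization and a least-squares polish onto the quadrature-mirror
constraints. fk4 agrees with the published coefficients to ~1e-8 and
fk6 to the precision of the reference digits used (~1e-4); all three are
orthonormal to machine precision, which is what the transform invariants
require.

## Energy-to-entropy screening

For coefficients c_i: E = Σc_i², p_i = c_i²/E, H = −Σ p_i ln p_i
(natural log; the argmax over wavelets does not depend on the base).
E·H⁻¹ rewards wavelets that concentrate signal power into few
coefficients. Scopes are either "overall" (all coefficients of the full
decomposition) or one band/level; an approximation scope shallower than
the admissible depth is computed by decomposing exactly to that level.
Degenerate scopes — all-zero coefficients (E = 0) or a point mass
(H = 0) — raise a typed error and the recording is excluded from that
scope rather than contaminating the average.

Ratios are averaged recordings → participant → cohort; the two-stage
average is not equivalent to a flat recording average on unbalanced
cohorts (a test asserts they differ), and the participant is also the
bootstrap resampling unit (10 000 percentile resamples of the mean by
default; a `resample_unit="recording"` flag exposes the variant).
Retention keeps the argmax wavelet per scope — ties broken by shorter
filter, then name, favouring compact near-linear-phase designs — plus
caller-forced inclusions (`haar`, `coif1` by default, ensuring every
wavelet family stays represented).

## Feature statistics

Features are coefficient *energies* of the retained wavelets at detail
levels D4..Dmax plus the deepest approximation only: D1–D3 carry only
content above 100 Hz (outside the hardware band-pass), and shallower
approximations duplicate retained detail content. The canonical six
retained wavelets yield exactly 192 features at 256 samples. Recordings
are averaged within participant before testing, so repeated measures
never inflate the sample size.

Mann–Whitney U is oriented "normal greater" (U + U′ = n₁n₂), so
CLES = U/(n₁n₂) reads directly as the probability that a random normal
participant exceeds a random patient; it is identical to the ROC AUC
(asserted to 1e-12 against brute-force pair counting). The z statistic
uses the normal approximation with midrank tie correction and no
continuity correction — ties are rare in continuous energies, and the
uncorrected z matches the published effect-size convention
r_es = |Z|/√N. BH adjustment is the standard step-up (statsmodels),
cross-checked against the definitional min-over-ranks form.

Redundancy pruning visits features in descending r_es (ties: descending
CLES, then name) and keeps a feature iff its participant-level Spearman
|ρ| with every *already kept* feature is ≤ 0.9. The order makes the
pairwise rule deterministic; a chain F1–F2–F3 with both links > 0.9 but
ρ(F1,F3) < 0.9 keeps {F1, F3}. Constant features have undefined ρ and
are treated as uncorrelated (logged).

## Peak measurement and minimal reconstruction

Peaks are signed extrema inside search windows bracketing the canonical
latencies: N35 = min on 20–45 ms, P50 = max on 40–70 ms, N95 = min on
75–130 ms; ties resolve to the earliest time, and amplitude is the
signal value at the extremum (not trough-to-peak). The windows are
package defaults chosen to bracket ~35/50/95 ms with margins consistent
with normal PERG morphology, and are configurable.

An index set is scored on the normal recordings (recording-level, not
participant-averaged): reconstruct each trace from only those
coefficients, re-measure the peak, and form voltage MAE (µV), time MAE
(ms) and their product, the weighted MAE (µV·ms). Because subset
reconstruction is linear, single-index reconstructions are cached and
summed for pairs. The greedy selection takes the best single index from
D4/D5/D6/Amax, then tries pairing it with each of the remaining top-5
singles; the best pair replaces the single only if it lowers the
weighted MAE by at least the improvement threshold (40%), strictly — an
equal score is not a reduction, which also keeps already-perfect singles
from acquiring spurious partners.

Numerical tie-breaking: the weighted MAE is a product, so it collapses
to zero whenever either factor does — on noise-free synthetic cohorts a
near-zero reconstruction can tie the true generator at 0 through a
coincidental time match. Ties are therefore broken on voltage MAE, then
time MAE, before the positional rule (lower level, detail before
approximation, lower position). With this rule the selection provably
returns the generating index with zero error on every single-atom
cohort whose extremum lies inside a canonical window.

## Benchmarking

Discrimination (AUC, r_es, Tukey boxes) uses participant-level values
over the whole cohort; Pearson correlations against |P50−N35| and
|N95−P50| use normal participants only, per the markers' clinical
definition in controls. Tukey boxes use type-7 (linear interpolation)
quartiles — stated explicitly because the 1.5·IQR fences depend on the
convention. The outlier rule is one-sided: a recording is dropped iff
its value exceeds the leave-one-out mean by more than k = 4 leave-one-out
SDs. Paired indices (e.g. D6-3 with A6-4) are summarised by the mean of
the two energies.

## Synthetic cohorts

A trace is three Gaussian bumps −a_N35·g(t;35,6) + a_P50·g(t;50,8)
− a_N95·g(t;95,12) (µV; default amplitudes 1/4/5) plus iid Gaussian
noise (0.2 µV) and optional drift, on the 0–150 ms grid. The widths keep
>95% of signal energy below 100 Hz, matching the acquisition band-pass
(tested). Participants share one multiplicative amplitude gain
(log-normal, σ calibrated so the P50 amplitude SD equals
`between_participant_sd`, default 0.8 µV) across eyes and repeats —
multiplicative so amplitudes stay positive, mimicking between-subject
response-gain variation. Disease participants multiply a_P50 by 0.3 and
a_N95 by 0.6: the P50-predominant attenuation characteristic of macular
disease with secondary ganglion-cell involvement. Eyes alternate RE/LE;
an optional per-eye gain exercises the eye-partition sensitivity
analyses. All randomness flows through one seeded generator; identical
seeds give bit-identical cohorts.

What the generator does *not* emulate: sweep-level artifacts and their
rejection, electrode/stimulus physics, non-Gaussian or autocorrelated
noise, latency variability between participants, and real morphological
diversity. Passing tests therefore demonstrate correctness of the
algorithms and internal consistency of the statistics under a controlled
generative model — not clinical performance on real cohorts, for which
the CSV reader and an external dataset are required.

## Validation design

The oracle `oracle_cles` estimates the CLES of any energy feature by
brute-force simulation at fixed waveform parameters (rank-based pair
fraction, ties 0.5; an injection mode bypasses the waveform model to
check the closed form P(X>Y) = Φ(Δ/√2) for shifted normals). The
parameter-recovery test compares the full pipeline's CLES on 40/40
cohorts against this oracle over 10 seeds; those cohorts use one
recording per participant and zero between-participant gain spread so
the estimator and the oracle target the same population quantity, and
agreement is judged at 3 standard errors (Hanley–McNeil for the 40/40
estimate, binomial for the 10 000-draw oracle, combined in quadrature at
the pooled proportion).

Problem sizes in the test suite (cohorts of 8–80 participants, 100
random traces per wavelet for the transform invariants, 200 small-sample
comparisons for the rank statistics, 10 seeds for parameter recovery)
are chosen so the whole suite completes in well under a minute while
every tolerance above remains binding.

## Known limitations

- The Fejér–Korovkin fk6/fk8 filters are reconstructed from the kernel
  construction rather than copied from a filter-bank table; they are
  exactly orthonormal but could differ from other software's
  coefficients at the ~1e-4 level (fk4 is verified to ~1e-8).
- The weighted-MAE product is degenerate whenever a reconstruction's
  peak time lands on the original's grid time; the factor-wise tie-break
  handles this, but on noise-free cohorts many index sets can still
  score exactly zero for a peak they do not represent — selection
  results on noise-free data should be read with the singles table.
- Eye-partition views assume at most two eyes per participant and break
  worst-eye ties toward the right eye.
- The pipeline fixes fs = 1700 Hz / 150 ms / 256 samples; other
  geometries would need new window conventions.
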