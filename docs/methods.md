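# Methods

This note documents the models, estimators and numerical choices behind
`oscnet`, and what the synthetic-data tests do and do not establish.

## Stimuli and design

An acoustic texture is 400 ms long and contains 72 FM sweeps of 100 ms.
Sweep onsets are uniform on `[0, duration − sweep_duration]` (a sweep may
not overhang the stimulus end), start frequencies uniform in log2
frequency over ±1.5 octaves around the texture's spectral center (the
spread is configurable; the design only fixes "uniform in log
frequency").  The spectral center is `707.1 · 2^(d/12)` Hz for a semitone
deviation `d ∈ ±{2, 1, 0.5, 0.25}`; integer rounding reproduces the
printed set {630 … 794} Hz.  Exactly `round(coherence · 72)` sweeps share
the coherent signed slope of ±3.3 octaves/s; the rest get a random sign
at full magnitude (a continuous-magnitude option exists).  Audio
rendering uses exponential frequency glides `f(t) = f0·2^(s·t)` with 5-ms
raised-cosine gates; these two choices (gate shape, random-sign incoherent
slopes) are renderer conventions, not measured quantities.

Blocks hold two repeats of each direction × coherence (4) × spectral
center (8) cell — 128 trials — in randomized order; tasks alternate
across blocks with a randomized starting task; response-button label
mappings are randomized per trial.

## Behavior

Decision speed is `1 / response_time`; trials without a response are
flagged and excluded.  Accuracy dynamics use a centered moving average of
the binary correctness series with a unit-height rectangular window of
four trials; edges use a shrinking window so length is preserved
(centered vs. trailing alignment is configurable; the choice is not
dictated by anything measurable here).  All regressions rank-transform
(average ranks for ties) and then z-score (population denominator) every
variable.  With a single predictor this makes the OLS weight exactly
Spearman's ρ, which the tests assert to 1e-10 against
`scipy.stats.spearmanr`.

## Time-frequency decomposition

Morlet wavelets with 6 cycles (σ_t = 6/(2πf); spectral bandwidth ≈ 0.5
octaves, recorded as metadata) on the grid {1, 2, 4} ∪ {2^e, e = 3…5 step
0.25} Hz — 12 bins.  (One published description mentions 14 bins; the
stated construction yields 12, so 12 is implemented and the total-bin
count `Ft` of the FCR correction is an explicit parameter.)  Coefficients
are evaluated at 41 points, −0.5…+1.5 s in 0.05-s steps, inside −1…+2 s
epochs; window presets for pre-stimulus (−0.85…0 s), post-stimulus
(0…+1 s) and response (+1…+1.5 s) intervals reuse the same machinery.

Numerics: kernels are truncated at ±4σ_t and normalized to unit total
energy, so power is exactly quadratic in signal amplitude and white noise
yields flat power across bins (asserted within 20%).  Wherever the
truncated support crosses the epoch edge — at the default grid only for
1, 2 and 4 Hz — the epoch is reflection-padded ("mirror extension"); the
tests assert that forcing the extension changes coefficients at ≥8 Hz by
less than 1e-8.  The evaluation runs as banded/polyphase matrix products
(the analysis stride is 25 samples at 500 Hz), which is the package's
hot path.  Log power uses a floor of 1e-30 × max power; baselines
(−0.5…0 s mean log power) are subtracted per trial by default, with a
trial-averaged option.

## Envelope coupling

For an ordered source pair (i, j) at one frequency, the orthogonalized
power envelope of j given i is `Im(y_j · x_i*/|x_i|)²` per time point;
time points with `|x_i| = 0` are excluded.  The per-trial coupling is the
Pearson correlation between log power of i and log orthogonalized power
of j-given-i over the 41 analysis points, averaged over the two
directions and symmetrized.  Two consequences worth noting:

* A *real*-scaled copy of a signal (zero-lag leakage, the field-spread
  case) is removed exactly; a copy rotated 90° in phase is by definition
  orthogonal and passes fully.  The leakage tests therefore use real
  mixing matrices.
* Forty-one points of a slowly varying envelope give a high-variance
  estimator.  This is inherent to trial-resolved envelope coupling and is
  the reason the synthetic generator must put some envelope variance at
  faster timescales (below).

Correlation internals run in single precision (ample for correlation
estimates); results are returned as float64.

## Graphs and diagnostics

Per trial the symmetric coupling matrix is thresholded by rank of
absolute correlation to a fixed density (default 10%, alternative 5%):
exactly `floor(density · N(N−1)/2)` edges, ties broken by lexicographic
index order for reproducibility.  Mean FC is the mean of the retained
(signed) correlation values.  Distances use BFS (scipy.sparse.csgraph);
disconnected pairs contribute 0 to efficiencies and nodes with fewer than
two neighbors have local efficiency 0 (standard conventions).  Modularity
uses Louvain (networkx) with a fixed seed and 10 restarts keeping the
best Q; Q is always re-evaluated from the Newman formula on the returned
partition, and on small graphs the tests compare against exhaustive
partition search.  Within-module z-scores use population SD with z = 0
for zero-spread modules; participation is `1 − Σ_m (κ_im/k_i)²` with 0
for isolated nodes.

## Two-level inference

Per subject: OLS on rank-z variables, behavioral series ~ neural
regressor + spectral center + coherence (+ optionally source power, the
`covary_power` option).  Group: mean weight across subjects, compared
with a null distribution obtained by circularly shifting every subject's
behavioral series by the same offset k = 1…n_shifts (wrap-around) and
refitting; shifting preserves the series' autocorrelation.  Offsets are
deterministic (1…n_shifts); subjects are truncated to the common
valid-trial minimum so one offset applies to all.  Rank transformation
commutes with circular shifts, so the null loop runs as one matrix
product per subject over all shifts.  Significance is two-sided at the
2.5th/97.5th percentiles.  Across bins, FCR correction first selects bins
whose 95% null interval excludes the observation, then rebuilds intervals
at level `1 − Fs·q/Ft` and keeps survivors.  Task contrasts test the mean
paired difference of weights against the shift-by-shift difference of the
two tasks' nulls; cross-correlation at integer trial lags uses the same
rank machinery (positive lag = metric trails behavior; the lag-0 value
equals the single-predictor GLM weight).

## Synthetic ground truth

Each source emits `A(t)·cos(2πf·t + φ)` plus pink (1/f, zero-DC) noise at
a configurable SNR (default 1), with φ independent per source and trial —
so planted coupling lives purely in the envelopes.  `log A` is a
zero-mean Gaussian process with SD 0.5 and a two-timescale spectrum: half
the variance below 0.3 Hz (the dominant timescale of beta-band power
envelopes) and half in a band-limited faster component with cutoff
carrier/6 Hz — the spectral half-bandwidth of the 6-cycle wavelet at the
carrier, i.e. the fastest fluctuation the measurement itself can resolve.
The fast component is essential: with all envelope variance below 0.3 Hz
a 2-s window holds ~1.5 independent envelope samples, per-trial
correlation estimates degenerate into order statistics of noise, and
density-thresholded graph metrics cease to track the planted state (in
piloting they *anti*-correlated with it).  Processes are synthesized
directly in the spectral domain (zero-phase Butterworth-magnitude gains;
time-domain IIR filtering is unstable at these relative cutoffs) and
standardized per trial and source.

The planted per-trial network state interpolates the source-correlation
target between a random matrix (uniform r = 0.1) and a modular one (4
modules, within r = 0.8, between r = 0.1): `R(w) = w·R_mod + (1−w)·R_rand`
with the latent `w ~ U(0,1)` per trial.  Both mean coupling and
segregation rise with `w`, so mean FC, local efficiency and modularity of
the estimated graphs increase with the latent while global efficiency
decreases.  (An earlier endpoint choice had the modular matrix's mean
off-diagonal *below* the random one's, silently reversing the sign of the
planted mean-FC effect — the endpoints' mean off-diagonals, 0.24 vs 0.1,
are what make the direction unambiguous.)

Behavior: decision speed = 1.8 + slope·z(w) + σ·ε with σ = 1 by default
(slope 0.3, σ = 1 gives population correlation 0.3/√1.09 ≈ 0.287),
floored at 0.05 s⁻¹ so response times stay positive; correctness is
Bernoulli at the target accuracy (0.70, emulating an adaptive staircase);
1% of trials have no response.  The generator does **not** emulate evoked
responses, spectral leakage between frequency bins, head-motion or
sensor artifacts, realistic source geometry, or any causal link from
stimulus acoustics to the network state — passing tests show estimator
correctness and calibration, not that real cortex behaves this way.

## Problem sizes and calibration checks

Scales were chosen so the full suite runs comfortably on one CPU:

* Null calibration: 500 repetitions of a no-effect study (12 subjects ×
  200 trials, 12 frequency bins, 100 shifts); the uncorrected
  false-positive rate must land in 3–7% and FCR-corrected selections must
  be strictly rarer.
* Parameter recovery: 20 runs of 12 subjects × 160 trials × 32 sources at
  200 Hz sampling with the 1, 2, 4 and 19.03 Hz bins, mean FC only and
  150 shifts.  The 19.03 Hz bin (the grid bin inside 19–22 Hz, nearest
  the 20-Hz carrier) must be flagged with a positive weight in ≥90% of
  runs; no 1–4 Hz bin may be flagged in half the runs.  The 200-Hz rate
  is purely computational: carrier (20 Hz) and envelope (≤3.3 Hz) content
  sit far below either Nyquist frequency.
* Leakage: over seeded runs with a real mixing matrix (strength 0.4),
  |orthogonalized| < |naive| coupling must hold in ≥95% of runs.

## Known limitations

* The per-trial envelope-correlation estimator is noisy by construction;
  whole-brain averages are informative, single pairs are not.
* Louvain is a heuristic; Q values are optimizer-dependent.  Q is
  validated against exhaustive search only for n ≤ 8.
* The affine latent→behavior model is a stand-in; recovered effect sizes
  are not comparable to regression weights estimated from real
  recordings.
* With unequal trial counts the circular null truncates subjects to the
  common minimum rather than modeling unequal lengths.
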