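# Methods

This note documents the models implemented in `lfpseg`, the defaults and
why they were chosen, what the surrogate-data generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Conventions

Time is in seconds, intervals are half-open `[start, end)`, sample
indexing is 0-based: sample *i* covers `[i/fs, (i+1)/fs)`. Half-open
intervals avoid double counting boundary samples in overlap metrics.
Labels: 0 baseline, 1 interictal, 2 ictal. Signal amplitudes are treated
as microvolts but nothing depends on the unit.

## Adaptive z-score detection

The detector holds a FIFO of the last `lag_s` seconds of *filtered* values
(`λ = round(lag_s · fs)` samples) and recomputes the memory's mean μ and
population standard deviation σ on every sample (running sums, refreshed
from scratch every 8192 pushes to keep floating-point drift bounded —
numerically identical to recomputing over the window each step but O(1)
per sample, which is what makes the overall O(n + m) cost hold). The first
λ samples only seed the memory: a training stage with no detections.

Per sample: `z = (x − μ)/σ`; an outlier (`|z| > threshold_sigma` under the
default two-sided polarity) updates the memory with the convex blend
`ι·x + (1−ι)·U_prev`; a non-outlier enters unchanged. A detection is an
outlier that is also a strict local extremum (maximum for z > 0, minimum
for z < 0) clearing a one-sample refractory period. Event-level grouping
is entirely delegated to the density classifier's Δ window.

Numerical and design choices:

* **Local extremum is a strict AND test**; ties break toward
  non-detection. An exclusive-or of the two one-sided comparisons would
  fire on every monotone slope, which contradicts a first-derivative peak
  test.
* **The memory update is a convex combination.** A difference form
  (`ι·x − (1−ι)·U_prev`) diverges and cannot implement a smoothed memory.
* **σ = 0 (constant window) declares z = 0**: a flat window carries no
  outlier evidence, and this avoids the division blow-up.
* **Polarity default `both`** (test |z|): LFP discharges are biphasic.
  `positive` restores the one-sided textbook form.
* **Default influence ι = 0.1.** The point of a *robust* outlier detector
  is that outliers should barely contaminate the trend estimate; a small
  nonzero ι retains slow adaptation to genuine regime changes (e.g.
  electrode drift). ι = 0 freezes the memory against outliers entirely,
  ι = 1 adapts within O(λ) samples and silences sustained discharges.
* Defaults `lag_s = 0.25`, `threshold_sigma = 5`, `delta_s = 4` are the
  midpoints of the optimization grid (below).

Streaming equivalence (chunked processing equals one-shot processing) and
the λ-bounded memory are asserted by tests.

### A known failure mode worth stating

A short-memory adaptive z-score cannot see amplitude changes that ramp
slower than its own window: sub-threshold samples on a slow rising flank
enter the memory raw, and σ inflates at up to `(1 + (τ²−1)/λ)` per sample
— fast enough to outrun any envelope smoother than that. The detector is
therefore a *sharp-transient* detector; it detects ictal discharges
because real ictal activity is a train of fast-upstroke spikes, not a
smoothly modulated sinusoid. This drove the surrogate ictal waveform
design (below).

## Automatic multiscale peak detection

Per analysis window (default `window_s = 5`): linear detrend (ordinary
least-squares line removal), then the local-maxima scalogram over scales
k = 1…L, L = ⌈N/2⌉ − 1: cell (k, i) is 0 exactly when
`x[i] > x[i−k] and x[i] > x[i+k]` for interior i (k ≤ i ≤ N−k−1), and
`r + α` otherwise with r uniform on [0, 1], α = 1. Row sums γ_k; selected
scale λ = argmin γ (ties to the smallest k); peaks are columns whose cells
are all zero for every k ≤ λ.

* **"All retained cells zero" replaces the printed deviation statistic.**
  Nonzero cells are ≥ α = 1, so a zero column-deviation statistic and an
  all-zero column are the same event; the package tests the latter
  directly.
* **Scales are linear (w_k = 2k), not powers of two**, matching the
  published multiscale method the algorithm extends.
* **Randomness protocol.** One PCG64 generator seeded from
  (`rng_seed`, window index) supplies N uniforms per scale row, rows in
  increasing k. The zero pattern never depends on the draws; the selected
  scale can, but only through near-ties of γ. For signals with a dominant
  rhythm the selection — and hence the peak output — is seed-stable; on
  featureless noise adjacent scales can tie and the peak set may vary
  slightly with the seed. The memory-lean scan used by the pipeline and
  the materialized L×N matrix used for analysis draw identically and are
  tested equal; a naive double-loop transcription is the independent test
  oracle.
* **Edge dead zone.** Boundary cells are nonzero by definition, so no peak
  can be reported within λ samples of a window edge. With 5 s windows and
  LFP-scale rhythms (λ of order tens of samples) the loss is a few tens of
  milliseconds per window join; for short windows on slow sinusoids it is
  material (a 2 s window of a 1 Hz sine retains one of its two crests).
  Window tiling is non-overlapping, duplicate peaks at joins are merged.
* **Conditioning**: powerline notch (Q = 90) then zero-phase Butterworth
  band-pass 0.5–50 Hz; either stage can be disabled. Zero-phase filtering
  keeps peak times unshifted.
* **Amplitude gate.** The scalogram reports *every* local maximum at the
  winning scale, including the noise floor's. Peaks below
  `threshold_sigma` baseline-σ (robust MAD estimate of the conditioned
  record) are dropped before density integration. Gating at the peak
  level, not the event level, is essential: floor peaks arrive densely
  enough to bridge the whole record into one Δ-integrated event, after
  which no event-level statistic can recover the true segmentation.
  Default `threshold_sigma = 4`, `delta_s = 2` (grid midpoints).

## Density classification

Greedy left-to-right grouping: an event grows while the next peak is
within Δ of the last; the event's span is first-peak to last-peak plus one
sample period (so single-peak events have measure under half-open
intervals; the trailing extension is clipped to the record). Labels by
peak count: ≥ `threshold_a` (default 20) → ictal; ≥ `threshold_b`
(default 1) → interictal; below → baseline. Events shorter than
`min_event_s` (default 0) are dropped. Δ doubles as the refractory
separation between events — one parameter serves both roles. The count
thresholds were calibrated on the surrogate generator: a sustained
discharge train contributes tens-to-hundreds of peaks per event, while a
single prominent spike suffices for an interictal transient. A
consequence worth knowing: ictal events shorter than roughly
`threshold_a / (2·discharge rate)` seconds (a few seconds at the
defaults) are classified interictal.

## Evaluation metrics

Per class, greedy one-to-one temporal matching: an output event is a true
positive for the first unmatched same-class reference with coincidence
ratio (intersection / reference length) strictly above `min_coincidence`
(0.8) and output length ≤ `max_length_ratio` (1.5) × reference length.
The length cap reads "must not exceed the reference by more than 50%" as
an upper bound on over-segmentation. Unmatched outputs are false
positives; unmatched references false negatives. Precision, recall and
F-score use the 0/0 → 0 convention. The Jaccard index is computed on the
class's time sets by exact interval arithmetic — the continuous-time limit
of counting labeled samples, identical up to one-sample quantization and
independent of any resampling choice. The composite score is the fixed
weighted sum 0.60/0.20/0.10/0.05/0.05 over ictal precision, ictal
Jaccard, ictal recall, interictal precision and interictal recall; the
weights are configurable and must sum to 1.

## Surrogate data

The generator emulates the statistical structure of 4AP brain-slice MEA
records: default 1800 s at 2 kHz, ictal count 5 ± 1, interictal count
80 ± 50 per record, ictal durations 50 ± 24 s, interictal durations
1.5 ± 0.8 s (truncated normals, floor 0.2 s), ictal spectral energy in
0.5–30 Hz, target SNR drawn from 20 ± 10 dB, 50 Hz powerline at half the
baseline σ. Events are placed uniformly with a minimum 8 s inter-event gap
(larger than the largest Δ in the optimization grid, so distinct events
never merge by construction); an infeasible packing after repeated
duration redraws raises an error.

* **Baseline**: 0.5–80 Hz band-limited Gaussian noise, σ = 10 µV.
* **Ictal archetype**: a train of sharp biphasic Ricker spikes at
  1.2–2.5 Hz (typical tonic 4AP discharge rates; also slower than the
  largest grid lag, so an adaptive memory re-arms between discharges),
  spike half-width 12–25 ms, per-spike amplitude heterogeneity
  (×0.6–1.5), a weak 6–12 Hz oscillatory background (3% of unit
  amplitude) and a 10% Tukey taper.
* **Interictal archetype**: 2+ biphasic Ricker spikes (15–30 ms) spread
  over 5–95% of the sampled duration.
* **SNR** is defined as mean event power over mean baseline-floor power
  (noise plus powerline), in dB; event waveforms are scaled exactly so the
  generated record hits the target, and `measure_snr` verifies the
  round-trip to within 1 dB.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: morphological diversity of interictal events
(polyspikes, low-frequency oscillations), pre-ictal buildup and
post-ictal depression, nonstationary noise floors, electrode drift and
artifacts, multi-channel structure. Detector scores on surrogate batches
are a regression guard for the implementation, not a claim about recorded
brain-slice performance.

## Parameter search protocol

The optimization grid is: adaptive z-score — threshold {4, 5, 6} σ,
Δ {3, 4, 5} s, lag {0.125, 0.25, 0.5} s; multiscale — threshold
{3, 4, 5, 6} σ, Δ {1.5, 2, 2.5} s. Records are split 70/30 at record
level (seeded). Every cell is scored on every training record; the
parameter vectors of the ten best cells are averaged coordinate-wise and
snapped to the nearest grid value (ties toward the smaller value). For
records with SNR < 20 dB a ±1-grid-step neighborhood search re-tunes the
winner; ties keep the incumbent, so parameters never move without strict
evidence, and the adjustment cannot leave the declared neighborhood.
Whether the re-tuned threshold moves up or down depends on the regime: it
rises when false-positive pressure dominates, but when events remain well
above the floor a lower threshold can buy ictal coverage (Jaccard weight
0.2) more than interictal false positives cost (weight 0.05). Reports
carry per-record and per-slice metric tables plus the Pearson correlation
between per-record score and SNR (reported as undefined for degenerate
batches).

## Problem sizes used in the test suite

The suite exercises the full protocol at desk scale: the end-to-end
regression runs 20 five-minute records sampled at 500 Hz (events live
below 50 Hz, so the 2 kHz nominal rate adds nothing to the physics);
distribution-recovery statistics use 100 records at 100 Hz; oracle
equivalence uses segments up to 200 samples against a literal double-loop
transcription; complexity contracts are verified by instrumented operation
counts (log-log slope 1 for the streaming detector, 2 for the per-window
scalogram).

## Known limitations

* The adaptive z-score detector is blind to amplitude ramps slower than
  its own memory (see above); records whose seizures onset gradually will
  be detected late or fragmented.
* The multiscale detector's per-window cost is quadratic; the default 5 s
  window at 2 kHz (W = 10⁴) is the practical ceiling on one core.
* The density classifier keys only on peak count and duration; the
  optional amplitude gate is the sole amplitude criterion, and no spectral
  features are used anywhere — by design, for hardware-friendliness.
* Event boundaries are peak-delimited, so tapered discharge edges are
  systematically trimmed; Jaccard values saturate slightly below 1 even
  for perfect event matching.
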