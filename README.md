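# lfpseg — time-series segmentation of epileptiform LFP recordings

`lfpseg` segments single-channel local field potential (LFP) recordings of
epileptiform activity — such as microelectrode-array recordings from
4-aminopyridine-treated brain slices — into **baseline (0)**, **interictal
(1)** and **ictal (2)** intervals. It is aimed at researchers who need
low-complexity, hardware-friendly event detection for seizure analysis or
closed-loop stimulation prototyping, and who want the whole pipeline
(detection, classification, evaluation, parameter search) testable without
any recorded data: a surrogate-data generator with exact ground truth is a
first-class part of the package.

## The two detectors

**Adaptive z-score detection (ZdensityRODE).** A streaming detector with a
FIFO memory of the last λ seconds of *filtered* samples. Sample *x* is an
outlier when

    z = (x − μ) / σ  >  τ

with μ, σ the memory's mean and standard deviation. Outliers update the
memory through a convex blend `ι·x + (1−ι)·U_prev` (influence ι ∈ [0,1]);
ordinary samples enter unchanged. A detection further requires a strict
local extremum and a one-sample refractory gap. Cost is O(n + m) for n
samples and m outliers.

**Automatic multiscale peak detection (AMPDE).** Per analysis window the
detrended signal is expanded into a local-maxima scalogram (LMS): an L×N
matrix with

    m[k, i] = 0          if x[i] > x[i−k] and x[i] > x[i+k]
    m[k, i] = r + α      otherwise  (r ~ U[0,1], α = 1)

for scales k = 1…L, L = ⌈N/2⌉ − 1. Row sums γ_k select the dominant scale
λ = argmin γ, and peaks are the columns whose cells are zero at every
retained scale k ≤ λ. Cost is O(W²) per window of length W. Detected peaks
then pass an amplitude gate expressed in baseline-σ units (robust MAD
estimate).

**Shared density classifier.** Both peak trains are grouped by look-forward
Δ-integration (an event grows while the next peak arrives within Δ) and
labeled by peak count: ≥ `threshold_a` → ictal, ≥ `threshold_b` →
interictal, otherwise baseline.

**Evaluation.** Events are matched one-to-one per class (coincidence ratio
> 0.8 of the reference and output length ≤ 1.5× reference). The composite
multi-criteria score is

    score = 0.60·P_ictal + 0.20·J_ictal + 0.10·R_ictal
          + 0.05·P_interictal + 0.05·R_interictal

with per-class precision P, recall R and time-overlap Jaccard J.

## Worked example

Simulate a 5-minute surrogate record (500 Hz, two ictal and eight
interictal events, 25 dB SNR), segment it with the adaptive z-score
detector and score the result against the generator's ground truth:

```
$ cat cfg.yaml
generator:
  sampling_rate: 500
  n_ictal: 2
  n_interictal: 8
  snr_db: 25

$ lfpseg simulate --config cfg.yaml --duration-s 300 --seed 7 --out-dir sim
wrote sim/signal.csv (10 events)

$ lfpseg segment sim/signal.csv --algorithm zdensity --out-dir seg
wrote seg/annotations.csv (10 events)

$ lfpseg evaluate sim/annotations.csv seg/annotations.csv --duration-s 300
{
 "ictal": {
  "precision": 1.0,
  "recall": 1.0,
  "f_score": 1.0,
  "jaccard": 0.964812776357768
 },
 "interictal": {
  "precision": 1.0,
  "recall": 1.0,
  "f_score": 1.0,
  "jaccard": 0.9163873003352359
 },
 "score": 0.9929625552715536
}
```

All ten planted events are recovered with exact one-to-one matches
(precision = recall = 1 for both classes); the Jaccard values slightly
below 1 reflect that detected event boundaries start at the first and end
at the last detected peak, trimming the tapered edges of each discharge.
The composite score weighs these per the formula above. The same pipeline
is available programmatically via `lfpseg.zdensity_segment` /
`lfpseg.ampde_segment`, and `lfpseg gridsearch` reproduces the parameter
sweep + 70/30 split + best-10 averaging protocol on surrogate batches.

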