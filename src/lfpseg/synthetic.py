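"""Surrogate epileptiform LFP generator with ground-truth annotations.

Emulates the statistical structure of 4-aminopyridine brain-slice MEA
recordings: ~30-minute records at 2 kHz containing about 5 +/- 1 ictal
events of 50 +/- 24 s and 80 +/- 50 interictal events of 1.5 +/- 0.8 s on
top of a band-limited Gaussian noise floor, with 50 Hz powerline
interference and an event-to-baseline SNR around 20 +/- 10 dB.

Waveform archetypes (the source data fixes only durations, band and SNR):

* ictal: a sustained train of sharp Ricker (Mexican-hat) spikes recurring
  at 1.2-2.5 Hz over a weak 6-12 Hz oscillatory background, tapered with a
  10% Tukey window.  Ictal LFP presents as recurring sharp discharges, not
  a stationary sinusoid; the fast upstrokes are what any short-memory
  amplitude detector keys on, the repetition rate matches tonic 4AP
  discharges and exceeds the largest memory lag in the optimization grid,
  and the spike rate and Ricker width keep the spectral energy inside the
  stated 0.5-30 Hz ictal band.
* interictal: 2+ biphasic Ricker spikes, ~15-30 ms half width, spread over
  the sampled duration with small jitter.

SNR is defined as mean event power over mean baseline-floor power (noise
plus powerline); event waveforms are scaled exactly so the generated record
hits the requested value.  Everything is reproducible from ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .core import (
    AnnotationTrack,
    DataError,
    EventInterval,
    GenerationError,
    ICTAL,
    INTERICTAL,
    LFPRecord,
    intervals_to_labels,
)

__all__ = ["GeneratorConfig", "generate_record", "measure_snr"]


@dataclass
class GeneratorConfig:
    """Study conditions of the surrogate dataset.

    ``n_ictal``, ``n_interictal`` and ``snr_db`` may be fixed explicitly;
    when left ``None`` they are drawn per record from the stated
    mean +/- SD (counts rounded and floored at 0, SNR truncated at 1 dB).
    Event durations are truncated normals, floored at ``min_dur_s``.
    """

    duration_s: float = 1800.0
    sampling_rate: float = 2000.0
    n_ictal: int | None = None
    n_interictal: int | None = None
    n_ictal_mean: float = 5.0
    n_ictal_sd: float = 1.0
    n_interictal_mean: float = 80.0
    n_interictal_sd: float = 50.0
    ictal_dur_mean_s: float = 50.0
    ictal_dur_sd_s: float = 24.0
    interictal_dur_mean_s: float = 1.5
    interictal_dur_sd_s: float = 0.8
    ictal_band_hz: tuple = (0.5, 30.0)
    snr_db: float | None = None
    snr_mean_db: float = 20.0
    snr_sd_db: float = 10.0
    powerline_hz: float = 50.0
    powerline_amp: float = 0.5  # relative to baseline noise sigma
    baseline_band_hz: tuple = (0.5, 80.0)
    baseline_sigma: float = 10.0  # microvolts
    min_gap_s: float = 8.0
    min_dur_s: float = 0.2
    seed: int = 0


def _trunc_normal(rng, mean, sd, lo):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > lo:
            return float(v)
    return float(lo + abs(rng.normal(0, sd)) + 1e-6)


def _draw_count(rng, mean, sd) -> int:
    return max(0, int(round(rng.normal(mean, sd))))


def _ricker(u: np.ndarray) -> np.ndarray:
    return (1.0 - u**2) * np.exp(-(u**2) / 2.0)


def _ictal_waveform(n: int, fs: float, rng, band) -> np.ndarray:
    t = np.arange(n) / fs
    dur = n / fs
    lo, hi = band
    rate = rng.uniform(1.2, 2.5)  # discharge repetition rate, Hz
    width = rng.uniform(0.012, 0.025)  # spike half-width scale, s
    isi = 1.0 / rate
    centers = np.arange(0.5 * isi, dur - 0.3 * isi, isi)
    centers = centers + rng.uniform(-0.1, 0.1, size=centers.size) * isi
    amps = rng.uniform(0.6, 1.5, size=centers.size)  # discharge heterogeneity
    sign = rng.choice([-1.0, 1.0])
    y = np.zeros(n)
    for c, a in zip(centers, amps):
        y += a * _ricker((t - c) / width)
    y *= sign
    fc = rng.uniform(max(6.0, 2 * lo), min(12.0, 0.4 * hi))
    y += 0.03 * np.sin(2 * np.pi * fc * t + rng.uniform(0, 2 * np.pi))
    y *= scipy.signal.windows.tukey(n, alpha=0.1)
    rms = np.sqrt(np.mean(y**2))
    return y / rms


def _interictal_waveform(n: int, fs: float, rng) -> np.ndarray:
    t = np.arange(n) / fs
    dur = n / fs
    k = max(2, int(round(dur / 0.7)))
    centers = np.linspace(0.05 * dur, 0.95 * dur, k)
    centers = centers + rng.uniform(-0.02, 0.02, size=k) * dur
    width = rng.uniform(0.015, 0.03)
    sign = rng.choice([-1.0, 1.0])
    y = np.zeros(n)
    for c in centers:
        y += _ricker((t - c) / width)
    y *= sign
    rms = np.sqrt(np.mean(y**2))
    return y / rms


def _place_events(rng, durations: list, labels: list, total_s: float, gap_s: float):
    """Random non-overlapping placement with a minimum inter-event gap."""
    n = len(durations)
    order = rng.permutation(n)
    durs = [durations[i] for i in order]
    labs = [labels[i] for i in order]
    slack = total_s - sum(durs) - gap_s * (n + 1)
    if slack < 0:
        return None
    extra = rng.dirichlet(np.ones(n + 1)) * slack
    starts = []
    cursor = 0.0
    for i in range(n):
        cursor += gap_s + extra[i]
        starts.append(cursor)
        cursor += durs[i]
    return list(zip(starts, durs, labs))


def generate_record(config: GeneratorConfig) -> tuple[LFPRecord, AnnotationTrack]:
    """Generate one surrogate record and its exact ground-truth track."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(round(cfg.duration_s * fs))
    if n < 8:
        raise GenerationError("record too short")
    nyq = fs / 2.0

    n_ict = cfg.n_ictal if cfg.n_ictal is not None else _draw_count(
        rng, cfg.n_ictal_mean, cfg.n_ictal_sd
    )
    n_int = cfg.n_interictal if cfg.n_interictal is not None else _draw_count(
        rng, cfg.n_interictal_mean, cfg.n_interictal_sd
    )
    snr_db = cfg.snr_db if cfg.snr_db is not None else _trunc_normal(
        rng, cfg.snr_mean_db, cfg.snr_sd_db, 1.0
    )

    # --- event durations and placement (retry on infeasible packing) -----
    placed = None
    for _ in range(100):
        durs = [
            _trunc_normal(rng, cfg.ictal_dur_mean_s, cfg.ictal_dur_sd_s, cfg.min_dur_s)
            for _ in range(n_ict)
        ] + [
            _trunc_normal(
                rng, cfg.interictal_dur_mean_s, cfg.interictal_dur_sd_s, cfg.min_dur_s
            )
            for _ in range(n_int)
        ]
        labs = [ICTAL] * n_ict + [INTERICTAL] * n_int
        placed = _place_events(rng, durs, labs, cfg.duration_s, cfg.min_gap_s)
        if placed is not None:
            break
    if placed is None and (n_ict or n_int):
        raise GenerationError(
            f"cannot pack {n_ict} ictal + {n_int} interictal events "
            f"(min gap {cfg.min_gap_s}s) into {cfg.duration_s}s"
        )
    placed = placed or []

    # --- baseline noise floor -------------------------------------------
    white = rng.standard_normal(n)
    lo = cfg.baseline_band_hz[0]
    hi = min(cfg.baseline_band_hz[1], 0.9 * nyq)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    noise = scipy.signal.sosfiltfilt(sos, white)
    noise *= cfg.baseline_sigma / np.std(noise)

    # --- powerline interference -----------------------------------------
    pl_amp = cfg.powerline_amp * cfg.baseline_sigma
    powerline = (
        pl_amp * np.sin(2 * np.pi * cfg.powerline_hz * np.arange(n) / fs
                        + rng.uniform(0, 2 * np.pi))
        if cfg.powerline_hz < nyq
        else np.zeros(n)
    )

    # --- events, scaled so measured SNR hits the target exactly ----------
    floor_power = cfg.baseline_sigma**2 + pl_amp**2 / 2.0
    ratio = 10.0 ** (snr_db / 10.0)
    event_rms = float(np.sqrt(max(ratio - 1.0, 0.0) * floor_power))

    x = noise + powerline
    intervals = []
    for start, dur, label in placed:
        i0 = int(round(start * fs))
        i1 = min(int(round((start + dur) * fs)), n)
        m = i1 - i0
        if m < 4:
            continue
        if label == ICTAL:
            w = _ictal_waveform(m, fs, rng, cfg.ictal_band_hz)
        else:
            w = _interictal_waveform(m, fs, rng)
        x[i0:i1] += event_rms * w
        intervals.append(EventInterval(i0 / fs, i1 / fs, label))

    record = LFPRecord(
        samples=x,
        sampling_rate=fs,
        record_id=f"synthetic-{cfg.seed}",
        channel_meta={"synthetic": "true", "snr_db": f"{snr_db:.3f}"},
    )
    track = AnnotationTrack(intervals=intervals, duration_s=n / fs)
    return record, track


def measure_snr(record: LFPRecord, track: AnnotationTrack) -> float:
    """Event power over baseline power, in dB.

    Requires the track to contain at least one event and the record at
    least one baseline sample.
    """
    labels = intervals_to_labels(track, record.sampling_rate, record.n_samples)
    ev = record.samples[labels > 0]
    base = record.samples[labels == 0]
    if ev.size == 0:
        raise DataError("track contains no event samples")
    if base.size == 0:
        raise DataError("track contains no baseline samples")
    return float(10.0 * np.log10(np.mean(ev**2) / np.mean(base**2)))
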