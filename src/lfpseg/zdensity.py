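"""Streaming adaptive z-score outlier detection (ZdensityRODE front end).

The detector keeps a FIFO memory of the last ``lag`` seconds of *filtered*
samples and flags a sample as an outlier when its z-score against the
memory's mean/std exceeds ``threshold_sigma``.  Outliers update the memory
through a convex combination controlled by ``influence`` (0 = the memory
ignores outliers entirely, 1 = full adaptation), while ordinary samples
enter the memory unchanged.  A detection additionally requires the sample
to be a strict local extremum of the conditioned signal and to clear a
one-sample refractory period; event-level grouping is delegated to the
density classifier via the ``delta_s`` parameter.

The memory strategy makes the detector robust to slow drift (electrode
degradation) while a small ``influence`` keeps prolonged discharges from
silencing their own detection too quickly.  Work per sample is O(1), so a
full pass is O(n + m) for n samples and m outliers.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from math import sqrt

import numpy as np
import scipy.signal

from .core import DataError, LFPRecord, ParameterError

__all__ = [
    "ZdensityParams",
    "RollingStats",
    "OutlierPeak",
    "condition_signal",
    "zscore",
    "is_local_max",
    "is_local_min",
    "update_filtered",
    "ZdensityDetector",
    "detect_outliers",
    "zdensity_segment",
]


@dataclass
class ZdensityParams:
    """Configuration of the adaptive z-score detector.

    lag_s
        Memory depth in seconds; the FIFO holds ``round(lag_s * fs)`` samples.
    threshold_sigma
        z-score level above which a sample counts as an outlier.
    influence
        Weight in [0, 1] given to outlier samples when updating the memory.
    delta_s
        Look-forward integration / refractory window handed to the density
        classifier.
    polarity
        ``positive`` tests z > threshold on local maxima (the one-sided
        textbook form), ``negative`` the mirrored test on local minima,
        ``both`` (default) tests |z| since LFP discharges are biphasic.
    """

    lag_s: float = 0.25
    threshold_sigma: float = 5.0
    influence: float = 0.1
    delta_s: float = 4.0
    notch_hz: float = 50.0
    notch_q: float = 90.0
    polarity: str = "both"

    def __post_init__(self) -> None:
        if self.lag_s <= 0:
            raise ParameterError("lag_s must be positive")
        if self.threshold_sigma <= 0:
            raise ParameterError("threshold_sigma must be positive")
        if not 0.0 <= self.influence <= 1.0:
            raise ParameterError("influence must lie in [0, 1]")
        if self.delta_s <= 0:
            raise ParameterError("delta_s must be positive")
        if self.polarity not in ("positive", "negative", "both"):
            raise ParameterError("polarity must be positive|negative|both")


@dataclass(frozen=True)
class OutlierPeak:
    """A detected outlier peak: time, conditioned amplitude and z-score."""

    time_s: float
    amplitude: float
    zscore: float


class RollingStats:
    """FIFO of the last ``maxlen`` filtered values with running mean/std.

    Mean and standard deviation always equal those of the current window
    contents; running sums are refreshed from scratch periodically to keep
    floating-point drift out of long streams.
    """

    _REFRESH = 8192

    def __init__(self, maxlen: int):
        if maxlen < 1:
            raise ParameterError("window length must be >= 1")
        self.maxlen = maxlen
        self._buf: deque[float] = deque(maxlen=maxlen)
        self._s1 = 0.0
        self._s2 = 0.0
        self._pushes = 0

    def push(self, v: float) -> None:
        if len(self._buf) == self.maxlen:
            old = self._buf[0]
            self._s1 -= old
            self._s2 -= old * old
        self._buf.append(v)
        self._s1 += v
        self._s2 += v * v
        self._pushes += 1
        if self._pushes % self._REFRESH == 0:
            self._s1 = float(sum(self._buf))
            self._s2 = float(sum(x * x for x in self._buf))

    def __len__(self) -> int:
        return len(self._buf)

    @property
    def full(self) -> bool:
        return len(self._buf) == self.maxlen

    @property
    def mean(self) -> float:
        n = len(self._buf)
        return self._s1 / n if n else 0.0

    @property
    def std(self) -> float:
        n = len(self._buf)
        if n == 0:
            return 0.0
        var = self._s2 / n - (self._s1 / n) ** 2
        return sqrt(var) if var > 0 else 0.0


def condition_signal(
    record: LFPRecord, notch_hz: float = 50.0, notch_q: float = 90.0
) -> LFPRecord:
    """Attenuate the powerline component with a zero-phase IIR notch."""
    nyq = record.sampling_rate / 2.0
    if not 0 < notch_hz < nyq:
        raise ParameterError(
            f"notch frequency {notch_hz} Hz outside (0, {nyq}) Hz"
        )
    b, a = scipy.signal.iirnotch(notch_hz, notch_q, fs=record.sampling_rate)
    filtered = scipy.signal.filtfilt(b, a, record.samples)
    return replace(record, samples=filtered)


def zscore(x: float, stats: RollingStats) -> float:
    """(x - mean) / std against the rolling memory.

    A zero-variance window (constant signal) carries no outlier evidence,
    so its z-score is declared 0 rather than infinite.
    """
    sd = stats.std
    if sd <= 0.0:
        return 0.0
    return (x - stats.mean) / sd


def is_local_max(x_prev: float, x: float, x_next: float) -> bool:
    """Strict local maximum; ties break toward non-detection."""
    return x_prev < x and x_next < x


def is_local_min(x_prev: float, x: float, x_next: float) -> bool:
    return x_prev > x and x_next > x


def update_filtered(
    x: float, prev_filtered: float, influence: float, is_outlier: bool
) -> float:
    """Value entering the memory: convex blend for outliers, raw otherwise."""
    if is_outlier:
        return influence * x + (1.0 - influence) * prev_filtered
    return x


class ZdensityDetector:
    """Carrier of the streaming state; supports chunked processing.

    Feeding a signal in one :meth:`process` call or in arbitrary chunks
    yields identical peaks.  The first ``lag`` samples only seed the memory
    (training stage, no detections).
    """

    def __init__(self, params: ZdensityParams, sampling_rate: float):
        if sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        self.params = params
        self.sampling_rate = sampling_rate
        self.lag_samples = max(1, int(round(params.lag_s * sampling_rate)))
        self.stats = RollingStats(self.lag_samples)
        self._u_prev = 0.0
        self._n = 0  # global index of the next incoming sample
        self._prev2: float | None = None  # raw x_{i-2}
        self._cand: tuple[float, float, bool, int] | None = None  # (x, z, outlier, idx)
        self._last_peak_idx = -10
        self.n_ops = 0  # instrumented operation count (O(1) work units)

    def process(self, samples: np.ndarray) -> list[OutlierPeak]:
        p = self.params
        tau = p.threshold_sigma
        pol = p.polarity
        fs = self.sampling_rate
        peaks: list[OutlierPeak] = []
        for x in np.asarray(samples, dtype=np.float64):
            x = float(x)
            i = self._n
            self.n_ops += 1
            if i < self.lag_samples:
                # training: fill the memory, no detections
                self.stats.push(x)
                self._u_prev = x
                self._prev2 = None if self._cand is None else self._cand[0]
                self._cand = (x, 0.0, False, i)
                self._n += 1
                continue
            z = zscore(x, self.stats)
            if pol == "positive":
                outlier = z > tau
            elif pol == "negative":
                outlier = -z > tau
            else:
                outlier = abs(z) > tau
            # confirm the previous sample as a peak now that its right
            # neighbor is known
            if self._cand is not None and self._prev2 is not None:
                cx, cz, cout, cidx = self._cand
                if cout and cidx >= self.lag_samples:
                    self.n_ops += 1
                    up = cz > 0 and is_local_max(self._prev2, cx, x)
                    down = cz < 0 and is_local_min(self._prev2, cx, x)
                    if (up or down) and cidx - self._last_peak_idx > 1:
                        peaks.append(
                            OutlierPeak(time_s=cidx / fs, amplitude=cx, zscore=cz)
                        )
                        self._last_peak_idx = cidx
            val = update_filtered(x, self._u_prev, p.influence, outlier)
            self.stats.push(val)
            self._u_prev = val
            self._prev2 = None if self._cand is None else self._cand[0]
            self._cand = (x, z, outlier, i)
            self._n += 1
        return peaks

    @property
    def memory_len(self) -> int:
        """Current live buffer size (bounded by the lag window)."""
        return len(self.stats)


def detect_outliers(record: LFPRecord, params: ZdensityParams) -> list[OutlierPeak]:
    """Single forward pass over a (conditioned) record.

    The record must be longer than the lag window; the first ``lag``
    samples never produce detections.
    """
    det = ZdensityDetector(params, record.sampling_rate)
    if record.n_samples <= det.lag_samples:
        raise DataError(
            f"record has {record.n_samples} samples; needs more than the "
            f"lag window ({det.lag_samples})"
        )
    return det.process(record.samples)


def zdensity_segment(record: LFPRecord, params: ZdensityParams, density_params=None):
    """Full pipeline: notch conditioning, outlier detection, density labeling.

    Returns ``(peaks, classified_events, AnnotationTrack)``.
    """
    from .density import DensityParams, segment_peaks

    if density_params is None:
        density_params = DensityParams()
    density_params = replace(density_params, delta_s=params.delta_s)
    cond = condition_signal(record, params.notch_hz, params.notch_q)
    peaks = detect_outliers(cond, params)
    events, track = segment_peaks(
        peaks,
        density_params,
        sample_period_s=1.0 / record.sampling_rate,
        duration_s=record.duration_s,
    )
    return peaks, events, track
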