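"""Windowed automatic multiscale peak detection (AMPDE).

For each analysis window the signal is linearly detrended and a local
maxima scalogram (LMS) is built: an L x N matrix whose cell ``m[k, i]`` is
0 exactly when sample ``i`` exceeds both of its neighbors ``k`` samples
away, and ``r + alpha`` otherwise, with ``r`` uniform on [0, 1] and
``alpha = 1``.  L = ceil(N/2) - 1 scales are evaluated (window lengths
``w_k = 2k``).  The row sums ``gamma_k`` summarize how many local maxima
survive at each scale; the scale ``lambda = argmin_k gamma_k`` is selected,
and peaks are the columns whose cells are all zero for every retained scale
``k <= lambda``.  Because nonzero cells are at least ``alpha = 1``, the
"all retained cells zero" test is equivalent to a zero column-wise
deviation statistic.

The zero-pattern of the LMS depends only on the data; the random component
only perturbs the row sums, so peak output is reproducible given
``rng_seed`` and, in practice, independent of it.  Cost per window of
length W is O(W^2) from the L x W scan, so a tiled record costs O(N * W).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil

import numpy as np
import scipy.signal

from .core import DataError, LFPRecord, ParameterError
from .zdensity import OutlierPeak

__all__ = [
    "AMPDEParams",
    "LMSMatrix",
    "ScaleSummary",
    "detrend_linear",
    "compute_lms",
    "select_scale",
    "detect_peaks_lms",
    "lms_peaks",
    "ampde_detect",
    "ampde_segment",
]


@dataclass
class AMPDEParams:
    """Configuration of the windowed multiscale peak detector.

    window_s
        Analysis window for the LMS computation.  5 s is long enough to
        contain the longest interictal transient while keeping the
        quadratic per-window cost at desk scale.
    threshold_sigma
        Amplitude gate, in units of the baseline noise sigma (robust MAD
        estimate), applied to detected peaks before density classification.
    delta_s
        Look-forward integration window handed to the density classifier.
    """

    alpha: float = 1.0
    window_s: float = 5.0
    delta_s: float = 2.0
    band_lo_hz: float = 0.5
    band_hi_hz: float = 50.0
    notch_hz: float = 50.0
    notch_q: float = 90.0
    rng_seed: int = 0
    threshold_sigma: float = 4.0
    use_notch: bool = True
    use_bandpass: bool = True

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ParameterError("alpha must be positive")
        if self.window_s <= 0:
            raise ParameterError("window_s must be positive")
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ParameterError("need 0 < band_lo_hz < band_hi_hz")
        if self.delta_s <= 0:
            raise ParameterError("delta_s must be positive")


@dataclass
class LMSMatrix:
    """Materialized local maxima scalogram (small-N analysis and tests)."""

    values: np.ndarray  # shape (L, N)
    alpha: float
    n_cell_ops: int  # instrumented count of evaluated (k, i) cells

    @property
    def n_scales(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class ScaleSummary:
    gamma: np.ndarray  # row sums, one per scale
    lambda_scale: int  # 1-based index of the selected scale


def detrend_linear(segment: np.ndarray) -> np.ndarray:
    """Remove the ordinary least-squares straight line from a segment."""
    segment = np.asarray(segment, dtype=np.float64)
    if segment.ndim != 1 or segment.size < 2:
        raise DataError("segment must be 1-D with at least 2 samples")
    return scipy.signal.detrend(segment, type="linear")


def _n_scales(n: int) -> int:
    return ceil(n / 2) - 1


def _local_max_mask(x: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of samples exceeding both k-spaced neighbors.

    Only interior indices ``k <= i <= N-k-1`` can be true; boundary cells
    of the LMS stay nonzero by definition.
    """
    n = x.size
    mask = np.zeros(n, dtype=bool)
    if n - 2 * k > 0:
        mask[k : n - k] = (x[k : n - k] > x[: n - 2 * k]) & (
            x[k : n - k] > x[2 * k :]
        )
    return mask


def compute_lms(
    segment: np.ndarray, alpha: float = 1.0, rng_seed: int = 0
) -> LMSMatrix:
    """Build the full L x N local maxima scalogram.

    Deterministic given ``rng_seed``: one PCG64 stream supplies N uniform
    draws per scale row, rows in increasing k.  The zero-pattern depends
    only on the data.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1 or x.size < 4:
        raise DataError("segment must be 1-D with at least 4 samples")
    n = x.size
    L = _n_scales(n)
    rng = np.random.default_rng(rng_seed)
    values = np.empty((L, n), dtype=np.float64)
    ops = 0
    for k in range(1, L + 1):
        row = rng.random(n) + alpha
        row[_local_max_mask(x, k)] = 0.0
        values[k - 1] = row
        ops += n
    return LMSMatrix(values=values, alpha=alpha, n_cell_ops=ops)


def select_scale(lms: LMSMatrix) -> ScaleSummary:
    """Row-wise sums and the argmin scale (ties break to the smallest k)."""
    gamma = lms.values.sum(axis=1)
    return ScaleSummary(gamma=gamma, lambda_scale=int(np.argmin(gamma)) + 1)


def detect_peaks_lms(lms: LMSMatrix, lambda_scale: int) -> list[int]:
    """Indices whose retained cells (scales k <= lambda) are all zero."""
    if not 1 <= lambda_scale <= lms.n_scales:
        raise ParameterError(
            f"lambda_scale {lambda_scale} outside 1..{lms.n_scales}"
        )
    sub = lms.values[:lambda_scale]
    return [int(i) for i in np.flatnonzero((sub == 0.0).all(axis=0))]


def lms_peaks(segment: np.ndarray, alpha: float = 1.0, rng=0):
    """Memory-lean LMS scan of one detrended segment.

    Equivalent to ``detect_peaks_lms(compute_lms(...), lambda)`` without
    materializing the L x N matrix; identical random draw protocol.

    Returns ``(peak_indices, gamma, lambda_scale, n_cell_ops)``.
    """
    x = np.asarray(segment, dtype=np.float64)
    if x.ndim != 1 or x.size < 4:
        raise DataError("segment must be 1-D with at least 4 samples")
    n = x.size
    L = _n_scales(n)
    rng = np.random.default_rng(rng)
    gamma = np.empty(L, dtype=np.float64)
    ops = 0
    for k in range(1, L + 1):
        r = rng.random(n)
        mask = _local_max_mask(x, k)
        gamma[k - 1] = (r + alpha)[~mask].sum()
        ops += n
    lam = int(np.argmin(gamma)) + 1
    keep = _local_max_mask(x, 1)
    for k in range(2, lam + 1):
        keep &= _local_max_mask(x, k)
    peaks = [int(i) for i in np.flatnonzero(keep)]
    return peaks, gamma, lam, ops


def _condition_for_ampde(record: LFPRecord, params: AMPDEParams) -> LFPRecord:
    """Notch (Q = notch_q) then zero-phase band-pass; either stage optional."""
    from .zdensity import condition_signal

    nyq = record.sampling_rate / 2.0
    out = record
    if params.use_notch:
        out = condition_signal(out, params.notch_hz, params.notch_q)
    if params.use_bandpass:
        if params.band_hi_hz >= nyq:
            raise ParameterError(
                f"band_hi_hz {params.band_hi_hz} must be below Nyquist {nyq}"
            )
        sos = scipy.signal.butter(
            4,
            [params.band_lo_hz, params.band_hi_hz],
            btype="bandpass",
            fs=record.sampling_rate,
            output="sos",
        )
        out = replace(out, samples=scipy.signal.sosfiltfilt(sos, out.samples))
    return out


def ampde_detect(
    record: LFPRecord, params: AMPDEParams, conditioned: bool = False
) -> list[OutlierPeak]:
    """Tile the record into consecutive windows and run the LMS per window.

    Window-local peak indices are converted to global times; a truncated
    final window is processed as-is when it still holds >= 4 samples.
    Peaks closer than one sample at window joins are merged.  The
    ``zscore`` field carries the deviation-statistic confidence (0 for all
    LMS peaks by construction); ``amplitude`` is the conditioned amplitude.
    """
    if record.n_samples == 0:
        raise DataError("empty record")
    cond = record if conditioned else _condition_for_ampde(record, params)
    fs = cond.sampling_rate
    x = cond.samples
    w = max(4, int(round(params.window_s * fs)))
    peaks: list[OutlierPeak] = []
    last_idx = -10
    for wi, off in enumerate(range(0, x.size, w)):
        seg = x[off : off + w]
        if seg.size < 4:
            break
        rng = np.random.default_rng(
            np.random.SeedSequence([int(params.rng_seed) & 0x7FFFFFFF, wi])
        )
        idx, _, _, _ = lms_peaks(detrend_linear(seg), params.alpha, rng)
        for i in idx:
            g = off + i
            if g - last_idx <= 1:  # duplicate at a window join
                continue
            peaks.append(
                OutlierPeak(time_s=g / fs, amplitude=float(x[g]), zscore=0.0)
            )
            last_idx = g
    return peaks


def baseline_sigma(samples: np.ndarray) -> float:
    """Robust noise-floor scale: median absolute deviation, normal-scaled."""
    from scipy.stats import median_abs_deviation

    return float(median_abs_deviation(samples, scale="normal"))


def ampde_segment(record: LFPRecord, params: AMPDEParams, density_params=None):
    """Full pipeline: conditioning, windowed LMS peaks, amplitude gate,
    density labeling.

    The amplitude gate drops peaks below ``threshold_sigma`` baseline-sigmas
    (AMPD reports every local maximum, including the noise floor's; the
    gate is what separates epileptiform excursions from it).

    Returns ``(peaks, classified_events, AnnotationTrack)``.
    """
    from .density import DensityParams, segment_peaks

    if density_params is None:
        density_params = DensityParams()
    cond = _condition_for_ampde(record, params)
    peaks = ampde_detect(cond, params, conditioned=True)
    gate = params.threshold_sigma * baseline_sigma(cond.samples)
    density_params = replace(
        density_params, delta_s=params.delta_s, min_peak_amplitude=gate
    )
    events, track = segment_peaks(
        peaks,
        density_params,
        sample_period_s=1.0 / record.sampling_rate,
        duration_s=record.duration_s,
    )
    return peaks, events, track
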