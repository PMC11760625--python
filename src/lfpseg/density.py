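"""Density-based interval classification shared by both detectors.

A peak train is grouped by greedy look-forward integration: an event keeps
growing while the next peak follows within ``delta_s`` of the current last
peak; a larger gap closes the event.  Events are then labeled by their peak
count — at least ``threshold_a`` peaks marks a sustained discharge (ictal,
label 2), at least ``threshold_b`` a brief transient (interictal, label 1) —
and everything else stays baseline.  ``delta_s`` doubles as the refractory
separation between events, so one parameter serves both roles.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import AnnotationTrack, DataError, EventInterval, ICTAL, INTERICTAL, ParameterError

__all__ = [
    "DensityParams",
    "RawEvent",
    "ClassifiedEvent",
    "integrate_peaks",
    "classify_events",
    "events_to_track",
    "segment_peaks",
]


@dataclass
class DensityParams:
    """Thresholds of the peak-density classifier.

    threshold_a / threshold_b
        Peak counts separating ictal (>= a), interictal ([b, a)) and
        baseline (< b).  A sustained ictal discharge contributes a high
        count within the integration window, while a single prominent
        outlier suffices for an interictal spike.
    min_event_s
        Events shorter than this are discarded.
    min_peak_amplitude
        Optional absolute amplitude gate applied to peaks before
        integration (``None`` disables it).  The AMPDE pipeline expresses
        it in baseline-sigma units.
    """

    delta_s: float = 4.0
    threshold_a: int = 20
    threshold_b: int = 1
    min_event_s: float = 0.0
    max_gap_s: float | None = None  # defaults to delta_s
    min_peak_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.delta_s <= 0:
            raise ParameterError("delta_s must be positive")
        if not self.threshold_a > self.threshold_b >= 1:
            raise ParameterError("need threshold_a > threshold_b >= 1")
        if self.min_event_s < 0:
            raise ParameterError("min_event_s must be >= 0")


@dataclass(frozen=True)
class RawEvent:
    """A contiguous group of peaks prior to labeling."""

    start_s: float
    end_s: float
    peak_count: int


@dataclass(frozen=True)
class ClassifiedEvent:
    interval: EventInterval
    peak_count: int
    peak_density: float  # peaks per second


def integrate_peaks(
    peak_times, delta_s: float, sample_period_s: float = 0.0005
) -> list[RawEvent]:
    """Greedy left-to-right grouping of a strictly increasing peak train.

    Event start is the first peak time; the end extends one sample period
    past the last peak so single-peak events keep nonzero measure under the
    half-open convention.
    """
    if delta_s <= 0:
        raise ParameterError("delta_s must be positive")
    times = [float(t) for t in peak_times]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise DataError("peak times must be strictly increasing")
    events: list[RawEvent] = []
    if not times:
        return events
    start = last = times[0]
    count = 1
    for t in times[1:]:
        if t - last <= delta_s:
            last = t
            count += 1
        else:
            events.append(RawEvent(start, last + sample_period_s, count))
            start = last = t
            count = 1
    events.append(RawEvent(start, last + sample_period_s, count))
    return events


def classify_events(
    events: list[RawEvent], params: DensityParams
) -> list[ClassifiedEvent]:
    """Label integrated events by peak count; sub-threshold events drop
    back to baseline."""
    out: list[ClassifiedEvent] = []
    for ev in events:
        dur = ev.end_s - ev.start_s
        if dur < params.min_event_s:
            continue
        if ev.peak_count >= params.threshold_a:
            label = ICTAL
        elif ev.peak_count >= params.threshold_b:
            label = INTERICTAL
        else:
            continue
        out.append(
            ClassifiedEvent(
                interval=EventInterval(ev.start_s, ev.end_s, label),
                peak_count=ev.peak_count,
                peak_density=ev.peak_count / dur,
            )
        )
    return out


def events_to_track(
    events: list[ClassifiedEvent], duration_s: float
) -> AnnotationTrack:
    """Assemble classified events into a valid annotation track, clipping
    any trailing overshoot from the one-sample end extension."""
    intervals = []
    for ev in events:
        iv = ev.interval
        end = min(iv.end_s, duration_s)
        start = min(iv.start_s, end - 1e-9)
        if start < 0:
            start = 0.0
        intervals.append(EventInterval(start, end, iv.label))
    return AnnotationTrack(intervals=intervals, duration_s=duration_s)


def segment_peaks(
    peaks,
    params: DensityParams,
    sample_period_s: float,
    duration_s: float,
):
    """Peak train -> labeled track: optional amplitude gate, delta
    integration, count-based labeling.

    ``peaks`` is a sequence of objects with ``time_s`` and ``amplitude``
    (e.g. ``OutlierPeak``).  Returns ``(classified_events, AnnotationTrack)``.
    """
    if params.min_peak_amplitude is not None:
        peaks = [p for p in peaks if abs(p.amplitude) >= params.min_peak_amplitude]
    raw = integrate_peaks(
        [p.time_s for p in peaks], params.delta_s, sample_period_s
    )
    events = classify_events(raw, params)
    return events, events_to_track(events, duration_s)
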