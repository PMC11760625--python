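"""Domain types and I/O shared by every stage of the segmentation pipeline.

The package works on single-channel local field potential (LFP) recordings:
a uniformly sampled voltage trace (microvolt scale, nominally 2 kHz) plus,
optionally, a reference annotation consisting of labeled time intervals.
Labels follow the convention used throughout epileptiform-activity work:
``0`` baseline, ``1`` interictal event, ``2`` ictal event.

Time is measured in seconds, intervals are half-open ``[start, end)`` and
sample indexing is 0-based, so sample ``i`` covers ``[i/fs, (i+1)/fs)``.
Half-open intervals avoid double counting boundary samples in the overlap
metrics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("lfpseg")

BASELINE = 0
INTERICTAL = 1
ICTAL = 2
VALID_LABELS = (BASELINE, INTERICTAL, ICTAL)

LABEL_NAMES = {BASELINE: "baseline", INTERICTAL: "interictal", ICTAL: "ictal"}


class LFPSegError(Exception):
    """Base class for all package errors."""


class FormatError(LFPSegError):
    """Unknown or malformed file format."""


class DataError(LFPSegError):
    """Input data violates a documented invariant."""


class ParameterError(LFPSegError):
    """Parameter outside its admissible range."""


class GenerationError(LFPSegError):
    """Synthetic record could not be generated under the given constraints."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LFPRecord:
    """A uniformly sampled single-channel LFP signal.

    Parameters
    ----------
    samples
        Amplitudes in signal units (conventionally microvolts).
    sampling_rate
        Samples per second; must be positive.
    record_id
        Free-form identifier.
    channel_meta
        Free-form key -> value map (brain region, slice id, ...).
    """

    samples: np.ndarray
    sampling_rate: float
    record_id: str = ""
    channel_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise DataError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise DataError("samples contain non-finite values")

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass(frozen=True)
class EventInterval:
    """A labeled half-open time interval ``[start_s, end_s)``."""

    start_s: float
    end_s: float
    label: int

    def __post_init__(self) -> None:
        if self.start_s < 0:
            raise DataError(f"interval start {self.start_s} < 0")
        if self.end_s <= self.start_s:
            raise DataError(
                f"interval end {self.end_s} must exceed start {self.start_s}"
            )
        if self.label not in VALID_LABELS:
            raise DataError(f"label {self.label} not in {VALID_LABELS}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class AnnotationTrack:
    """Ordered, non-overlapping labeled intervals over ``[0, duration_s]``.

    Gaps between intervals are implicitly baseline (label 0).  Touching
    intervals are legal; overlapping ones are not.
    """

    intervals: list[EventInterval]
    duration_s: float

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        ivs = sorted(self.intervals, key=lambda iv: (iv.start_s, iv.end_s))
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start_s < prev.end_s - 1e-12:
                raise DataError(
                    f"overlapping intervals: [{prev.start_s}, {prev.end_s}) and "
                    f"[{cur.start_s}, {cur.end_s})"
                )
        for iv in ivs:
            if iv.end_s > self.duration_s + 1e-9:
                raise DataError(
                    f"interval [{iv.start_s}, {iv.end_s}) exceeds record "
                    f"duration {self.duration_s}"
                )
        self.intervals = ivs

    def of_label(self, label: int) -> list[EventInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# Label <-> interval conversion
# ---------------------------------------------------------------------------


def intervals_to_labels(
    track: AnnotationTrack, sampling_rate: float, n_samples: int
) -> np.ndarray:
    """Expand an annotation track into a per-sample label sequence.

    Sample ``i`` receives the label of the interval containing time
    ``i / sampling_rate`` under the half-open convention; uncovered samples
    are baseline (0).
    """
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be positive")
    if abs(n_samples - track.duration_s * sampling_rate) > 1 + 1e-6:
        raise DataError(
            f"n_samples={n_samples} inconsistent with duration_s="
            f"{track.duration_s} at {sampling_rate} Hz"
        )
    labels = np.zeros(n_samples, dtype=np.int8)
    for iv in track.intervals:
        i0 = int(np.ceil(iv.start_s * sampling_rate - 1e-9))
        i1 = int(np.ceil(iv.end_s * sampling_rate - 1e-9))
        labels[max(i0, 0) : min(i1, n_samples)] = iv.label
    return labels


def labels_to_intervals(labels: np.ndarray, sampling_rate: float) -> AnnotationTrack:
    """Collapse a per-sample label sequence into an annotation track.

    Maximal runs of identical nonzero labels become intervals; baseline runs
    are omitted.  Inverse of :func:`intervals_to_labels` on valid inputs.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise DataError("empty label sequence")
    if not np.all(np.isin(labels, VALID_LABELS)):
        raise DataError("labels must be drawn from {0, 1, 2}")
    if sampling_rate <= 0:
        raise ParameterError("sampling_rate must be positive")
    n = labels.size
    boundaries = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [n]))
    intervals = [
        EventInterval(start_s=s / sampling_rate, end_s=e / sampling_rate,
                      label=int(labels[s]))
        for s, e in zip(starts, ends)
        if labels[s] != BASELINE
    ]
    return AnnotationTrack(intervals=intervals, duration_s=n / sampling_rate)


# ---------------------------------------------------------------------------
# Signal I/O
# ---------------------------------------------------------------------------

_FMT_BY_SUFFIX = {
    ".csv": "csv",
    ".txt": "csv",
    ".bin": "raw-binary-float32",
    ".f32": "raw-binary-float32",
    ".h5": "hdf5",
    ".hdf5": "hdf5",
}


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _infer_fmt(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "raw-binary-float32", "hdf5"):
            raise FormatError(f"unknown format {fmt!r}")
        return fmt
    try:
        return _FMT_BY_SUFFIX[path.suffix.lower()]
    except KeyError:
        raise FormatError(f"cannot infer format from suffix {path.suffix!r}")


def _impute(samples: np.ndarray, policy: str) -> np.ndarray:
    bad = ~np.isfinite(samples)
    if not bad.any():
        return samples
    if policy == "reject":
        raise DataError(
            f"{int(bad.sum())} non-finite samples (strict policy; "
            "pass impute_nan='linear' to interpolate)"
        )
    if policy == "linear":
        if bad.all():
            raise DataError("all samples non-finite; cannot interpolate")
        idx = np.arange(samples.size)
        samples = samples.copy()
        samples[bad] = np.interp(idx[bad], idx[~bad], samples[~bad])
        return samples
    raise ParameterError(f"unknown impute policy {policy!r}")


def load_record(
    path: str | Path,
    fmt: str | None = None,
    sampling_rate: float | None = None,
    record_id: str | None = None,
    impute_nan: str = "reject",
) -> LFPRecord:
    """Load a signal from CSV, raw little-endian float32, or HDF5.

    CSV and binary files expect a JSON sidecar ``<file>.json`` carrying at
    least ``sampling_rate`` unless it is passed explicitly.  HDF5 files store
    the signal in dataset ``/signal`` with a ``sampling_rate`` attribute.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = _infer_fmt(path, fmt)
    meta: dict = {}
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as fh:
            if "signal" not in fh:
                raise FormatError(f"{path}: missing /signal dataset")
            dset = fh["signal"]
            samples = np.asarray(dset[...], dtype=np.float64)
            rate = sampling_rate or float(dset.attrs.get("sampling_rate", 0))
            meta = {k: str(v) for k, v in dset.attrs.items()
                    if k != "sampling_rate"}
    else:
        if fmt == "csv":
            try:
                samples = np.loadtxt(path, dtype=np.float64, ndmin=1)
            except ValueError as exc:
                raise FormatError(f"{path}: not a one-column CSV: {exc}") from exc
        else:
            samples = np.fromfile(path, dtype="<f4").astype(np.float64)
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        rate = sampling_rate or float(meta.pop("sampling_rate", 0))
    if samples.size == 0:
        raise DataError(f"{path}: empty signal")
    if rate <= 0:
        raise DataError(
            f"{path}: sampling rate not found in sidecar/attributes and not supplied"
        )
    samples = _impute(samples, impute_nan)
    rid = record_id or str(meta.pop("record_id", path.stem))
    return LFPRecord(samples=samples, sampling_rate=rate, record_id=rid,
                     channel_meta={k: str(v) for k, v in meta.items()})


def write_record(record: LFPRecord, path: str | Path, fmt: str | None = None) -> None:
    """Write a signal in one of the supported formats (see :func:`load_record`)."""
    path = Path(path)
    fmt = _infer_fmt(path, fmt)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as fh:
            dset = fh.create_dataset("signal", data=record.samples)
            dset.attrs["sampling_rate"] = record.sampling_rate
            dset.attrs["record_id"] = record.record_id
            for k, v in record.channel_meta.items():
                dset.attrs[k] = str(v)
        return
    if fmt == "csv":
        np.savetxt(path, record.samples, fmt="%.10g")
    else:
        record.samples.astype("<f4").tofile(path)
    sidecar = {
        "sampling_rate": record.sampling_rate,
        "record_id": record.record_id,
        **record.channel_meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


# ---------------------------------------------------------------------------
# Annotation I/O  (CSV with header start_s,end_s,label)
# ---------------------------------------------------------------------------


def load_annotations(path: str | Path, duration_s: float | None = None) -> AnnotationTrack:
    """Read an annotation track from ``start_s,end_s,label`` CSV.

    If ``duration_s`` is omitted it is taken as the largest interval end.
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path)
    required = {"start_s", "end_s", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    intervals = [
        EventInterval(float(r.start_s), float(r.end_s), int(r.label))
        for r in df.itertuples()
    ]
    if duration_s is None:
        if not intervals:
            raise DataError(f"{path}: empty annotation file needs explicit duration_s")
        duration_s = max(iv.end_s for iv in intervals)
    return AnnotationTrack(intervals=intervals, duration_s=duration_s)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [(iv.start_s, iv.end_s, iv.label) for iv in track.intervals],
        columns=["start_s", "end_s", "label"],
    )
    df.to_csv(path, index=False)


def convert_external_annotations(path: str | Path) -> AnnotationTrack:
    """Converter stub for externally deposited annotation formats.

    The public brain-slice dataset ships annotations in its own layout;
    converting it is an optional workflow outside this package's scope.
    Re-save such annotations as ``start_s,end_s,label`` CSV and use
    :func:`load_annotations`.
    """
    raise NotImplementedError(
        "convert external annotations to start_s,end_s,label CSV first"
    )
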