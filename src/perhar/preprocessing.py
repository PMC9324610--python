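"""Reading, resampling, windowing, and temporal splitting of labeled inertial recordings.

The central objects are :class:`ActivityRecording` (one subject's contiguous
multichannel time series with a per-sample activity label) and
:class:`Segment` (a fixed-length, single-class window cut from a recording).
Segments remember their source recording and half-open sample interval so
that temporal-overlap constraints (triplet mining, reference/test leakage
checks) can be enforced exactly.

All sample intervals are 0-based and half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence
import warnings

import numpy as np
from scipy.interpolate import CubicSpline


@dataclass
class ActivityRecording:
    """One subject's uniformly sampled multichannel time series.

    Parameters
    ----------
    subject_id : str
        Opaque subject identifier.
    channels : ndarray, shape (C, T)
        Sensor channels (rows) over time (columns), in sensor units.
    labels : ndarray, shape (T,)
        Per-sample activity-class identifier.
    rate_hz : float
        Sampling rate in samples per second.
    recording_id : str
        Identifier of the source recording; segments cut from recordings
        with different ids never count as temporally overlapping.
    sample_index : ndarray, shape (T,), optional
        Index of each sample in the *original* source recording. Defaults to
        ``arange(T)``; temporal splitting preserves original indices so that
        downstream segments from the two halves can be proven disjoint.
    meta : dict
        Free-form metadata (e.g. ground-truth generator parameters).
    """

    subject_id: str
    channels: np.ndarray
    labels: np.ndarray
    rate_hz: float
    recording_id: str = ""
    sample_index: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.channels.ndim != 2:
            raise ValueError("channels must be a 2-D (C, T) array")
        if self.channels.shape[1] != self.labels.shape[0]:
            raise ValueError("labels length must equal number of time samples")
        if self.channels.shape[0] < 1 or self.channels.shape[1] < 1:
            raise ValueError("need at least one channel and one sample")
        if not np.all(np.isfinite(self.channels)):
            raise ValueError("channels contain non-finite values")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not self.recording_id:
            self.recording_id = f"{self.subject_id}"
        if self.sample_index is None:
            self.sample_index = np.arange(self.n_samples)
        else:
            self.sample_index = np.asarray(self.sample_index, dtype=int)
            if self.sample_index.shape[0] != self.n_samples:
                raise ValueError("sample_index length must equal T")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def n_samples(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate_hz


@dataclass
class Segment:
    """A fixed-length single-class window cut from a recording."""

    subject_id: str
    label: object
    window: np.ndarray  # (C, W)
    rate_hz: float
    source_id: str
    interval: tuple[int, int]  # half-open [start, end) in source samples

    def __post_init__(self) -> None:
        self.window = np.asarray(self.window, dtype=float)
        start, end = self.interval
        if end - start != self.window.shape[1]:
            raise ValueError("interval length must equal window width")

    @property
    def width(self) -> int:
        return self.window.shape[1]

    @property
    def n_channels(self) -> int:
        return self.window.shape[0]


def segments_overlap(a: Segment, b: Segment) -> bool:
    """True when two segments share at least one source sample."""
    if a.source_id != b.source_id:
        return False
    return max(a.interval[0], b.interval[0]) < min(a.interval[1], b.interval[1])


class SegmentSet:
    """A homogeneous collection of segments (shared C, W and sampling rate).

    Exposes vectorized views (stacked windows, label/subject arrays) used by
    the training and inference code.
    """

    def __init__(self, segments: Sequence[Segment]):
        self.segments = list(segments)
        if self.segments:
            c = self.segments[0].n_channels
            w = self.segments[0].width
            r = self.segments[0].rate_hz
            for s in self.segments:
                if s.n_channels != c or s.width != w or s.rate_hz != r:
                    raise ValueError("segments must share channel count, width and rate")

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments)

    def __getitem__(self, i):
        if isinstance(i, (list, np.ndarray)):
            return SegmentSet([self.segments[j] for j in np.asarray(i).tolist()])
        return self.segments[i]

    @property
    def windows(self) -> np.ndarray:
        """Stacked windows, shape (n, C, W)."""
        return np.stack([s.window for s in self.segments])

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([s.label for s in self.segments])

    @property
    def subject_ids(self) -> np.ndarray:
        return np.asarray([s.subject_id for s in self.segments])

    @property
    def source_ids(self) -> np.ndarray:
        return np.asarray([s.source_id for s in self.segments])

    @property
    def intervals(self) -> np.ndarray:
        return np.asarray([s.interval for s in self.segments], dtype=int).reshape(-1, 2)

    def subset(self, mask) -> "SegmentSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SegmentSet([self.segments[int(i)] for i in idx])


@dataclass
class SplitSpec:
    """Temporal reference/test split specification (fraction of each
    uniform-label run reserved, from its start, as reference data)."""

    reference_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.reference_fraction < 1.0:
            raise ValueError("reference_fraction must lie in (0, 1)")


def _label_runs(labels: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of constant label as half-open (start, end) pairs."""
    n = labels.shape[0]
    if n == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate(([0], change, [n]))
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(len(bounds) - 1)]


def _contiguous_runs(recording: ActivityRecording) -> list[tuple[int, int]]:
    """Runs of constant label AND contiguous source sample index.

    A recording produced by :func:`temporal_reference_split` may contain
    index jumps where samples were removed; windows must never straddle one.
    """
    runs: list[tuple[int, int]] = []
    idx = recording.sample_index
    for start, end in _label_runs(recording.labels):
        s = start
        jumps = np.flatnonzero(np.diff(idx[start:end]) != 1) + 1 + start
        for j in jumps.tolist():
            runs.append((s, int(j)))
            s = int(j)
        runs.append((s, end))
    return runs


def resample_uniform(recording: ActivityRecording, target_hz: float) -> ActivityRecording:
    """Resample a recording to ``target_hz`` with per-channel cubic interpolation.

    Duration is preserved to within one sample period; labels are mapped to
    the nearest original sample. A recording already at the target rate is
    returned sample-identical.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if recording.rate_hz == target_hz:
        return recording
    t_old = recording.n_samples
    if t_old < 4:
        raise ValueError("cubic resampling requires at least 4 samples")
    duration = t_old / recording.rate_hz
    n_new = int(round(duration * target_hz))
    times_old = np.arange(t_old) / recording.rate_hz
    times_new = np.arange(n_new) / target_hz
    spline = CubicSpline(times_old, recording.channels, axis=1)
    channels = spline(times_new)
    nearest = np.clip(np.round(times_new * recording.rate_hz).astype(int), 0, t_old - 1)
    return ActivityRecording(
        subject_id=recording.subject_id,
        channels=channels,
        labels=recording.labels[nearest],
        rate_hz=target_hz,
        recording_id=recording.recording_id,
        meta=dict(recording.meta),
    )


def sliding_window_segment(
    recording: ActivityRecording,
    window_seconds: float,
    overlap: float,
) -> SegmentSet:
    """Cut uniform-label fixed-width windows from a recording.

    Window width ``W = round(window_seconds * rate_hz)``; successive window
    starts advance by ``step = max(1, round(W * (1 - overlap)))`` within each
    maximal run of constant label. Windows that would span a label change
    (or a sample-index discontinuity left by temporal splitting) are never
    emitted. Returns an empty set when no run can fit one window.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must lie in [0, 1)")
    if not window_seconds > 0:
        raise ValueError("window_seconds must be positive")
    w = int(round(window_seconds * recording.rate_hz))
    if w < 1:
        raise ValueError("window shorter than one sample")
    step = max(1, int(round(w * (1.0 - overlap))))
    segments: list[Segment] = []
    idx = recording.sample_index
    for run_start, run_end in _contiguous_runs(recording):
        for s in range(run_start, run_end - w + 1, step):
            src_start = int(idx[s])
            segments.append(
                Segment(
                    subject_id=recording.subject_id,
                    label=recording.labels[s],
                    window=recording.channels[:, s : s + w],
                    rate_hz=recording.rate_hz,
                    source_id=recording.recording_id,
                    interval=(src_start, src_start + w),
                )
            )
    return SegmentSet(segments)


def temporal_reference_split(
    recording: ActivityRecording,
    spec: SplitSpec | None = None,
) -> tuple[ActivityRecording, ActivityRecording]:
    """Split each uniform-label run along time into reference and test parts.

    For every maximal run of constant label, the first
    ``floor(reference_fraction * run_length)`` samples go to the reference
    recording; the rest go to the test recording. The split happens *before*
    windowing, so segments later cut from the two parts can never share a
    source sample. Original sample indices are preserved on both halves.
    """
    spec = spec or SplitSpec()
    ref_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for start, end in _label_runs(recording.labels):
        cut = start + int(np.floor(spec.reference_fraction * (end - start)))
        if cut == start or cut == end:
            warnings.warn(
                f"run [{start},{end}) too short to contribute to both sides",
                stacklevel=2,
            )
        ref_idx.append(np.arange(start, cut))
        test_idx.append(np.arange(cut, end))

    def _make(indices: list[np.ndarray], tag: str) -> ActivityRecording | None:
        if indices:
            sel = np.concatenate(indices)
        else:
            sel = np.array([], dtype=int)
        if sel.size == 0:
            raise ValueError(f"temporal split produced an empty {tag} part")
        return ActivityRecording(
            subject_id=recording.subject_id,
            channels=recording.channels[:, sel],
            labels=recording.labels[sel],
            rate_hz=recording.rate_hz,
            recording_id=recording.recording_id,
            sample_index=recording.sample_index[sel],
            meta=dict(recording.meta),
        )

    return _make(ref_idx, "reference"), _make(test_idx, "test")


def standardize_windows(
    train: SegmentSet, *others: SegmentSet
) -> tuple[np.ndarray, np.ndarray, list[SegmentSet]]:
    """Per-channel z-score standardization fit on training windows.

    Optional (off by default in all pipelines): returns the fitted per-channel
    mean and standard deviation plus standardized copies of every passed set.
    """
    x = train.windows
    mean = x.mean(axis=(0, 2))
    std = x.std(axis=(0, 2))
    std = np.where(std > 0, std, 1.0)

    def _apply(ss: SegmentSet) -> SegmentSet:
        out = []
        for s in ss:
            out.append(
                Segment(
                    subject_id=s.subject_id,
                    label=s.label,
                    window=(s.window - mean[:, None]) / std[:, None],
                    rate_hz=s.rate_hz,
                    source_id=s.source_id,
                    interval=s.interval,
                )
            )
        return SegmentSet(out)

    return mean, std, [_apply(ss) for ss in (train, *others)]


def segment_recordings(
    recordings: Sequence[ActivityRecording],
    window_seconds: float,
    overlap: float,
    resample_hz: float | None = None,
) -> SegmentSet:
    """Segment a batch of recordings, optionally resampling first."""
    all_segments: list[Segment] = []
    for rec in recordings:
        if resample_hz is not None:
            rec = resample_uniform(rec, resample_hz)
        all_segments.extend(sliding_window_segment(rec, window_seconds, overlap))
    return SegmentSet(all_segments)
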