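"""Short-Time Energy (STE) activity segmentation.

Continuous node recordings are cut into activity samples by thresholding the
windowed energy of the multichannel stream: frame energy is the sum of squared
amplitudes over a sliding window, pooled across all channels (single-target
assumption).  Supra-threshold frame runs are merged across short gaps
("hangover") and short runs are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensing import SensorStream

__all__ = [
    "EnergySeries",
    "Segment",
    "short_time_energy",
    "detect_segments",
    "auto_threshold",
    "segment_stream",
    "extract_segments",
]

#: default STE parameters (seconds); activities last >= 0.4 s at 25 Hz
DEFAULT_WINDOW_S = 0.5
DEFAULT_HOP_S = 0.25
DEFAULT_HANGOVER_S = 0.5
DEFAULT_MIN_DURATION_S = 0.6


@dataclass
class EnergySeries:
    """Frame energies of a stream: window/hop geometry in samples."""

    frame_energies: np.ndarray
    window_len: int
    hop: int

    def __post_init__(self):
        self.frame_energies = np.asarray(self.frame_energies, dtype=float)
        if np.any(self.frame_energies < 0):
            raise ValueError("frame energies must be non-negative")


@dataclass(frozen=True, order=True)
class Segment:
    """Half-open sample interval [start, end) of one detected activity."""

    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError("segment must satisfy 0 <= start < end")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


def short_time_energy(
    stream: SensorStream | np.ndarray,
    window_len: int | None = None,
    hop: int | None = None,
    sampling_rate: float | None = None,
) -> EnergySeries:
    """Channel-pooled short-time energy of a multichannel stream.

    Frame ``n`` covers samples ``[n*hop, n*hop + window_len)`` and its energy
    is the double sum of squared amplitudes over window samples and channels.
    Defaults: 0.5 s window, 0.25 s hop at the stream's sampling rate.
    """
    if isinstance(stream, SensorStream):
        values = stream.values
        fs = stream.sampling_rate
    else:
        values = np.atleast_2d(np.asarray(stream))
        fs = sampling_rate if sampling_rate is not None else 25.0
    if window_len is None:
        window_len = max(int(round(DEFAULT_WINDOW_S * fs)), 1)
    if hop is None:
        hop = max(int(round(DEFAULT_HOP_S * fs)), 1)
    if window_len < 1 or hop < 1:
        raise ValueError("window_len and hop must be >= 1")
    t = values.shape[1]
    if window_len > t:
        raise ValueError(f"window ({window_len}) longer than stream ({t})")
    sq = (values.astype(float) ** 2).sum(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(sq)])
    n_frames = (t - window_len) // hop + 1
    starts = np.arange(n_frames) * hop
    energies = csum[starts + window_len] - csum[starts]
    return EnergySeries(frame_energies=energies, window_len=window_len, hop=hop)


def auto_threshold(energy: EnergySeries, factor: float = 5.0) -> float:
    """Noise-floor-based threshold: ``factor`` times the noise-floor energy.

    The noise floor is estimated as the median energy of the quietest quarter
    of frames, which is robust even when active frames dominate the recording.
    """
    e = np.sort(energy.frame_energies)
    quiet = e[: max(len(e) // 4, 1)]
    floor = float(np.median(quiet))
    return max(factor * floor, np.finfo(float).tiny)


def detect_segments(
    energy: EnergySeries,
    threshold: float | None = None,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    hangover_s: float = DEFAULT_HANGOVER_S,
    sampling_rate: float = 25.0,
) -> list[Segment]:
    """Threshold frame energies into sorted, non-overlapping sample segments.

    Maximal runs of frames with energy above ``threshold`` are merged across
    gaps shorter than ``hangover_s`` and dropped if shorter than
    ``min_duration_s``.  ``threshold=None`` uses :func:`auto_threshold`.
    """
    if threshold is None:
        threshold = auto_threshold(energy)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    active = energy.frame_energies > threshold
    if not active.any():
        return []
    hop, win = energy.hop, energy.window_len
    idx = np.flatnonzero(active)
    # frame runs: split where consecutive active frames are non-adjacent
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    runs = [(grp[0], grp[-1]) for grp in np.split(idx, breaks)]
    # hangover merge: gap duration measured in frame hops
    merged = [runs[0]]
    for f0, f1 in runs[1:]:
        gap_s = (f0 - merged[-1][1] - 1) * hop / sampling_rate
        if gap_s < hangover_s:
            merged[-1] = (merged[-1][0], f1)
        else:
            merged.append((f0, f1))
    segments: list[Segment] = []
    t_total = len(energy.frame_energies) * hop + win  # upper bound on stream length
    for f0, f1 in merged:
        start = int(f0) * hop
        end = int(f1) * hop + win
        if segments and start < segments[-1].end:
            start = segments[-1].end
        if (end - start) / sampling_rate < min_duration_s:
            continue
        segments.append(Segment(start=start, end=min(end, t_total)))
    return segments


def segment_stream(
    stream: SensorStream,
    threshold: float | None = None,
    window_len: int | None = None,
    hop: int | None = None,
    min_duration_s: float = DEFAULT_MIN_DURATION_S,
    hangover_s: float = DEFAULT_HANGOVER_S,
) -> list[Segment]:
    """Convenience: STE + thresholding on a stream in one call."""
    energy = short_time_energy(stream, window_len=window_len, hop=hop)
    return detect_segments(
        energy, threshold=threshold, min_duration_s=min_duration_s,
        hangover_s=hangover_s, sampling_rate=stream.sampling_rate)


def extract_segments(stream: SensorStream, segments: list[Segment]) -> list[SensorStream]:
    """Cut detected segments out of a stream, inheriting its metadata."""
    samples = []
    for k, seg in enumerate(segments):
        end = min(seg.end, stream.n_samples)
        meta = dict(stream.metadata, segment_index=int(k),
                    segment_start=int(seg.start), segment_end=int(end))
        samples.append(SensorStream(
            values=stream.values[:, seg.start:end],
            sampling_rate=stream.sampling_rate, metadata=meta))
    return samples
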