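"""Electro-optical synchrony analysis.

Detects photon bursts in the 1 kHz fluorescence frame series recorded
synchronously with the ion current, and quantifies how often translocation
events coincide with a burst.  A labeled molecule dwelling at the pore
mouth can fluoresce before it threads, so the correlation window extends a
few milliseconds before the electrical event start.  Chance coincidence is
estimated by circularly shifting the burst train by a random offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhotonTrace",
    "OpticalBurst",
    "SyncResult",
    "detect_bursts",
    "correlate",
]


@dataclass
class PhotonTrace:
    """Photon-count frame series with background statistics (counts/frame)."""

    frame_counts: np.ndarray
    frame_rate_hz: float = 1000.0
    background_mean: float | None = None
    background_rms: float | None = None

    def __post_init__(self):
        self.frame_counts = np.asarray(self.frame_counts, dtype=float)
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        if (self.frame_counts < 0).any():
            raise ValueError("photon counts must be nonnegative")


@dataclass(frozen=True)
class OpticalBurst:
    """A maximal run of frames above the burst threshold (half-open frames)."""

    start_frame: int
    end_frame: int
    peak_counts: float
    integrated_counts: float

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValueError("end_frame must exceed start_frame")


@dataclass(frozen=True)
class SyncResult:
    """Per-event burst coincidence and its time-shuffled chance level."""

    correlated: np.ndarray
    fraction_correlated: float
    null_fraction: float


def detect_bursts(trace: PhotonTrace, k_rms: float = 10.0,
                  min_frames: int = 1) -> list[OpticalBurst]:
    """Find maximal runs of frames strictly above background_mean + k_rms * RMS.

    Background statistics are taken from the trace metadata when present,
    otherwise estimated robustly (median / scaled MAD) from the frames,
    which requires at least 100 frames.
    """
    x = trace.frame_counts
    mean, rms = trace.background_mean, trace.background_rms
    if mean is None or rms is None:
        if x.size < 100:
            raise ValueError("need >= 100 frames to estimate the background")
        mean = float(np.median(x))
        rms = 1.4826 * float(np.median(np.abs(x - mean)))
    thresh = mean + k_rms * rms
    above = x > thresh  # strict: a frame exactly at threshold is not a burst
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [x.size]])
    return [
        OpticalBurst(
            start_frame=int(s),
            end_frame=int(e),
            peak_counts=float(x[s:e].max()),
            integrated_counts=float(x[s:e].sum()),
        )
        for s, e in zip(starts, ends)
        if e - s >= min_frames
    ]


def _overlap_fraction(event_windows, burst_windows, duration_s) -> np.ndarray:
    """Boolean flag per event window: does any burst window intersect it?"""
    flags = np.zeros(len(event_windows), dtype=bool)
    if not burst_windows:
        return flags
    b0 = np.array([b[0] for b in burst_windows])
    b1 = np.array([b[1] for b in burst_windows])
    for i, (t0, t1) in enumerate(event_windows):
        flags[i] = bool(np.any((b1 > t0) & (b0 < t1)))
    return flags


def correlate(events, bursts, sampling_rate_hz: float,
              frame_rate_hz: float = 1000.0, pre_window_ms: float = 5.0,
              post_window_ms: float = 1.0, seed=0,
              duration_s: float | None = None) -> SyncResult:
    """Flag each electrical event as optically correlated or not.

    An event is correlated iff a burst overlaps the window
    [start - pre_window, end + post_window] on the shared time axis (both
    recordings start at t = 0).  The chance level is the correlated fraction
    after circularly shifting all burst times by one random offset.
    """
    if sampling_rate_hz <= 0 or frame_rate_hz <= 0:
        raise ValueError("rates must be positive; check the shared time base")
    ev_windows = []
    for ev in events:
        start = getattr(ev, "start_idx", None)
        end = getattr(ev, "end_idx", None)
        if start is None:
            start, end = ev
        t0 = start / sampling_rate_hz - pre_window_ms * 1e-3
        t1 = end / sampling_rate_hz + post_window_ms * 1e-3
        ev_windows.append((t0, t1))
    burst_windows = [
        (b.start_frame / frame_rate_hz, b.end_frame / frame_rate_hz)
        for b in bursts
    ]
    if duration_s is None:
        last_ev = max((w[1] for w in ev_windows), default=0.0)
        last_b = max((w[1] for w in burst_windows), default=0.0)
        duration_s = max(last_ev, last_b, 1e-9)

    flags = _overlap_fraction(ev_windows, burst_windows, duration_s)
    rng = np.random.default_rng(seed)
    shift = rng.uniform(0.1, 0.9) * duration_s
    shifted = [((b0 + shift) % duration_s, (b1 + shift) % duration_s)
               for b0, b1 in burst_windows]
    # a window wrapping the origin splits into two pieces
    unwrapped = []
    for b0, b1 in shifted:
        if b1 >= b0:
            unwrapped.append((b0, b1))
        else:
            unwrapped.extend([(b0, duration_s), (0.0, b1)])
    null_flags = _overlap_fraction(ev_windows, unwrapped, duration_s)
    return SyncResult(
        correlated=flags,
        fraction_correlated=float(flags.mean()) if flags.size else 0.0,
        null_fraction=float(null_flags.mean()) if null_flags.size else 0.0,
    )
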