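"""Raw-signal cleanup for tablet sensor streams.

Four heuristics are applied before feature extraction:

* **Device-flip correction** — some participants hold the tablet rotated
  180 degrees, which shifts the compass by half a turn and inverts the
  lateral inertial axes.  The flip is detected from the sign of the
  gravity-axis accelerometer (a flat-held device reads +g on z; the median
  over the stream gives a robust estimate) and undone by the involutive
  device-frame rotation.
* **Compass unwrapping with an 80-degree gate** — successive compass
  samples that jump by more than 80 degrees are treated as wraparound
  (corrected by +/-360); jumps that remain above the gate after wrap
  correction are rejected as glitches and linearly interpolated, with a
  rejection count recorded.
* **Moving-window smoothing** — a centered 100-sample moving average with
  truncated edges, used to stabilise the acceleration magnitude before
  peak detection.
* **Peak detection** — prominence-gated local maxima/minima of a smoothed
  series, merged into an alternating peak/trough event sequence; troughs
  feed the hesitation count downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.signal import find_peaks

from vrtask.simulate import SensorStream, flip_transform

__all__ = [
    "CleanStream",
    "PeakEvent",
    "correct_flip",
    "unwrap_heading",
    "moving_window_smooth",
    "detect_peaks",
    "accel_magnitude",
    "preprocess_stream",
]

COMPASS_GATE_DEG = 80.0
SMOOTH_WINDOW = 100
PROMINENCE_FRAC = 0.05


@dataclass
class CleanStream:
    """A preprocessed stream: original channels plus the unwrapped heading
    and the cleanup flags."""

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray
    heading: np.ndarray
    heading_unwrapped: np.ndarray
    sample_period_s: float
    flags: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]


class PeakEvent(NamedTuple):
    kind: str  # "peak" or "trough"
    index: int
    value: float


def correct_flip(stream: SensorStream) -> SensorStream:
    """Undo a 180-degree device flip if one is detected.

    A stream is declared flipped when the median gravity-axis (z)
    accelerometer reading has inverted sign relative to the flat-held
    orientation (+g).  Idempotent: a corrected stream is never re-flipped.
    """
    if float(np.median(stream.accel[:, 2])) >= 0.0:
        return stream
    corrected = flip_transform(stream)
    corrected.flip_corrected = True
    return corrected


def unwrap_heading(
    heading: np.ndarray,
    threshold_deg: float = COMPASS_GATE_DEG,
    return_rejections: bool = False,
):
    """Unwrap a compass series into continuous degrees.

    Successive differences larger than ``threshold_deg`` in magnitude are
    first wrap-corrected by the nearest multiple of 360; samples whose
    corrected difference still exceeds the gate are rejected as glitches
    and linearly interpolated between the neighbouring accepted samples.
    Wrapping the output back to [0, 360) recovers every accepted input
    sample exactly.
    """
    h = np.asarray(heading, dtype=float)
    if h.ndim != 1 or h.size < 2:
        raise ValueError("heading series must be 1-D with at least 2 samples")
    n = h.size
    out = np.empty(n)
    accepted = np.ones(n, dtype=bool)
    out[0] = h[0]
    last_raw = h[0]
    last_unwrapped = h[0]
    for i in range(1, n):
        d = h[i] - last_raw
        dc = d - 360.0 * np.round(d / 360.0)
        if abs(dc) > threshold_deg:
            accepted[i] = False
            continue
        last_unwrapped = last_unwrapped + dc
        last_raw = h[i]
        out[i] = last_unwrapped
    n_rejected = int(n - accepted.sum())
    if n_rejected:
        idx = np.arange(n)
        out[~accepted] = np.interp(idx[~accepted], idx[accepted], out[accepted])
    if return_rejections:
        return out, n_rejected
    return out


def moving_window_smooth(series: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Centered moving average with edge handling by window truncation.

    Output length equals input length; a constant series is a fixed point
    and the output is bounded by the input range.  For even windows the
    window extends ``window // 2`` samples to the left and
    ``window // 2 - 1`` to the right of each sample.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if window == 1:
        return x.copy()
    kernel = np.ones(window)
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones(x.size), kernel, mode="same")
    return sums / counts


def detect_peaks(
    series: np.ndarray, prominence_frac: float = PROMINENCE_FRAC
) -> list[PeakEvent]:
    """Alternating prominent local maxima/minima of a smoothed series.

    The prominence floor is ``prominence_frac`` times the series' dynamic
    range.  Peaks and troughs are merged in index order; where two events
    of the same kind are adjacent, only the more extreme one (higher peak,
    deeper trough; earlier index on ties) is kept, so the returned events
    strictly alternate.  A flat series yields no events.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("series must have at least 3 samples")
    span = float(x.max() - x.min())
    if span == 0.0:
        return []
    floor = prominence_frac * span
    peak_idx, _ = find_peaks(x, prominence=floor)
    trough_idx, _ = find_peaks(-x, prominence=floor)
    events = sorted(
        [PeakEvent("peak", int(i), float(x[i])) for i in peak_idx]
        + [PeakEvent("trough", int(i), float(x[i])) for i in trough_idx],
        key=lambda e: e.index,
    )
    merged: list[PeakEvent] = []
    for ev in events:
        if merged and merged[-1].kind == ev.kind:
            prev = merged[-1]
            better = (
                ev.value > prev.value if ev.kind == "peak" else ev.value < prev.value
            )
            if better:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def accel_magnitude(accel: np.ndarray, remove_gravity: bool = True) -> np.ndarray:
    """Euclidean norm of the three accelerometer axes.

    With ``remove_gravity`` the per-axis median (the static gravity
    component of a mostly-flat-held device) is subtracted first, so the
    magnitude tracks movement intensity and drops to noise level when the
    hand stops.
    """
    a = np.asarray(accel, dtype=float)
    if remove_gravity:
        a = a - np.median(a, axis=0, keepdims=True)
    return np.sqrt((a**2).sum(axis=1))


def preprocess_stream(
    stream: SensorStream,
    threshold_deg: float = COMPASS_GATE_DEG,
) -> CleanStream:
    """Full cleanup of one stream: flip correction then compass unwrapping."""
    corrected = correct_flip(stream)
    unwrapped, n_rej = unwrap_heading(
        corrected.heading, threshold_deg=threshold_deg, return_rejections=True
    )
    return CleanStream(
        t=corrected.t,
        accel=corrected.accel,
        gyro=corrected.gyro,
        heading=corrected.heading,
        heading_unwrapped=unwrapped,
        sample_period_s=corrected.sample_period_s,
        flags={
            "flip_corrected": corrected.flip_corrected,
            "n_compass_rejections": n_rej,
        },
    )
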