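"""Independent brute-force oracles for the feature extractor.

Every function here re-derives a pipeline quantity with explicit loops and
none of the package's vectorised code paths, so tests can compare the two
routes sample by sample.
"""

from __future__ import annotations

import numpy as np


def oracle_end_error(final_heading: float, ref_heading: float) -> float:
    d = abs(final_heading - ref_heading) % 360.0
    return min(d, 360.0 - d)


def oracle_displacement(unwrapped) -> float:
    total = 0.0
    for i in range(1, len(unwrapped)):
        total += abs(unwrapped[i] - unwrapped[i - 1])
    return total


def oracle_tilt(channel) -> float:
    best = channel[0]
    for v in channel:
        if abs(v) > abs(best):
            best = v
    return float(best)


def oracle_rate_of_change(channel, block: int) -> float:
    n_blocks = len(channel) // block
    means = []
    for b in range(n_blocks):
        s = 0.0
        for i in range(b * block, (b + 1) * block):
            s += channel[i]
        means.append(s / block)
    return float(np.mean(means))


def oracle_average(channel) -> float:
    s = 0.0
    for v in channel:
        s += v
    return s / len(channel)


def oracle_jerk(channel, block: int, interval_s: float, mode: str = "absolute") -> float:
    n_blocks = len(channel) // block
    sums = []
    for b in range(n_blocks):
        s = 0.0
        for i in range(b * block, (b + 1) * block):
            s += channel[i]
        sums.append(s)
    diffs = [(sums[b + 1] - sums[b]) / interval_s for b in range(n_blocks - 1)]
    if mode == "absolute":
        diffs = [abs(d) for d in diffs]
    return float(np.mean(diffs))


def oracle_smooth(x, window: int):
    """Centered truncated moving average matching 'same'-mode convolution
    alignment: window extends floor((w-1)/2) to the right."""
    n = len(x)
    off = (window - 1) // 2
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i + off - window + 1)
        hi = min(n - 1, i + off)
        out[i] = np.mean(x[lo : hi + 1])
    return out


def _prominence(x, i: int) -> float:
    n = len(x)
    j = i - 1
    left_min = x[i]
    while j >= 0 and x[j] <= x[i]:
        left_min = min(left_min, x[j])
        j -= 1
    j = i + 1
    right_min = x[i]
    while j < n and x[j] <= x[i]:
        right_min = min(right_min, x[j])
        j += 1
    return x[i] - max(left_min, right_min)


def oracle_events(x, prominence_frac: float = 0.05):
    """Alternating prominent extrema: ('peak'|'trough', index, value)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    span = max(x) - min(x)
    if span == 0:
        return []
    floor = prominence_frac * span
    events = []
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            if _prominence(x, i) >= floor:
                events.append(("peak", i, float(x[i])))
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            if _prominence(-x, i) >= floor:
                events.append(("trough", i, float(x[i])))
    merged = []
    for ev in events:
        if merged and merged[-1][0] == ev[0]:
            prev = merged[-1]
            better = ev[2] > prev[2] if ev[0] == "peak" else ev[2] < prev[2]
            if better:
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def oracle_hesitations(
    accel,
    window: int = 100,
    stop_frac: float = 0.10,
    prominence_frac: float = 0.05,
) -> int:
    a = np.asarray(accel, dtype=float)
    centered = a - np.median(a, axis=0, keepdims=True)
    mag = np.array([np.sqrt(sum(v**2 for v in row)) for row in centered])
    smoothed = oracle_smooth(mag, window)
    level = stop_frac * np.percentile(smoothed, 95)
    count = 0
    for kind, _, value in oracle_events(smoothed, prominence_frac):
        if kind == "trough" and value < level:
            count += 1
    return count


def oracle_f1(tp: int, fp: int, fn: int) -> float:
    """F1 via precision/recall, the route the formula is derived from."""
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
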