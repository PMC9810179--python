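"""The seven movement-feature families extracted from one trial response.

Per preprocessed stream the extractor produces a fixed 27-entry vector:

========================  =====  =============================================
feature                   count  definition
========================  =====  =============================================
end_error                 1      absolute minimal circular difference, in
                                 [0, 180] degrees, between the final heading
                                 sample and the recorded reference bearing
                                 (the path-integration proxy)
total_angular_displacement 1     sum of absolute consecutive changes of the
                                 unwrapped heading, degrees
tilt_{x,y,z}              3      the single largest-magnitude gyroscope
                                 sample per axis, sign preserved, degrees
roc_{axis}_{T}            9      gyroscopic rate of change: the trace is cut
                                 into consecutive blocks of T in {0.1, 0.5,
                                 1.0} s; each block's samples are summed and
                                 divided by the block length; block values
                                 are averaged (trailing partial block
                                 dropped)
accel_{x,y,z}             3      arithmetic mean of the accelerometer per
                                 axis over the response window, m/s^2
jerk_{axis}_{T}           9      block sums of raw acceleration over T
                                 windows; successive differences of those
                                 sums divided by T; mean of absolute
                                 differences (m/s^3); a signed variant is
                                 available
hesitations               1      number of stop-and-go events: troughs of
                                 the 100-sample-smoothed gravity-removed
                                 acceleration magnitude that fall below 10%
                                 of the trace's 95th percentile
========================  =====  =============================================

The vector layout is fixed so feature-importance reports are stable across
runs; :func:`feature_names` is the single source of truth for the order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from vrtask.protocol import ReferencePoint, wrap_signed
from vrtask.preprocess import (
    CleanStream,
    moving_window_smooth,
    detect_peaks,
    accel_magnitude,
    preprocess_stream,
    SMOOTH_WINDOW,
    PROMINENCE_FRAC,
)
from vrtask.simulate import Session

__all__ = [
    "FeatureConfig",
    "AXES",
    "INTERVALS_S",
    "end_error",
    "total_angular_displacement",
    "tilt_max",
    "gyro_rate_of_change",
    "average_acceleration",
    "average_jerk",
    "count_hesitations",
    "extract_features",
    "feature_names",
    "cohort_feature_tables",
    "correlation_filter",
]

AXES = ("x", "y", "z")
INTERVALS_S = (0.1, 0.5, 1.0)


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable choices of the feature extractor.

    jerk_mode        : "absolute" (mean |block difference|; default, since a
                       signed mean cancels on back-and-forth movement) or
                       "signed".
    smooth_window    : samples in the hesitation moving average.
    stop_frac        : a trough counts as a stop only below this fraction of
                       the smoothed magnitude's 95th percentile.
    prominence_frac  : prominence floor for peak detection, as a fraction of
                       the smoothed dynamic range.
    """

    jerk_mode: str = "absolute"
    smooth_window: int = SMOOTH_WINDOW
    stop_frac: float = 0.10
    prominence_frac: float = PROMINENCE_FRAC
    intervals_s: tuple = INTERVALS_S

    def __post_init__(self) -> None:
        if self.jerk_mode not in ("absolute", "signed"):
            raise ValueError("jerk_mode must be 'absolute' or 'signed'")


def end_error(clean: CleanStream, reference: ReferencePoint) -> float:
    """Absolute angular pointing error in [0, 180] degrees."""
    if clean.heading.size == 0:
        raise ValueError("empty heading trace")
    final = float(clean.heading[-1])
    return abs(wrap_signed(reference.heading_deg - final))


def total_angular_displacement(clean: CleanStream) -> float:
    """Sum of absolute consecutive changes of the unwrapped heading (deg)."""
    h = clean.heading_unwrapped
    if h.size < 2:
        raise ValueError("heading trace must have at least 2 samples")
    return float(np.abs(np.diff(h)).sum())


def tilt_max(clean: CleanStream) -> np.ndarray:
    """Per-axis largest-magnitude gyroscope sample, sign preserved."""
    g = clean.gyro
    if g.size == 0:
        raise ValueError("empty gyro channels")
    idx = np.abs(g).argmax(axis=0)
    return g[idx, np.arange(3)].astype(float)


def _block_length(clean: CleanStream, interval_s: float) -> int:
    # Intervals are realised as the nearest whole number of samples; at the
    # 0.003 s period the 0.1/0.5/1.0 s windows are 33/167/333 samples
    # (within 1% of nominal).  A >2% mismatch is rejected.
    nb = interval_s / clean.sample_period_s
    block = int(round(nb))
    if block < 1 or abs(nb - block) > 0.02 * nb:
        raise ValueError(
            f"interval {interval_s} s is not a whole number of samples "
            f"(period {clean.sample_period_s} s) within tolerance"
        )
    return block


def gyro_rate_of_change(clean: CleanStream, interval_s: float) -> np.ndarray:
    """Per-axis mean of block averages of the raw gyro samples.

    The trace is partitioned into consecutive non-overlapping blocks of
    ``interval_s``; each block contributes (sum of samples) / (samples per
    block); a trailing partial block is dropped.
    """
    block = _block_length(clean, interval_s)
    n = clean.gyro.shape[0]
    n_blocks = n // block
    if n_blocks < 1:
        raise ValueError("trace shorter than one interval")
    g = clean.gyro[: n_blocks * block]
    block_means = g.reshape(n_blocks, block, 3).mean(axis=1)
    return block_means.mean(axis=0)


def average_acceleration(clean: CleanStream) -> np.ndarray:
    """Per-axis arithmetic mean of the accelerometer over the response."""
    if clean.accel.size == 0:
        raise ValueError("empty accel channels")
    return clean.accel.mean(axis=0)


def average_jerk(
    clean: CleanStream, interval_s: float, mode: str = "absolute"
) -> np.ndarray:
    """Per-axis block-difference jerk in m/s^3.

    Raw acceleration is summed over consecutive ``interval_s`` blocks;
    successive differences of those block sums, divided by ``interval_s``,
    estimate the change of acceleration per unit time.  The differences are
    averaged as absolute values by default ("absolute" mode) because a
    signed mean cancels to ~0 whenever the movement reverses.
    """
    block = _block_length(clean, interval_s)
    n = clean.accel.shape[0]
    n_blocks = n // block
    if n_blocks < 2:
        raise ValueError("trace must span at least 2 complete intervals")
    a = clean.accel[: n_blocks * block]
    block_sums = a.reshape(n_blocks, block, 3).sum(axis=1)
    diffs = np.diff(block_sums, axis=0) / interval_s
    if mode == "absolute":
        return np.abs(diffs).mean(axis=0)
    if mode == "signed":
        return diffs.mean(axis=0)
    raise ValueError("mode must be 'absolute' or 'signed'")


def count_hesitations(clean: CleanStream, config: FeatureConfig | None = None) -> int:
    """Number of stop-and-go events in the response movement.

    The gravity-removed acceleration magnitude is smoothed with the
    100-sample moving window; prominence-gated troughs whose smoothed
    value falls below ``stop_frac`` of the trace's 95th percentile are
    counted as hesitations.
    """
    config = config or FeatureConfig()
    mag = accel_magnitude(clean.accel)
    smoothed = moving_window_smooth(mag, window=config.smooth_window)
    events = detect_peaks(smoothed, prominence_frac=config.prominence_frac)
    stop_level = config.stop_frac * np.percentile(smoothed, 95)
    return sum(
        1 for ev in events if ev.kind == "trough" and ev.value < stop_level
    )


def feature_names(config: FeatureConfig | None = None) -> list[str]:
    """Fixed column order of the 27-entry feature vector."""
    config = config or FeatureConfig()
    names = ["end_error", "total_angular_displacement"]
    names += [f"tilt_{ax}" for ax in AXES]
    names += [
        f"roc_{ax}_{t}" for ax in AXES for t in config.intervals_s
    ]
    names += [f"accel_{ax}" for ax in AXES]
    names += [
        f"jerk_{ax}_{t}" for ax in AXES for t in config.intervals_s
    ]
    names += ["hesitations"]
    return names


def extract_features(
    clean: CleanStream,
    reference: ReferencePoint,
    config: FeatureConfig | None = None,
) -> pd.Series:
    """Assemble the full 27-entry feature vector for one trial response."""
    config = config or FeatureConfig()
    values: dict[str, float] = {
        "end_error": end_error(clean, reference),
        "total_angular_displacement": total_angular_displacement(clean),
    }
    tilt = tilt_max(clean)
    for i, ax in enumerate(AXES):
        values[f"tilt_{ax}"] = float(tilt[i])
    for t in config.intervals_s:
        roc = gyro_rate_of_change(clean, t)
        for i, ax in enumerate(AXES):
            values[f"roc_{ax}_{t}"] = float(roc[i])
    acc = average_acceleration(clean)
    for i, ax in enumerate(AXES):
        values[f"accel_{ax}"] = float(acc[i])
    for t in config.intervals_s:
        jerk = average_jerk(clean, t, mode=config.jerk_mode)
        for i, ax in enumerate(AXES):
            values[f"jerk_{ax}_{t}"] = float(jerk[i])
    values["hesitations"] = float(count_hesitations(clean, config))
    return pd.Series(values, index=feature_names(config), dtype=float)


def cohort_feature_tables(
    sessions: Sequence[Session],
    labels: Sequence[str],
    config: FeatureConfig | None = None,
    include_demographics: bool = True,
) -> dict[int, pd.DataFrame]:
    """Preprocess and extract features for a whole cohort.

    Returns one DataFrame per trial (keyed by trial id): one row per
    participant with the 27 movement features, optionally the demographics
    (age, sex, occupation), and the group label.
    """
    config = config or FeatureConfig()
    rows_by_trial: dict[int, list] = {}
    for session, label in zip(sessions, labels):
        for stream in session.streams:
            trial_id = int(stream.truth.get("trial_id"))
            clean = preprocess_stream(stream)
            row = extract_features(clean, session.reference, config).to_dict()
            row["participant_id"] = session.profile.participant_id
            if include_demographics:
                row["age"] = session.profile.age
                row["sex"] = session.profile.sex
                row["occupation"] = session.profile.occupation
            row["label"] = label
            rows_by_trial.setdefault(trial_id, []).append(row)
    tables = {}
    for trial_id, rows in sorted(rows_by_trial.items()):
        df = pd.DataFrame(rows).set_index("participant_id")
        tables[trial_id] = df
    return tables


def correlation_filter(
    df: pd.DataFrame, threshold: float = 0.95, columns: Sequence[str] | None = None
) -> list[str]:
    """Naive pairwise-correlation feature filter.

    Returns the columns to KEEP: of any pair of numeric feature columns
    with absolute Pearson correlation above ``threshold``, the
    later-ordered one is dropped.  Disabled by default in the pipeline.
    """
    cols = list(columns) if columns is not None else [
        c for c in df.columns if df[c].dtype.kind in "fi" and c != "label"
    ]
    corr = df[cols].corr().abs()
    drop: set[str] = set()
    for i, ci in enumerate(cols):
        if ci in drop:
            continue
        for cj in cols[i + 1 :]:
            if cj in drop:
                continue
            r = corr.loc[ci, cj]
            if np.isfinite(r) and r > threshold:
                drop.add(cj)
    return [c for c in cols if c not in drop]
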