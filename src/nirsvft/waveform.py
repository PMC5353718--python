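"""Frontal-region waveform features: integral and centroid.

The analysis pipeline for one recording is

1. **QC** — drop cluster channels with large step/spike discontinuities
   (jump detector on first differences) or zero variance (dead channel).
2. **Baseline correction** — per channel, subtract the line through the
   pre-task mean and the late-post-task mean (or the pre-task mean alone).
3. **ROI averaging** — unweighted mean of the surviving frontal channels.
4. **Features** — the *integral* (signed trapezoidal area of the averaged
   signal over the 60 s task window, signal-unit x s) indexes activation
   intensity; the *centroid* (time after task onset at which the cumulative
   positive signal area over task + post-task reaches half its total)
   indexes activation timing.

A subject with fewer than 6 of the 11 cluster channels surviving QC is
excluded from all further analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
import pandas as pd

from .config import WaveformConfig
from .synthgen import Recording

__all__ = [
    "FrontalWaveform",
    "FeatureRow",
    "detect_bad_channels",
    "baseline_correct",
    "cluster_frontal",
    "compute_integral",
    "compute_centroid",
    "extract_features",
    "extract_cohort_features",
    "features_frame",
]


@dataclass
class FrontalWaveform:
    """ROI-averaged, baseline-corrected signal over the full measurement."""

    subject_id: str
    sampling_interval_s: float
    signal: np.ndarray | None           # None when no valid channels remain
    n_valid_channels: int
    task_onset_index: int
    task_offset_index: int


@dataclass
class FeatureRow:
    subject_id: str
    integral_value: float               # signal-unit x s; NaN when excluded
    centroid_value_s: float             # s after task onset; NaN when undefined
    n_valid_channels: int
    qc_pass: bool
    exclusion_reason: str | None = None


def detect_bad_channels(
    recording: Recording,
    cluster: Sequence[int],
    jump_k: float = 10.0,
    jump_floor_frac: float = 0.5,
) -> set[int]:
    """Channels (1-based) in ``cluster`` failing the artifact screen.

    A channel is bad when its largest sample-to-sample jump exceeds both
    ``jump_k`` times the MAD of its first differences and
    ``jump_floor_frac`` of its robust peak-to-peak range, or when it is
    constant (dead).  With Gaussian sensor noise of SD sigma the difference
    MAD is ~0.95 sigma, so the default k=10 catches the >=10 sigma step and
    spike artifacts while the maximum clean-noise jump (~6-7 sigma) stays
    clear; the range floor keeps smooth noise-free channels -- whose
    difference MAD is vanishingly small -- from being flagged.
    """
    cluster = list(cluster)
    if not cluster:
        raise ValueError("cluster must not be empty")
    bad: set[int] = set()
    for ch in cluster:
        x = recording.channels[ch - 1]
        if float(np.ptp(x)) == 0.0:
            bad.add(ch)
            continue
        diffs = np.diff(x)
        max_jump = float(np.abs(diffs).max())
        mad = float(np.median(np.abs(diffs - np.median(diffs))))
        lo, hi = np.percentile(x, [0.5, 99.5])
        floor = jump_floor_frac * float(hi - lo)
        if max_jump > jump_k * mad and max_jump > floor:
            bad.add(ch)
    return bad


def baseline_correct(
    signal: np.ndarray,
    pre_window: tuple[int, int],
    post_window: tuple[int, int],
    mode: str = "prepost",
) -> np.ndarray:
    """Remove slow drift relative to the rest periods.

    ``prepost`` subtracts the straight line through (centre of pre-task
    window, pre-task mean) and (centre of late post-task window, its mean),
    so a pure linear drift maps to zero; ``pre`` subtracts the pre-task mean
    only.  Windows are half-open sample-index ranges, each >= 2 samples.
    """
    signal = np.asarray(signal, dtype=float)
    for name, (a, b) in (("pre_window", pre_window), ("post_window", post_window)):
        if b - a < 2:
            raise ValueError(f"{name} must span at least 2 samples, got [{a}, {b})")
    pre_mean = signal[pre_window[0]:pre_window[1]].mean()
    if mode == "pre":
        return signal - pre_mean
    post_mean = signal[post_window[0]:post_window[1]].mean()
    c_pre = (pre_window[0] + pre_window[1] - 1) / 2.0
    c_post = (post_window[0] + post_window[1] - 1) / 2.0
    slope = (post_mean - pre_mean) / (c_post - c_pre)
    idx = np.arange(signal.size)
    return signal - (pre_mean + slope * (idx - c_pre))


def _windows(recording: Recording) -> tuple[tuple[int, int], tuple[int, int], int, int]:
    dt = recording.sampling_interval_s
    onset = int(round(recording.task_onset_s / dt))
    offset = int(round(recording.task_offset_s / dt))
    n = recording.n_samples
    post_late = max(offset + 1, n - int(round(5.0 / dt)))
    return (0, onset), (post_late, n), onset, offset


def cluster_frontal(
    recording: Recording,
    cluster: Sequence[int],
    bad: set[int] = frozenset(),
    config: WaveformConfig | None = None,
) -> FrontalWaveform:
    """Average the baseline-corrected surviving cluster channels into one ROI
    signal.  An empty surviving set yields a QC-failure waveform (signal
    None, 0 valid channels) rather than an exception."""
    config = config or WaveformConfig()
    good = [ch for ch in cluster if ch not in bad]
    pre_w, post_w, onset, offset = _windows(recording)
    if not good:
        return FrontalWaveform(recording.subject_id,
                               recording.sampling_interval_s,
                               None, 0, onset, offset)
    corrected = np.stack([
        baseline_correct(recording.channels[ch - 1], pre_w, post_w,
                         mode=config.baseline_mode)
        for ch in good])
    signal = corrected.mean(axis=0)
    if config.smooth_window > 1:
        k = np.ones(config.smooth_window) / config.smooth_window
        signal = np.convolve(signal, k, mode="same")
    return FrontalWaveform(recording.subject_id,
                           recording.sampling_interval_s,
                           signal, len(good), onset, offset)


def compute_integral(w: FrontalWaveform) -> float:
    """Signed trapezoidal area of the ROI signal over the task window."""
    y = w.signal[w.task_onset_index:w.task_offset_index + 1]
    return float(np.trapezoid(y, dx=w.sampling_interval_s))


def compute_centroid(w: FrontalWaveform) -> float:
    """Half-area crossing time of the positive signal, s after task onset.

    Only positive signal values over [task onset, end of measurement] count.
    The crossing is located in the bracketing sample panel by inverting the
    trapezoid rule exactly (the cumulative area is quadratic in time when
    the signal is linear within a panel), taking the earliest crossing on an
    exact tie.  Returns NaN when the total positive area is zero (undefined
    centroid).
    """
    dt = w.sampling_interval_s
    y = np.clip(w.signal[w.task_onset_index:], 0.0, None)
    cum = cumulative_trapezoid(y, dx=dt, initial=0.0)
    total = cum[-1]
    if total <= 0.0:
        return float("nan")
    half = total / 2.0
    j = int(np.searchsorted(cum, half, side="left"))
    if j == 0:
        return 0.0
    # remaining area inside the panel [j-1, j]: rem = y0*tau + s*tau^2/2
    rem = half - cum[j - 1]
    y0, y1 = y[j - 1], y[j]
    slope = (y1 - y0) / dt
    if rem <= 0.0:
        tau = 0.0
    elif abs(slope) * dt < 1e-12 * max(y0, 1.0):
        tau = rem / y0 if y0 > 0 else dt
    else:
        disc = y0 * y0 + 2.0 * slope * rem
        tau = (math.sqrt(max(disc, 0.0)) - y0) / slope
    tau = min(max(tau, 0.0), dt)
    return float((j - 1) * dt + tau)


def extract_features(
    recording: Recording,
    cluster: Sequence[int] | None = None,
    config: WaveformConfig | None = None,
) -> FeatureRow:
    """QC -> baseline -> ROI average -> integral/centroid for one recording.

    Subjects with fewer than ``min_valid_channels`` surviving channels are
    excluded (reason ``insufficient_channels``); an undefined centroid is
    flagged (reason ``undefined_centroid``) but does not fail QC.
    """
    config = config or WaveformConfig()
    cluster = tuple(cluster) if cluster is not None else config.cluster
    bad = detect_bad_channels(recording, cluster,
                              jump_k=config.jump_k,
                              jump_floor_frac=config.jump_floor_frac)
    w = cluster_frontal(recording, cluster, bad, config)
    if w.n_valid_channels < config.min_valid_channels:
        return FeatureRow(recording.subject_id, float("nan"), float("nan"),
                          w.n_valid_channels, qc_pass=False,
                          exclusion_reason="insufficient_channels")
    integral = compute_integral(w)
    centroid = compute_centroid(w)
    reason = "undefined_centroid" if np.isnan(centroid) else None
    return FeatureRow(recording.subject_id, integral, centroid,
                      w.n_valid_channels, qc_pass=True,
                      exclusion_reason=reason)


def extract_cohort_features(
    recordings: Iterable[Recording],
    cluster: Sequence[int] | None = None,
    config: WaveformConfig | None = None,
) -> pd.DataFrame:
    return features_frame(
        extract_features(r, cluster, config) for r in recordings)


def features_frame(rows: Iterable[FeatureRow]) -> pd.DataFrame:
    frame = pd.DataFrame([r.__dict__ for r in rows])
    if frame.empty:
        frame = pd.DataFrame(columns=[
            "subject_id", "integral_value", "centroid_value_s",
            "n_valid_channels", "qc_pass", "exclusion_reason"])
    return frame
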