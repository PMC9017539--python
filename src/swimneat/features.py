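"""Sliding-window time-domain features for 6-axis inertial signals.

Only time-domain statistics are computed — they cost O(n) per window and
carry enough information to separate cyclic whole-body activities, whereas
frequency-domain and wavelet features need transforms costing at least
O(n log n). Two window-geometry features complement the classical moments:
the peak-to-valley distance (sample separation of a window's maximum and
minimum) and the peak-to-peak distance (separation between the maxima of
consecutive windows), which capture intra-cycle shape and cycle period
respectively.

Conventions (fixed so downstream tests are exact):
  * variance is the population variance (divide by n);
  * skewness and kurtosis are moment-based, kurtosis is excess kurtosis;
  * quartiles use linear interpolation between order statistics;
  * a zero-variance channel reports skewness, kurtosis and any correlation
    involving it as 0, and the channel is flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import IMUSignal, CHANNELS

__all__ = [
    "TimeWindow",
    "FeatureVector",
    "window_stream",
    "extract_basic",
    "peak_to_valley_distance",
    "peak_to_peak_distance",
    "feature_table",
    "DEFAULT_CORRELATION_PAIRS",
]

# acceleration-axis pairs and gyro-axis pairs
DEFAULT_CORRELATION_PAIRS: tuple[tuple[str, str], ...] = (
    ("acc_x", "acc_y"), ("acc_x", "acc_z"), ("acc_y", "acc_z"),
    ("gyro_x", "gyro_y"), ("gyro_x", "gyro_z"), ("gyro_y", "gyro_z"),
)

_VAR_EPS = 1e-12


@dataclass
class TimeWindow:
    """A fixed-length slice of a 6-axis signal."""

    samples: np.ndarray          # (n_samples, n_channels)
    sample_rate: float
    start_index: int = 0
    label: str | None = None
    channel_names: tuple[str, ...] = CHANNELS

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("window samples must be 2-D (samples x channels)")
        if len(self.samples) < 4:
            raise ValueError("windows need >= 4 samples (kurtosis undefined below)")

    def __len__(self) -> int:
        return len(self.samples)

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]


@dataclass
class FeatureVector:
    """Named features for one window, plus degenerate-channel flags."""

    values: dict[str, float]
    degenerate_channels: tuple[str, ...] = ()
    label: str | None = None


def window_stream(signal: IMUSignal, window_seconds: float,
                  overlap_fraction: float = 0.5) -> Iterator[TimeWindow]:
    """Slice a signal into fixed-length windows with the given overlap.

    The trailing partial window is dropped. A window longer than the signal
    yields an empty sequence. Window labels are the majority per-sample
    label inside the window (when the signal is annotated).
    """
    if not (0 <= overlap_fraction < 1):
        raise ValueError("overlap_fraction must be in [0, 1)")
    n_win = int(round(window_seconds * signal.sample_rate))
    if n_win < 4:
        raise ValueError("window too short: need >= 4 samples")
    step = max(1, int(round(n_win * (1 - overlap_fraction))))
    n = len(signal.samples)
    start = 0
    while start + n_win <= n:
        label = None
        if signal.labels is not None:
            seg = signal.labels[start:start + n_win]
            uniq, counts = np.unique(seg, return_counts=True)
            label = str(uniq[np.argmax(counts)])
        yield TimeWindow(signal.samples[start:start + n_win], signal.sample_rate,
                         start_index=start, label=label,
                         channel_names=signal.channel_names)
        start += step


def extract_basic(w: TimeWindow,
                  correlation_pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
                  ) -> FeatureVector:
    """Per-channel moments, quartiles and peak-to-valley distance, plus
    Pearson correlations for the configured channel pairs."""
    values: dict[str, float] = {}
    degenerate: list[str] = []
    variances: dict[str, float] = {}
    for name in w.channel_names:
        x = w.channel(name)
        var = float(np.var(x))
        variances[name] = var
        values[f"{name}_mean"] = float(np.mean(x))
        values[f"{name}_variance"] = var
        if var < _VAR_EPS:
            degenerate.append(name)
            values[f"{name}_skewness"] = 0.0
            values[f"{name}_kurtosis"] = 0.0
        else:
            values[f"{name}_skewness"] = float(stats.skew(x, bias=True))
            values[f"{name}_kurtosis"] = float(stats.kurtosis(x, fisher=True, bias=True))
        q1, q3 = np.percentile(x, [25, 75])
        values[f"{name}_first_quartile"] = float(q1)
        values[f"{name}_quartile_difference"] = float(q3 - q1)
        values[f"{name}_peak_to_valley"] = float(peak_to_valley_distance(w, name))
    for a, b in correlation_pairs:
        key = f"corr_{a}_{b}"
        if variances[a] < _VAR_EPS or variances[b] < _VAR_EPS:
            values[key] = 0.0
        else:
            values[key] = float(np.corrcoef(w.channel(a), w.channel(b))[0, 1])
    return FeatureVector(values=values, degenerate_channels=tuple(degenerate),
                         label=w.label)


def peak_to_valley_distance(w: TimeWindow, channel: str) -> int:
    """Sample distance between the window's maximum and minimum.

    First occurrence wins under ties; a constant channel reports 0.
    """
    x = w.channel(channel)
    if np.ptp(x) == 0:
        return 0
    return int(abs(int(np.argmax(x)) - int(np.argmin(x))))


def peak_to_peak_distance(current: TimeWindow, previous: TimeWindow,
                          channel: str) -> int:
    """Global sample distance between consecutive windows' maxima.

    Captures the stroke period when windows tile the signal: a signal
    periodic at exactly one window length yields the window length.
    """
    if previous.start_index >= current.start_index:
        raise ValueError("previous window must precede the current window")
    peak_prev = previous.start_index + int(np.argmax(previous.channel(channel)))
    peak_cur = current.start_index + int(np.argmax(current.channel(channel)))
    return int(abs(peak_cur - peak_prev))


def feature_table(signal: IMUSignal, window_seconds: float = 2.0,
                  overlap_fraction: float = 0.5,
                  correlation_pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
                  ) -> pd.DataFrame:
    """Full feature table: one row per window.

    Adds the peak-to-peak distance per channel; the first window (which has
    no predecessor) records the sentinel value of one window length, and a
    boolean ``p2p_sentinel`` column marks such rows.
    """
    rows = []
    prev: TimeWindow | None = None
    for w in window_stream(signal, window_seconds, overlap_fraction):
        fv = extract_basic(w, correlation_pairs)
        row = dict(fv.values)
        for name in w.channel_names:
            if prev is None:
                row[f"{name}_peak_to_peak"] = float(len(w))
            else:
                row[f"{name}_peak_to_peak"] = float(
                    peak_to_peak_distance(w, prev, name))
        row["p2p_sentinel"] = prev is None
        row["start_index"] = w.start_index
        if fv.label is not None:
            row["label"] = fv.label
        rows.append(row)
        prev = w
    return pd.DataFrame(rows)
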