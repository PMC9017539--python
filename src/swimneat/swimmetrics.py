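"""Swim analytics: stroke recognition, roll-angle metrics, fatigue, asymmetry.

The body-roll angle about the swimmer's central (X) axis is obtained by
integrating the Y-axis gyroscope and removing the slow integration drift.
Zero crossings of the de-drifted angle delimit alternating left/right
half-cycles, whose mean durations TL and TR, extreme angles, sliding
variance (a fatigue proxy: a tiring swimmer holds the rhythm but loses
motion-control precision, inflating the cycle-to-cycle angle spread) and
left/right differences (an asymmetry screen for unilateral injury or
imbalance) summarize the swim.

Stroke recognition comes in two flavours: a transparent rule cascade
reading the axis signatures directly, and an evolved-network classifier
over windowed time-domain features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .evolve import EvolutionConfig, EvolutionResult, evolve_until
from .features import feature_table
from .genome import Genome
from .io import IMUSignal
from .network import activate_batch, build_phenotype
from .synth import StrokeParams, dominant_frequency, generate_stroke, STROKES

__all__ = [
    "SwimMetrics",
    "StrokeRuleThresholds",
    "rotation_angle",
    "segment_periods",
    "fatigue_index",
    "asymmetry_indices",
    "classify_stroke_rules",
    "classify_stroke_neat",
    "compute_swim_metrics",
    "stroke_feature_table",
    "StrokeClassifier",
]


@dataclass
class SwimMetrics:
    """Session-level roll-angle analytics. NaN marks an undefined metric."""

    rotation_angle: np.ndarray
    TL: float
    TR: float
    angle_max: float
    angle_min: float
    fatigue_variance: float
    asymmetry_angle: float
    asymmetry_period: float
    cycles: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class StrokeRuleThresholds:
    """Cutoffs for the rule cascade; amplitudes are 95th-percentile |value|."""

    z_sign_margin: float = 0.3        # G0
    y_gyro_large: float = 100.0       # deg/s
    x_gyro_large: float = 150.0       # deg/s
    acc_z_amp_large: float = 2.0      # G0, amplitude about the mean
    peaks_per_cycle_cutoff: float = 1.5

    def __post_init__(self) -> None:
        if min(self.y_gyro_large, self.x_gyro_large, self.acc_z_amp_large,
               self.peaks_per_cycle_cutoff) <= 0:
            raise ValueError("rule thresholds must be positive")


def rotation_angle(gyro_y: np.ndarray, sample_rate: float,
                   drift_window_s: float = 5.0) -> np.ndarray:
    """Integrate Y-gyro (deg/s) into a de-drifted roll angle (degrees).

    Cumulative trapezoidal integration, then subtraction of a centred
    moving average over ``drift_window_s`` so the angle oscillates about
    zero regardless of gyro bias.
    """
    gyro_y = np.asarray(gyro_y, dtype=float)
    if gyro_y.size == 0:
        raise ValueError("empty angular-velocity series")
    angle = cumulative_trapezoid(gyro_y, dx=1.0 / sample_rate, initial=0.0)
    win = max(3, int(round(drift_window_s * sample_rate)))
    win = min(win, len(angle))
    return angle - uniform_filter1d(angle, size=win, mode="nearest")


def _zero_crossings(angle: np.ndarray, sample_rate: float,
                    hysteresis: float) -> tuple[list[float], list[int]]:
    """Schmitt-trigger zero crossings with sub-sample interpolation.

    Returns crossing times and the sign entered after each crossing. Noise
    wiggles inside ±hysteresis do not count as crossings.
    """
    times: list[float] = []
    signs: list[int] = []
    state = 0
    last_cross_idx = 0
    for i, v in enumerate(angle):
        new_state = state
        if v > hysteresis:
            new_state = 1
        elif v < -hysteresis:
            new_state = -1
        if new_state != state and state != 0:
            # locate the actual sign change between the last confirmed
            # excursion and here, and interpolate the zero instant
            j = i
            while j > last_cross_idx and np.sign(angle[j - 1]) == new_state:
                j -= 1
            a0, a1 = angle[j - 1], angle[j]
            frac = a0 / (a0 - a1) if a0 != a1 else 0.5
            times.append((j - 1 + frac) / sample_rate)
            signs.append(new_state)
            last_cross_idx = j
        state = new_state if new_state != 0 else state
    return times, signs


def segment_periods(angle: np.ndarray, sample_rate: float,
                    hysteresis_fraction: float = 0.05
                    ) -> tuple[float, float, pd.DataFrame]:
    """Mean left (TL) and right (TR) half-cycle durations from zero crossings.

    The angle must already be de-drifted. Hysteresis is the given fraction
    of the interquartile range; incomplete edge half-cycles are discarded.
    With fewer than 2 crossings, TL and TR are NaN.
    """
    angle = np.asarray(angle, dtype=float)
    iqr = float(np.subtract(*np.percentile(angle, [75, 25])))
    hyst = hysteresis_fraction * iqr
    empty = pd.DataFrame(columns=["side", "start", "duration", "peak_angle"])
    if iqr == 0:
        return math.nan, math.nan, empty
    times, signs = _zero_crossings(angle, sample_rate, hyst)
    if len(times) < 2:
        return math.nan, math.nan, empty
    rows = []
    for t0, t1, sign_after in zip(times[:-1], times[1:], signs[:-1]):
        i0, i1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
        seg = angle[i0:i1 + 1]
        if seg.size == 0:
            continue
        side = "left" if sign_after > 0 else "right"
        peak = float(seg.max() if sign_after > 0 else seg.min())
        rows.append({"side": side, "start": t0, "duration": t1 - t0,
                     "peak_angle": peak})
    table = pd.DataFrame(rows)
    if table.empty:
        return math.nan, math.nan, empty
    left = table.loc[table["side"] == "left", "duration"]
    right = table.loc[table["side"] == "right", "duration"]
    TL = float(left.mean()) if len(left) else math.nan
    TR = float(right.mean()) if len(right) else math.nan
    return TL, TR, table


def fatigue_index(angle: np.ndarray, horizon_s: float,
                  sample_rate: float) -> np.ndarray:
    """Sliding variance of the per-half-cycle peak roll angle.

    One value per window position (windows advance one half-cycle at a
    time); larger values mean less repeatable strokes, the fatigue proxy.
    """
    n = len(angle)
    if horizon_s >= n / sample_rate:
        raise ValueError("horizon must be shorter than the series")
    _, _, table = segment_periods(np.asarray(angle, dtype=float), sample_rate)
    if table.empty:
        return np.zeros(0)
    t = table["start"].to_numpy()
    peaks = np.abs(table["peak_angle"].to_numpy())
    out = []
    for t0 in t:
        if t0 + horizon_s > t[-1]:
            break
        mask = (t >= t0) & (t <= t0 + horizon_s)
        if mask.sum() >= 2:
            out.append(float(np.var(peaks[mask])))
    return np.asarray(out)


def asymmetry_indices(cycles: pd.DataFrame) -> tuple[float, float]:
    """Left/right differences: (asymmetry_angle, asymmetry_period).

    asymmetry_angle = |mean left peak − mean |right trough||, in degrees;
    asymmetry_period = |TL − TR|, in seconds. NaN when a side is missing.
    """
    left = cycles[cycles["side"] == "left"]
    right = cycles[cycles["side"] == "right"]
    if left.empty or right.empty:
        return math.nan, math.nan
    mean_left = float(left["peak_angle"].mean())
    mean_right = float(np.abs(right["peak_angle"]).mean())
    d_angle = abs(mean_left - mean_right)
    d_period = abs(float(left["duration"].mean()) - float(right["duration"].mean()))
    return d_angle, d_period


def compute_swim_metrics(signal: IMUSignal, drift_window_s: float = 5.0,
                         fatigue_horizon_s: float = 10.0) -> SwimMetrics:
    """Full roll-angle analytics for one signal."""
    angle = rotation_angle(signal.channel("gyro_y"), signal.sample_rate,
                           drift_window_s)
    TL, TR, cycles = segment_periods(angle, signal.sample_rate)
    if cycles.empty:
        return SwimMetrics(angle, TL, TR, float(np.max(angle)),
                           float(np.min(angle)), math.nan, math.nan, math.nan,
                           cycles)
    horizon = min(fatigue_horizon_s, 0.5 * len(angle) / signal.sample_rate)
    fat = fatigue_index(angle, horizon, signal.sample_rate)
    d_angle, d_period = asymmetry_indices(cycles)
    return SwimMetrics(
        rotation_angle=angle, TL=TL, TR=TR,
        angle_max=float(np.max(angle)), angle_min=float(np.min(angle)),
        fatigue_variance=float(np.mean(fat)) if fat.size else math.nan,
        asymmetry_angle=d_angle, asymmetry_period=d_period, cycles=cycles)


def _amplitude(x: np.ndarray) -> float:
    """95th percentile of |x|: a noise-robust amplitude measure."""
    return float(np.percentile(np.abs(x), 95))


def _peaks_per_cycle(x: np.ndarray, sample_rate: float) -> float:
    """Significant local maxima per stroke cycle of a cyclic channel."""
    f = dominant_frequency(x, sample_rate)
    if f <= 0:
        return 0.0
    n_cycles = len(x) / sample_rate * f
    prominence = 0.3 * _amplitude(x)
    peaks, _ = find_peaks(x, prominence=prominence)
    return len(peaks) / n_cycles


def classify_stroke_rules(signal: IMUSignal,
                          thresholds: StrokeRuleThresholds | None = None
                          ) -> str:
    """Rule cascade over the axis signatures.

    mean Z-acc below −margin → backstroke; else large Y-gyro → freestyle;
    else large X-gyro with large Z-acc amplitude → butterfly (two maxima
    per X-gyro cycle) or breaststroke (one); anything else → 'unknown'.
    """
    th = thresholds or StrokeRuleThresholds()
    acc_z = signal.channel("acc_z")
    if float(np.mean(acc_z)) < -th.z_sign_margin:
        return "backstroke"
    if _amplitude(signal.channel("gyro_y")) >= th.y_gyro_large:
        return "freestyle"
    gyro_x = signal.channel("gyro_x")
    z_amp = _amplitude(acc_z - acc_z.mean())
    if _amplitude(gyro_x) >= th.x_gyro_large and z_amp >= th.acc_z_amp_large:
        ppc = _peaks_per_cycle(gyro_x, signal.sample_rate)
        return "butterfly" if ppc >= th.peaks_per_cycle_cutoff else "breaststroke"
    return "unknown"


# ---------------------------------------------------------------------------
# evolved-network stroke classification over feature vectors
# ---------------------------------------------------------------------------

@dataclass
class StrokeClassifier:
    genome: Genome
    classes: list[str]
    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    holdout_accuracy: float
    confusion: pd.DataFrame
    evolution: EvolutionResult

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = (features[self.feature_names].to_numpy(dtype=float) - self.mean) / self.std
        p = build_phenotype(self.genome)
        scores = activate_batch(p, X)
        return np.asarray(self.classes)[np.argmax(scores, axis=1)]


def stroke_feature_table(n_windows_per_class: int = 200, seed: int = 0,
                         intensity: str = "medium", sample_rate: float = 50.0,
                         window_seconds: float = 2.0,
                         overlap_fraction: float = 0.5) -> pd.DataFrame:
    """Labelled 4-class feature table from the default synthetic strokes.

    One extra window per class absorbs the first-window peak-to-peak
    sentinel, which is then dropped.
    """
    step_s = window_seconds * (1 - overlap_fraction)
    duration = (n_windows_per_class + 1) * step_s + window_seconds
    children = np.random.SeedSequence(seed).spawn(len(STROKES))
    frames = []
    for stroke, child in zip(STROKES, children):
        sig = generate_stroke(StrokeParams(stroke, intensity=intensity),
                              duration, sample_rate,
                              np.random.default_rng(child))
        tab = feature_table(sig, window_seconds, overlap_fraction)
        tab = tab[~tab["p2p_sentinel"]].head(n_windows_per_class)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


def classify_stroke_neat(features: pd.DataFrame,
                         config: EvolutionConfig | None = None,
                         test_fraction: float = 0.25) -> StrokeClassifier:
    """Evolve a stroke classifier over a labelled feature table.

    One network output per class, argmax decision; fitness is training
    accuracy. The split is stratified and, like the evolution itself,
    fully determined by ``config.seed``.
    """
    if "label" not in features.columns:
        raise ValueError("feature table needs a 'label' column")
    classes = sorted(features["label"].unique())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to classify")
    feature_names = [c for c in features.columns
                     if c not in ("label", "start_index", "p2p_sentinel")]
    config = config or EvolutionConfig(population_size=96, max_generations=120,
                                       fitness_threshold=0.97, seed=0)
    config = replace(config, n_inputs=len(feature_names), n_outputs=len(classes))

    rng = np.random.default_rng(config.seed)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = features.index[features["label"] == cls].to_numpy()
        idx = idx[rng.permutation(len(idx))]
        n_test = max(1, int(round(test_fraction * len(idx))))
        test_idx.extend(idx[:n_test])
        train_idx.extend(idx[n_test:])
    train = features.loc[sorted(train_idx)]
    test = features.loc[sorted(test_idx)]

    X_train = train[feature_names].to_numpy(dtype=float)
    mean = X_train.mean(axis=0)
    std = X_train.std(axis=0)
    std[std == 0] = 1.0
    X_train = (X_train - mean) / std
    y_train = np.array([classes.index(v) for v in train["label"]])
    X_test = (test[feature_names].to_numpy(dtype=float) - mean) / std
    y_test = np.array([classes.index(v) for v in test["label"]])

    def evaluate(genome: Genome) -> float:
        p = build_phenotype(genome)
        pred = np.argmax(activate_batch(p, X_train), axis=1)
        return float(np.mean(pred == y_train))

    result = evolve_until(config, evaluate)
    p = build_phenotype(result.best_genome)
    pred = np.argmax(activate_batch(p, X_test), axis=1)
    accuracy = float(np.mean(pred == y_test))
    confusion = pd.crosstab(
        pd.Series(np.asarray(classes)[y_test], name="true"),
        pd.Series(np.asarray(classes)[pred], name="predicted"),
        dropna=False).reindex(index=classes, columns=classes, fill_value=0)
    return StrokeClassifier(genome=result.best_genome, classes=classes,
                            feature_names=feature_names, mean=mean, std=std,
                            holdout_accuracy=accuracy, confusion=confusion,
                            evolution=result)
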