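"""Seeded synthetic 6-axis swim-signal generator.

No public recordings exist for waist-worn swim IMU data with the axis
convention used here (X along the body's central axis, Y left-right,
Z up-down), so every downstream stage is exercised on synthetic signals
built from the four strokes' qualitative signatures:

  * backstroke — the swimmer faces up, so the Z-axis acceleration is
    negative on average; body roll about the central axis makes the Y-axis
    gyro large;
  * freestyle — face down (mean Z-acc positive), Y-gyro large from roll;
  * butterfly and breaststroke — motion lives in the XZ plane: X-gyro and
    Z-acc amplitudes are large and Y-gyro is small; the two are told apart
    by the X-gyro cycle shape (butterfly's dolphin kick gives a two-lobed
    pulse per cycle, breaststroke a single smooth pulse).

Intensity raises the stroke frequency and the X-axis acceleration
amplitude. All channels respect the physical envelope of the hardware:
|acc| <= 15 G0 per axis, |gyro| <= 1500 deg/s per axis, stroke frequency
below 2 Hz. Signals are fully reproducible from their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CHANNELS, IMUSignal

__all__ = [
    "STROKES",
    "ROLLING_STROKES",
    "INTENSITIES",
    "ACC_BOUND",
    "GYRO_BOUND",
    "MAX_STROKE_FREQUENCY",
    "StrokeParams",
    "generate_stroke",
    "generate_session",
    "rotation_asymmetry_profile",
    "dominant_frequency",
]

STROKES: tuple[str, ...] = ("butterfly", "backstroke", "breaststroke", "freestyle")
ROLLING_STROKES: tuple[str, ...] = ("backstroke", "freestyle")
INTENSITIES: tuple[str, ...] = ("low", "medium", "high")

ACC_BOUND = 15.0          # G0 per axis
GYRO_BOUND = 1500.0       # deg/s per axis
MAX_STROKE_FREQUENCY = 2.0  # Hz

# intensity -> (stroke frequency Hz, X-acc amplitude scale)
INTENSITY_FREQUENCY = {"low": 0.5, "medium": 1.0, "high": 1.5}
INTENSITY_XACC_SCALE = {"low": 1.0, "medium": 1.5, "high": 2.0}

# per-stroke Z-acc baseline (G0): only backstroke is negative
_ACC_Z_BASELINE = {"butterfly": 0.6, "backstroke": -1.0,
                   "breaststroke": 0.6, "freestyle": 1.0}
# per-stroke Z-acc oscillation amplitude (G0): large for the XZ-plane strokes
_ACC_Z_AMP = {"butterfly": 5.0, "backstroke": 1.2,
              "breaststroke": 4.0, "freestyle": 1.2}
# per-stroke X-gyro amplitude (deg/s): large for the XZ-plane strokes
_GYRO_X_AMP = {"butterfly": 300.0, "backstroke": 25.0,
               "breaststroke": 300.0, "freestyle": 25.0}
# Y-gyro amplitude for the non-rolling strokes (deg/s, small); the rolling
# strokes derive Y-gyro from the roll-angle trajectory instead
_GYRO_Y_SMALL = 30.0


@dataclass
class StrokeParams:
    """One stroke segment's generating parameters.

    ``asymmetry`` scales the left roll amplitude by (1 + a) and the right by
    (1 − a). ``fatigue_drift`` is the fractional standard deviation that the
    per-cycle roll-angle targets reach by the end of the segment (the
    cycle-to-cycle jitter grows linearly with time from 0 to this value).
    """

    stroke: str
    intensity: str = "medium"
    stroke_frequency: float | None = None   # Hz; default set by intensity
    roll_amplitude_deg: float = 45.0        # roll target for rolling strokes
    acc_x_amp: float = 2.0                  # G0, before the intensity scale
    acc_y_amp: float = 0.8                  # G0
    asymmetry: float = 0.0
    fatigue_drift: float = 0.0
    noise_sd_acc: float = 0.15              # G0 per channel
    noise_sd_gyro: float = 8.0              # deg/s per channel

    def __post_init__(self) -> None:
        if self.stroke not in STROKES:
            raise ValueError(f"unknown stroke {self.stroke!r}; one of {STROKES}")
        if self.intensity not in INTENSITIES:
            raise ValueError(f"unknown intensity {self.intensity!r}")
        if self.asymmetry < 0 or self.fatigue_drift < 0:
            raise ValueError("asymmetry and fatigue_drift must be >= 0")

    @property
    def frequency(self) -> float:
        f = (self.stroke_frequency if self.stroke_frequency is not None
             else INTENSITY_FREQUENCY[self.intensity])
        if not (0 < f < MAX_STROKE_FREQUENCY):
            raise ValueError(
                f"stroke frequency must lie in (0, {MAX_STROKE_FREQUENCY}) Hz")
        return f

    @property
    def xacc_scale(self) -> float:
        return INTENSITY_XACC_SCALE[self.intensity]

    def validate_bounds(self) -> None:
        """Reject parameter sets whose *nominal* signal leaves the envelope.

        Noise tails are clipped at generation time; clipping is not allowed
        to mask an out-of-range deterministic waveform.
        """
        f = self.frequency
        acc_x_nominal = self.acc_x_amp * self.xacc_scale
        acc_z_nominal = abs(_ACC_Z_BASELINE[self.stroke]) + _ACC_Z_AMP[self.stroke]
        if max(acc_x_nominal, self.acc_y_amp, acc_z_nominal) > ACC_BOUND:
            raise ValueError("nominal acceleration amplitude exceeds "
                             f"{ACC_BOUND} G0")
        if self.stroke in ROLLING_STROKES:
            worst_angle = (self.roll_amplitude_deg * (1 + self.asymmetry)
                           * (1 + 4 * self.fatigue_drift))
            gyro_y_nominal = worst_angle * math.pi * 2 * f
        else:
            gyro_y_nominal = _GYRO_Y_SMALL
        if max(_GYRO_X_AMP[self.stroke], gyro_y_nominal) > GYRO_BOUND:
            raise ValueError("nominal angular velocity exceeds "
                             f"{GYRO_BOUND} deg/s")


def rotation_asymmetry_profile(params: StrokeParams, n_cycles: int = 50,
                               rng: np.random.Generator | int | None = None
                               ) -> pd.DataFrame:
    """Per-half-cycle roll targets and durations for a rolling stroke.

    Returns a table with one row per half-cycle: cycle index, side
    ('left'/'right'), signed target angle (degrees, left positive) and
    duration (seconds). Non-rolling strokes return an empty table. With
    asymmetry 0 and fatigue_drift 0 the profile is exactly symmetric.
    """
    if params.stroke not in ROLLING_STROKES:
        return pd.DataFrame(columns=["cycle", "side", "target_angle", "duration"])
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) \
        else rng
    half = 0.5 / params.frequency
    a = params.asymmetry
    amp_left = params.roll_amplitude_deg * (1 + a)
    amp_right = params.roll_amplitude_deg * (1 - a)
    rows = []
    for k in range(n_cycles):
        # jitter s.d. grows linearly over the session, reaching
        # fatigue_drift (as a fraction of the amplitude) on the last cycle
        sd = params.fatigue_drift * (k / max(n_cycles - 1, 1))
        jl = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        jr = float(rng.normal(0.0, sd)) if sd > 0 else 0.0
        rows.append({"cycle": k, "side": "left",
                     "target_angle": amp_left * (1 + jl), "duration": half})
        rows.append({"cycle": k, "side": "right",
                     "target_angle": -amp_right * (1 + jr), "duration": half})
    return pd.DataFrame(rows)


def _roll_gyro_trace(profile: pd.DataFrame, n_samples: int,
                     sample_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Y-gyro (deg/s) and cycle index from a half-cycle roll profile.

    Within each half-cycle of duration d and target A the roll angle follows
    A·sin(π τ / d), so the angular velocity is A·(π/d)·cos(π τ / d):
    continuous, zero-crossing exactly at the half-cycle boundaries.
    """
    gyro = np.zeros(n_samples)
    cycles = np.zeros(n_samples, dtype=int)
    t0 = 0.0
    for row in profile.itertuples(index=False):
        i0 = int(round(t0 * sample_rate))
        i1 = min(int(round((t0 + row.duration) * sample_rate)), n_samples)
        if i0 >= n_samples:
            break
        tau = np.arange(i0, i1) / sample_rate - t0
        gyro[i0:i1] = row.target_angle * (math.pi / row.duration) * \
            np.cos(math.pi * tau / row.duration)
        cycles[i0:i1] = row.cycle
        t0 += row.duration
    return gyro, cycles


def _butterfly_shape(theta: np.ndarray) -> np.ndarray:
    """Two-lobed cycle waveform: two significant maxima per period."""
    w = np.sin(theta) + 0.85 * np.sin(2 * theta - math.pi / 2)
    return w / 1.6  # normalize roughly to unit peak


def generate_stroke(params: StrokeParams, duration_s: float,
                    sample_rate: float = 50.0,
                    seed: int | np.random.Generator | None = 0) -> IMUSignal:
    """Generate one labelled stroke segment.

    The deterministic waveforms encode the stroke signature; i.i.d.
    Gaussian noise is added per channel and only its tails are clipped to
    the hardware envelope.
    """
    params.validate_bounds()
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    f = params.frequency
    theta = 2 * math.pi * f * t
    stroke = params.stroke

    acc_x = params.acc_x_amp * params.xacc_scale * np.sin(theta)
    acc_y = params.acc_y_amp * np.sin(theta + 0.5)
    if stroke == "butterfly":
        z_wave = 0.8 * np.sin(theta) + 0.25 * np.sin(2 * theta)
    else:
        z_wave = np.sin(theta)
    acc_z = _ACC_Z_BASELINE[stroke] + _ACC_Z_AMP[stroke] * z_wave

    if stroke == "butterfly":
        gyro_x = _GYRO_X_AMP[stroke] * _butterfly_shape(theta)
    elif stroke == "breaststroke":
        gyro_x = _GYRO_X_AMP[stroke] * np.sin(theta)
    else:
        gyro_x = _GYRO_X_AMP[stroke] * np.sin(theta + 1.0)

    if stroke in ROLLING_STROKES:
        n_cycles = int(math.ceil(duration_s * f)) + 1
        profile = rotation_asymmetry_profile(params, n_cycles, rng)
        gyro_y, cycle_index = _roll_gyro_trace(profile, n, sample_rate)
    else:
        gyro_y = _GYRO_Y_SMALL * np.sin(theta + 0.3)
        cycle_index = np.floor(f * t).astype(int)
    gyro_z = 20.0 * np.sin(theta + 2.0)

    samples = np.column_stack([acc_x, acc_y, acc_z, gyro_x, gyro_y, gyro_z])
    noise = np.column_stack([
        rng.normal(0.0, params.noise_sd_acc, n),
        rng.normal(0.0, params.noise_sd_acc, n),
        rng.normal(0.0, params.noise_sd_acc, n),
        rng.normal(0.0, params.noise_sd_gyro, n),
        rng.normal(0.0, params.noise_sd_gyro, n),
        rng.normal(0.0, params.noise_sd_gyro, n),
    ])
    samples += noise
    samples[:, :3] = np.clip(samples[:, :3], -ACC_BOUND, ACC_BOUND)
    samples[:, 3:] = np.clip(samples[:, 3:], -GYRO_BOUND, GYRO_BOUND)

    labels = np.full(n, stroke, dtype=object)
    return IMUSignal(samples=samples, sample_rate=sample_rate, labels=labels,
                     cycle_index=cycle_index,
                     metadata={"stroke": stroke, "intensity": params.intensity,
                               "stroke_frequency": f})


def generate_session(segments: list[tuple[StrokeParams, float]],
                     sample_rate: float = 50.0,
                     seed: int | None = 0,
                     transition_s: float = 0.2) -> IMUSignal:
    """Concatenate labelled stroke segments with short smoothed transitions.

    Total length is exactly the sum of the segment lengths; a short moving
    average straddling each boundary removes the waveform discontinuity.
    """
    if not segments:
        raise ValueError("session needs at least one segment")
    children = np.random.SeedSequence(seed).spawn(len(segments))
    parts = [generate_stroke(p, d, sample_rate, np.random.default_rng(s))
             for (p, d), s in zip(segments, children)]
    samples = np.concatenate([sig.samples for sig in parts])
    labels = np.concatenate([sig.labels for sig in parts])
    cycles = np.concatenate([sig.cycle_index for sig in parts])

    # smooth a neighbourhood of each internal boundary with a short MA
    n_t = max(2, int(round(transition_s * sample_rate)))
    kernel = np.ones(5) / 5.0
    boundary = 0
    for sig in parts[:-1]:
        boundary += len(sig)
        lo = max(0, boundary - n_t)
        hi = min(len(samples), boundary + n_t)
        for ch in range(samples.shape[1]):
            seg = np.convolve(samples[lo:hi, ch], kernel, mode="same")
            samples[lo:hi, ch] = seg
    samples[:, :3] = np.clip(samples[:, :3], -ACC_BOUND, ACC_BOUND)
    samples[:, 3:] = np.clip(samples[:, 3:], -GYRO_BOUND, GYRO_BOUND)
    return IMUSignal(samples=samples, sample_rate=sample_rate, labels=labels,
                     cycle_index=cycles,
                     metadata={"segments": [
                         {"stroke": p.stroke, "intensity": p.intensity,
                          "duration": d} for p, d in segments],
                         "seed": seed})


def dominant_frequency(x: np.ndarray, sample_rate: float) -> float:
    """Frequency (Hz) of the largest non-DC peak of the magnitude spectrum."""
    x = np.asarray(x, dtype=float)
    spectrum = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / sample_rate)
    spectrum[0] = 0.0
    return float(freqs[int(np.argmax(spectrum))])
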