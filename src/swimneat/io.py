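"""The 6-axis inertial-signal container and its CSV dialect.

The on-disk form is a plain CSV with columns ``time, acc_x, acc_y, acc_z,
gyro_x, gyro_y, gyro_z`` (acceleration in G0, one standard gravity;
angular velocity in degrees per second) plus an optional ``label`` column,
with a JSON sidecar (``<path>.json``) holding the sampling rate and any
generator metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CHANNELS", "IMUSignal", "write_imu_csv", "read_imu_csv"]

CHANNELS: tuple[str, ...] = ("acc_x", "acc_y", "acc_z",
                             "gyro_x", "gyro_y", "gyro_z")


@dataclass
class IMUSignal:
    """6-axis sampled inertial data with optional per-sample annotations."""

    samples: np.ndarray                    # (n_samples, 6)
    sample_rate: float
    labels: np.ndarray | None = None       # per-sample stroke label
    cycle_index: np.ndarray | None = None  # per-sample stroke-cycle counter
    channel_names: tuple[str, ...] = CHANNELS
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != len(self.channel_names):
            raise ValueError(
                f"samples must be (n, {len(self.channel_names)}); "
                f"got {self.samples.shape}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("signal contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]


def write_imu_csv(signal: IMUSignal, path: str | Path) -> None:
    """Write the CSV plus its JSON sidecar (``<path>.json``)."""
    path = Path(path)
    frame = pd.DataFrame(signal.samples, columns=list(signal.channel_names))
    frame.insert(0, "time", signal.time)
    if signal.labels is not None:
        frame["label"] = signal.labels
    frame.to_csv(path, index=False)
    sidecar = {"sample_rate": signal.sample_rate, **signal.metadata}
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_imu_csv(path: str | Path, sample_rate: float | None = None) -> IMUSignal:
    """Read the CSV dialect; the sampling rate comes from the sidecar
    unless given explicitly (falling back to the time column spacing)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"malformed IMU CSV {path}: {exc}") from exc
    missing = [c for c in CHANNELS if c not in frame.columns]
    if missing:
        raise ValueError(
            f"IMU CSV {path} is missing channel column(s) {missing}")
    metadata: dict = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sample_rate is None and sidecar.exists():
        with open(sidecar) as fh:
            metadata = json.load(fh)
        sample_rate = metadata.pop("sample_rate", None)
    if sample_rate is None:
        if "time" in frame.columns and len(frame) > 1:
            dt = float(np.median(np.diff(frame["time"].to_numpy())))
            sample_rate = 1.0 / dt
        else:
            raise ValueError(
                f"cannot determine sample rate for {path}: no sidecar, "
                "no usable time column")
    labels = frame["label"].to_numpy(dtype=str) if "label" in frame.columns else None
    return IMUSignal(samples=frame[list(CHANNELS)].to_numpy(dtype=float),
                     sample_rate=float(sample_rate), labels=labels,
                     metadata=metadata)
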