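"""The raw unit of analysis: a tri-axial accelerometer + gyroscope recording.

Acceleration axes follow the trunk-mounted convention used throughout the
package: mediolateral (ML), anterior-posterior (AP) and superior-inferior
(SI), in m/s^2. Gyroscope channels are roll/pitch/yaw angular velocity in
deg/s; the pitch channel (forward/backward trunk tilt rate) drives
transition segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError

ACCEL_COLUMNS = ("acc_ml", "acc_ap", "acc_si")
GYRO_COLUMNS = ("gyr_roll", "gyr_pitch", "gyr_yaw")
CSV_HEADER = ("t",) + ACCEL_COLUMNS + GYRO_COLUMNS


@dataclass
class ImuRecording:
    """Time series from one sit-to-stand test.

    Parameters
    ----------
    sample_rate_hz : float
        Sampling rate, strictly positive.
    accel : ndarray, shape (n, 3)
        Acceleration in (ML, AP, SI) order, m/s^2.
    gyro : ndarray, shape (n, 3)
        Angular velocity in (roll, pitch, yaw) order, deg/s.
    ground_truth_events : list of (str, float), optional
        Known transition events as ``(event_type, time_s)`` pairs,
        strictly increasing in time and alternating seat-off/seat-on.
        Present on simulated recordings; absent on field data.
    """

    sample_rate_hz: float
    accel: np.ndarray
    gyro: np.ndarray
    ground_truth_events: list[tuple[str, float]] | None = None
    participant_id: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.sample_rate_hz <= 0:
            raise DomainError(f"sample_rate_hz must be positive, got {self.sample_rate_hz}")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise DomainError(f"accel must have shape (n, 3), got {self.accel.shape}")
        if self.gyro.shape != self.accel.shape:
            raise DomainError(
                f"gyro shape {self.gyro.shape} must match accel shape {self.accel.shape}"
            )
        if len(self.accel) < 2:
            raise DomainError("recording must contain at least 2 samples")
        if self.ground_truth_events:
            times = [t for _, t in self.ground_truth_events]
            if not all(a < b for a, b in zip(times, times[1:])):
                raise DomainError("ground_truth_events must be strictly increasing in time")

    def __len__(self) -> int:
        return len(self.accel)

    @property
    def duration_s(self) -> float:
        return len(self) / self.sample_rate_hz

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.sample_rate_hz

    def channel(self, name: str) -> np.ndarray:
        """Return one named channel (``acc_ml`` ... ``gyr_yaw``) as a 1-d array."""
        try:
            kind, idx = _CHANNEL_INDEX[name]
        except KeyError:
            raise DomainError(f"unknown channel {name!r}; expected one of {list(_CHANNEL_INDEX)}")
        return (self.accel if kind == "accel" else self.gyro)[:, idx]

    @property
    def pitch_velocity(self) -> np.ndarray:
        return self.gyro[:, 1]


_CHANNEL_INDEX = {
    "acc_ml": ("accel", 0), "acc_ap": ("accel", 1), "acc_si": ("accel", 2),
    "gyr_roll": ("gyro", 0), "gyr_pitch": ("gyro", 1), "gyr_yaw": ("gyro", 2),
}


def write_recording_csv(recording: ImuRecording, path: str | Path) -> None:
    """Write a recording to CSV with header ``t,acc_ml,...,gyr_yaw``.

    Ground-truth events, when present, are stored in ``#``-prefixed header
    comments so the file round-trips losslessly while staying plain CSV.
    """
    path = Path(path)
    frame = pd.DataFrame(
        np.column_stack([recording.times, recording.accel, recording.gyro]),
        columns=list(CSV_HEADER),
    )
    with path.open("w") as fh:
        fh.write(f"# sample_rate_hz={recording.sample_rate_hz!r}\n")
        if recording.ground_truth_events:
            for kind, t in recording.ground_truth_events:
                fh.write(f"# event={kind}@{float(t)!r}\n")
        frame.to_csv(fh, index=False, float_format="%.9g")


def read_recording_csv(path: str | Path) -> ImuRecording:
    """Read a recording written by :func:`write_recording_csv`.

    Also accepts plain CSVs without comment lines, inferring the sampling
    rate from the median spacing of the ``t`` column.
    """
    path = Path(path)
    rate = None
    events: list[tuple[str, float]] = []
    with path.open() as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("sample_rate_hz="):
                rate = float(body.split("=", 1)[1])
            elif body.startswith("event="):
                kind, t = body.split("=", 1)[1].rsplit("@", 1)
                events.append((kind, float(t)))
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        frame = pd.read_csv(fh)
    missing = [c for c in CSV_HEADER if c not in frame.columns]
    if missing:
        raise DomainError(f"recording CSV {path} is missing columns {missing}")
    if rate is None:
        dt = np.median(np.diff(frame["t"].to_numpy()))
        if dt <= 0:
            raise DomainError(f"cannot infer sampling rate from {path}")
        rate = 1.0 / dt
    return ImuRecording(
        sample_rate_hz=rate,
        accel=frame[list(ACCEL_COLUMNS)].to_numpy(),
        gyro=frame[list(GYRO_COLUMNS)].to_numpy(),
        ground_truth_events=events or None,
        participant_id=path.stem,
    )
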