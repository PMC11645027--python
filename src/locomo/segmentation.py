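"""Transition segmentation from gyroscope pitch angular velocity.

Each postural transition (seat-off or seat-on) of a sit-to-stand test
produces a dominant negative trough in the pitch angular-velocity trace:
the trunk flexes forward rapidly both when rising and when sitting down.
Detecting those local minima localises every transition; windows around
them become sit-to-stand (SiSt), stand-to-sit (StSi), full-cycle (SSS)
and whole-test (FTSTS) segments for feature extraction.

Transitions alternate SiSt / StSi starting from the first event of the
test (a participant always starts seated). Window boundaries extend from
each trough to where the pitch-velocity magnitude falls below a fraction
of the trough depth, capped at the midpoint to the neighbouring trough.
Indices are 0-based and windows half-open ``[start, end)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ConfigError, SegmentationError
from .recording import ImuRecording

SEGMENT_KINDS = ("SiSt", "StSi", "SSS", "FTSTS")


@dataclass(frozen=True)
class SegmentationConfig:
    """Detection thresholds.

    min_prominence : deg/s
        Minimum trough prominence; rejects sway and noise wiggles.
    min_separation_s : s
        Minimum spacing between detected transitions.
    boundary_fraction : in (0, 1]
        Fraction of the trough depth at which a window boundary is placed.
    differentiate : bool
        Treat the pitch channel as an angle and differentiate it first.
        Off by default: a gyroscope already measures angular rate.
    """

    min_prominence: float = 20.0
    min_separation_s: float = 0.5
    boundary_fraction: float = 0.1
    differentiate: bool = False

    def __post_init__(self) -> None:
        if self.min_prominence <= 0:
            raise ConfigError("min_prominence must be positive")
        if self.min_separation_s <= 0:
            raise ConfigError("min_separation_s must be positive")
        if not 0 < self.boundary_fraction <= 1:
            raise ConfigError("boundary_fraction must be in (0, 1]")


@dataclass(frozen=True)
class TransitionSegment:
    """A labelled half-open index window ``[start_index, end_index)``."""

    kind: str
    start_index: int
    end_index: int
    repetition: int

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ConfigError(f"unknown segment kind {self.kind!r}")
        if not 0 <= self.start_index < self.end_index:
            raise ConfigError(
                f"invalid window [{self.start_index}, {self.end_index}) for {self.kind}"
            )

    def duration_s(self, rate_hz: float) -> float:
        return (self.end_index - self.start_index) / rate_hz


def detect_transition_minima(
    pitch_velocity: np.ndarray,
    rate_hz: float,
    config: SegmentationConfig | None = None,
) -> list[int]:
    """Indices of the dominant local minima of the pitch angular velocity.

    Returns strict local minima with prominence >= ``min_prominence``,
    pairwise separated by at least ``min_separation_s``, sorted ascending.
    An empty or flat trace yields an empty list, not an error.
    """
    if config is None:
        config = SegmentationConfig()
    x = np.asarray(pitch_velocity, dtype=float)
    if x.size < 3:
        return []
    if config.differentiate:
        x = np.gradient(x) * rate_hz
    distance = max(1, int(round(config.min_separation_s * rate_hz)))
    idx, _ = sps.find_peaks(-x, prominence=config.min_prominence, distance=distance)
    return [int(i) for i in idx]


def _window_bounds(
    x: np.ndarray, minimum: int, left_cap: int, right_cap: int, fraction: float
) -> tuple[int, int]:
    """Expand from a trough until |pitch velocity| drops below fraction*depth."""
    depth = abs(x[minimum])
    threshold = fraction * depth
    start = minimum
    while start > left_cap and abs(x[start - 1]) >= threshold:
        start -= 1
    end = minimum
    while end < right_cap - 1 and abs(x[end + 1]) >= threshold:
        end += 1
    return start, end + 1  # half-open


def build_segments(
    recording: ImuRecording,
    minima: list[int],
    config: SegmentationConfig | None = None,
) -> list[TransitionSegment]:
    """Turn alternating transition minima into labelled segments.

    For n full cycles (2n minima) returns n SiSt + n StSi + n SSS segments
    plus one FTSTS segment spanning the first SiSt start to the last StSi
    end. An odd trailing event is dropped with a warning; zero minima is a
    segmentation error.
    """
    if config is None:
        config = SegmentationConfig()
    if len(minima) == 0:
        raise SegmentationError(
            f"no transition minima found in recording {recording.participant_id!r}"
        )
    minima = sorted(int(i) for i in minima)
    if len(minima) % 2 == 1:
        warnings.warn(
            f"odd number of transition events ({len(minima)}); dropping the trailing one",
            stacklevel=2,
        )
        minima = minima[:-1]
        if not minima:
            raise SegmentationError(
                f"only one transition minimum in recording {recording.participant_id!r}"
            )

    x = recording.pitch_velocity
    if config.differentiate:
        x = np.gradient(np.asarray(x, dtype=float)) * recording.sample_rate_hz
    n = len(recording)
    segments: list[TransitionSegment] = []
    windows: list[tuple[int, int]] = []
    for j, m in enumerate(minima):
        left_cap = 0 if j == 0 else (minima[j - 1] + m) // 2
        right_cap = n if j == len(minima) - 1 else (m + minima[j + 1] + 1) // 2
        windows.append(_window_bounds(x, m, left_cap, right_cap, config.boundary_fraction))

    n_cycles = len(minima) // 2
    for k in range(n_cycles):
        sist = TransitionSegment("SiSt", *windows[2 * k], repetition=k + 1)
        stsi = TransitionSegment("StSi", *windows[2 * k + 1], repetition=k + 1)
        sss = TransitionSegment("SSS", sist.start_index, stsi.end_index, repetition=k + 1)
        segments.extend([sist, stsi, sss])
    segments.append(
        TransitionSegment("FTSTS", windows[0][0], windows[-1][1], repetition=1)
    )
    return segments


def segment_recording(
    recording: ImuRecording, config: SegmentationConfig | None = None
) -> list[TransitionSegment]:
    """Convenience: detect minima then build segments on one recording."""
    if config is None:
        config = SegmentationConfig()
    minima = detect_transition_minima(
        recording.pitch_velocity, recording.sample_rate_hz, config
    )
    return build_segments(recording, minima, config)
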