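"""Time- and frequency-domain features of sit-to-stand accelerometry.

Nine metric families are computed per acceleration channel (ML, AP, SI and
the resultant Euclidean norm) and per analysis context (the whole FTSTS
test window plus the SiSt, StSi and SSS transition types, averaged across
the five repetitions): transition duration, maximum acceleration
magnitude, range, RMS, peak resultant magnitude (AMax), jerk, total
spectral power, and the 50% / 95% spectral edge frequencies. The grid
4 contexts x 4 channels x 9 metrics yields the 144 primary metrics;
duration and AMax do not genuinely vary by channel and are replicated
across channels to honour that count (a ``compact`` layout with 120
entries drops the replicates). Coefficients of variation across
repetitions are attached as a supplement, not counted in the 144.

Spectral metrics use the one-sided DFT with the DC bin excluded — the
signals are zero-centered upstream, so DC carries no information — with
no windowing or zero-padding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, FeatureError
from .recording import ImuRecording
from .segmentation import TransitionSegment

CONTEXTS = ("FTSTS", "SiSt", "StSi", "SSS")
CHANNELS = ("ML", "AP", "SI", "RES")
METRICS = ("duration", "max", "range", "rms", "amax", "jerk", "total_power", "sef50", "sef95")
#: Metrics that are identical across channels (replicated to keep the 9x4 grid).
CHANNEL_INVARIANT_METRICS = ("duration", "amax")


def resultant(ml: np.ndarray, ap: np.ndarray, si: np.ndarray) -> np.ndarray:
    """Elementwise Euclidean norm of the three acceleration axes."""
    ml, ap, si = (np.asarray(a, dtype=float) for a in (ml, ap, si))
    if not (ml.shape == ap.shape == si.shape):
        raise DomainError(
            f"channel lengths differ: {ml.shape}, {ap.shape}, {si.shape}"
        )
    return np.sqrt(ml**2 + ap**2 + si**2)


def duration(segment_samples: np.ndarray, rate_hz: float) -> float:
    """Transition duration: sample count divided by the sampling rate."""
    if rate_hz <= 0:
        raise DomainError(f"rate_hz must be positive, got {rate_hz}")
    n = len(segment_samples)
    if n == 0:
        raise DomainError("cannot compute the duration of an empty segment")
    return n / rate_hz


def range_acc(x: np.ndarray) -> float:
    """Peak-to-peak amplitude max(x) - min(x)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("cannot compute the range of an empty signal")
    return float(x.max() - x.min())


def rms(x: np.ndarray) -> float:
    """Root mean square: sqrt of the mean squared value."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("cannot compute the RMS of an empty signal")
    return float(np.sqrt(np.mean(x**2)))


def amax(res: np.ndarray) -> float:
    """Peak of the resultant acceleration magnitude over the segment."""
    res = np.asarray(res, dtype=float)
    if res.size == 0:
        raise DomainError("cannot compute AMax of an empty signal")
    return float(res.max())


def jerk(x: np.ndarray, T: float) -> float:
    """Movement-smoothness statistic: sum of squared consecutive
    differences of the acceleration, divided by the window duration T.

    The raw sample differences are used (no division by the sample
    interval), so the value carries units of m^2/s^5 at a fixed rate.
    Zero iff the signal is constant.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DomainError("jerk requires at least 2 samples")
    if T <= 0:
        raise DomainError(f"window duration must be positive, got {T}")
    return float(np.sum(np.diff(x) ** 2) / T)


def _one_sided_power(x: np.ndarray) -> np.ndarray:
    """Squared DFT magnitudes over the one-sided spectrum, DC excluded."""
    return np.abs(np.fft.rfft(np.asarray(x, dtype=float)))[1:] ** 2


def total_power(x: np.ndarray) -> float:
    """Total spectral energy: sum of squared one-sided DFT magnitudes."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise DomainError("cannot compute total power of an empty signal")
    return float(_one_sided_power(x).sum())


def sef(x: np.ndarray, rate_hz: float, fraction: float) -> float:
    """Spectral edge frequency: the smallest frequency below which at
    least ``fraction`` of the signal's one-sided power is concentrated.
    """
    if not 0 < fraction < 1:
        raise DomainError(f"fraction must be in (0, 1), got {fraction}")
    if rate_hz <= 0:
        raise DomainError(f"rate_hz must be positive, got {rate_hz}")
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DomainError("SEF requires at least 2 samples")
    power = _one_sided_power(x)
    total = power.sum()
    if total <= 0:
        raise DomainError("SEF is undefined for a zero-power signal")
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate_hz)[1:]
    cumulative = np.cumsum(power)
    edge = int(np.searchsorted(cumulative, fraction * total))
    return float(freqs[min(edge, len(freqs) - 1)])


@dataclass
class Aggregate:
    mean: float
    cv: float | None  # None when undefined (fewer than 2 values, or zero mean)


def aggregate_segments(values: list[float]) -> Aggregate:
    """Mean and coefficient of variation across repetitions.

    CV is the sample (ddof=1) standard deviation over |mean|; it is
    flagged undefined (None) rather than NaN for a single value or a
    zero mean.
    """
    if len(values) == 0:
        raise DomainError("cannot aggregate an empty list of values")
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    if len(arr) < 2 or mean == 0.0:
        return Aggregate(mean=mean, cv=None)
    return Aggregate(mean=mean, cv=float(arr.std(ddof=1) / abs(mean)))


@dataclass
class FeatureVector:
    """The named primary metrics for one participant's test, plus the
    per-segment-type CV supplement (keys ``cv_{context}_{channel}_{metric}``).
    """

    values: dict[str, float]
    cv_supplement: dict[str, float | None] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values)


def feature_names(layout: str = "primary144") -> list[str]:
    """Ordered names of the primary feature columns for a layout."""
    names = []
    for context in CONTEXTS:
        for metric in METRICS:
            if layout == "compact" and metric in CHANNEL_INVARIANT_METRICS:
                names.append(f"{context}_RES_{metric}")
                continue
            for channel in CHANNELS:
                names.append(f"{context}_{channel}_{metric}")
    return names


def _segment_metrics(
    channels: dict[str, np.ndarray], rate_hz: float
) -> dict[tuple[str, str], float]:
    """All 9x4 metrics on one window of the four acceleration channels."""
    res = channels["RES"]
    T = duration(res, rate_hz)
    peak_res = amax(res)
    out: dict[tuple[str, str], float] = {}
    for name in CHANNELS:
        x = channels[name]
        out[(name, "duration")] = T
        out[(name, "max")] = float(np.max(np.abs(x)))
        out[(name, "range")] = range_acc(x)
        out[(name, "rms")] = rms(x)
        out[(name, "amax")] = peak_res
        out[(name, "jerk")] = jerk(x, T)
        out[(name, "total_power")] = total_power(x)
        out[(name, "sef50")] = sef(x, rate_hz, 0.5)
        out[(name, "sef95")] = sef(x, rate_hz, 0.95)
    return out


def build_feature_vector(
    recording: ImuRecording,
    segments: list[TransitionSegment],
    layout: str = "primary144",
) -> FeatureVector:
    """Assemble the full feature vector from a segmented recording.

    FTSTS-context metrics are computed on the whole-test window; SiSt,
    StSi and SSS metrics are means across repetitions of the per-segment
    metrics, with their CVs attached as a supplement.
    """
    if layout not in ("primary144", "compact"):
        raise DomainError(f"unknown layout {layout!r}")
    by_kind: dict[str, list[TransitionSegment]] = {k: [] for k in CONTEXTS}
    for seg in segments:
        by_kind[seg.kind].append(seg)
    if not by_kind["FTSTS"] or not by_kind["SiSt"]:
        raise FeatureError("segments must include at least one full cycle and FTSTS window")

    ml, ap, si = recording.accel.T
    res = resultant(ml, ap, si)
    full = {"ML": ml, "AP": ap, "SI": si, "RES": res}
    rate = recording.sample_rate_hz

    def window(seg: TransitionSegment) -> dict[str, np.ndarray]:
        return {k: v[seg.start_index : seg.end_index] for k, v in full.items()}

    values: dict[str, float] = {}
    cv_supplement: dict[str, float | None] = {}
    for context in CONTEXTS:
        segs = sorted(by_kind[context], key=lambda s: s.repetition)
        per_rep = [_segment_metrics(window(s), rate) for s in segs]
        for metric in METRICS:
            channels = (
                ("RES",)
                if layout == "compact" and metric in CHANNEL_INVARIANT_METRICS
                else CHANNELS
            )
            for channel in channels:
                key = f"{context}_{channel}_{metric}"
                agg = aggregate_segments([m[(channel, metric)] for m in per_rep])
                if not np.isfinite(agg.mean):
                    raise FeatureError(f"non-finite value for {key}")
                values[key] = agg.mean
                if context != "FTSTS":
                    cv_supplement[f"cv_{key}"] = agg.cv
    return FeatureVector(values=values, cv_supplement=cv_supplement)


def feature_table(
    rows: list[tuple[str, FeatureVector]],
    metadata=None,
    include_cv: bool = False,
):
    """Stack per-participant feature vectors into a DataFrame.

    Parameters
    ----------
    rows : list of (participant_id, FeatureVector)
    metadata : DataFrame, optional
        Cohort manifest indexed or keyed by ``participant_id``; its
        ``group`` and ``glfs`` columns are joined in when present.
    include_cv : bool
        Also emit the ``cv_``-prefixed supplement columns.
    """
    import pandas as pd

    records = []
    for pid, fv in rows:
        rec = {"participant_id": pid, **fv.values}
        if include_cv:
            rec.update({k: (np.nan if v is None else v) for k, v in fv.cv_supplement.items()})
        records.append(rec)
    frame = pd.DataFrame.from_records(records)
    if metadata is not None:
        meta = metadata[[c for c in ("participant_id", "group", "glfs") if c in metadata.columns]]
        frame = meta.merge(frame, on="participant_id", how="right")
    return frame
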