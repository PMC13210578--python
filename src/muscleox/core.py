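"""Shared time-series data model, file I/O, windowed reductions and signal QC.

All downstream analyses (SmO2 kinetics, Doppler flow, CPET reduction) operate
on :class:`SampledTrace`, a uniformly sampled signal in which missing samples
are encoded as NaN.  Time is expressed in seconds from recording start and
every windowed operation uses half-open windows ``[start, end)`` so each
sample belongs to exactly one adjacent window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SampledTrace",
    "ProtocolEvents",
    "QcReport",
    "TraceParseError",
    "QualityError",
    "UndefinedMetricError",
    "ExclusionError",
    "ConfigError",
    "read_trace_csv",
    "write_trace_csv",
    "window_mean",
    "detect_signal_loss",
    "moving_average",
]

#: jitter tolerance (fraction of the median step) when inferring the sampling
#: rate and mapping irregular timestamps onto the uniform grid
RATE_JITTER_TOL = 0.01

#: SmO2 physical bounds (%) used as the default validity band in QC
SMO2_BOUNDS = (0.0, 100.0)


class TraceParseError(ValueError):
    """Raised when a trace file cannot be interpreted as a sampled signal."""


class QualityError(ValueError):
    """Raised when a window has too little valid data for a reliable estimate."""


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined on the given signal (e.g. no recovery)."""


class ExclusionError(ValueError):
    """Raised when QC has excluded a recording from analysis."""


class ConfigError(ValueError):
    """Raised on invalid simulator or analysis configuration."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampledTrace:
    """A uniformly sampled physiological signal.

    Parameters
    ----------
    values
        Sample values; missing samples are NaN.
    rate
        Sampling rate in Hz (> 0).
    t0
        Time of the first sample, seconds from recording start.
    channel
        Signal label, e.g. ``"smo2_pct"`` or ``"velocity_cms"``.
    units
        Unit string for display ("%", "cm/s", "L/min", ...).
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    channel: str = "signal"
    units: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size == 0:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not (self.rate > 0):
            raise ValueError("rate must be > 0")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        return 1.0 / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def span(self) -> tuple[float, float]:
        """Half-open time span ``[t0, t0 + n/rate)`` covered by the samples."""
        return (self.t0, self.t0 + self.values.size / self.rate)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def index_of(self, t: float) -> int:
        """Index of the sample at (or nearest to) time ``t``."""
        i = int(round((t - self.t0) * self.rate))
        return min(max(i, 0), self.values.size - 1)

    def window_indices(self, start_s: float, end_s: float) -> tuple[int, int]:
        """Sample index range covering the half-open window ``[start, end)``."""
        eps = 1e-9 / self.rate
        i0 = int(math.ceil((start_s - self.t0) * self.rate - eps))
        i1 = int(math.ceil((end_s - self.t0) * self.rate - eps))
        return max(i0, 0), min(max(i1, 0), self.values.size)

    def crop(self, start_s: float, end_s: float) -> "SampledTrace":
        """Sub-trace over ``[start, end)``."""
        i0, i1 = self.window_indices(start_s, end_s)
        if i1 <= i0:
            raise ValueError("empty crop window")
        return SampledTrace(self.values[i0:i1], self.rate,
                            t0=self.t0 + i0 / self.rate,
                            channel=self.channel, units=self.units)

    def with_values(self, values: np.ndarray) -> "SampledTrace":
        return SampledTrace(values, self.rate, t0=self.t0,
                            channel=self.channel, units=self.units)


@dataclass
class ProtocolEvents:
    """Protocol timestamps (seconds from recording start).

    Cuff tests use ``cuff_inflate_t``/``cuff_release_t``; exercise tests use
    ``exercise_start_t``/``exercise_end_t``.  ``baseline_window_s`` is the
    duration of the pre-test window over which baseline values are averaged.
    """

    cuff_inflate_t: float | None = None
    cuff_release_t: float | None = None
    exercise_start_t: float | None = None
    exercise_end_t: float | None = None
    baseline_window_s: float = 30.0

    def __post_init__(self) -> None:
        if (self.cuff_inflate_t is not None and self.cuff_release_t is not None
                and not self.cuff_inflate_t < self.cuff_release_t):
            raise ValueError("cuff_inflate_t must precede cuff_release_t")
        if (self.exercise_start_t is not None and self.exercise_end_t is not None
                and not self.exercise_start_t < self.exercise_end_t):
            raise ValueError("exercise_start_t must precede exercise_end_t")
        if not self.baseline_window_s > 0:
            raise ValueError("baseline_window_s must be > 0")

    def validate_span(self, trace: SampledTrace) -> None:
        lo, hi = trace.span
        for name in ("cuff_inflate_t", "cuff_release_t",
                     "exercise_start_t", "exercise_end_t"):
            t = getattr(self, name)
            if t is not None and not (lo <= t <= hi):
                raise ValueError(f"{name}={t} outside trace span {trace.span}")

    def to_json(self, path: str | Path) -> None:
        payload = {k: v for k, v in asdict(self).items() if v is not None}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolEvents":
        payload = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in payload.items() if k in known})


@dataclass
class QcReport:
    """Signal-loss report for one recording.

    ``loss_segments`` are maximal runs of lost samples (missing or outside the
    validity band) longer than the configured gap; ``excluded`` is set when any
    such run intersects the caller's analysis window.
    """

    loss_segments: list[tuple[float, float]] = field(default_factory=list)
    excluded: bool = False
    reason: str = ""


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_trace_csv(path: str | Path, channel: str | None = None) -> SampledTrace:
    """Read a two-column trace CSV (``time_s,<channel>``) onto a uniform grid.

    The sampling rate is inferred from the median inter-sample interval.
    Gaps larger than one step are filled with NaN so the returned trace is
    uniformly sampled; empty value fields also become NaN.

    Raises
    ------
    TraceParseError
        If the file is empty, has fewer than two rows, or the time column is
        not strictly increasing.
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise TraceParseError(f"cannot read trace CSV {path}: {exc}") from exc
    if df.shape[1] < 2 or df.shape[0] < 2:
        raise TraceParseError(f"{path}: need >= 2 rows and 2 columns (time_s,value)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if channel is None:
        channel = str(df.columns[1])
        col = df.iloc[:, 1]
    else:
        if channel not in df.columns:
            raise TraceParseError(f"{path}: no column named {channel!r}")
        col = df[channel]
    v = col.to_numpy(dtype=float)
    if np.any(np.isnan(t)):
        raise TraceParseError(f"{path}: missing timestamps")
    steps = np.diff(t)
    if np.any(steps <= 0):
        raise TraceParseError(f"{path}: time column must be strictly increasing")
    dt = float(np.median(steps))
    n = int(round((t[-1] - t[0]) / dt)) + 1
    idx = np.round((t - t[0]) / dt).astype(int)
    # reject timestamps that do not sit on the inferred grid (beyond jitter)
    if np.any(np.abs((t - t[0]) / dt - idx) > RATE_JITTER_TOL * 2):
        raise TraceParseError(f"{path}: irregular sampling exceeds jitter tolerance")
    if np.unique(idx).size != idx.size:
        raise TraceParseError(f"{path}: duplicate timestamps on inferred grid")
    grid = np.full(n, np.nan)
    grid[idx] = v
    return SampledTrace(grid, rate=1.0 / dt, t0=float(t[0]), channel=channel)


def write_trace_csv(trace: SampledTrace, path: str | Path) -> None:
    """Write a trace as ``time_s,<channel>`` CSV; missing samples as empty fields."""
    df = pd.DataFrame({"time_s": np.round(trace.times, 6), trace.channel: trace.values})
    df.to_csv(path, index=False, float_format="%.10g", na_rep="")


# ---------------------------------------------------------------------------
# windowed reductions and QC
# ---------------------------------------------------------------------------

def window_mean(trace: SampledTrace, start_s: float, end_s: float,
                min_valid_frac: float = 0.5) -> float:
    """Mean of non-missing samples in the half-open window ``[start, end)``.

    Raises ``ValueError`` if the window lies outside the trace span and
    :class:`QualityError` if fewer than ``min_valid_frac`` of its samples are
    observed.
    """
    if not end_s > start_s:
        raise ValueError("end_s must exceed start_s")
    lo, hi = trace.span
    eps = 0.5 * trace.dt
    if start_s < lo - eps or end_s > hi + eps:
        raise ValueError(
            f"window [{start_s}, {end_s}) outside trace span [{lo}, {hi})")
    i0, i1 = trace.window_indices(start_s, end_s)
    vals = trace.values[i0:i1]
    if vals.size == 0:
        raise ValueError("window contains no samples")
    ok = ~np.isnan(vals)
    if ok.mean() < min_valid_frac:
        raise QualityError(
            f"window [{start_s}, {end_s}): only {ok.mean():.0%} of samples observed")
    return float(vals[ok].mean())


def detect_signal_loss(trace: SampledTrace, max_gap_s: float = 2.0,
                       bounds: tuple[float, float] | None = SMO2_BOUNDS,
                       analysis_windows: list[tuple[float, float]] | None = None,
                       ) -> QcReport:
    """Flag runs of lost samples and decide exclusion for an analysis window.

    A sample is *lost* if missing or outside ``bounds``.  Maximal runs longer
    than ``max_gap_s`` become loss segments; the recording is excluded when a
    segment intersects any of the caller's ``analysis_windows`` (the whole
    trace if none are given).
    """
    lost = np.isnan(trace.values)
    if bounds is not None:
        with np.errstate(invalid="ignore"):
            lost |= (trace.values < bounds[0]) | (trace.values > bounds[1])
    segments: list[tuple[float, float]] = []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], lost.view(np.int8), [0]))))
    for a, b in zip(edges[::2], edges[1::2]):
        dur = (b - a) / trace.rate
        if dur > max_gap_s:
            segments.append((trace.t0 + a / trace.rate, trace.t0 + b / trace.rate))
    if analysis_windows is None:
        analysis_windows = [trace.span]
    excluded = False
    reason = ""
    for (s, e) in segments:
        for (ws, we) in analysis_windows:
            if s < we and e > ws:
                excluded = True
                reason = (f"signal lost for {e - s:.1f}s at t={s:.1f}s "
                          f"inside analysis window [{ws:.1f}, {we:.1f})")
                break
        if excluded:
            break
    return QcReport(loss_segments=segments, excluded=excluded, reason=reason)


def moving_average(trace: SampledTrace, width_s: float) -> SampledTrace:
    """Centered moving mean ignoring missing samples; same length as the input.

    The kernel width is rounded to the nearest odd sample count.  At the trace
    edges the window shrinks to the available samples.  ``width_s`` below one
    sample period is an error.
    """
    if width_s < trace.dt:
        raise ValueError(f"width_s={width_s} smaller than sample period {trace.dt}")
    k = int(round(width_s * trace.rate))
    if k % 2 == 0:
        k += 1
    if k <= 1:
        return trace
    v = trace.values
    ok = ~np.isnan(v)
    filled = np.where(ok, v, 0.0)
    kern = np.ones(k)
    num = np.convolve(filled, kern, mode="same")
    cnt = np.convolve(ok.astype(float), kern, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(cnt > 0, num / cnt, np.nan)
    return trace.with_values(out)
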