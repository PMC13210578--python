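"""SmO2 kinetic metrics for the vascular occlusion test and steady-state exercise.

The reoxygenation descriptors follow the 63%-of-increment convention: with the
increment ``I`` defined as target level minus SmO2 at recovery onset, the time
constant ``tau`` is the time to first reach ``SmO2(onset) + 0.63*I`` (a
threshold crossing, not an exponential fit; for a mono-exponential recovery
this equals ``-tau_exp * ln 0.37 ~= 0.994 * tau_exp``).  The relative
reoxygenation rate is ``R = I / tau``.  The occlusion test targets the
post-release hyperemic peak (``R_peak``); the exercise test targets the
pre-exercise baseline (``R_bl``).

Metrics that are undefined on a given signal (no recovery, threshold never
crossed) are reported as NaN by the bundle-level analyzers; the low-level
operations raise :class:`~muscleox.core.UndefinedMetricError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (ExclusionError, ProtocolEvents, QcReport, QualityError,
                   SampledTrace, UndefinedMetricError, detect_signal_loss,
                   moving_average, window_mean)

__all__ = [
    "CuffMetrics",
    "SseMetrics",
    "occlusion_slope",
    "reox_increment_tau",
    "relative_rate",
    "rep10s",
    "analyze_cuff",
    "analyze_sse",
]

#: fraction of the increment defining the time-constant threshold
TAU_FRACTION = 0.63

#: default search window (s) for the post-release SmO2 peak
DEFAULT_PEAK_WINDOW_S = 60.0

#: default centered-smoothing width (s) used inside the increment/tau
#: computation (peak target + threshold crossing); 0 disables
DEFAULT_REOX_SMOOTH_S = 0.5

#: half-width (s) of the endpoint-averaging windows of Rep 10 s
REP10S_ENDPOINT_S = 0.5


@dataclass
class CuffMetrics:
    """SmO2 metric bundle for one cuff-occlusion recording.

    Units: percentages for levels and increments, %/s for rates, s for tau.
    ``r_peak`` is stored as exactly ``i_peak / tau_peak``; undefined metrics
    are NaN.  ``desat_auc`` (%*s, area between baseline and signal during
    occlusion) is an optional, unvalidated descriptor.
    """

    baseline_smo2: float
    occlusion_slope: float
    min_smo2_at_release: float
    rep10s: float
    i_peak: float
    tau_peak: float
    r_peak: float
    desat_auc: float = float("nan")


@dataclass
class SseMetrics:
    """SmO2 metric bundle for one steady-state-exercise recording."""

    baseline_smo2: float
    pre_recovery_smo2: float
    rep10s: float
    i_bl: float
    tau_bl: float
    r_bl: float


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def occlusion_slope(trace: SampledTrace, t_inflate: float, t_release: float,
                    min_coverage_s: float = 30.0) -> float:
    """OLS slope (%/s) of SmO2 vs time over the occlusion ``[t_inflate, t_release)``.

    Requires at least ``min_coverage_s`` of non-missing data in the window.
    """
    if not t_release > t_inflate:
        raise ValueError("t_release must exceed t_inflate")
    i0, i1 = trace.window_indices(t_inflate, t_release)
    v = trace.values[i0:i1]
    t = trace.times[i0:i1]
    ok = ~np.isnan(v)
    if ok.sum() / trace.rate < min_coverage_s:
        raise QualityError(
            f"occlusion window has only {ok.sum() / trace.rate:.1f}s of data "
            f"(need {min_coverage_s}s)")
    slope, _ = np.polyfit(t[ok], v[ok], 1)
    return float(slope)


def reox_increment_tau(trace: SampledTrace, t_start: float,
                       target: str = "peak_in_window",
                       window_s: float = DEFAULT_PEAK_WINDOW_S,
                       level: float | None = None,
                       smooth_s: float = 0.0) -> tuple[float, float]:
    """Reoxygenation increment ``I`` (%) and time constant ``tau`` (s).

    ``target="peak_in_window"`` takes the target level as the maximum SmO2 in
    ``[t_start, t_start + window_s)`` (occlusion test); ``target="fixed_level"``
    uses the caller-supplied ``level`` (exercise test, pre-test baseline).
    ``tau`` is the time of the first sample at or after ``t_start`` whose value
    reaches ``SmO2(t_start) + 0.63*I``.

    ``smooth_s > 0`` applies a centered moving average of that width to the
    signal used for the start value, the peak target and the crossing — a
    robustness option for noisy recordings that leaves a noiseless
    mono-exponential's grid crossing unchanged.

    Raises :class:`UndefinedMetricError` when there is no recovery (I <= 0) or
    the threshold is never crossed within the search span.
    """
    lo, hi = trace.span
    if not lo <= t_start < hi:
        raise ValueError(f"t_start={t_start} outside trace span {trace.span}")
    work = moving_average(trace, smooth_s) if smooth_s >= trace.dt else trace
    i_start = work.index_of(t_start)
    v0 = work.values[i_start]
    if math.isnan(v0):
        raise QualityError("SmO2 missing at recovery onset")

    if target == "peak_in_window":
        j0, j1 = work.window_indices(t_start, t_start + window_s)
        seg = work.values[j0:j1]
        if np.all(np.isnan(seg)):
            raise QualityError("no data in peak search window")
        target_level = float(np.nanmax(seg))
        search_end = j1
    elif target == "fixed_level":
        if level is None:
            raise ValueError("fixed_level target requires level=")
        target_level = float(level)
        search_end = work.values.size
    else:
        raise ValueError(f"unknown target mode {target!r}")

    increment = target_level - v0
    if increment <= 0:
        raise UndefinedMetricError(
            f"no recovery: target {target_level:.2f} <= start {v0:.2f}")
    threshold = v0 + TAU_FRACTION * increment
    seg = work.values[i_start:search_end]
    with np.errstate(invalid="ignore"):
        crossed = np.flatnonzero(seg >= threshold - 1e-9)
    if crossed.size == 0:
        raise UndefinedMetricError(
            f"63% threshold {threshold:.2f} never reached in search window")
    tau = max(crossed[0], 1) / trace.rate   # instant jump -> one sample period
    return float(increment), float(tau)


def relative_rate(increment: float, tau: float) -> float:
    """Relative reoxygenation rate ``R = I / tau`` (%/s)."""
    if increment == 0:
        return 0.0
    if tau <= 0:
        raise ValueError("tau must be > 0")
    return increment / tau


def rep10s(trace: SampledTrace, t_start: float, mode: str = "diff",
           endpoint_s: float = REP10S_ENDPOINT_S) -> float:
    """10-s reoxygenation rate (%/s) from recovery onset ``t_start``.

    ``mode="diff"`` (default): endpoint-averaged difference quotient
    ``(v1 - v0) / 10`` where ``v0``/``v1`` are means of the ``endpoint_s``
    windows ending at ``t_start`` and ``t_start + 10``.  ``mode="slope"``:
    OLS slope over ``[t_start, t_start + 10)``.
    """
    if mode == "slope":
        i0, i1 = trace.window_indices(t_start, t_start + 10.0)
        v, t = trace.values[i0:i1], trace.times[i0:i1]
        ok = ~np.isnan(v)
        if ok.mean() < 0.5:
            raise QualityError("Rep 10 s window mostly missing")
        return float(np.polyfit(t[ok], v[ok], 1)[0])
    if mode != "diff":
        raise ValueError(f"unknown Rep 10 s mode {mode!r}")
    v0 = window_mean(trace, t_start - endpoint_s, t_start)
    v1 = window_mean(trace, t_start + 10.0 - endpoint_s, t_start + 10.0)
    return (v1 - v0) / 10.0


# ---------------------------------------------------------------------------
# bundle analyzers
# ---------------------------------------------------------------------------

def _qc_or_default(trace: SampledTrace, qc: QcReport | None,
                   windows: list[tuple[float, float]],
                   max_gap_s: float) -> QcReport:
    if qc is not None:
        return qc
    return detect_signal_loss(trace, max_gap_s=max_gap_s,
                              analysis_windows=windows)


def analyze_cuff(trace: SampledTrace, events: ProtocolEvents,
                 qc: QcReport | None = None, *,
                 baseline_s: float | None = None,
                 peak_window_s: float = DEFAULT_PEAK_WINDOW_S,
                 reox_smooth_s: float = DEFAULT_REOX_SMOOTH_S,
                 rep10s_mode: str = "diff",
                 qc_max_gap_s: float = 2.0) -> CuffMetrics:
    """Assemble all cuff-occlusion-test SmO2 metrics.

    Baseline is the mean over the last ``baseline_s`` (default: the events'
    ``baseline_window_s``) before inflation; the desaturation slope spans the
    whole occlusion; the reoxygenation target is the maximum SmO2 within
    ``peak_window_s`` after release.  If QC (computed over the post-release
    recovery window when not supplied) flags a loss event there, the recording
    is excluded and :class:`ExclusionError` raised.  Undefined reoxygenation
    metrics surface as NaN fields.
    """
    if events.cuff_inflate_t is None or events.cuff_release_t is None:
        raise ValueError("cuff analysis requires cuff_inflate_t and cuff_release_t")
    events.validate_span(trace)
    t_inf, t_rel = events.cuff_inflate_t, events.cuff_release_t
    if baseline_s is None:
        baseline_s = events.baseline_window_s
    recovery_window = (t_rel, min(t_rel + peak_window_s, trace.span[1]))
    qc = _qc_or_default(trace, qc, [recovery_window], qc_max_gap_s)
    if qc.excluded:
        raise ExclusionError(f"recording excluded by QC: {qc.reason}")

    baseline = window_mean(trace, t_inf - baseline_s, t_inf)
    slope = occlusion_slope(trace, t_inf, t_rel)
    min_at_release = window_mean(trace, t_rel - REP10S_ENDPOINT_S, t_rel)

    try:
        r10 = rep10s(trace, t_rel, mode=rep10s_mode)
    except (QualityError, UndefinedMetricError):
        r10 = float("nan")
    try:
        inc, tau = reox_increment_tau(trace, t_rel, target="peak_in_window",
                                      window_s=peak_window_s,
                                      smooth_s=reox_smooth_s)
        r_peak = relative_rate(inc, tau)
    except UndefinedMetricError:
        inc = tau = r_peak = float("nan")

    # optional: area between the baseline level and the signal during occlusion
    i0, i1 = trace.window_indices(t_inf, t_rel)
    v = trace.values[i0:i1]
    ok = ~np.isnan(v)
    auc = float(np.trapezoid(baseline - v[ok], trace.times[i0:i1][ok])) \
        if ok.sum() > 1 else float("nan")

    return CuffMetrics(baseline_smo2=baseline, occlusion_slope=slope,
                       min_smo2_at_release=min_at_release, rep10s=r10,
                       i_peak=inc, tau_peak=tau, r_peak=r_peak, desat_auc=auc)


def analyze_sse(trace: SampledTrace, events: ProtocolEvents,
                qc: QcReport | None = None, *,
                baseline_s: float | None = None,
                pre_recovery_s: float = 10.0,
                reox_smooth_s: float = DEFAULT_REOX_SMOOTH_S,
                rep10s_mode: str = "diff",
                qc_max_gap_s: float = 2.0) -> SseMetrics:
    """Assemble all steady-state-exercise SmO2 metrics.

    Baseline is averaged over the window before exercise start;
    ``pre_recovery_smo2`` over the last ``pre_recovery_s`` of exercise.
    Recovery metrics start at exercise end and target the pre-exercise
    baseline (fixed-level mode).  QC covers the exercise + recovery period.
    """
    if events.exercise_start_t is None or events.exercise_end_t is None:
        raise ValueError("SSE analysis requires exercise_start_t and exercise_end_t")
    events.validate_span(trace)
    t_start, t_end = events.exercise_start_t, events.exercise_end_t
    if baseline_s is None:
        baseline_s = events.baseline_window_s
    qc = _qc_or_default(trace, qc, [(t_start, trace.span[1])], qc_max_gap_s)
    if qc.excluded:
        raise ExclusionError(f"recording excluded by QC: {qc.reason}")

    baseline = window_mean(trace, t_start - baseline_s, t_start)
    pre_rec = window_mean(trace, t_end - pre_recovery_s, t_end)

    try:
        r10 = rep10s(trace, t_end, mode=rep10s_mode)
    except (QualityError, UndefinedMetricError):
        r10 = float("nan")
    try:
        inc, tau = reox_increment_tau(trace, t_end, target="fixed_level",
                                      level=baseline, smooth_s=reox_smooth_s)
        r_bl = relative_rate(inc, tau)
    except UndefinedMetricError:
        inc = tau = r_bl = float("nan")

    return SseMetrics(baseline_smo2=baseline, pre_recovery_smo2=pre_rec,
                      rep10s=r10, i_bl=inc, tau_bl=tau, r_bl=r_bl)
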