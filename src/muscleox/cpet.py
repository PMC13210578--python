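"""Reduction of CPET and steady-state gas-exchange/HR/power series.

The maximal test is summarized by the highest rolling 30-s mean of VO2
(``abs_vo2max``), with HR_max and PPO read from the same window; relative
VO2max divides by body mass.  The steady-state test is summarized by means
over the last 30 s of exercise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SampledTrace, window_mean

__all__ = [
    "CpetResult",
    "SseSummary",
    "rolling_30s_max",
    "cpet_summary",
    "sse_summary",
]

#: default averaging window (s) for gas-exchange summaries
AVG_WINDOW_S = 30.0

#: VO2 slope (L/min per s) in the peak window below which the uptake is
#: considered to have plateaued (~0.15 L/min over a 30 s window)
PLATEAU_SLOPE_LMIN_S = 0.005


@dataclass
class CpetResult:
    """Maximal-test summary: VO2max (absolute L/min, relative mL/kg/min),
    HR_max (bpm) and PPO (W), plus the VO2-plateau verification flag."""

    abs_vo2max: float
    rel_vo2max: float
    hr_max: float
    ppo: float
    plateau: bool
    window_start_s: float


@dataclass
class SseSummary:
    """Steady-state-test summary over the last 30 s of exercise."""

    abs_vo2: float
    rel_vo2: float
    hr_mean: float
    po: float


def rolling_30s_max(trace: SampledTrace,
                    window_s: float = AVG_WINDOW_S,
                    disjoint: bool = False) -> tuple[float, float]:
    """Highest ``window_s`` mean of the series and that window's start time.

    Windows advance sample-by-sample by default; ``disjoint=True`` restricts
    them to consecutive non-overlapping bins.
    """
    nw = int(round(window_s * trace.rate))
    v = trace.values
    if v.size < nw:
        raise ValueError(f"series spans {v.size / trace.rate:.0f}s < {window_s}s")
    means = np.convolve(np.nan_to_num(v), np.ones(nw), "valid") / nw
    if np.any(np.isnan(v)):  # recompute honestly where samples are missing
        cnt = np.convolve((~np.isnan(v)).astype(float), np.ones(nw), "valid")
        num = np.convolve(np.where(np.isnan(v), 0.0, v), np.ones(nw), "valid")
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(cnt > 0, num / cnt, -np.inf)
    starts = np.arange(means.size)
    if disjoint:
        starts = starts[::nw]
        means = means[::nw]
    k = int(np.argmax(means))
    return float(means[k]), float(trace.t0 + starts[k] / trace.rate)


def _check_aligned(*traces: SampledTrace) -> None:
    ref = traces[0]
    for tr in traces[1:]:
        if (abs(tr.t0 - ref.t0) > 1e-6 or abs(tr.rate - ref.rate) > 1e-9
                or len(tr) != len(ref)):
            raise ValueError("series are not aligned (t0/rate/length differ)")


def cpet_summary(vo2: SampledTrace, hr: SampledTrace, power: SampledTrace,
                 body_mass_kg: float, window_s: float = AVG_WINDOW_S,
                 plateau_slope_thresh: float = PLATEAU_SLOPE_LMIN_S) -> CpetResult:
    """Summarize an incremental maximal test from aligned VO2/HR/power series.

    ``abs_vo2max`` is the highest rolling ``window_s`` VO2 mean; HR_max is the
    HR mean and PPO the maximum commanded power within that same window;
    ``rel_vo2max = abs_vo2max * 1000 / body_mass_kg``.  The plateau flag is
    informational (VO2 slope in the peak window below the threshold) and never
    blocks output.
    """
    _check_aligned(vo2, hr, power)
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    abs_vo2max, w_start = rolling_30s_max(vo2, window_s)
    w_end = w_start + window_s
    hr_max = window_mean(hr, w_start, w_end)
    i0, i1 = power.window_indices(w_start, w_end)
    ppo = float(np.nanmax(power.values[i0:i1]))
    j0, j1 = vo2.window_indices(w_start, w_end)
    vv, tt = vo2.values[j0:j1], vo2.times[j0:j1]
    ok = ~np.isnan(vv)
    slope = float(np.polyfit(tt[ok], vv[ok], 1)[0]) if ok.sum() > 1 else 0.0
    return CpetResult(abs_vo2max=abs_vo2max,
                      rel_vo2max=abs_vo2max * 1000.0 / body_mass_kg,
                      hr_max=hr_max, ppo=ppo,
                      plateau=bool(abs(slope) < plateau_slope_thresh),
                      window_start_s=w_start)


def sse_summary(vo2: SampledTrace, hr: SampledTrace, power: SampledTrace,
                exercise_end_t: float, body_mass_kg: float,
                window_s: float = AVG_WINDOW_S) -> SseSummary:
    """Summarize a steady-state bout by means over its last ``window_s``."""
    _check_aligned(vo2, hr, power)
    if body_mass_kg <= 0:
        raise ValueError("body_mass_kg must be > 0")
    w0 = exercise_end_t - window_s
    abs_vo2 = window_mean(vo2, w0, exercise_end_t)
    return SseSummary(abs_vo2=abs_vo2,
                      rel_vo2=abs_vo2 * 1000.0 / body_mass_kg,
                      hr_mean=window_mean(hr, w0, exercise_end_t),
                      po=window_mean(power, w0, exercise_end_t))
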