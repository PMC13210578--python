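"""Doppler-derived volumetric flow and reactive-hyperemia metrics.

Velocity/diameter series are converted to volumetric flow with the standard
conduit-artery relation ``Q = TAMV * pi * (d/2)^2 * 60`` (mL/min from cm/s and
cm).  Beats are segmented at prominence-filtered local minima of the velocity
waveform; the hyperemia readout is the highest mean flow over three
consecutive post-release beats, referenced to the mean per-beat flow over the
baseline minute before cuff inflation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import ProtocolEvents, QualityError, SampledTrace

__all__ = [
    "BeatSeries",
    "HyperemiaMetrics",
    "flow_from_velocity_diameter",
    "segment_beats",
    "peak_flow_3beats",
    "analyze_hyperemia",
]

#: minimum spacing (s) between beat onsets during segmentation
MIN_BEAT_PERIOD_S = 0.3

#: default prominence threshold as a fraction of the velocity pulse amplitude
PROMINENCE_FRACTION = 0.3

#: post-release gap (s) beyond which the first detected beat is flagged as
#: delayed insonation (the true hyperemic peak may have been missed)
DELAYED_INSONATION_GAP_S = 2.0


@dataclass
class BeatSeries:
    """Segmented beats: contiguous windows with per-beat TAMV and flow.

    ``onsets``/``ends`` delimit each beat (s); ``tamv`` is the time-averaged
    mean velocity within the beat (cm/s); ``flow`` the per-beat volumetric
    flow (mL/min), NaN until a diameter is applied via :meth:`with_flows`.
    """

    onsets: np.ndarray
    ends: np.ndarray
    tamv: np.ndarray
    flow: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.flow is None:
            self.flow = np.full(self.tamv.size, np.nan)

    def __len__(self) -> int:
        return self.onsets.size

    def with_flows(self, diameter_cm: float) -> "BeatSeries":
        return BeatSeries(self.onsets, self.ends, self.tamv,
                          flow_from_velocity_diameter(self.tamv, diameter_cm))


@dataclass
class HyperemiaMetrics:
    """Reactive-hyperemia flow bundle (all mL/min).

    ``delta_flow`` is stored as exactly ``peak_flow - baseline_flow``.
    ``flags`` collects QC warnings such as ``delayed_insonation`` (first
    post-release beat detected late; peak may be underestimated) and
    ``no_hyperemia`` (peak below baseline).
    """

    baseline_flow: float
    peak_flow: float
    delta_flow: float
    diameter_cm: float
    n_baseline_beats: int
    n_post_beats: int
    flags: list[str] = field(default_factory=list)


def flow_from_velocity_diameter(tamv, diameter_cm: float):
    """Volumetric flow ``Q = TAMV * pi * (d/2)^2 * 60`` in mL/min.

    Accepts scalar or array ``tamv`` (cm/s).  Negative mean velocities are
    clamped to zero with a warning (retrograde net flow over a whole beat is
    outside this model).
    """
    if diameter_cm <= 0:
        raise ValueError("diameter_cm must be > 0")
    tamv = np.asarray(tamv, dtype=float)
    if np.any(tamv < 0):
        warnings.warn("negative time-averaged mean velocity clamped to 0",
                      stacklevel=2)
        tamv = np.clip(tamv, 0.0, None)
    q = tamv * np.pi * (diameter_cm / 2.0) ** 2 * 60.0
    return float(q) if q.ndim == 0 else q


def segment_beats(trace: SampledTrace,
                  min_period_s: float = MIN_BEAT_PERIOD_S,
                  prominence_frac: float = PROMINENCE_FRACTION) -> BeatSeries:
    """Segment a pulsatile velocity trace into beats at waveform minima.

    Onsets are local minima separated by at least ``min_period_s`` with
    prominence above ``prominence_frac`` of the overall pulse amplitude; each
    beat's TAMV is the mean velocity between consecutive onsets.  Missing
    samples are ignored within beats but the onset search requires a finite
    signal, so leading/trailing missing runs are trimmed first.

    Raises :class:`QualityError` if fewer than 3 beats are found.
    """
    v = trace.values
    finite = np.flatnonzero(~np.isnan(v))
    if finite.size < 3:
        raise QualityError("velocity trace has too few observed samples")
    a, b = finite[0], finite[-1] + 1
    seg = v[a:b]
    # interior gaps: interpolate for onset detection only
    ok = ~np.isnan(seg)
    if not ok.all():
        seg = np.interp(np.arange(seg.size), np.flatnonzero(ok), seg[ok])
    amp = float(seg.max() - seg.min())
    if amp <= 0:
        raise QualityError("velocity trace is constant; no beats detectable")
    minima, _ = find_peaks(-seg, distance=max(int(round(min_period_s * trace.rate)), 1),
                           prominence=prominence_frac * amp)
    if minima.size < 4:
        raise QualityError(f"only {max(minima.size - 1, 0)} beats found (need >= 3)")
    # find_peaks cannot mark an onset at the array edge; if a full leading
    # beat exists (e.g. the window starts exactly at cuff release), recover it
    period = int(round(np.median(np.diff(minima))))
    while period > 0 and minima[0] - period >= 0:
        minima = np.insert(minima, 0, minima[0] - period)
    onsets_idx = minima + a
    onsets = trace.t0 + onsets_idx / trace.rate
    tamv = np.array([
        np.nanmean(v[i:j]) for i, j in zip(onsets_idx[:-1], onsets_idx[1:])])
    return BeatSeries(onsets=onsets[:-1], ends=onsets[1:], tamv=tamv)


def peak_flow_3beats(beats: BeatSeries, t_release: float) -> float:
    """Highest mean flow (mL/min) over three consecutive post-release beats."""
    if np.any(np.isnan(beats.flow)):
        raise ValueError("beat flows not set; call BeatSeries.with_flows first")
    post = beats.flow[beats.onsets >= t_release - 1e-9]
    if post.size < 3:
        raise QualityError(f"only {post.size} post-release beats (need >= 3)")
    means = np.convolve(post, np.ones(3) / 3.0, mode="valid")
    return float(means.max())


def analyze_hyperemia(velocity: SampledTrace,
                      diameter: SampledTrace | float,
                      events: ProtocolEvents, *,
                      baseline_s: float = 60.0,
                      post_s: float = 180.0,
                      min_period_s: float = MIN_BEAT_PERIOD_S,
                      prominence_frac: float = PROMINENCE_FRACTION,
                      ) -> HyperemiaMetrics:
    """Reactive-hyperemia metrics from a velocity trace and vessel diameter.

    Baseline flow is the mean per-beat flow over ``baseline_s`` before cuff
    inflation; peak flow the highest 3-beat mean within ``post_s`` after
    release; ``delta_flow = peak - baseline``.  The diameter may be a scalar
    (cm) or a trace, in which case its mean over the baseline window is used
    and held fixed.
    """
    if events.cuff_inflate_t is None or events.cuff_release_t is None:
        raise ValueError("hyperemia analysis requires cuff inflate/release events")
    t_inf, t_rel = events.cuff_inflate_t, events.cuff_release_t

    if isinstance(diameter, SampledTrace):
        from .core import window_mean
        d_cm = window_mean(diameter, max(t_inf - baseline_s, diameter.span[0]), t_inf)
    else:
        d_cm = float(diameter)
    if d_cm <= 0:
        raise ValueError("diameter must be > 0")

    base_beats = segment_beats(
        velocity.crop(max(t_inf - baseline_s, velocity.span[0]), t_inf),
        min_period_s, prominence_frac).with_flows(d_cm)
    post_end = min(t_rel + post_s, velocity.span[1])
    post_beats = segment_beats(
        velocity.crop(t_rel, post_end), min_period_s, prominence_frac
    ).with_flows(d_cm)

    baseline_flow = float(base_beats.flow.mean())
    peak_flow = peak_flow_3beats(post_beats, t_rel)

    flags: list[str] = []
    first_gap = float(post_beats.onsets[0] - t_rel)
    if first_gap > DELAYED_INSONATION_GAP_S:
        flags.append("delayed_insonation")
    delta = peak_flow - baseline_flow
    if delta < 0:
        flags.append("no_hyperemia")
        warnings.warn("peak flow below baseline (no hyperemia)", stacklevel=2)

    return HyperemiaMetrics(baseline_flow=baseline_flow, peak_flow=peak_flow,
                            delta_flow=delta, diameter_cm=d_cm,
                            n_baseline_beats=len(base_beats),
                            n_post_beats=len(post_beats), flags=flags)
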