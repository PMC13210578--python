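"""Synthetic physiological-trace and cohort generators with known ground truth.

Every generator is a pure function of its config (including the seed) and
returns, alongside the signal(s), the protocol events and a ground-truth
record of the generating parameters, so each analysis stage can be tested by
round-trip without participant data.

The default parameter values emulate the study conditions these analyses are
built for: SmO2 baseline plateau in the mid-60s %, near-linear desaturation at
about -0.06 %/s over a 3 min thigh-cuff occlusion, mono-exponential
reoxygenation with a hyperemic overshoot, a 3 min steady-state cycling bout
with an exponential SmO2 drop and recovery (tau ~ 14.5 s), and a femoral
reactive-hyperemia flow envelope stepping from ~70 to ~1400 mL/min at cuff
release.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .core import ConfigError, ProtocolEvents, SampledTrace

__all__ = [
    "CuffSimConfig",
    "SseSimConfig",
    "DopplerSimConfig",
    "MetricSpec",
    "CohortSimConfig",
    "CpetSimConfig",
    "gen_cuff_trace",
    "gen_sse_trace",
    "gen_doppler",
    "gen_cohort",
    "gen_cpet",
]


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------

@dataclass
class CuffSimConfig:
    """Forward model of a vascular-occlusion-test SmO2 trace.

    Phases: baseline plateau -> linear desaturation during occlusion ->
    mono-exponential reoxygenation toward ``baseline + overshoot`` with time
    constant ``tau_true`` -> slow exponential relaxation of the overshoot back
    to baseline.  ``i_true`` (the reoxygenation increment, peak minus the
    value at release) defaults to ``|desat_slope|*occl_duration_s +
    overshoot_pct``.
    """

    baseline_pct: float = 65.0
    desat_slope: float = -0.06          # %/s, negative during occlusion
    occl_duration_s: float = 180.0
    tau_true: float = 10.0              # s, reoxygenation time constant
    overshoot_pct: float = 5.0          # % above baseline at hyperemic peak
    i_true: float | None = None         # %, peak - SmO2(release); derived if None
    return_tau_s: float = 60.0          # s, overshoot relaxation
    baseline_duration_s: float = 60.0
    post_duration_s: float = 180.0
    rate_hz: float = 10.0
    noise_sd: float = 0.5               # % SmO2, additive i.i.d. Gaussian
    dropout_prob: float = 0.0           # per-sample missing probability
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_pct < 100.0:
            raise ConfigError("baseline_pct must be in (0, 100)")
        if self.desat_slope >= 0:
            raise ConfigError("desat_slope must be negative")
        if self.tau_true <= 0 or self.return_tau_s <= 0:
            raise ConfigError("time constants must be > 0")
        if self.noise_sd < 0 or not 0 <= self.dropout_prob < 1:
            raise ConfigError("invalid noise_sd or dropout_prob")
        floor = self.baseline_pct + self.desat_slope * self.occl_duration_s
        if floor <= 0:
            raise ConfigError("desaturation reaches the 0% floor before release")
        if self.i_true is None:
            self.i_true = self.baseline_pct + self.overshoot_pct - floor
        if self.i_true <= 0 or floor + self.i_true > 100.0:
            raise ConfigError(
                "i_true inconsistent with slope x duration and the SmO2 range")

    @property
    def min_at_release(self) -> float:
        return self.baseline_pct + self.desat_slope * self.occl_duration_s

    @property
    def peak_pct(self) -> float:
        return self.min_at_release + self.i_true


@dataclass
class SseSimConfig:
    """Forward model of a steady-state-exercise SmO2 trace.

    Baseline plateau -> exponential approach to ``baseline - drop_pct`` with
    ``onset_tau_s`` during exercise -> mono-exponential recovery to baseline
    with ``rec_tau_true`` after exercise ends.
    """

    baseline_pct: float = 68.0
    drop_pct: float = 7.8
    onset_tau_s: float = 25.0
    exercise_duration_s: float = 180.0
    rec_tau_true: float = 14.5
    baseline_duration_s: float = 60.0
    post_duration_s: float = 180.0
    rate_hz: float = 10.0
    noise_sd: float = 0.5
    dropout_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_pct < 100.0:
            raise ConfigError("baseline_pct must be in (0, 100)")
        if not 0.0 <= self.drop_pct < self.baseline_pct:
            raise ConfigError("drop_pct must satisfy 0 <= drop < baseline")
        if self.rec_tau_true <= 0 or self.onset_tau_s <= 0:
            raise ConfigError("time constants must be > 0")
        if self.noise_sd < 0 or not 0 <= self.dropout_prob < 1:
            raise ConfigError("invalid noise_sd or dropout_prob")


@dataclass
class DopplerSimConfig:
    """Forward model of pulsatile femoral velocity with a hyperemic envelope.

    Beats are half-sinusoid velocity pulses on a regular grid (period
    ``60/hr_bpm``), each scaled so the beat's time-averaged mean velocity x
    lumen area x 60 equals the envelope flow at that beat onset.  The envelope
    is ``baseline_flow`` before cuff inflation, ~0 during occlusion, steps to
    ``peak_flow`` at release and decays exponentially back to baseline.
    """

    baseline_flow: float = 70.0         # mL/min
    peak_flow: float = 1400.0           # mL/min
    decay_tau_s: float = 30.0
    hr_bpm: float = 70.0
    diameter_cm: float = 0.6
    baseline_duration_s: float = 60.0
    occl_duration_s: float = 180.0
    post_duration_s: float = 180.0
    rate_hz: float = 100.0
    noise_sd: float = 0.5               # cm/s on the velocity samples
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.peak_flow >= self.baseline_flow > 0:
            raise ConfigError("need peak_flow >= baseline_flow > 0")
        if not 30.0 < self.hr_bpm < 220.0:
            raise ConfigError("hr_bpm must be in (30, 220)")
        if self.diameter_cm <= 0:
            raise ConfigError("diameter_cm must be > 0")
        if self.decay_tau_s <= 0 or self.noise_sd < 0:
            raise ConfigError("invalid decay_tau_s or noise_sd")


@dataclass
class MetricSpec:
    """One metric of a paired pre/post cohort.

    ``effect_d`` is the true standardized effect (post minus pre in pooled-SD
    units); ``rho`` the within-subject pre/post correlation.
    """

    name: str
    mean_pre: float
    sd_pre: float
    effect_d: float = 0.0
    sd_post: float | None = None
    rho: float = 0.7

    def __post_init__(self) -> None:
        if self.sd_pre <= 0 or (self.sd_post is not None and self.sd_post <= 0):
            raise ConfigError("SDs must be > 0")
        if abs(self.rho) > 1:
            raise ConfigError("|rho| must be <= 1 (covariance not positive definite)")


@dataclass
class CohortSimConfig:
    """Paired pre/post cohort with configurable per-metric effects."""

    metrics: Sequence[MetricSpec] = field(default_factory=list)
    n_subjects: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ConfigError("n_subjects must be >= 2")
        if not self.metrics:
            raise ConfigError("at least one MetricSpec required")


@dataclass
class CpetSimConfig:
    """Incremental ramp test: power steps up until exhaustion, VO2 saturates.

    Power starts at ``start_power_w`` and increases ``increment_w`` every
    ``step_s`` up to ``ppo_w``; VO2 follows the power linearly until it
    plateaus at ``vo2max_lmin`` (held for ``plateau_s``); HR rises toward
    ``hr_max_bpm``.
    """

    vo2max_lmin: float = 3.6
    ppo_w: float = 300.0
    hr_max_bpm: float = 186.0
    vo2_rest_lmin: float = 0.5
    hr_rest_bpm: float = 70.0
    start_power_w: float = 100.0
    increment_w: float = 5.0
    step_s: float = 15.0
    plateau_s: float = 60.0
    rate_hz: float = 1.0
    noise_sd_lmin: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppo_w <= self.start_power_w:
            raise ConfigError("ppo_w must exceed start_power_w")
        if self.vo2max_lmin <= self.vo2_rest_lmin:
            raise ConfigError("vo2max must exceed resting VO2")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _apply_noise(values: np.ndarray, rng: np.random.Generator, noise_sd: float,
                 dropout_prob: float, clip: tuple[float, float] | None) -> np.ndarray:
    out = values.copy()
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd, size=out.size)
    if clip is not None:
        out = np.clip(out, *clip)
    if dropout_prob > 0:
        out[rng.random(out.size) < dropout_prob] = np.nan
    return out


def gen_cuff_trace(cfg: CuffSimConfig) -> tuple[SampledTrace, ProtocolEvents, dict]:
    """Simulate a cuff-occlusion SmO2 trace; see :class:`CuffSimConfig`."""
    rng = np.random.default_rng(cfg.seed)
    t_inflate = cfg.baseline_duration_s
    t_release = t_inflate + cfg.occl_duration_s
    total = t_release + cfg.post_duration_s
    t = np.arange(0.0, total, 1.0 / cfg.rate_hz)
    v = np.full(t.size, cfg.baseline_pct)

    occl = (t >= t_inflate) & (t < t_release)
    v[occl] = cfg.baseline_pct + cfg.desat_slope * (t[occl] - t_inflate)

    # recovery: pure mono-exponential rise toward the hyperemic peak until it
    # is 99% complete, then exponential relaxation of the overshoot to baseline
    rec = t >= t_release
    s = t[rec] - t_release
    peak, i_true = cfg.peak_pct, cfg.i_true
    s_pk = cfg.tau_true * np.log(100.0)        # 99% completion of the rise
    rise = peak - i_true * np.exp(-s / cfg.tau_true)
    v_pk = peak - 0.01 * i_true
    relax = cfg.baseline_pct + (v_pk - cfg.baseline_pct) * np.exp(
        -(s - s_pk) / cfg.return_tau_s)
    v[rec] = np.where(s <= s_pk, rise, relax)

    vals = _apply_noise(v, rng, cfg.noise_sd, cfg.dropout_prob, (0.0, 100.0))
    trace = SampledTrace(vals, rate=cfg.rate_hz, channel="smo2_pct", units="%")
    events = ProtocolEvents(cuff_inflate_t=t_inflate, cuff_release_t=t_release)
    truth = asdict(cfg) | {
        "kind": "cuff",
        "t_inflate": t_inflate,
        "t_release": t_release,
        "min_at_release": cfg.min_at_release,
        "peak_pct": cfg.peak_pct,
    }
    return trace, events, truth


def gen_sse_trace(cfg: SseSimConfig) -> tuple[SampledTrace, ProtocolEvents, dict]:
    """Simulate a steady-state-exercise SmO2 trace; see :class:`SseSimConfig`."""
    rng = np.random.default_rng(cfg.seed)
    t_start = cfg.baseline_duration_s
    t_end = t_start + cfg.exercise_duration_s
    total = t_end + cfg.post_duration_s
    t = np.arange(0.0, total, 1.0 / cfg.rate_hz)
    v = np.full(t.size, cfg.baseline_pct)

    ex = (t >= t_start) & (t < t_end)
    v[ex] = cfg.baseline_pct - cfg.drop_pct * (
        1.0 - np.exp(-(t[ex] - t_start) / cfg.onset_tau_s))
    v_end = cfg.baseline_pct - cfg.drop_pct * (
        1.0 - np.exp(-cfg.exercise_duration_s / cfg.onset_tau_s))

    rec = t >= t_end
    v[rec] = cfg.baseline_pct - (cfg.baseline_pct - v_end) * np.exp(
        -(t[rec] - t_end) / cfg.rec_tau_true)

    vals = _apply_noise(v, rng, cfg.noise_sd, cfg.dropout_prob, (0.0, 100.0))
    trace = SampledTrace(vals, rate=cfg.rate_hz, channel="smo2_pct", units="%")
    events = ProtocolEvents(exercise_start_t=t_start, exercise_end_t=t_end)
    truth = asdict(cfg) | {
        "kind": "sse",
        "t_start": t_start,
        "t_end": t_end,
        "value_at_end": float(v_end),
        "i_true_bl": float(cfg.baseline_pct - v_end),
    }
    return trace, events, truth


def gen_doppler(cfg: DopplerSimConfig
                ) -> tuple[SampledTrace, SampledTrace, ProtocolEvents, dict]:
    """Simulate pulsatile velocity + constant diameter; see :class:`DopplerSimConfig`.

    Beat onsets are aligned so one falls exactly at cuff release; the first
    post-release beat therefore carries exactly ``peak_flow``.
    """
    rng = np.random.default_rng(cfg.seed)
    t_inflate = cfg.baseline_duration_s
    t_release = t_inflate + cfg.occl_duration_s
    total = t_release + cfg.post_duration_s
    dt = 1.0 / cfg.rate_hz
    n = int(round(total / dt))
    t = np.arange(n) * dt
    v = np.zeros(n)

    period = 60.0 / cfg.hr_bpm
    area = np.pi * (cfg.diameter_cm / 2.0) ** 2        # cm^2

    def beat_flow(onset: float) -> float:
        if onset < t_inflate:
            return cfg.baseline_flow
        if onset < t_release:
            return 0.0
        return cfg.baseline_flow + (cfg.peak_flow - cfg.baseline_flow) * np.exp(
            -(onset - t_release) / cfg.decay_tau_s)

    # onsets on a grid anchored at release (one onset exactly at t_release)
    k_min = -int(np.floor(t_release / period))
    k_max = int(np.floor((total - t_release) / period))
    onsets = [t_release + k * period for k in range(k_min, k_max)]
    beats = []
    for onset in onsets:
        q = beat_flow(onset)
        if q <= 0:
            continue
        vb = q * np.pi / (120.0 * area)                # peak velocity, cm/s
        i0 = int(np.ceil(onset / dt - 1e-9))
        i1 = min(int(np.ceil((onset + period) / dt - 1e-9)), n)
        s = t[i0:i1] - onset
        v[i0:i1] = vb * np.sin(np.pi * s / period)
        beats.append({"onset_s": onset, "flow_ml_min": q})

    if cfg.noise_sd > 0:
        v = np.clip(v + rng.normal(0.0, cfg.noise_sd, size=n), 0.0, None)

    vel = SampledTrace(v, rate=cfg.rate_hz, channel="velocity_cms", units="cm/s")
    dia = SampledTrace(np.full(int(round(total * 10)), cfg.diameter_cm),
                       rate=10.0, channel="diameter_cm", units="cm")
    events = ProtocolEvents(cuff_inflate_t=t_inflate, cuff_release_t=t_release,
                            baseline_window_s=60.0)

    post_flows = np.array([b["flow_ml_min"] for b in beats
                           if b["onset_s"] >= t_release - 1e-9])
    peak3 = float(max(np.convolve(post_flows, np.ones(3) / 3.0, mode="valid"))
                  ) if post_flows.size >= 3 else float("nan")
    truth = asdict(cfg) | {
        "kind": "doppler",
        "t_inflate": t_inflate,
        "t_release": t_release,
        "beats": beats,
        "peak_flow_3beat_expected": peak3,
    }
    return vel, dia, events, truth


def gen_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw a paired pre/post cohort: bivariate normal per metric.

    Returns a tidy frame with columns ``subject_id, metric, pre, post`` and
    the generating parameters (including each metric's true post mean).
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    truth_metrics = {}
    for m in cfg.metrics:
        sd_post = m.sd_post if m.sd_post is not None else m.sd_pre
        pooled = np.sqrt((m.sd_pre ** 2 + sd_post ** 2) / 2.0)
        mean_post = m.mean_pre + m.effect_d * pooled
        z1 = rng.standard_normal(cfg.n_subjects)
        z2 = m.rho * z1 + np.sqrt(max(1.0 - m.rho ** 2, 0.0)) * rng.standard_normal(
            cfg.n_subjects)
        pre = m.mean_pre + m.sd_pre * z1
        post = mean_post + sd_post * z2
        for i in range(cfg.n_subjects):
            rows.append({"subject_id": f"S{i + 1:02d}", "metric": m.name,
                         "pre": pre[i], "post": post[i]})
        truth_metrics[m.name] = asdict(m) | {
            "mean_post": float(mean_post), "sd_post": float(sd_post)}
    table = pd.DataFrame(rows)
    truth = {"n_subjects": cfg.n_subjects, "seed": cfg.seed,
             "metrics": truth_metrics}
    return table, truth


def gen_cpet(cfg: CpetSimConfig
             ) -> tuple[SampledTrace, SampledTrace, SampledTrace, dict]:
    """Simulate aligned VO2/HR/power series for an incremental ramp test."""
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round((cfg.ppo_w - cfg.start_power_w) / cfg.increment_w)) + 1
    ramp_s = n_steps * cfg.step_s
    total = ramp_s + cfg.plateau_s
    t = np.arange(0.0, total, 1.0 / cfg.rate_hz)
    power = np.minimum(
        cfg.start_power_w + cfg.increment_w * np.floor(t / cfg.step_s), cfg.ppo_w)
    # VO2 tracks power linearly, saturating at vo2max
    frac = (power - cfg.start_power_w) / (cfg.ppo_w - cfg.start_power_w)
    vo2_drive = cfg.vo2_rest_lmin + (cfg.vo2max_lmin - cfg.vo2_rest_lmin) * (
        0.3 + 0.7 * frac)
    vo2 = np.minimum(vo2_drive, cfg.vo2max_lmin)
    hr = cfg.hr_rest_bpm + (cfg.hr_max_bpm - cfg.hr_rest_bpm) * np.clip(
        t / ramp_s, 0.0, 1.0)
    if cfg.noise_sd_lmin > 0:
        vo2 = vo2 + rng.normal(0.0, cfg.noise_sd_lmin, t.size)
        hr = hr + rng.normal(0.0, 1.0, t.size)
    mk = lambda vals, ch, u: SampledTrace(vals, rate=cfg.rate_hz, channel=ch, units=u)
    truth = asdict(cfg) | {"kind": "cpet", "duration_s": float(total)}
    return (mk(vo2, "vo2_lmin", "L/min"), mk(hr, "hr_bpm", "bpm"),
            mk(power, "power_w", "W"), truth)
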