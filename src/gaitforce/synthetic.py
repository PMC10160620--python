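"""Synthetic in-shoe force recordings with known ground truth.

The generator emulates the statistical structure that the analysis
pipeline assumes, so every downstream stage can be tested against exact,
pre-noise ground truth instead of a downloaded archive:

* two-peak vertical ground reaction force stance profiles
  ``A * (sin(pi*u) + r * sin(3*pi*u))`` on normalized stance position u,
* Gaussian stride-to-stride timing with configurable mean and CV,
* a left/right stance-duration offset creating gait asymmetry,
* decomposition of each foot's force into 8 sensor channels,
* truncated Gaussian sensor noise, a 2 s startup ramp, and periodic
  turn segments (three strides with 1.5x inflated duration) mimicking
  turns at the ends of a walking corridor.

Double support is emergent: each stance lasts ``(0.5 + dsf)`` of the
local stride, so consecutive contralateral stances overlap by ``dsf`` of
a stride on each side. Ground-truth events and per-stride features are
recorded before sampling and noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .exceptions import ConfigError
from .io_gaitdb import SensorTrace, SubjectMeta

G_MPS2 = 9.80665

#: heel-to-forefoot load sharing of the 8 insole sensors (sums to 1)
DEFAULT_SENSOR_WEIGHTS = (0.16, 0.14, 0.12, 0.10, 0.10, 0.12, 0.13, 0.13)

STARTUP_RAMP_S = 2.0
TURN_STRIDES = 3          # strides per turn segment
TURN_INFLATION = 1.5      # stride-time multiplier inside a turn


def stance_profile(u, amplitude_bw: float, shape_ratio: float):
    """Two-peak stance force profile in body weights.

    ``f(u) = A * (sin(pi*u) + r * sin(3*pi*u))`` for normalized stance
    position ``u in [0, 1]``. The profile is zero at foot-strike (u=0) and
    toe-off (u=1) and, for ``r > 1/9``, shows the canonical loading and
    push-off maxima flanking a midstance minimum.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u < 0) or np.any(u > 1):
        raise ConfigError("normalized stance position must lie in [0, 1]")
    r = shape_ratio
    if not 0 <= r < 1:
        raise ConfigError("shape ratio must lie in [0, 1)")
    out = amplitude_bw * (np.sin(np.pi * u) + r * np.sin(3 * np.pi * u))
    return float(out) if out.ndim == 0 else out


def stance_profile_peak(shape_ratio: float) -> tuple[float, float]:
    """Location and value of the first local maximum of the unit profile.

    Returns ``(u*, f*)`` with ``f* = sin(pi*u*) + r*sin(3*pi*u*)``. For
    ``r <= 1/9`` the profile is single-peaked at midstance.
    """
    r = shape_ratio
    if r <= 1.0 / 9.0:
        return 0.5, 1.0 - r
    deriv = lambda u: math.cos(math.pi * u) + 3 * r * math.cos(3 * math.pi * u)
    u_star = brentq(deriv, 1e-9, 0.5 - 1e-9)
    return u_star, math.sin(math.pi * u_star) + r * math.sin(3 * math.pi * u_star)


@dataclass
class GaitProfileParams:
    """Free parameters of one simulated subject.

    Defaults describe a healthy adult walking at a self-selected ~1.15 m/s:
    stride time 1100 ms with 2.2% stride-to-stride CV, stance occupying
    63.5% of the stride (double support fraction 0.135 per side), and a
    1.25 BW profile amplitude.
    """

    subject_id: str = "S01"
    group: str = "control"
    amplitude_bw: float = 1.25
    shape_ratio: float = 0.40
    body_mass_kg: float = 73.0
    stride_time_mean_ms: float = 1100.0
    stride_time_cv_pct: float = 2.2
    double_support_fraction_mean: float = 0.135
    asymmetry_offset_ms: float = 0.0
    amplitude_jitter_cv_pct: float = 0.0
    sensor_weights: Sequence[float] = DEFAULT_SENSOR_WEIGHTS
    sensor_noise_sd_n: float = 2.0
    walk_duration_s: float = 90.0
    speed_mps: float = 1.15
    turn_every_s: float = 0.0
    seed: int | None = None
    # demographics passed through to SubjectMeta
    sex: str = "unknown"
    age: float | None = None
    height_cm: float | None = None
    hoehn_yahr: float | None = None
    updrs: float | None = None
    tug_s: float | None = None

    @property
    def stance_fraction_mean(self) -> float:
        # stance = one single-support half-stride plus a double-support
        # overlap on each end: 0.5 + dsf of the stride
        return 0.5 + self.double_support_fraction_mean

    def validate(self) -> None:
        if not 0 < self.double_support_fraction_mean < 0.5:
            raise ConfigError(
                "double_support_fraction_mean must lie in (0, 0.5); "
                "stance_fraction <= 0.5 implies negative double support")
        if not 0 <= self.shape_ratio < 1:
            raise ConfigError("shape_ratio must lie in [0, 1)")
        if self.stride_time_cv_pct < 0:
            raise ConfigError("stride_time_cv_pct must be >= 0")
        w = np.asarray(self.sensor_weights, dtype=float)
        if w.shape != (8,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError("sensor_weights must be 8 nonnegative values "
                              "summing to 1 within 1e-9")
        if self.body_mass_kg <= 0:
            raise ConfigError("body_mass_kg must be positive")
        if self.walk_duration_s <= 0:
            raise ConfigError("walk_duration_s must be positive")


@dataclass
class GroundTruth:
    """Pre-noise events and per-stride features of a simulated subject.

    ``strides`` columns: foot, fs_s, next_fs_s, stride_ms, stance_ms,
    single_support_ms, ds_lead_ms, ds_trail_ms, peak_bw, is_turn.
    Events alternate FS -> TO per foot and all stances are positive.
    """

    subject_id: str
    group: str
    fs_left: np.ndarray
    to_left: np.ndarray
    fs_right: np.ndarray
    to_right: np.ndarray
    strides: pd.DataFrame


def _draw_steps(params: GaitProfileParams, rng: np.random.Generator):
    """Foot-strike schedule. Returns (fs_times, feet, turn_step_flags)."""
    step_mean = params.stride_time_mean_ms / 2000.0          # s
    # sqrt(2) so that stride time (sum of two independent steps) has the
    # requested CV
    step_sd = step_mean * params.stride_time_cv_pct * math.sqrt(2) / 100.0
    t = 0.3
    foot = 0  # 0 = left, 1 = right
    times, feet, turn_flags = [], [], []
    next_turn = params.turn_every_s if params.turn_every_s > 0 else math.inf
    turn_steps_left = 0
    # overshoot so the final strides have a defined next foot-strike
    horizon = params.walk_duration_s + 3 * step_mean
    while t < horizon:
        times.append(t)
        feet.append(foot)
        turn_flags.append(turn_steps_left > 0)
        d = rng.normal(step_mean, step_sd) if step_sd > 0 else step_mean
        d = max(d, 0.3 * step_mean)
        if turn_steps_left > 0:
            d *= TURN_INFLATION
            turn_steps_left -= 1
        elif t >= next_turn:
            turn_steps_left = 2 * TURN_STRIDES
            next_turn += params.turn_every_s
        t += d
        foot = 1 - foot
    return np.array(times), np.array(feet), np.array(turn_flags, dtype=bool)


def simulate_subject(params: GaitProfileParams,
                     signals: bool = True,
                     ) -> tuple[SensorTrace | None, SubjectMeta, GroundTruth]:
    """Simulate one subject's walk.

    With ``signals=False`` only events and ground truth are produced
    (cheap path for statistical calibration studies). Deterministic for a
    fixed ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    fs, feet, turn_step = _draw_steps(params, rng)
    n = len(fs)
    if n < 6:
        raise ConfigError("walk too short to contain any complete stride")

    sf = params.stance_fraction_mean
    # left stance lengthened, right shortened, by half the offset each
    stance_off = np.where(feet == 0, 0.5, -0.5) * params.asymmetry_offset_ms / 1000.0
    stride_local = np.full(n, np.nan)
    stride_local[: n - 2] = fs[2:] - fs[:-2]
    stride_local[n - 2:] = params.stride_time_mean_ms / 1000.0  # tail fallback
    stance = sf * stride_local + stance_off
    to = fs + stance
    # physicality clamp: walking requires the toe-off to fall inside the
    # contralateral stance (positive double support on both sides); the
    # irregular steps at turn boundaries can otherwise push it marginally
    # outside its window
    margin = 0.02
    to[: n - 2] = np.clip(to[: n - 2], fs[1: n - 1] + margin,
                          fs[2:] - margin)

    jitter_cv = params.amplitude_jitter_cv_pct / 100.0
    jit = rng.normal(0.0, jitter_cv, size=n) if jitter_cv > 0 else np.zeros(n)
    amp = params.amplitude_bw * (1.0 + jit)
    amp = np.maximum(amp, 0.1 * params.amplitude_bw)
    _, f_unit_peak = stance_profile_peak(params.shape_ratio)

    rows = []
    for i in range(1, n - 2):
        rows.append({
            "foot": "L" if feet[i] == 0 else "R",
            "fs_s": fs[i],
            "next_fs_s": fs[i + 2],
            "stride_ms": (fs[i + 2] - fs[i]) * 1000.0,
            "stance_ms": (to[i] - fs[i]) * 1000.0,
            "single_support_ms": (fs[i + 1] - to[i - 1]) * 1000.0,
            "ds_lead_ms": (to[i - 1] - fs[i]) * 1000.0,
            "ds_trail_ms": (to[i] - fs[i + 1]) * 1000.0,
            "peak_bw": amp[i] * f_unit_peak,
            "is_turn": bool(turn_step[i] or turn_step[i + 1]),
        })
    strides = pd.DataFrame(rows)
    if len(strides) and (strides["ds_lead_ms"].min() <= 0
                         or strides["ds_trail_ms"].min() <= 0):
        # systematic violations survive the physicality clamp only when
        # the parameters themselves are inconsistent
        raise ConfigError("parameters imply negative double support; "
                          "reduce cv or asymmetry_offset_ms")

    left = feet == 0
    gt = GroundTruth(
        subject_id=params.subject_id,
        group=params.group,
        fs_left=fs[left], to_left=to[left],
        fs_right=fs[~left], to_right=to[~left],
        strides=strides,
    )
    meta = SubjectMeta(
        subject_id=params.subject_id, group=params.group, sex=params.sex,
        age=params.age, height_cm=params.height_cm,
        body_mass_kg=params.body_mass_kg,
        walking_speed_mps=params.speed_mps, hoehn_yahr=params.hoehn_yahr,
        updrs=params.updrs, tug_s=params.tug_s)
    if not signals:
        return None, meta, gt

    dt = 0.01
    n_samp = int(round(params.walk_duration_s / dt))
    times = np.arange(n_samp) * dt
    bw_n = params.body_mass_kg * G_MPS2
    fz = np.zeros((n_samp, 2))
    for i in range(n):
        lo = int(math.ceil(fs[i] / dt))
        hi = min(int(math.floor(to[i] / dt)), n_samp - 1)
        if hi < lo:
            continue
        u = np.clip((times[lo:hi + 1] - fs[i]) / (to[i] - fs[i]), 0.0, 1.0)
        fz[lo:hi + 1, feet[i]] += bw_n * stance_profile(
            u, amp[i], params.shape_ratio)
    ramp = np.clip(times / STARTUP_RAMP_S, 0.0, 1.0)
    fz *= ramp[:, None]

    w = np.asarray(params.sensor_weights, dtype=float)
    channels = []
    for side in (0, 1):
        ch = fz[:, side:side + 1] * w[None, :]
        if params.sensor_noise_sd_n > 0:
            ch = ch + rng.normal(0.0, params.sensor_noise_sd_n, size=ch.shape)
        channels.append(np.maximum(ch, 0.0))
    trace = SensorTrace(
        subject_id=params.subject_id, sample_times=times,
        left_sensors=channels[0], right_sensors=channels[1],
        sampling_rate=1.0 / dt, body_mass_kg=params.body_mass_kg)
    return trace, meta, gt


# --------------------------------------------------------------------------
# cohort simulation


@dataclass
class GroupParams:
    """A group's subject template plus between-subject spreads.

    ``base`` holds within-subject settings; per-subject values are drawn
    around it. Walking speeds are drawn uniformly in
    ``[speed_lo, speed_hi]`` so that speed-band cohort selection is
    exercised. Clinical scores are drawn from the normal distributions
    given by the ``*_mean``/``*_sd`` pairs.
    """

    base: GaitProfileParams
    stride_time_bs_sd_ms: float = 80.0
    amplitude_bs_sd: float = 0.0
    cv_bs_sd_pct: float = 0.0
    asymmetry_bs_sd_ms: float = 0.0
    speed_lo: float = 1.0
    speed_hi: float = 1.3
    age_mean: float = 64.0
    age_sd: float = 9.0
    height_mean_cm: float = 168.0
    height_sd_cm: float = 8.0
    mass_mean_kg: float = 73.0
    mass_sd_kg: float = 12.0
    hoehn_yahr_mean: float = 0.0
    hoehn_yahr_sd: float = 0.0
    updrs_mean: float = 0.0
    updrs_sd: float = 0.0
    tug_mean_s: float = 10.0
    tug_sd_s: float = 1.4
    female_fraction: float = 0.4


def pd_group_params(**overrides) -> GroupParams:
    """Parkinson-like group settings.

    Stride timing, stance/double-support fractions, profile amplitude,
    asymmetry and clinical scores are centred on the values typical of
    speed-matched Parkinson cohorts (stride 1071 +/- 81 ms, CV 2.2%,
    stance 63.7% of stride, first force peak ~1.38 BW, single-support
    asymmetry ~6.5%).
    """
    _, f_peak = stance_profile_peak(0.40)
    base = GaitProfileParams(
        group="PD", amplitude_bw=1.38 / f_peak, shape_ratio=0.40,
        stride_time_mean_ms=1071.0, stride_time_cv_pct=2.2,
        double_support_fraction_mean=0.137, asymmetry_offset_ms=25.0,
        body_mass_kg=73.0, walk_duration_s=90.0, turn_every_s=22.0)
    gp = GroupParams(
        base=base, stride_time_bs_sd_ms=81.0,
        amplitude_bs_sd=0.21 / f_peak, cv_bs_sd_pct=0.8,
        asymmetry_bs_sd_ms=12.0,
        age_mean=63.0, age_sd=9.0, height_mean_cm=167.0, height_sd_cm=7.0,
        mass_mean_kg=73.0, mass_sd_kg=11.0,
        hoehn_yahr_mean=2.2, hoehn_yahr_sd=0.3,
        updrs_mean=30.0, updrs_sd=10.0,
        tug_mean_s=10.8, tug_sd_s=1.8, female_fraction=18 / 54)
    for key, val in overrides.items():
        if hasattr(gp, key):
            setattr(gp, key, val)
        elif hasattr(base, key):
            setattr(base, key, val)
        else:
            raise ConfigError(f"unknown group parameter {key!r}")
    return gp


def control_group_params(**overrides) -> GroupParams:
    """Healthy-control group settings (speed-matched cohort magnitudes)."""
    _, f_peak = stance_profile_peak(0.40)
    base = GaitProfileParams(
        group="control", amplitude_bw=1.34 / f_peak, shape_ratio=0.40,
        stride_time_mean_ms=1107.0, stride_time_cv_pct=2.1,
        double_support_fraction_mean=0.131, asymmetry_offset_ms=17.0,
        body_mass_kg=74.0, walk_duration_s=90.0, turn_every_s=22.0)
    gp = GroupParams(
        base=base, stride_time_bs_sd_ms=80.0,
        amplitude_bs_sd=0.17 / f_peak, cv_bs_sd_pct=0.6,
        asymmetry_bs_sd_ms=8.0,
        age_mean=65.0, age_sd=9.0, height_mean_cm=169.0, height_sd_cm=9.0,
        mass_mean_kg=74.0, mass_sd_kg=13.0,
        hoehn_yahr_mean=0.0, hoehn_yahr_sd=0.0,
        updrs_mean=0.0, updrs_sd=1.0,
        tug_mean_s=10.0, tug_sd_s=1.4, female_fraction=16 / 39)
    for key, val in overrides.items():
        if hasattr(gp, key):
            setattr(gp, key, val)
        elif hasattr(base, key):
            setattr(base, key, val)
        else:
            raise ConfigError(f"unknown group parameter {key!r}")
    return gp


def _draw_subject_params(gp: GroupParams, subject_id: str, seed: int,
                         rng: np.random.Generator) -> GaitProfileParams:
    b = gp.base
    stride = rng.normal(b.stride_time_mean_ms, gp.stride_time_bs_sd_ms) \
        if gp.stride_time_bs_sd_ms > 0 else b.stride_time_mean_ms
    if gp.cv_bs_sd_pct > 0:
        cv = float(np.clip(rng.normal(b.stride_time_cv_pct, gp.cv_bs_sd_pct),
                           0.2, 15.0))
    else:
        cv = b.stride_time_cv_pct
    amp = rng.normal(b.amplitude_bw, gp.amplitude_bs_sd) \
        if gp.amplitude_bs_sd > 0 else b.amplitude_bw
    asym = rng.normal(b.asymmetry_offset_ms, gp.asymmetry_bs_sd_ms) \
        if gp.asymmetry_bs_sd_ms > 0 else b.asymmetry_offset_ms
    speed = rng.uniform(gp.speed_lo, gp.speed_hi)
    mass = max(rng.normal(gp.mass_mean_kg, gp.mass_sd_kg), 40.0)
    return replace(
        b, subject_id=subject_id, seed=seed,
        stride_time_mean_ms=max(stride, 600.0),
        stride_time_cv_pct=cv,
        amplitude_bw=max(amp, 0.6),
        asymmetry_offset_ms=abs(asym),
        speed_mps=speed, body_mass_kg=mass,
        sex="F" if rng.uniform() < gp.female_fraction else "M",
        age=rng.normal(gp.age_mean, gp.age_sd),
        height_cm=rng.normal(gp.height_mean_cm, gp.height_sd_cm),
        hoehn_yahr=max(rng.normal(gp.hoehn_yahr_mean, gp.hoehn_yahr_sd), 0.0)
        if gp.hoehn_yahr_sd > 0 else gp.hoehn_yahr_mean,
        updrs=max(rng.normal(gp.updrs_mean, gp.updrs_sd), 0.0)
        if gp.updrs_sd > 0 else gp.updrs_mean,
        tug_s=max(rng.normal(gp.tug_mean_s, gp.tug_sd_s), 4.0),
    )


def simulate_cohort(pd_params: GroupParams, control_params: GroupParams,
                    n_pd: int, n_control: int, seed: int,
                    signals: bool = True,
                    ) -> tuple[list[SensorTrace | None], list[SubjectMeta],
                               list[GroundTruth]]:
    """Simulate a two-group cohort with per-subject parameter draws.

    Subject-level randomness (parameter draws and walk realizations) is
    fully determined by ``seed``. Subjects are ordered PD first, then
    controls, with ids ``PD01..`` / ``CO01..``.
    """
    if n_pd < 1 or n_control < 1:
        raise ConfigError("need at least one subject per group")
    ss = np.random.SeedSequence(seed)
    draw_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = [int(s.generate_state(1)[0] % (2**31 - 1))
                   for s in ss.spawn(n_pd + n_control)]
    traces, metas, gts = [], [], []
    specs = [(pd_params, f"PD{i + 1:02d}") for i in range(n_pd)] + \
            [(control_params, f"CO{i + 1:02d}") for i in range(n_control)]
    for (gp, sid), child in zip(specs, child_seeds):
        sp = _draw_subject_params(gp, sid, child, draw_rng)
        trace, meta, gt = simulate_subject(sp, signals=signals)
        traces.append(trace)
        metas.append(meta)
        gts.append(gt)
    return traces, metas, gts


def simulate_mean_stance_curves(n_subjects: int, rng: np.random.Generator,
                                amplitude_bw: float = 1.35,
                                amplitude_sd: float = 0.17,
                                shape_ratio: float = 0.40,
                                shape_sd: float = 0.02,
                                n_points: int = 101) -> np.ndarray:
    """Subject-mean stance curves drawn directly from the profile family.

    Lightweight sampler for statistical calibration studies: each row is
    one subject's mean normalized stance curve (BW) with between-subject
    variation in amplitude and shape. Endpoints are exactly zero for all
    subjects (the profile vanishes at foot-strike and toe-off).
    """
    u = np.linspace(0.0, 1.0, n_points)
    amps = rng.normal(amplitude_bw, amplitude_sd, size=n_subjects)
    ratios = np.clip(rng.normal(shape_ratio, shape_sd, size=n_subjects),
                     0.0, 0.9)
    return np.stack([stance_profile(u, a, r) for a, r in zip(amps, ratios)])
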