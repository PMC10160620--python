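"""Per-stride temporal and kinetic gait variables and per-subject summaries.

Temporal variables follow the standard event algebra: stride time is the
interval between two consecutive foot-strikes of the same foot, stance
from foot-strike to toe-off of that foot, single support between toe-off
and foot-strike of the contralateral foot (equivalent to the
contralateral swing), and double support between the foot-strike of one
foot and the toe-off of the contralateral foot. Per stride the double
support is reported as the mean of its leading and trailing components,
so that one stride contributes one number on the same scale as the
conventional single "double support time" column (~13–14% of stride,
not the ~27% a sum of both components would give); the sum is available
via ``double_support_mode="sum"``.

Force variables are normalized by body weight. The loading and push-off
peaks are the maxima of the first and second halves of stance (split at
50% of stance duration, earliest-sample tie-break), which stays defined
for flat or single-peaked pathological strides. The weight-transfer pair
uses strict local maxima: the first local maximum of the front foot's
force after its foot-strike and the last local maximum of the back
foot's force before its toe-off.

Asymmetry uses the classic symmetry index
``SI = |x_R - x_L| / (0.5 (x_R + x_L)) * 100`` (0 for perfect symmetry)
and stride-to-stride variability the coefficient of variation
``CV = 100 * sd / mean`` with the n-1 sample standard deviation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, InsufficientStridesError
from .events import StrideFrame
from .io_gaitdb import SubjectMeta
from .preprocess import ForceSignal

STANCE_GRID_POINTS = 101

#: variables summarized per subject (means, CVs, symmetry indices)
TEMPORAL_VARS = (
    "stride_time_ms", "single_support_ms", "single_support_pct",
    "double_support_ms", "double_support_pct",
    "stance_time_ms", "stance_pct",
)
FORCE_VARS = (
    "fz_peak1_bw", "t_peak1_ms", "t_peak1_pct",
    "fz_peak2_bw", "t_peak2_ms", "t_peak2_pct",
    "fz_tot_peak_bw", "t_tot_peak_ms", "t_tot_peak_pct",
    "fz_peak_front_bw", "fz_peak_back_bw", "delta_fz_bw",
    "gwt_ms", "abs_gwt_ms",
)
ALL_VARS = TEMPORAL_VARS + FORCE_VARS


@dataclass
class StrideRecord:
    """All temporal and force features of one gait cycle of one foot."""

    foot: str
    fs_s: float
    stride_time_ms: float = math.nan
    stance_time_ms: float = math.nan
    stance_pct: float = math.nan
    single_support_ms: float = math.nan
    single_support_pct: float = math.nan
    double_support_ms: float = math.nan
    double_support_pct: float = math.nan
    ds_lead_ms: float = math.nan
    ds_trail_ms: float = math.nan
    fz_peak1_bw: float = math.nan
    t_peak1_ms: float = math.nan
    t_peak1_pct: float = math.nan
    fz_peak2_bw: float = math.nan
    t_peak2_ms: float = math.nan
    t_peak2_pct: float = math.nan
    fz_tot_peak_bw: float = math.nan
    t_tot_peak_ms: float = math.nan
    t_tot_peak_pct: float = math.nan
    fz_peak_front_bw: float = math.nan
    fz_peak_back_bw: float = math.nan
    delta_fz_bw: float = math.nan
    gwt_ms: float = math.nan
    abs_gwt_ms: float = math.nan
    excluded: bool = False
    exclusion_reason: str = ""
    qc_notes: str = ""

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class SubjectSummary:
    """Per-subject means (L/R averaged), CVs and symmetry indices."""

    meta: SubjectMeta
    means: dict
    cvs: dict
    sis: dict
    n_strides_used: int
    mean_curve_fz: np.ndarray | None = None
    mean_curve_fztot: np.ndarray | None = None


def symmetry_index(x_right: float, x_left: float) -> float:
    """``SI = |x_R - x_L| / (0.5 (x_R + x_L)) * 100``; 0 = perfect symmetry."""
    denom = 0.5 * (x_right + x_left)
    if denom <= 0:
        raise AnalysisError("symmetry index undefined: x_R + x_L <= 0")
    return abs(x_right - x_left) / denom * 100.0


def coefficient_of_variation(values: Sequence[float], ddof: int = 1) -> float:
    """``CV = 100 * sd / mean`` with the n-1 sample SD by default."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise AnalysisError("CV undefined for fewer than 2 values")
    mean = float(np.mean(x))
    if mean <= 0:
        raise AnalysisError("CV undefined for non-positive mean")
    return 100.0 * float(np.std(x, ddof=ddof)) / mean


def temporal_features(frame: StrideFrame,
                      double_support_mode: str = "mean") -> StrideRecord:
    """Temporal part of a stride record from the event quintuple."""
    rec = StrideRecord(foot=frame.foot, fs_s=frame.fs_s)
    if not frame.valid:
        rec.excluded = True
        rec.exclusion_reason = frame.reason or "invalid_frame"
        return rec
    stride_ms = (frame.next_fs_s - frame.fs_s) * 1000.0
    rec.stride_time_ms = stride_ms
    rec.stance_time_ms = (frame.to_s - frame.fs_s) * 1000.0
    rec.single_support_ms = (frame.contralateral_fs_s
                             - frame.contralateral_to_s) * 1000.0
    rec.ds_lead_ms = (frame.contralateral_to_s - frame.fs_s) * 1000.0
    rec.ds_trail_ms = (frame.to_s - frame.contralateral_fs_s) * 1000.0
    if double_support_mode == "mean":
        rec.double_support_ms = 0.5 * (rec.ds_lead_ms + rec.ds_trail_ms)
    elif double_support_mode == "sum":
        rec.double_support_ms = rec.ds_lead_ms + rec.ds_trail_ms
    elif double_support_mode == "lead":
        # per-foot convention: the double support initiated by this
        # foot's strike; the only convention under which a left/right
        # double-support asymmetry is expressible (the mean of both
        # components is identical for the two feet by construction)
        rec.double_support_ms = rec.ds_lead_ms
    else:
        raise AnalysisError(f"unknown double_support_mode {double_support_mode!r}")
    rec.stance_pct = 100.0 * rec.stance_time_ms / stride_ms
    rec.single_support_pct = 100.0 * rec.single_support_ms / stride_ms
    rec.double_support_pct = 100.0 * rec.double_support_ms / stride_ms
    return rec


def force_peaks(fz_stance: np.ndarray, stance_times: np.ndarray,
                body_weight_n: float, fs_time_s: float,
                stride_time_ms: float) -> dict:
    """Loading / push-off peaks of one stance segment.

    Halves are split at 50% of stance duration; within each half the
    maximum is taken, tie-broken to the earliest sample. Peak times are
    relative to the foot-strike, in ms and % of stride.
    """
    if len(fz_stance) < 5:
        raise AnalysisError("stance segment too short for peak extraction")
    if body_weight_n is None or body_weight_n <= 0:
        raise AnalysisError("body weight required for BW normalization "
                            "(no body mass in demographics?)")
    rel = stance_times - fs_time_s
    stance_dur = rel[-1]
    first = rel < 0.5 * stance_dur
    out = {}
    for name, mask in (("1", first), ("2", ~first)):
        seg = fz_stance[mask]
        i = int(np.argmax(seg))                      # earliest on ties
        t_ms = float(rel[mask][i]) * 1000.0
        out[f"fz_peak{name}_bw"] = float(seg[i]) / body_weight_n
        out[f"t_peak{name}_ms"] = t_ms
        out[f"t_peak{name}_pct"] = 100.0 * t_ms / stride_time_ms
    return out


def total_peak(fz_tot_stance: np.ndarray, stance_times: np.ndarray,
               body_weight_n: float, fs_time_s: float,
               stride_time_ms: float) -> dict:
    """Peak of the two-foot total force over the reference foot's stance."""
    if body_weight_n is None or body_weight_n <= 0:
        raise AnalysisError("body weight required for BW normalization")
    i = int(np.argmax(fz_tot_stance))
    t_ms = float(stance_times[i] - fs_time_s) * 1000.0
    return {"fz_tot_peak_bw": float(fz_tot_stance[i]) / body_weight_n,
            "t_tot_peak_ms": t_ms,
            "t_tot_peak_pct": 100.0 * t_ms / stride_time_ms}


def _strict_local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices i with x[i-1] < x[i] > x[i+1] (interior, strict)."""
    if len(x) < 3:
        return np.array([], dtype=int)
    return np.where((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:]))[0] + 1


def weight_transfer(fz_front: np.ndarray, fz_back: np.ndarray,
                    times: np.ndarray, front_fs_s: float, back_to_s: float,
                    body_weight_n: float) -> dict:
    """Force and timing of the weight transfer between the two feet.

    ``fz_peak_front`` is the value at the first strict local maximum of
    the front foot's force at or after its foot-strike; ``fz_peak_back``
    the value at the last strict local maximum of the back foot's force
    at or before its toe-off. ``delta_fz = front - back`` (signed, BW)
    and ``gwt = t(front max) - t(back max)`` in ms (signed; its
    magnitude is also reported for comparability with studies quoting a
    duration).
    """
    if body_weight_n is None or body_weight_n <= 0:
        raise AnalysisError("body weight required for BW normalization")
    front_cand = _strict_local_maxima(fz_front)
    front_cand = front_cand[times[front_cand] >= front_fs_s]
    back_cand = _strict_local_maxima(fz_back)
    back_cand = back_cand[times[back_cand] <= back_to_s]
    if len(front_cand) == 0 or len(back_cand) == 0:
        raise AnalysisError("no local force maximum in the weight-transfer "
                            "search window")
    i_front = int(front_cand[0])
    i_back = int(back_cand[-1])
    gwt_ms = (times[i_front] - times[i_back]) * 1000.0
    return {
        "fz_peak_front_bw": float(fz_front[i_front]) / body_weight_n,
        "fz_peak_back_bw": float(fz_back[i_back]) / body_weight_n,
        "delta_fz_bw": float(fz_front[i_front] - fz_back[i_back]) / body_weight_n,
        "gwt_ms": float(gwt_ms),
        "abs_gwt_ms": abs(float(gwt_ms)),
    }


def normalize_stance(fz_stance: np.ndarray,
                     n_points: int = STANCE_GRID_POINTS) -> np.ndarray:
    """Linearly interpolate one stance segment onto a 0–100% grid."""
    if len(fz_stance) < 5:
        raise AnalysisError("stance too short to normalize")
    x_old = np.linspace(0.0, 100.0, len(fz_stance))
    x_new = np.linspace(0.0, 100.0, n_points)
    return np.interp(x_new, x_old, np.asarray(fz_stance, dtype=float))


def extract_stride(frame: StrideFrame, signal: ForceSignal,
                   double_support_mode: str = "mean") -> StrideRecord:
    """Full stride record: temporal algebra plus force features.

    Force-feature failures (e.g. no local maximum in the weight-transfer
    window) do not invalidate the stride; the affected fields stay NaN
    and are noted in ``qc_notes``.
    """
    rec = temporal_features(frame, double_support_mode)
    if rec.excluded:
        return rec
    own = signal.fz_left if frame.foot == "L" else signal.fz_right
    other = signal.fz_right if frame.foot == "L" else signal.fz_left
    sl = slice(frame.fs_idx, frame.to_idx + 1)
    stance_times = signal.sample_times[sl]
    notes = []
    try:
        rec_dict = force_peaks(own[sl], stance_times, signal.body_weight_n,
                               frame.fs_s, rec.stride_time_ms)
        for k, v in rec_dict.items():
            setattr(rec, k, v)
    except AnalysisError as exc:
        notes.append(f"peaks: {exc}")
    try:
        tot = total_peak(signal.fz_total[sl], stance_times,
                         signal.body_weight_n, frame.fs_s, rec.stride_time_ms)
        for k, v in tot.items():
            setattr(rec, k, v)
    except AnalysisError as exc:
        notes.append(f"total_peak: {exc}")
    try:
        # weight-transfer window: back foot's stance reaches at most one
        # stance length before the front foot-strike
        lo = max(frame.fs_idx - (frame.to_idx - frame.fs_idx), 0)
        hi = frame.to_idx + 1
        wt = weight_transfer(own[lo:hi], other[lo:hi],
                             signal.sample_times[lo:hi],
                             frame.fs_s, frame.contralateral_to_s,
                             signal.body_weight_n)
        for k, v in wt.items():
            setattr(rec, k, v)
    except AnalysisError as exc:
        notes.append(f"weight_transfer: {exc}")
    rec.qc_notes = "; ".join(notes)
    return rec


def stance_curves(frame: StrideFrame, signal: ForceSignal,
                  n_points: int = STANCE_GRID_POINTS
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (per-foot, total) stance curves of one stride, in BW."""
    if signal.body_weight_n is None or signal.body_weight_n <= 0:
        raise AnalysisError("body weight required for BW normalization")
    own = signal.fz_left if frame.foot == "L" else signal.fz_right
    sl = slice(frame.fs_idx, frame.to_idx + 1)
    fz = normalize_stance(own[sl], n_points) / signal.body_weight_n
    fztot = normalize_stance(signal.fz_total[sl], n_points) / signal.body_weight_n
    return fz, fztot


def subject_summary(records: Sequence[StrideRecord], meta: SubjectMeta,
                    mean_curve_fz: np.ndarray | None = None,
                    mean_curve_fztot: np.ndarray | None = None,
                    min_strides_per_foot: int = 2) -> SubjectSummary:
    """Collapse a subject's included strides to means, CVs and SIs.

    For every variable the per-foot mean across included strides is
    computed first; the reported mean is the L/R average, the CV is
    computed per foot across strides and then averaged L/R, and the SI
    is computed from the two per-foot means. Variables whose CV or SI is
    undefined (non-positive mean) are left NaN.
    """
    included = [r for r in records if not r.excluded]
    df = pd.DataFrame([r.as_dict() for r in included])
    if df.empty:
        raise InsufficientStridesError(
            f"subject {meta.subject_id}: no included strides")
    for foot in ("L", "R"):
        if (df["foot"] == foot).sum() < min_strides_per_foot:
            raise InsufficientStridesError(
                f"subject {meta.subject_id}: fewer than "
                f"{min_strides_per_foot} included strides on foot {foot}")
    def lr_mean(d: dict) -> float:
        vals = [v for v in (d.get("L", math.nan), d.get("R", math.nan))
                if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    means, cvs, sis = {}, {}, {}
    grouped = df.groupby("foot")
    for var in ALL_VARS:
        foot_means, foot_cvs = {}, {}
        for foot, sub in grouped:
            vals = sub[var].dropna().to_numpy()
            foot_means[foot] = float(np.mean(vals)) if len(vals) else math.nan
            try:
                foot_cvs[foot] = coefficient_of_variation(vals)
            except AnalysisError:
                foot_cvs[foot] = math.nan
        means[var] = lr_mean(foot_means)
        cvs[var] = lr_mean(foot_cvs)
        try:
            sis[var] = symmetry_index(foot_means.get("R", math.nan),
                                      foot_means.get("L", math.nan))
        except (AnalysisError, ValueError):
            sis[var] = math.nan
        if math.isnan(foot_means.get("R", math.nan)) or \
           math.isnan(foot_means.get("L", math.nan)):
            sis[var] = math.nan
    return SubjectSummary(meta=meta, means=means, cvs=cvs, sis=sis,
                          n_strides_used=len(included),
                          mean_curve_fz=mean_curve_fz,
                          mean_curve_fztot=mean_curve_fztot)
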