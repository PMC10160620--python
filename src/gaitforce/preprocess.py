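"""Raw sensor channels -> clean per-foot vertical force, analysis window.

Processing order is a contract: sensor summation, then the 20 N noise
floor, then zero-phase low-pass filtering, then the startup trim. The
floor is applied to per-foot summed signals (not per sensor channel) and
the total force is recomputed from the two filtered per-foot signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.signal import butter, filtfilt

from .exceptions import AnalysisError
from .io_gaitdb import SensorTrace

if TYPE_CHECKING:  # pragma: no cover
    from .features import StrideRecord

G_MPS2 = 9.80665

NOISE_FLOOR_N = 20.0
FILTER_CUTOFF_HZ = 15.0
FILTER_ORDER = 4
STARTUP_TRIM_S = 5.0
TURN_MAD_K = 3.0
MAD_SCALE = 1.4826  # consistency factor: MAD -> sigma under normality


@dataclass
class ForceSignal:
    """Per-foot and total vertical ground reaction force for one subject."""

    subject_id: str
    sample_times: np.ndarray
    fz_left: np.ndarray
    fz_right: np.ndarray
    fz_total: np.ndarray
    sampling_rate: float
    body_weight_n: float | None = None
    flags: set = field(default_factory=set)

    def __len__(self) -> int:
        return self.sample_times.shape[0]


def sum_sensors(trace: SensorTrace) -> ForceSignal:
    """Row-wise sum of each shoe's 8 sensors; total = left + right.

    Body weight is mass * g (g = 9.80665 m/s^2) when the trace carries a
    body mass; otherwise it stays None and body-weight normalization will
    fail later with an explicit error.
    """
    fz_left = trace.left_sensors.sum(axis=1)
    fz_right = trace.right_sensors.sum(axis=1)
    bw = trace.body_mass_kg * G_MPS2 if trace.body_mass_kg else None
    return ForceSignal(
        subject_id=trace.subject_id,
        sample_times=trace.sample_times.copy(),
        fz_left=fz_left, fz_right=fz_right, fz_total=fz_left + fz_right,
        sampling_rate=trace.sampling_rate, body_weight_n=bw)


def denoise_floor(values: np.ndarray, floor: float = NOISE_FLOOR_N) -> np.ndarray:
    """Replace values strictly below ``floor`` (N) by zero. Idempotent."""
    values = np.asarray(values, dtype=float)
    return np.where(values < floor, 0.0, values)


def lowpass(values: np.ndarray, sampling_rate: float,
            cutoff_hz: float = FILTER_CUTOFF_HZ,
            order: int = FILTER_ORDER) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    The forward-backward pass doubles the effective order and squares the
    magnitude response; DC gain is exactly 1 and events are not delayed
    by filter phase.
    """
    if sampling_rate <= 2 * cutoff_hz:
        raise AnalysisError(
            f"sampling rate {sampling_rate} Hz too low for a {cutoff_hz} Hz cutoff")
    b, a = butter(order, cutoff_hz, btype="low", fs=sampling_rate)
    padlen = 3 * (max(len(a), len(b)) - 1)
    if len(values) <= padlen:
        raise AnalysisError(
            f"signal of {len(values)} samples is shorter than the filter "
            f"padding ({padlen}); skip filtering for this segment")
    return filtfilt(b, a, np.asarray(values, dtype=float))


def trim_startup(signal: ForceSignal, trim_s: float = STARTUP_TRIM_S) -> ForceSignal:
    """Drop all samples with time < ``trim_s``; times are not re-zeroed."""
    keep = signal.sample_times >= trim_s
    if not np.any(keep):
        raise AnalysisError(
            f"recording of {signal.sample_times[-1] if len(signal) else 0:.1f} s "
            f"is not longer than the {trim_s} s startup trim")
    return ForceSignal(
        subject_id=signal.subject_id,
        sample_times=signal.sample_times[keep],
        fz_left=signal.fz_left[keep], fz_right=signal.fz_right[keep],
        fz_total=signal.fz_total[keep],
        sampling_rate=signal.sampling_rate,
        body_weight_n=signal.body_weight_n,
        flags=signal.flags | {"trimmed"})


def preprocess_signal(trace: SensorTrace,
               noise_floor_n: float = NOISE_FLOOR_N,
               filter_cutoff_hz: float = FILTER_CUTOFF_HZ,
               filter_order: int = FILTER_ORDER,
               startup_trim_s: float = STARTUP_TRIM_S) -> ForceSignal:
    """Full preprocessing chain in the contractual order.

    sum -> denoise floor -> zero-phase low-pass -> startup trim; the total
    force is the sum of the two processed per-foot signals.
    """
    sig = sum_sensors(trace)
    left = denoise_floor(sig.fz_left, noise_floor_n)
    right = denoise_floor(sig.fz_right, noise_floor_n)
    left = lowpass(left, sig.sampling_rate, filter_cutoff_hz, filter_order)
    right = lowpass(right, sig.sampling_rate, filter_cutoff_hz, filter_order)
    out = ForceSignal(
        subject_id=sig.subject_id, sample_times=sig.sample_times,
        fz_left=left, fz_right=right, fz_total=left + right,
        sampling_rate=sig.sampling_rate, body_weight_n=sig.body_weight_n,
        flags={"denoised", "filtered"})
    if startup_trim_s > 0:
        out = trim_startup(out, startup_trim_s)
    return out


def turn_mask(stride_times_ms: Sequence[float], k: float = TURN_MAD_K,
              rule: str = "mad") -> np.ndarray:
    """Flag turn-like strides from their durations.

    Default rule: a stride is flagged when its duration deviates from the
    per-subject median by more than ``k`` scaled MADs (MAD * 1.4826), and
    every flagged run is expanded by one neighboring stride on each side
    (transition strides in and out of a turn are partly irregular).
    Strides must be given in walking order. With fewer than 5 strides the
    rule degrades to "none" with a warning. An automated proxy for manual
    turn identification; set ``rule="none"`` to keep all strides.
    """
    x = np.asarray(stride_times_ms, dtype=float)
    if rule == "none":
        return np.zeros(len(x), dtype=bool)
    if rule != "mad":
        raise AnalysisError(f"unknown turn rule {rule!r}")
    if len(x) < 5:
        warnings.warn("fewer than 5 strides: turn rule degraded to 'none'",
                      stacklevel=2)
        return np.zeros(len(x), dtype=bool)
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    # numerical floor so exactly-periodic strides are never flagged by
    # float rounding when MAD collapses to zero
    flagged = np.abs(x - med) > max(k * mad, 1e-9 * abs(med) + 1e-12)
    expanded = flagged.copy()
    expanded[:-1] |= flagged[1:]
    expanded[1:] |= flagged[:-1]
    return expanded


def exclude_turns(strides: "list[StrideRecord]", k: float = TURN_MAD_K,
                  rule: str = "mad") -> "list[StrideRecord]":
    """Mark turn-like strides excluded (in place); returns the same list.

    Strides from both feet are pooled in time order: a corridor turn
    inflates both feet's strides, and the per-subject median stride time
    is foot-independent.
    """
    order = np.argsort([s.fs_s for s in strides])
    times = [strides[i].stride_time_ms for i in order]
    mask = turn_mask(times, k=k, rule=rule)
    for pos, flag in zip(order, mask):
        if flag:
            strides[pos].excluded = True
            strides[pos].exclusion_reason = "turn"
    return strides
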