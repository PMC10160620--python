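"""Threshold-based gait event detection and stride assembly.

Foot-strike (FS) is the first sample at or above the 20 N contact
threshold after a sub-threshold run; toe-off (TO) is the first sample
strictly below it after a supra-threshold run. Events are reported at
sample resolution (no sub-sample interpolation): at 100 Hz every event
time is a multiple of 10 ms, matching the millisecond-scale reporting
convention of in-shoe force studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import AnalysisError, NoGaitError
from .preprocess import ForceSignal

CONTACT_THRESHOLD_N = 20.0
MIN_PHASE_MS = 100.0


@dataclass
class FootEvents:
    """Alternating FS/TO events of one foot, paired stance by stance.

    ``fs_idx[k]`` and ``to_idx[k]`` bound the k-th retained stance; the
    sequence always starts with an FS and ends with a TO (a leading TO
    or trailing FS from a truncated stance is discarded).
    """

    foot: str
    fs_idx: np.ndarray
    to_idx: np.ndarray
    fs_times: np.ndarray
    to_times: np.ndarray

    @property
    def n_stances(self) -> int:
        return len(self.fs_idx)


@dataclass
class GaitEvents:
    left: FootEvents
    right: FootEvents


@dataclass
class StrideFrame:
    """The event quintuple of one stride of one foot.

    A valid normal-walking stride satisfies
    ``fs < contralateral_to < contralateral_fs < to < next_fs``.
    """

    foot: str
    fs_s: float
    contralateral_to_s: float
    contralateral_fs_s: float
    to_s: float
    next_fs_s: float
    fs_idx: int
    contralateral_to_idx: int
    contralateral_fs_idx: int
    to_idx: int
    next_fs_idx: int
    valid: bool = True
    reason: str = ""


@dataclass
class StrideQC:
    """Per-subject stride bookkeeping for the QC report."""

    n_detected: int = 0
    n_valid: int = 0
    n_invalid_ordering: int = 0
    invalid_reasons: dict = field(default_factory=dict)


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Run-length encode a boolean array as (start, stop, value) triples."""
    out = []
    n = len(mask)
    start = 0
    for i in range(1, n + 1):
        if i == n or mask[i] != mask[start]:
            out.append((start, i, bool(mask[start])))
            start = i
    return out


def detect_events(fz: np.ndarray, sample_times: np.ndarray,
                  threshold: float = CONTACT_THRESHOLD_N,
                  min_phase_ms: float = MIN_PHASE_MS,
                  foot: str = "?") -> FootEvents:
    """Detect FS/TO events of one foot from its processed force signal.

    Any stance or swing phase shorter than ``min_phase_ms`` is merged
    into its neighbors (debounce against threshold chatter); shortest
    plausible double support at these walking speeds is ~100 ms. A stance
    already in progress at the first sample, or still in progress at the
    last, is discarded so the sequence starts at FS and ends at TO.
    """
    fz = np.asarray(fz, dtype=float)
    sample_times = np.asarray(sample_times, dtype=float)
    above = fz >= threshold
    if not np.any(above):
        raise NoGaitError(f"foot {foot}: no samples reach the "
                          f"{threshold} N contact threshold")
    dt = float(np.median(np.diff(sample_times))) if len(sample_times) > 1 else 0.01
    min_samples = max(int(round(min_phase_ms / 1000.0 / dt)), 1)

    # debounce: repeatedly flip the shortest interior run below min length
    for _ in range(len(fz)):
        runs = _runs(above)
        interior = [(stop - start, i) for i, (start, stop, _) in enumerate(runs)
                    if 0 < i < len(runs) - 1 and stop - start < min_samples]
        if not interior:
            break
        _, i = min(interior)
        start, stop, val = runs[i]
        above[start:stop] = not val

    fs_list, to_list = [], []
    n = len(above)
    for start, stop, val in _runs(above):
        if val and start > 0 and stop < n:
            fs_list.append(start)
            to_list.append(stop)
    fs_idx = np.array(fs_list, dtype=int)
    to_idx = np.array(to_list, dtype=int)
    return FootEvents(foot=foot, fs_idx=fs_idx, to_idx=to_idx,
                      fs_times=sample_times[fs_idx] if len(fs_idx) else np.array([]),
                      to_times=sample_times[to_idx] if len(to_idx) else np.array([]))


def detect_gait_events(signal: ForceSignal,
                       threshold: float = CONTACT_THRESHOLD_N,
                       min_phase_ms: float = MIN_PHASE_MS) -> GaitEvents:
    """Detect events separately for each foot of a processed signal."""
    return GaitEvents(
        left=detect_events(signal.fz_left, signal.sample_times, threshold,
                           min_phase_ms, foot="L"),
        right=detect_events(signal.fz_right, signal.sample_times, threshold,
                            min_phase_ms, foot="R"))


def _frames_for_foot(own: FootEvents, other: FootEvents,
                     qc: StrideQC) -> list[StrideFrame]:
    frames: list[StrideFrame] = []
    for k in range(own.n_stances - 1):
        fs_i, to_i, next_i = own.fs_idx[k], own.to_idx[k], own.fs_idx[k + 1]
        qc.n_detected += 1
        c_fs_pos = [p for p in range(other.n_stances)
                    if fs_i < other.fs_idx[p] < next_i]
        c_to_pos = [p for p in range(other.n_stances)
                    if fs_i < other.to_idx[p] < next_i]
        valid, reason = True, ""
        cfs_p = c_fs_pos[0] if c_fs_pos else None
        if len(c_fs_pos) != 1:
            valid, reason = False, ("no_contralateral_fs" if not c_fs_pos
                                    else "multiple_contralateral_fs")
        # the leading contralateral toe-off must fall before the
        # contralateral foot-strike of the same cycle
        if cfs_p is not None:
            lead = [p for p in c_to_pos if other.to_idx[p] < other.fs_idx[cfs_p]]
        else:
            lead = c_to_pos
        cto_p = lead[0] if lead else None
        if valid and len(lead) != 1:
            valid, reason = False, ("no_contralateral_to" if not lead
                                    else "multiple_contralateral_to")
        if valid:
            cto_i, cfs_i = other.to_idx[cto_p], other.fs_idx[cfs_p]
            if not (fs_i < cto_i < cfs_i < to_i < next_i):
                valid, reason = False, "ordering_violation"
        frame = StrideFrame(
            foot=own.foot,
            fs_s=float(own.fs_times[k]),
            contralateral_to_s=float(other.to_times[cto_p]) if cto_p is not None else float("nan"),
            contralateral_fs_s=float(other.fs_times[cfs_p]) if cfs_p is not None else float("nan"),
            to_s=float(own.to_times[k]),
            next_fs_s=float(own.fs_times[k + 1]),
            fs_idx=int(fs_i),
            contralateral_to_idx=int(other.to_idx[cto_p]) if cto_p is not None else -1,
            contralateral_fs_idx=int(other.fs_idx[cfs_p]) if cfs_p is not None else -1,
            to_idx=int(to_i),
            next_fs_idx=int(next_i),
            valid=valid, reason=reason)
        if valid:
            qc.n_valid += 1
        else:
            qc.n_invalid_ordering += 1
            qc.invalid_reasons[reason] = qc.invalid_reasons.get(reason, 0) + 1
        frames.append(frame)
    return frames


def build_strides(events: GaitEvents) -> tuple[list[StrideFrame], StrideQC]:
    """Assemble per-foot stride frames and an ordering QC report.

    Frames violating the normal-walking ordering invariant are marked
    invalid (and counted), never silently dropped.
    """
    qc = StrideQC()
    if events.left.n_stances < 2 and events.right.n_stances < 2:
        raise AnalysisError("need at least 2 foot-strikes on one foot "
                            "to form a stride")
    frames = _frames_for_foot(events.left, events.right, qc)
    frames += _frames_for_foot(events.right, events.left, qc)
    frames.sort(key=lambda f: f.fs_s)
    return frames, qc
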