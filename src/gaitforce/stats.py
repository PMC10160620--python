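"""Speed-matched cohort selection and group-level inference.

Scalar variables are compared with classic pooled-variance unpaired
Student's t-tests (two-sided) and associations with Pearson correlation.
The stance-normalized force curves are compared over the whole 0–100%
stance grid with a one-dimensional statistical parametric map: a
pointwise two-sample t statistic whose family-wise critical threshold is
the (1 - alpha) quantile of the permutation distribution of the maximum
absolute t over group-label permutations. The permutation threshold is
assumption-light and exactly enumerable for small groups; group-label
assignments are enumerated completely whenever their number does not
exceed ``n_perm``, otherwise ``n_perm`` Monte-Carlo permutations are
drawn with a stated seed. No correction is applied across the many
scalar variables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AnalysisError, ConfigError
from .features import ALL_VARS, FORCE_VARS, TEMPORAL_VARS, SubjectSummary
from .io_gaitdb import SubjectMeta

SPEED_LO_MPS = 1.0
SPEED_HI_MPS = 1.3
ALPHA = 0.05
N_PERM = 10000

#: variables whose symmetry index is tabulated (ms-scale and BW-scale)
SI_TEMPORAL_VARS = ("stride_time_ms", "single_support_ms",
                    "double_support_ms", "stance_time_ms")
SI_FORCE_VARS = ("fz_peak1_bw", "t_peak1_ms", "fz_peak2_bw", "t_peak2_ms",
                 "fz_tot_peak_bw", "t_tot_peak_ms", "fz_peak_front_bw",
                 "fz_peak_back_bw", "delta_fz_bw", "gwt_ms")


def select_speed_matched(subjects: Sequence[SubjectMeta],
                         lo: float = SPEED_LO_MPS,
                         hi: float = SPEED_HI_MPS,
                         ) -> tuple[list[SubjectMeta], dict]:
    """Keep subjects whose walking speed lies in [lo, hi] (inclusive).

    Subjects without a recorded speed are dropped with a warning.
    Returns the kept subjects and per-group counts.
    """
    kept = []
    for s in subjects:
        if s.walking_speed_mps is None:
            warnings.warn(f"subject {s.subject_id} has no walking speed; "
                          "dropped from cohort selection", stacklevel=2)
            continue
        if lo <= s.walking_speed_mps <= hi:
            kept.append(s)
    counts = {"PD": sum(1 for s in kept if s.group == "PD"),
              "control": sum(1 for s in kept if s.group == "control")}
    return kept, counts


def ttest_unpaired(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Pooled-variance two-sided Student's t-test.

    Degenerate inputs: zero pooled variance with equal means gives
    (0, 1); zero pooled variance with unequal means gives (+/-inf, 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("t-test needs at least 2 values per group")
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        warnings.warn("zero variance with unequal means: p -> 0", stacklevel=2)
        return math.copysign(math.inf, np.mean(a) - np.mean(b)), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson r with the two-sided t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise AnalysisError("Pearson correlation needs at least 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise AnalysisError("Pearson correlation undefined for zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class SpmResult:
    """1D statistical parametric map with its permutation threshold."""

    t_field: np.ndarray
    critical_threshold: float
    clusters: list            # [(start_pct, end_pct), ...]
    n_permutations: int
    seed: int | None
    method: str               # "enumeration" or "monte-carlo"
    p_max: float              # permutation p of the observed max |t|
    dropped_points: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _pooled_t(x: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    """Pointwise pooled-variance t over columns of x for one labeling."""
    a, b = x[idx_a], x[idx_b]
    na, nb = len(idx_a), len(idx_b)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / se
    return np.where(se == 0, 0.0, t)


def spm_ttest_1d(curves_a: np.ndarray, curves_b: np.ndarray,
                 alpha: float = ALPHA, n_perm: int = N_PERM,
                 seed: int | None = None) -> SpmResult:
    """Two-sample 1D SPM with a permutation max-|t| threshold.

    ``curves_a``/``curves_b`` hold one mean curve per subject (rows).
    Grid points with zero pooled variance are dropped from the maximum
    with a warning (their t is reported as 0). Clusters are contiguous
    runs with ``|t| >= critical_threshold``, reported in % of the grid.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[1] != b.shape[1]:
        raise ConfigError("curve grids of the two groups differ")
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("SPM needs at least 2 subjects per group")
    na, nb = len(a), len(b)
    n = na + nb
    x = np.vstack([a, b])
    q = x.shape[1]

    pooled_var = np.vstack([a - a.mean(axis=0), b - b.mean(axis=0)]).var(axis=0)
    dropped = np.where(pooled_var == 0)[0]
    valid = pooled_var > 0
    if len(dropped):
        warnings.warn(f"{len(dropped)} zero-variance grid point(s) dropped "
                      "from the max-|t| statistic", stacklevel=2)

    t_obs = _pooled_t(x, np.arange(na), np.arange(na, n))

    n_exact = math.comb(n, na)
    if n_exact <= n_perm:
        method = "enumeration"
        labelings = list(combinations(range(n), na))
        max_stats = np.empty(len(labelings))
        for i, combo in enumerate(labelings):
            idx_a = np.array(combo)
            idx_b = np.setdiff1d(np.arange(n), idx_a, assume_unique=True)
            t = _pooled_t(x, idx_a, idx_b)
            max_stats[i] = np.max(np.abs(t[valid])) if valid.any() else 0.0
        n_used = len(labelings)
    else:
        method = "monte-carlo"
        rng = np.random.default_rng(seed)
        max_stats = np.empty(n_perm)
        # observed labeling is included in the null set
        max_stats[0] = np.max(np.abs(t_obs[valid])) if valid.any() else 0.0
        done = 1
        chunk = max(1, int(5_000_000 / (n * q)))
        xv = x[:, valid] if valid.any() else x[:, :1] * 0.0
        qv = xv.shape[1]
        while done < n_perm:
            m = min(chunk, n_perm - done)
            perms = rng.permuted(np.tile(np.arange(n), (m, 1)), axis=1)
            xa = xv[perms[:, :na]]            # (m, na, qv)
            xb = xv[perms[:, na:]]
            ma, mb = xa.mean(axis=1), xb.mean(axis=1)
            va = xa.var(axis=1, ddof=1)
            vb = xb.var(axis=1, ddof=1)
            sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
            se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(se == 0, 0.0, (ma - mb) / se)
            max_stats[done:done + m] = np.max(np.abs(t), axis=1) if qv else 0.0
            done += m
        n_used = n_perm

    order = np.sort(max_stats)
    k = int(math.ceil((1.0 - alpha) * n_used))
    threshold = float(order[min(k, n_used) - 1])
    obs_max = np.max(np.abs(t_obs[valid])) if valid.any() else 0.0
    p_max = float(np.mean(max_stats >= obs_max - 1e-12))

    supra = (np.abs(t_obs) >= threshold) & valid
    clusters = []
    start = None
    for i in range(q + 1):
        on = i < q and supra[i]
        if on and start is None:
            start = i
        elif not on and start is not None:
            clusters.append((100.0 * start / (q - 1), 100.0 * (i - 1) / (q - 1)))
            start = None
    return SpmResult(t_field=t_obs, critical_threshold=threshold,
                     clusters=clusters, n_permutations=n_used, seed=seed,
                     method=method, p_max=p_max, dropped_points=dropped)


@dataclass
class CohortComparison:
    """The five group-comparison tables plus the two SPM results."""

    n_pd: int
    n_control: int
    characteristics: pd.DataFrame
    sex_counts: dict
    temporal: pd.DataFrame          # means and CVs with p values
    temporal_si: pd.DataFrame
    force: pd.DataFrame
    force_si: pd.DataFrame
    spm_fz: SpmResult | None
    spm_fztot: SpmResult | None


def _group_stats_table(rows: list[tuple[str, np.ndarray, np.ndarray]]
                       ) -> pd.DataFrame:
    """mean +/- SD per group and the t-test for a list of variables."""
    out = []
    for name, a, b in rows:
        a = a[~np.isnan(a)]
        b = b[~np.isnan(b)]
        try:
            t, p = ttest_unpaired(a, b)
        except AnalysisError:
            t, p = math.nan, math.nan
        out.append({
            "variable": name,
            "pd_mean": np.mean(a) if len(a) else math.nan,
            "pd_sd": np.std(a, ddof=1) if len(a) > 1 else math.nan,
            "pd_n": len(a),
            "control_mean": np.mean(b) if len(b) else math.nan,
            "control_sd": np.std(b, ddof=1) if len(b) > 1 else math.nan,
            "control_n": len(b),
            "t": t, "p": p,
        })
    return pd.DataFrame(out)


def _pull(summaries: list[SubjectSummary], table: str, var: str) -> np.ndarray:
    return np.array([getattr(s, table).get(var, math.nan) for s in summaries],
                    dtype=float)


def compare_cohorts(summaries: Sequence[SubjectSummary],
                    alpha: float = ALPHA, n_perm: int = N_PERM,
                    seed: int | None = None,
                    speed_lo: float = SPEED_LO_MPS,
                    speed_hi: float = SPEED_HI_MPS,
                    select_speed: bool = True) -> CohortComparison:
    """Full group comparison of a cohort of subject summaries.

    Applies the speed-band selection, then emits participant
    characteristics, temporal and force tables (means and CVs with t-test
    p values), the symmetry-index tables, and the SPM comparison of the
    per-foot and total stance-normalized force curves.
    """
    summaries = list(summaries)
    if select_speed:
        kept_meta, _ = select_speed_matched([s.meta for s in summaries],
                                            speed_lo, speed_hi)
        kept_ids = {m.subject_id for m in kept_meta}
        summaries = [s for s in summaries if s.meta.subject_id in kept_ids]
    pd_grp = [s for s in summaries if s.meta.group == "PD"]
    co_grp = [s for s in summaries if s.meta.group == "control"]
    if not pd_grp or not co_grp:
        raise AnalysisError("both groups must be nonempty after selection")

    def meta_arr(group, attr):
        return np.array([getattr(s.meta, attr) if getattr(s.meta, attr)
                         is not None else math.nan for s in group], dtype=float)

    char_rows = []
    for label, attr in (("age_years", "age"), ("height_cm", "height_cm"),
                        ("body_mass_kg", "body_mass_kg"),
                        ("walking_speed_mps", "walking_speed_mps"),
                        ("hoehn_yahr", "hoehn_yahr"), ("updrs", "updrs"),
                        ("tug_s", "tug_s")):
        char_rows.append((label, meta_arr(pd_grp, attr), meta_arr(co_grp, attr)))
    characteristics = _group_stats_table(char_rows)
    sex_counts = {
        "PD": {"M": sum(s.meta.sex == "M" for s in pd_grp),
               "F": sum(s.meta.sex == "F" for s in pd_grp)},
        "control": {"M": sum(s.meta.sex == "M" for s in co_grp),
                    "F": sum(s.meta.sex == "F" for s in co_grp)},
    }

    temporal = _group_stats_table(
        [(v, _pull(pd_grp, "means", v), _pull(co_grp, "means", v))
         for v in TEMPORAL_VARS]
        + [(f"cv_{v}", _pull(pd_grp, "cvs", v), _pull(co_grp, "cvs", v))
           for v in TEMPORAL_VARS])
    temporal_si = _group_stats_table(
        [(f"si_{v}", _pull(pd_grp, "sis", v), _pull(co_grp, "sis", v))
         for v in SI_TEMPORAL_VARS])
    force = _group_stats_table(
        [(v, _pull(pd_grp, "means", v), _pull(co_grp, "means", v))
         for v in FORCE_VARS]
        + [(f"cv_{v}", _pull(pd_grp, "cvs", v), _pull(co_grp, "cvs", v))
           for v in FORCE_VARS])
    force_si = _group_stats_table(
        [(f"si_{v}", _pull(pd_grp, "sis", v), _pull(co_grp, "sis", v))
         for v in SI_FORCE_VARS])

    def curve_stack(group, attr):
        curves = [getattr(s, attr) for s in group if getattr(s, attr) is not None]
        return np.vstack(curves) if len(curves) >= 2 else None

    spm_fz = spm_fztot = None
    a_fz, b_fz = curve_stack(pd_grp, "mean_curve_fz"), curve_stack(co_grp, "mean_curve_fz")
    if a_fz is not None and b_fz is not None:
        spm_fz = spm_ttest_1d(a_fz, b_fz, alpha, n_perm, seed)
    a_t, b_t = curve_stack(pd_grp, "mean_curve_fztot"), curve_stack(co_grp, "mean_curve_fztot")
    if a_t is not None and b_t is not None:
        seed2 = None if seed is None else seed + 1
        spm_fztot = spm_ttest_1d(a_t, b_t, alpha, n_perm, seed2)

    return CohortComparison(
        n_pd=len(pd_grp), n_control=len(co_grp),
        characteristics=characteristics, sex_counts=sex_counts,
        temporal=temporal, temporal_si=temporal_si,
        force=force, force_si=force_si,
        spm_fz=spm_fz, spm_fztot=spm_fztot)
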