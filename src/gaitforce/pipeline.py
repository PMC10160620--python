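"""End-to-end orchestration: simulate -> extract -> compare.

Each stage is a plain function over in-memory objects plus a thin
file-level wrapper; subject-level failures during extraction are
isolated and logged in the QC table rather than aborting the cohort.
All outputs are delimited text, written sorted by subject id so that
results are independent of processing order.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import events as ev
from . import features as ft
from . import io_gaitdb as gio
from . import preprocess as pp
from . import stats as st
from . import synthetic as syn
from .exceptions import AnalysisError, ConfigError, GaitForceError

log = logging.getLogger("gaitforce")


@dataclass
class PipelineConfig:
    """Fully resolved configuration of one pipeline run.

    Unknown keys in a config file are rejected; every run writes the
    resolved config next to its outputs for reproducibility.
    """

    noise_floor_n: float = pp.NOISE_FLOOR_N
    filter_cutoff_hz: float = pp.FILTER_CUTOFF_HZ
    filter_order: int = pp.FILTER_ORDER
    startup_trim_s: float = pp.STARTUP_TRIM_S
    turn_rule: str = "mad"
    turn_mad_k: float = pp.TURN_MAD_K
    contact_threshold_n: float = ev.CONTACT_THRESHOLD_N
    min_phase_ms: float = ev.MIN_PHASE_MS
    double_support_mode: str = "mean"
    speed_lo: float = st.SPEED_LO_MPS
    speed_hi: float = st.SPEED_HI_MPS
    select_speed: bool = True
    alpha: float = st.ALPHA
    n_perm: int = st.N_PERM
    seed: int | None = None
    height_unit: str = "cm"
    filename_pattern: str = r"^(?P<id>[^.]+)"
    # simulate stage (run_all only)
    simulate: bool = False
    n_pd: int = 5
    n_control: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class SubjectResult:
    """Everything extracted from one subject's recording."""

    summary: ft.SubjectSummary
    strides: pd.DataFrame
    qc: dict


def process_subject(trace: gio.SensorTrace, meta: gio.SubjectMeta,
                    cfg: PipelineConfig | None = None) -> SubjectResult:
    """Run preprocess -> events -> strides -> features for one subject."""
    cfg = cfg or PipelineConfig()
    trace = trace.with_body_mass(meta.body_mass_kg)
    signal = pp.preprocess_signal(
        trace, noise_floor_n=cfg.noise_floor_n,
        filter_cutoff_hz=cfg.filter_cutoff_hz,
        filter_order=cfg.filter_order, startup_trim_s=cfg.startup_trim_s)
    gait_events = ev.detect_gait_events(
        signal, threshold=cfg.contact_threshold_n, min_phase_ms=cfg.min_phase_ms)
    frames, qc = ev.build_strides(gait_events)
    records = [ft.extract_stride(f, signal, cfg.double_support_mode)
               for f in frames]
    usable = [r for r in records if not r.excluded]
    pp.exclude_turns(usable, k=cfg.turn_mad_k, rule=cfg.turn_rule)
    n_turn = sum(1 for r in usable if r.excluded)

    curves_fz, curves_fztot = [], []
    for frame, rec in zip(frames, records):
        if rec.excluded or not frame.valid:
            continue
        try:
            c1, c2 = ft.stance_curves(frame, signal)
        except AnalysisError:
            continue
        curves_fz.append(c1)
        curves_fztot.append(c2)
    mean_fz = np.mean(curves_fz, axis=0) if curves_fz else None
    mean_fztot = np.mean(curves_fztot, axis=0) if curves_fztot else None

    summary = ft.subject_summary(records, meta, mean_fz, mean_fztot)
    qc_row = {
        "subject_id": meta.subject_id,
        "n_detected": qc.n_detected,
        "n_valid": qc.n_valid,
        "n_invalid_ordering": qc.n_invalid_ordering,
        "n_turn_excluded": n_turn,
        "n_used": summary.n_strides_used,
    }
    strides_df = pd.DataFrame([r.as_dict() for r in records])
    return SubjectResult(summary=summary, strides=strides_df, qc=qc_row)


def run_extract(records_dir, demographics_path, out_dir,
                cfg: PipelineConfig | None = None) -> list[ft.SubjectSummary]:
    """Extract features for every force record in a directory.

    One bad file never aborts the cohort: failures are logged and
    reported in the QC table with an error note. Returns the summaries
    of successfully processed subjects (sorted by subject id).
    """
    cfg = cfg or PipelineConfig()
    records_dir = Path(records_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "strides").mkdir(exist_ok=True)
    metas = {m.subject_id: m for m in gio.read_demographics(
        demographics_path, height_unit=cfg.height_unit)}
    files = sorted(records_dir.glob("*.txt"))
    summaries, qc_rows = [], []
    curve_rows_fz, curve_rows_tot = [], []
    for path in files:
        try:
            sid = gio.subject_id_from_filename(path, cfg.filename_pattern)
            if sid not in metas:
                raise AnalysisError(f"no demographics row for {sid}")
            trace = gio.read_force_record(path, sid)
            res = process_subject(trace, metas[sid], cfg)
        except GaitForceError as exc:
            log.warning("subject file %s failed: %s", path.name, exc)
            qc_rows.append({"subject_id": path.name, "error": str(exc)})
            continue
        summaries.append(res.summary)
        qc_rows.append(res.qc)
        res.strides.to_csv(out_dir / "strides" / f"{sid}.tsv",
                           sep="\t", index=False)
        if res.summary.mean_curve_fz is not None:
            curve_rows_fz.append([sid] + list(res.summary.mean_curve_fz))
            curve_rows_tot.append([sid] + list(res.summary.mean_curve_fztot))
    summaries.sort(key=lambda s: s.meta.subject_id)

    rows = []
    for s in summaries:
        row = {"subject_id": s.meta.subject_id, "group": s.meta.group,
               "n_strides_used": s.n_strides_used}
        row.update({f"mean_{k}": v for k, v in s.means.items()})
        row.update({f"cv_{k}": v for k, v in s.cvs.items()})
        row.update({f"si_{k}": v for k, v in s.sis.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "summaries.tsv", sep="\t", index=False)
    pd.DataFrame(qc_rows).to_csv(out_dir / "qc.tsv", sep="\t", index=False)
    grid_cols = ["subject_id"] + [f"pct{i}" for i in range(ft.STANCE_GRID_POINTS)]
    pd.DataFrame(curve_rows_fz, columns=grid_cols).to_csv(
        out_dir / "curves_fz.tsv", sep="\t", index=False)
    pd.DataFrame(curve_rows_tot, columns=grid_cols).to_csv(
        out_dir / "curves_fztot.tsv", sep="\t", index=False)
    cfg.dump(out_dir / "config.resolved.yaml")
    log.info("extracted %d/%d subjects", len(summaries), len(files))
    return summaries


def run_simulate(out_dir, cfg: PipelineConfig) -> None:
    """Write a synthetic cohort (force records + demographics + ground truth)."""
    out_dir = Path(out_dir)
    (out_dir / "records").mkdir(parents=True, exist_ok=True)
    traces, metas, gts = syn.simulate_cohort(
        syn.pd_group_params(), syn.control_group_params(),
        cfg.n_pd, cfg.n_control, seed=cfg.seed or 0)
    for trace in traces:
        gio.write_force_record(trace, out_dir / "records" / f"{trace.subject_id}.txt")
    gio.write_demographics(metas, out_dir / "demographics.tsv")
    gt_frames = []
    for gt in gts:
        df = gt.strides.copy()
        df.insert(0, "subject_id", gt.subject_id)
        gt_frames.append(df)
    pd.concat(gt_frames, ignore_index=True).to_csv(
        out_dir / "ground_truth.tsv", sep="\t", index=False)


def run_compare(summaries, out_dir, cfg: PipelineConfig | None = None
                ) -> st.CohortComparison:
    """Group comparison tables + SPM report from subject summaries."""
    cfg = cfg or PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    comp = st.compare_cohorts(
        summaries, alpha=cfg.alpha, n_perm=cfg.n_perm, seed=cfg.seed,
        speed_lo=cfg.speed_lo, speed_hi=cfg.speed_hi,
        select_speed=cfg.select_speed)
    comp.characteristics.to_csv(out_dir / "table1_characteristics.tsv",
                                sep="\t", index=False)
    comp.temporal.to_csv(out_dir / "table2_temporal.tsv", sep="\t", index=False)
    comp.temporal_si.to_csv(out_dir / "table3_temporal_si.tsv", sep="\t", index=False)
    comp.force.to_csv(out_dir / "table4_force.tsv", sep="\t", index=False)
    comp.force_si.to_csv(out_dir / "table5_force_si.tsv", sep="\t", index=False)
    spm_lines = [f"groups: PD n={comp.n_pd}, control n={comp.n_control}"]
    for name, res in (("Fz", comp.spm_fz), ("Fz_tot", comp.spm_fztot)):
        if res is None:
            spm_lines.append(f"{name}: not computed (missing curves)")
            continue
        spm_lines.append(
            f"{name}: max|t|={np.max(np.abs(res.t_field)):.3f} "
            f"threshold={res.critical_threshold:.3f} ({res.method}, "
            f"{res.n_permutations} permutations) clusters={res.clusters}")
    (out_dir / "spm_report.txt").write_text("\n".join(spm_lines) + "\n")
    cfg.dump(out_dir / "config.resolved.yaml")
    return comp


def run_all(work_dir, cfg: PipelineConfig | None = None) -> st.CohortComparison:
    """simulate (optional) -> extract -> compare, one seed for the chain."""
    cfg = cfg or PipelineConfig()
    work_dir = Path(work_dir)
    records_dir = work_dir / "records"
    demographics = work_dir / "demographics.tsv"
    if cfg.simulate:
        run_simulate(work_dir, cfg)
    if not records_dir.is_dir() or not demographics.exists():
        raise ConfigError(f"no input cohort under {work_dir} "
                          "(need records/ and demographics.tsv)")
    summaries = run_extract(records_dir, demographics, work_dir / "features", cfg)
    if not summaries:
        raise AnalysisError("no subjects could be extracted")
    return run_compare(summaries, work_dir / "comparison", cfg)
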