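"""Stride feature algebra, peaks, symmetry index, CV, stance normalization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitforce.events import StrideFrame
from gaitforce.exceptions import AnalysisError, InsufficientStridesError
from gaitforce.features import (StrideRecord, coefficient_of_variation,
                                force_peaks, normalize_stance,
                                subject_summary, symmetry_index,
                                temporal_features, total_peak,
                                weight_transfer)
from gaitforce.io_gaitdb import SubjectMeta
from gaitforce.synthetic import stance_profile, stance_profile_peak

BW = 73.0 * 9.80665


def _frame(fs=0.0, cto=0.146, cfs=0.535, to=0.682, nxt=1.071, foot="L"):
    return StrideFrame(foot=foot, fs_s=fs, contralateral_to_s=cto,
                       contralateral_fs_s=cfs, to_s=to, next_fs_s=nxt,
                       fs_idx=0, contralateral_to_idx=0, contralateral_fs_idx=0,
                       to_idx=0, next_fs_idx=0)


class TestTemporalFeatures:
    def test_event_algebra_at_cohort_scale_values(self):
        """stride 1071, stance 682, single support 389, DS mean 146.5 ms."""
        rec = temporal_features(_frame())
        assert rec.stride_time_ms == pytest.approx(1071.0)
        assert rec.stance_time_ms == pytest.approx(682.0)
        assert rec.single_support_ms == pytest.approx(389.0)
        assert rec.ds_lead_ms == pytest.approx(146.0)
        assert rec.ds_trail_ms == pytest.approx(147.0)
        assert rec.double_support_ms == pytest.approx(146.5)
        assert rec.stance_pct == pytest.approx(100 * 682 / 1071)

    def test_double_support_sum_mode(self):
        rec = temporal_features(_frame(), double_support_mode="sum")
        assert rec.double_support_ms == pytest.approx(293.0)

    def test_symmetric_63pct_stance(self):
        rec = temporal_features(_frame(fs=0, cto=0.13, cfs=0.5, to=0.63, nxt=1.0))
        assert rec.stance_pct == pytest.approx(63.0)

    def test_invalid_frame_gives_excluded_record(self):
        f = _frame()
        f.valid = False
        f.reason = "ordering_violation"
        rec = temporal_features(f)
        assert rec.excluded and rec.exclusion_reason == "ordering_violation"
        assert math.isnan(rec.stride_time_ms)

    def test_generator_strides_match_ground_truth(self, noisy_subject):
        """Full-pipeline stride times agree with pre-noise ground truth."""
        import gaitforce as gf
        _, trace, meta, gt = noisy_subject
        res = gf.process_subject(trace, meta)
        picked = res.strides[~res.strides.excluded]
        merged = 0
        g = gt.strides
        for _, row in picked.iterrows():
            match = g[(g.foot == row.foot) & (abs(g.fs_s - row.fs_s) < 0.05)]
            if len(match) == 1:
                merged += 1
                assert abs(match.stride_ms.iloc[0] - row.stride_time_ms) <= 20.0
        assert merged > 0.9 * len(picked)


class TestForcePeaks:
    def test_constant_plateau_tie_breaks_to_earliest(self):
        n = 69
        t = np.arange(n) * 0.01
        fz = np.full(n, BW)
        out = force_peaks(fz, t, BW, 0.0, 1071.0)
        assert out["fz_peak1_bw"] == pytest.approx(1.0)
        assert out["fz_peak2_bw"] == pytest.approx(1.0)
        assert out["t_peak1_ms"] == pytest.approx(0.0)
        # second half starts at the first sample at >= 50% of stance
        assert out["t_peak2_ms"] == pytest.approx(t[n // 2] * 1000, abs=1e-9)

    def test_symmetric_profile_peak_times_mirror(self):
        t = np.arange(69) * 0.01
        u = t / t[-1]
        fz = BW * stance_profile(u, 1.25, 0.4)
        out = force_peaks(fz, t, BW, 0.0, 1071.0)
        assert (out["t_peak1_ms"] + out["t_peak2_ms"]) == pytest.approx(
            t[-1] * 1000, abs=15)

    def test_generator_stance_peaks_match_root_finding_oracle(self):
        u_star, f_star = stance_profile_peak(0.4)
        t = np.arange(0, 0.6825, 0.01)
        u = t / t[-1]
        fz = BW * stance_profile(u, 1.25, 0.4)
        out = force_peaks(fz, t, BW, 0.0, 1071.0)
        expect = 1.25 * f_star
        assert abs(out["fz_peak1_bw"] - expect) / expect < 0.005
        assert abs(out["fz_peak2_bw"] - expect) / expect < 0.005
        assert out["t_peak1_ms"] == pytest.approx(u_star * 682.5, abs=10)

    def test_too_short_stance_rejected(self):
        with pytest.raises(AnalysisError):
            force_peaks(np.ones(3), np.arange(3) * 0.01, BW, 0.0, 1000.0)


class TestTotalPeak:
    def test_single_loaded_foot_total_equals_foot_peak(self):
        t = np.arange(69) * 0.01
        u = t / t[-1]
        fz = BW * stance_profile(u, 1.25, 0.4)
        out = total_peak(fz, t, BW, 0.0, 1071.0)
        _, f_star = stance_profile_peak(0.4)
        assert out["fz_tot_peak_bw"] == pytest.approx(1.25 * f_star, rel=0.005)

    def test_overlapping_stances_peak_exceeds_single_foot(self, clean_subject):
        import gaitforce as gf
        _, trace, meta, _ = clean_subject
        res = gf.process_subject(trace, meta)
        m = res.summary.means
        assert m["fz_tot_peak_bw"] > max(m["fz_peak1_bw"], m["fz_peak2_bw"])


class TestWeightTransfer:
    def _curves(self):
        """Front max 1.35 BW at +163 ms, back last max 1.24 BW at -58 ms."""
        t = np.arange(-500, 800) / 1000.0
        front = 1.35 * BW * np.exp(-0.5 * ((t - 0.163) / 0.12) ** 2)
        front[t < 0] = 0.0
        back = 1.24 * BW * np.exp(-0.5 * ((t + 0.058) / 0.12) ** 2)
        back[t > 0.137] = 0.0
        return t, front, back

    def test_cohort_scale_delta_and_transfer_time(self):
        t, front, back = self._curves()
        out = weight_transfer(front, back, t, 0.0, 0.137, BW)
        assert out["fz_peak_front_bw"] == pytest.approx(1.35, abs=0.01)
        assert out["fz_peak_back_bw"] == pytest.approx(1.24, abs=0.01)
        assert out["delta_fz_bw"] == pytest.approx(0.11, abs=0.02)
        assert out["gwt_ms"] == pytest.approx(221.0, abs=2.0)

    def test_identical_profiles_zero_delta(self):
        t = np.arange(-300, 600) / 1000.0
        bump = BW * np.exp(-0.5 * (t / 0.1) ** 2)
        out = weight_transfer(bump, bump, t, -0.3, 0.4, BW)
        assert out["delta_fz_bw"] == pytest.approx(0.0, abs=1e-12)

    def test_no_local_maximum_raises(self):
        t = np.arange(100) * 0.01
        ramp = np.linspace(0, BW, 100)
        with pytest.raises(AnalysisError, match="local"):
            weight_transfer(ramp, ramp, t, 0.0, 0.99, BW)

    def test_generator_transfer_interval_matches_ground_truth(self, clean_subject):
        """gwt equals the analytic inter-maximum interval within a sample."""
        import gaitforce as gf
        params, trace, meta, gt = clean_subject
        res = gf.process_subject(trace, meta)
        u_star, _ = stance_profile_peak(params.shape_ratio)
        s = gt.strides.iloc[5]
        stance = s.stance_ms / 1000.0
        # front peak1 at u* of own stance; back peak2 at (1-u*) of the
        # contralateral stance that began one step earlier
        # back foot's push-off peak sits u* of a stance before its toe-off,
        # which happens ds_lead after the front foot-strike
        t_front = u_star * stance
        t_back = (s.ds_lead_ms / 1000.0) - u_star * stance
        expect_ms = (t_front - t_back) * 1000.0
        assert res.summary.means["gwt_ms"] == pytest.approx(expect_ms, abs=15.0)


class TestSymmetryIndexAndCV:
    def test_equal_values_give_zero(self):
        assert symmetry_index(389.0, 389.0) == 0.0

    def test_forced_arithmetic_20_percent(self):
        assert symmetry_index(1.1, 0.9) == pytest.approx(20.0)

    def test_undefined_for_nonpositive_sum(self):
        with pytest.raises(AnalysisError):
            symmetry_index(0.0, 0.0)

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(st.floats(0.1, 1e3), st.floats(0.1, 1e3), st.floats(0.01, 1e3))
    def test_scale_invariance(self, xr, xl, c):
        assert symmetry_index(c * xr, c * xl) == pytest.approx(
            symmetry_index(xr, xl), rel=1e-9)

    def test_cv_constant_list_is_zero(self):
        assert coefficient_of_variation([5.0] * 10) == 0.0

    def test_cv_n_minus_one_convention(self):
        assert coefficient_of_variation([90.0, 110.0]) == pytest.approx(
            14.142135623, abs=1e-6)

    def test_cv_undefined_cases(self):
        with pytest.raises(AnalysisError):
            coefficient_of_variation([1.0])
        with pytest.raises(AnalysisError):
            coefficient_of_variation([-1.0, 1.0])

    def test_cv_recovers_simulated_dispersion(self, rng):
        draws = rng.normal(1000.0, 22.0, size=70)
        assert coefficient_of_variation(draws) == pytest.approx(2.2, abs=0.7)


META = SubjectMeta("s1", "PD", 73.0, 1.1)


def _rec(foot, ss, stride=1071.0):
    return StrideRecord(foot=foot, fs_s=0.0, stride_time_ms=stride,
                        single_support_ms=ss)


class TestSubjectSummary:
    def test_periodic_symmetric_subject_zero_cv_and_si(self, clean_subject):
        import gaitforce as gf
        _, trace, meta, _ = clean_subject
        res = gf.process_subject(trace, meta)
        assert res.summary.cvs["stride_time_ms"] == pytest.approx(0.0, abs=0.05)
        assert res.summary.sis["stride_time_ms"] == pytest.approx(0.0, abs=0.05)
        assert res.summary.sis["single_support_ms"] == pytest.approx(0.0, abs=0.6)

    def test_si_from_per_foot_means_400_378(self):
        """SI = |400-378| / 389 * 100 = 5.655% from per-foot means."""
        recs = [_rec("L", 399.0), _rec("L", 401.0),
                _rec("R", 377.0), _rec("R", 379.0)]
        summ = subject_summary(recs, META)
        assert summ.means["single_support_ms"] == pytest.approx(389.0)
        assert summ.sis["single_support_ms"] == pytest.approx(22 / 389 * 100,
                                                              abs=1e-9)

    def test_insufficient_strides_per_foot_rejected(self):
        recs = [_rec("L", 400.0), _rec("L", 401.0), _rec("R", 380.0)]
        with pytest.raises(InsufficientStridesError):
            subject_summary(recs, META)

    def test_excluded_strides_do_not_contribute(self):
        recs = [_rec("L", 400.0), _rec("L", 400.0),
                _rec("R", 400.0), _rec("R", 400.0)]
        outlier = _rec("L", 900.0)
        outlier.excluded = True
        summ = subject_summary(recs + [outlier], META)
        assert summ.means["single_support_ms"] == pytest.approx(400.0)
        assert summ.n_strides_used == 4


class TestNormalizeStance:
    def test_identity_when_already_101_samples(self):
        x = np.linspace(0, 1, 101) ** 2
        assert np.allclose(normalize_stance(x), x)

    def test_linear_ramp_exact(self):
        ramp = np.linspace(0.0, 1.0, 68)
        out = normalize_stance(ramp)
        assert np.allclose(out, np.linspace(0.0, 1.0, 101), atol=1e-12)

    def test_too_short_stance_rejected(self):
        with pytest.raises(AnalysisError):
            normalize_stance(np.ones(4))

    def test_generator_stance_matches_analytic_profile(self):
        t = np.arange(0, 0.6825, 0.01)
        u = t / t[-1]
        fz = stance_profile(u, 1.25, 0.4)
        out = normalize_stance(fz)
        exact = stance_profile(np.linspace(0, 1, 101), 1.25, 0.4)
        rms = np.sqrt(np.mean((out - exact) ** 2))
        assert rms / exact.max() < 0.005
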