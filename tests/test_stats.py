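"""Cohort selection, scalar tests, and the permutation SPM."""

import itertools
import math

import numpy as np
import pytest

from gaitforce.exceptions import AnalysisError
from gaitforce.features import SubjectSummary
from gaitforce.io_gaitdb import SubjectMeta
from gaitforce.stats import (compare_cohorts, pearson, select_speed_matched,
                             spm_ttest_1d, ttest_unpaired)
from gaitforce.synthetic import simulate_mean_stance_curves


def _meta(sid, speed, group="PD"):
    return SubjectMeta(sid, group, 73.0, speed)


class TestSpeedSelection:
    def test_inclusive_boundaries(self):
        speeds = [0.99, 1.00, 1.15, 1.30, 1.31]
        metas = [_meta(f"s{i}", v) for i, v in enumerate(speeds)]
        kept, counts = select_speed_matched(metas)
        assert [m.walking_speed_mps for m in kept] == [1.00, 1.15, 1.30]
        assert counts == {"PD": 3, "control": 0}

    def test_empty_input_empty_cohort(self):
        kept, counts = select_speed_matched([])
        assert kept == [] and counts == {"PD": 0, "control": 0}

    def test_missing_speed_dropped_with_warning(self):
        metas = [_meta("a", 1.1), _meta("b", None)]
        with pytest.warns(UserWarning, match="no walking speed"):
            kept, _ = select_speed_matched(metas)
        assert [m.subject_id for m in kept] == ["a"]

    def test_uniform_band_refilter_brute_force(self, rng):
        """Selection equals an elementwise re-filter of drawn speeds."""
        speeds = rng.uniform(0.8, 1.5, size=200)
        metas = [_meta(f"s{i}", v) for i, v in enumerate(speeds)]
        kept, _ = select_speed_matched(metas)
        expect = {f"s{i}" for i, v in enumerate(speeds) if 1.0 <= v <= 1.3}
        assert {m.subject_id for m in kept} == expect


class TestTTest:
    def test_identical_lists_t0_p1(self):
        assert ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0.0, 1.0)

    def test_pooled_variance_closed_form(self):
        """{1,2,3} vs {2,3,4}: sp2 = 1, t = -1/sqrt(2/3), df = 4."""
        t, p = ttest_unpaired([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247448714, abs=1e-9)
        assert p == pytest.approx(0.2878641347, abs=1e-9)

    def test_zero_variance_degenerate_cases(self):
        assert ttest_unpaired([5.0, 5.0], [5.0, 5.0]) == (0.0, 1.0)
        with pytest.warns(UserWarning, match="zero variance"):
            t, p = ttest_unpaired([5.0, 5.0], [7.0, 7.0])
        assert p == 0.0 and t == -math.inf

    def test_rejection_rate_matches_analytic_power(self, rng):
        """Stride-time effect d = 36/80.6 at n = 54/39 -> power ~0.56."""
        from scipy.stats import nct, t as tdist
        n1, n2, mu1, mu2, sd = 54, 39, 1071.0, 1107.0, 80.6
        reps, hits = 400, 0
        for _ in range(reps):
            a = rng.normal(mu1, sd, n1)
            b = rng.normal(mu2, sd, n2)
            _, p = ttest_unpaired(a, b)
            hits += p <= 0.05
        d = (mu2 - mu1) / sd
        ncp = d / math.sqrt(1 / n1 + 1 / n2)
        crit = tdist.ppf(0.975, n1 + n2 - 2)
        power = 1 - nct.cdf(crit, n1 + n2 - 2, ncp) + nct.cdf(-crit, n1 + n2 - 2, ncp)
        se = math.sqrt(power * (1 - power) / reps)
        assert abs(hits / reps - power) < 4 * se


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_independent_streams_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        r, _ = pearson(x, y)
        assert abs(r) < 0.1

    def test_bivariate_normal_recovers_rho(self, rng):
        """rho = 0.36 at n = 54 over replicates -> mean r ~ 0.36."""
        rho, n, reps = 0.36, 54, 400
        rs = []
        for _ in range(reps):
            x = rng.normal(size=n)
            y = rho * x + math.sqrt(1 - rho ** 2) * rng.normal(size=n)
            rs.append(pearson(x, y)[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(AnalysisError):
            pearson([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(AnalysisError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestSpm:
    def test_identical_groups_zero_field_no_clusters(self, rng):
        curves = simulate_mean_stance_curves(5, rng)
        res = spm_ttest_1d(curves, curves.copy(), n_perm=500, seed=0)
        assert np.allclose(res.t_field, 0.0)
        assert res.clusters == []

    def test_pointwise_equivalence_with_scalar_ttest(self, rng):
        a = simulate_mean_stance_curves(10, rng)
        b = simulate_mean_stance_curves(10, rng, amplitude_bw=1.45)
        res = spm_ttest_1d(a, b, n_perm=200, seed=1)
        for j in range(1, 100):                     # interior grid points
            t, _ = ttest_unpaired(a[:, j], b[:, j])
            assert res.t_field[j] == pytest.approx(t, abs=1e-10)

    def test_deterministic_under_seed(self, rng):
        a = simulate_mean_stance_curves(12, rng)
        b = simulate_mean_stance_curves(12, rng)
        r1 = spm_ttest_1d(a, b, n_perm=300, seed=42)
        r2 = spm_ttest_1d(a, b, n_perm=300, seed=42)
        assert r1.critical_threshold == r2.critical_threshold
        assert np.array_equal(r1.t_field, r2.t_field)

    def test_constant_offset_yields_full_span_cluster(self, rng):
        a = simulate_mean_stance_curves(10, rng)
        b = a + 0.5
        res = spm_ttest_1d(a, b, n_perm=1000, seed=3)
        assert np.max(np.abs(res.t_field)) > res.critical_threshold
        assert len(res.clusters) == 1
        start, end = res.clusters[0]
        assert end - start > 90.0                   # effectively whole stance

    def test_threshold_monotone_in_alpha(self, rng):
        a = simulate_mean_stance_curves(8, rng)
        b = simulate_mean_stance_curves(8, rng)
        thr = [spm_ttest_1d(a, b, alpha=al, n_perm=500, seed=5).critical_threshold
               for al in (0.10, 0.05, 0.01)]
        assert thr[0] <= thr[1] <= thr[2]

    def test_complete_enumeration_matches_itertools_oracle(self, rng):
        """Small groups: threshold equals a brute-force enumeration."""
        a = simulate_mean_stance_curves(4, rng)
        b = simulate_mean_stance_curves(4, rng, amplitude_bw=1.5)
        res = spm_ttest_1d(a, b, alpha=0.05, n_perm=10000, seed=None)
        assert res.method == "enumeration"
        assert res.n_permutations == math.comb(8, 4)
        x = np.vstack([a, b])
        var0 = np.vstack([a - a.mean(0), b - b.mean(0)]).var(axis=0) > 0

        def tmax(idx_a):
            idx_b = [i for i in range(8) if i not in idx_a]
            ga, gb = x[list(idx_a)], x[idx_b]
            sp2 = (3 * ga.var(0, ddof=1) + 3 * gb.var(0, ddof=1)) / 6
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (ga.mean(0) - gb.mean(0)) / np.sqrt(sp2 * 0.5)
            t = np.where(np.sqrt(sp2) == 0, 0.0, t)
            return np.max(np.abs(t[var0]))

        maxs = sorted(tmax(c) for c in itertools.combinations(range(8), 4))
        k = math.ceil(0.95 * len(maxs))
        assert res.critical_threshold == pytest.approx(maxs[k - 1], abs=1e-12)

    def test_zero_variance_endpoints_dropped_with_warning(self, rng):
        a = simulate_mean_stance_curves(6, rng)
        b = simulate_mean_stance_curves(6, rng)
        # the profile is exactly zero at foot-strike for every subject
        with pytest.warns(UserWarning, match="zero-variance"):
            res = spm_ttest_1d(a, b, n_perm=200, seed=7)
        assert 0 in res.dropped_points
        assert res.t_field[0] == 0.0


def _summary(sid, group, speed, means, curve=None):
    meta = SubjectMeta(sid, group, 73.0, speed)
    return SubjectSummary(meta=meta, means=dict(means), cvs={k: 1.0 for k in means},
                          sis={k: 1.0 for k in means}, n_strides_used=50,
                          mean_curve_fz=curve, mean_curve_fztot=curve)


class TestCompareCohorts:
    def test_clone_cohort_all_p_one_no_clusters(self, rng):
        curve = simulate_mean_stance_curves(1, rng)[0]
        base = {"stride_time_ms": 1100.0, "fz_peak1_bw": 1.3}
        summaries = [
            _summary(f"p{i}", "PD", 1.1, base, curve) for i in range(5)
        ] + [
            _summary(f"c{i}", "control", 1.1, base, curve) for i in range(5)
        ]
        comp = compare_cohorts(summaries, n_perm=300, seed=0)
        stride_row = comp.temporal.set_index("variable").loc["stride_time_ms"]
        assert stride_row["p"] == pytest.approx(1.0)
        assert comp.spm_fz.clusters == []

    def test_speed_selection_reduces_group_n(self, rng):
        curve = simulate_mean_stance_curves(1, rng)[0]
        base = {"stride_time_ms": 1100.0}
        summaries = (
            [_summary(f"p{i}", "PD", 1.1 + 0.001 * i, base, curve) for i in range(6)]
            + [_summary("p_fast", "PD", 1.45, base, curve)]
            + [_summary(f"c{i}", "control", 1.2, base, curve) for i in range(5)])
        comp = compare_cohorts(summaries, n_perm=200, seed=0)
        assert comp.n_pd == 6 and comp.n_control == 5
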