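import itertools
import math

import numpy as np
import pytest
from scipy.stats import kstest, rankdata

from adipoct.metrics import make_record
from adipoct.stats import (
    DoseBinResult,
    derive_acceptable_accuracy,
    determine_dose_limit,
    dose_bin_tests,
    exclude_outliers_3sigma,
    holm_adjust,
    interval_effect_test,
    mann_whitney_u,
    simulate_threshold_records,
    truncation_effect_test,
)

# ---------------------------------------------------------------------------
# independent oracle: brute-force permutation MWU
# ---------------------------------------------------------------------------


def brute_force_pvalues(a, b):
    """Enumerate every rank assignment; returns (U1, p_less, p_greater, p_two)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    w_obs = ranks[:n1].sum()
    idx = np.array(list(itertools.combinations(range(n1 + n2), n1)))
    ws = ranks[idx].sum(axis=1)
    p_less = float((ws <= w_obs + 1e-9).mean())
    p_greater = float((ws >= w_obs - 1e-9).mean())
    u1 = w_obs - n1 * (n1 + 1) / 2.0
    return u1, p_less, p_greater, min(1.0, 2.0 * min(p_less, p_greater))


class TestMannWhitneyExact:
    def test_separated_samples_example(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], sidedness="two")
        assert res.method == "exact"
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.10)  # 2/20 rank assignments

    def test_interleaved_example(self):
        res = mann_whitney_u([1, 3], [2, 4], sidedness="two")
        assert res.u_statistic == 1.0  # rank-sum 4 minus n1(n1+1)/2 = 3

    def test_identical_multisets_saturated_null(self):
        res = mann_whitney_u([5, 6, 7, 8], [5, 6, 7, 8], sidedness="two")
        assert res.p_value >= 0.99

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_method_refuses_ties(self):
        with pytest.raises(ValueError, match="untied"):
            mann_whitney_u([1, 1, 2], [3, 4, 5], method="exact")

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 8), (8, 8), (3, 17)])
    def test_matches_enumeration_spot_checks(self, n1, n2, rng):
        a = rng.normal(size=n1)
        b = rng.normal(size=n2) + 0.5
        u1, pl, pg, p2 = brute_force_pvalues(a, b)
        for sidedness, expected in (("one_less", pl), ("one_greater", pg), ("two", p2)):
            res = mann_whitney_u(a, b, sidedness=sidedness, method="exact")
            assert res.u_statistic == pytest.approx(u1)
            assert res.p_value == pytest.approx(expected, abs=1e-12)

    def test_scipy_cross_check(self, rng):
        scipy_stats = pytest.importorskip("scipy.stats")
        a, b = rng.normal(size=7), rng.normal(size=9)
        ours = mann_whitney_u(a, b, sidedness="two", method="exact")
        ref = scipy_stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert ours.u_statistic == pytest.approx(ref.statistic)


class TestMannWhitneyNormal:
    def test_ties_fall_back_to_normal(self):
        res = mann_whitney_u([1, 1, 2, 3], [2, 3, 3, 4], sidedness="two")
        assert res.method == "normal_tie_corrected"
        assert 0.0 <= res.p_value <= 1.0

    def test_all_tied_data_is_degenerate(self):
        res = mann_whitney_u([3, 3, 3], [3, 3, 3], sidedness="two")
        assert res.p_value == 1.0

    def test_large_sample_close_to_exact(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(size=30) + 0.4
        p_normal = mann_whitney_u(a, b, sidedness="two", method="normal").p_value
        p_exact = mann_whitney_u(a, b, sidedness="two", method="exact", exact_threshold=40).p_value
        assert p_normal == pytest.approx(p_exact, abs=0.005)

    def test_tie_corrected_close_to_tied_enumeration(self):
        # continuous data carrying a few genuine ties
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(25):
            x = rng.normal(size=16)
            for _ in range(rng.integers(1, 4)):
                i, j = rng.choice(16, 2, replace=False)
                x[j] = x[i]
            a, b = x[:8], x[8:]
            _, pl, pg, _ = brute_force_pvalues(a, b)
            worst = max(
                worst,
                abs(mann_whitney_u(a, b, "one_less", method="normal").p_value - pl),
                abs(mann_whitney_u(a, b, "one_greater", method="normal").p_value - pg),
            )
        assert worst <= 0.01


class TestHolm:
    def test_adjustment(self):
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_monotone_and_bounded(self):
        adj = holm_adjust([0.5, 0.001, 0.2, 0.9])
        assert all(0 <= p <= 1 for p in adj)


# ---------------------------------------------------------------------------
# outlier exclusion
# ---------------------------------------------------------------------------


def _acc_records(values, compartment="VAT", **kwargs):
    return [
        make_record(f"S{i:03d}", compartment, 100.0, 100.0 - (100.0 - v), **kwargs)
        for i, v in enumerate(values)
    ]


class TestOutlierExclusion:
    def test_small_group_cannot_flag_its_own_outlier(self):
        # with n=6 the candidate inflates the sd so much that |z| < 3 always
        # (max attainable |z| with ddof=1 is (n-1)/sqrt(n) ~ 2.04): the
        # single-pass include-the-candidate rule excludes nothing here
        values = [90.0, 91.0, 92.0, 89.0, 90.0, 25.0]
        acc = np.array(values)
        z = abs(acc - acc.mean()) / acc.std(ddof=1)
        assert z.max() < 3.0  # oracle: the rule's own arithmetic
        kept, excluded = exclude_outliers_3sigma(_acc_records(values))
        assert excluded == []
        assert len(kept) == 6

    def test_cohort_scale_outlier_excluded(self, rng):
        # 46 records, one extreme low value: mirrors the study cohort where
        # exactly one record is dropped and 45 remain
        values = list(np.clip(rng.normal(87.0, 8.0, size=45), 60.0, 100.0)) + [25.0]
        acc = np.array(values)
        assert abs(25.0 - acc.mean()) > 3.0 * acc.std(ddof=1)  # oracle
        kept, excluded = exclude_outliers_3sigma(_acc_records(values))
        assert len(kept) == 45
        assert len(excluded) == 1
        assert excluded[0].accuracy == pytest.approx(25.0)

    def test_no_outliers_identity(self):
        values = [90.0, 92.0, 88.0, 91.0]
        kept, excluded = exclude_outliers_3sigma(_acc_records(values))
        assert len(kept) == 4 and excluded == []

    def test_tiny_group_warns_and_keeps(self, caplog):
        records = _acc_records([90.0, 50.0])
        with caplog.at_level("WARNING"):
            kept, excluded = exclude_outliers_3sigma(records)
        assert len(kept) == 2 and excluded == []
        assert "skipping outlier exclusion" in caplog.text


# ---------------------------------------------------------------------------
# confounder screens
# ---------------------------------------------------------------------------


def _screen_records(rng, n_a, n_b, shift=0.0, sd=8.0, by="truncated"):
    records = []
    for comp in ("SAT", "VAT"):
        for i in range(n_a + n_b):
            in_a = i < n_a
            acc = float(np.clip(rng.normal(88.0 - (shift if in_a else 0.0), sd), 1, 100))
            records.append(
                make_record(
                    f"S{i:03d}",
                    comp,
                    100.0,
                    acc,
                    source="manual",
                    truncated=(in_a if by == "truncated" else False),
                    days_between=(5.0 if in_a else 40.0) if by == "days" else 0.0,
                )
            )
    return records


class TestTruncationEffect:
    def test_reports_group_means_at_cohort_sizes(self, rng):
        records = _screen_records(rng, 17, 29)
        results = truncation_effect_test(records)
        for comp in ("SAT", "VAT"):
            res = results[comp]
            assert res.n1 == 17 and res.n2 == 29
            assert res.mean_a is not None and res.mean_b is not None
            assert res.sidedness == "two"

    def test_power_under_planted_shift(self):
        rejections = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            records = _screen_records(rng, 17, 29, shift=15.0, sd=8.0)
            if truncation_effect_test(records)["SAT"].p_value < 0.05:
                rejections += 1
        assert rejections / 200 > 0.90

    def test_empty_stratum_rejected(self, rng):
        records = _screen_records(rng, 0, 10)
        with pytest.raises(ValueError, match="empty stratum"):
            truncation_effect_test(records)


class TestIntervalEffect:
    def test_cutoff_strata(self, rng):
        records = _screen_records(rng, 12, 34, by="days")
        results = interval_effect_test(records, cutoff_days=15.0)
        assert results["SAT"].n1 == 12 and results["SAT"].n2 == 34

    def test_cutoff_beyond_all_offsets_fails(self, rng):
        records = _screen_records(rng, 12, 34, by="days")
        with pytest.raises(ValueError, match="empty stratum"):
            interval_effect_test(records, cutoff_days=1000.0)

    def test_sat_drift_only_rejects_sat(self):
        # SAT records drift with the interval, VAT records do not: the screen
        # should flag SAT and clear VAT in the majority of replicates
        sat_hits = vat_hits = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            records = []
            for i in range(40):
                days = 5.0 if i < 16 else 45.0
                drift = 0.3 * days if days > 15 else 0.0
                sat = float(np.clip(rng.normal(95.0 - drift, 3.0), 1, 100))
                vat = float(np.clip(rng.normal(88.0, 6.0), 1, 100))
                records.append(
                    make_record(f"S{i}", "SAT", 100.0, sat, source="manual", days_between=days)
                )
                records.append(
                    make_record(f"S{i}", "VAT", 100.0, vat, source="manual", days_between=days)
                )
            results = interval_effect_test(records)
            sat_hits += results["SAT"].p_value < 0.05
            vat_hits += results["VAT"].p_value < 0.05
        assert sat_hits / n_rep > 0.8
        assert vat_hits / n_rep < 0.3


# ---------------------------------------------------------------------------
# acceptable accuracy
# ---------------------------------------------------------------------------


class TestAcceptableAccuracy:
    def test_mean_of_subset(self):
        records = _acc_records([90.0, 95.0, 100.0], compartment="SAT", source="manual")
        acc = derive_acceptable_accuracy(records, "SAT", rule="all_days")
        assert acc.value == pytest.approx(95.0)
        assert acc.n_used == 3

    def test_short_interval_rule_brute_force(self, rng):
        days = [3, 40, 10, 80, 2, 20, 14, 15]
        values = [90.0, 80.0, 92.0, 75.0, 95.0, 85.0, 91.0, 88.0]
        records = [
            make_record(f"S{i}", "SAT", 100.0, v, source="manual", days_between=d)
            for i, (v, d) in enumerate(zip(values, days))
        ]
        acc = derive_acceptable_accuracy(records, "SAT", rule="short_interval", cutoff_days=15)
        expected = np.mean([v for v, d in zip(values, days) if d < 15])
        assert acc.value == pytest.approx(expected)
        assert acc.rule == "short_interval"

    def test_fixed_mode_bypasses_derivation(self):
        records = _acc_records([70.0, 75.0, 72.0], compartment="SAT", source="manual")
        acc = derive_acceptable_accuracy(records, "SAT", rule="all_days", fixed_value=94.5)
        assert acc.value == 94.5
        assert acc.rule == "fixed"
        assert len(acc.reference_sample) == 3  # sample still exposed for testing

    def test_auto_rule_follows_interval_screen(self):
        rng = np.random.default_rng(3)
        records = []
        for i in range(30):
            days = 5.0 if i < 15 else 45.0
            sat = float(np.clip(rng.normal(95.0 - (10.0 if days > 15 else 0.0), 2.0), 1, 100))
            records.append(
                make_record(f"S{i}", "SAT", 100.0, sat, source="manual", days_between=days)
            )
            records.append(
                make_record(f"S{i}", "VAT", 100.0, rng.normal(88, 2), source="manual", days_between=days)
            )
        assert derive_acceptable_accuracy(records, "SAT", rule="auto").rule == "short_interval"
        assert derive_acceptable_accuracy(records, "VAT", rule="auto").rule == "all_days"


# ---------------------------------------------------------------------------
# dose bins and the limit
# ---------------------------------------------------------------------------


def _bin(low, high, p, n=14, small=False, mean=90.0):
    return DoseBinResult(low=low, high=high, n=n, mean=mean, sd=3.0, p_value=p, small_n=small)


class TestDoseBinTests:
    def test_sizes_and_small_n_flags(self, rng):
        edges = (0.35, 0.40, 0.45, 0.50, math.inf)
        sizes = {0: 9, 1: 5, 2: 14, 3: 18}
        records = []
        i = 0
        for b, n in sizes.items():
            for _ in range(n):
                dose = edges[b] + 0.01 if math.isinf(edges[b + 1]) else rng.uniform(edges[b], edges[b + 1])
                records.append(
                    make_record(f"S{i}", "SAT", 100.0, rng.normal(92, 3), ssde_5_25=dose)
                )
                i += 1
        ref = list(rng.normal(94.5, 6.6, size=12))
        results = dose_bin_tests(records, ref, bin_edges=edges, small_n_min=6)
        assert len(results) == 4
        assert [r.n for r in results] == [9, 5, 14, 18]
        assert [r.small_n for r in results] == [False, True, False, False]

    def test_empty_bin_skipped(self, rng):
        records = [make_record("S0", "SAT", 100.0, 90.0, ssde_5_25=0.37)] * 6
        results = dose_bin_tests(records, [94.0, 95.0, 93.0], bin_edges=(0.35, 0.4, 0.45))
        assert len(results) == 1
        assert results[0].low == 0.35

    def test_null_pvalues_approximately_uniform(self):
        # bin and reference drawn from the same distribution: the one-sided p
        # should be close to uniform (discrete support aside)
        ps = []
        for seed in range(300):
            rng = np.random.default_rng(seed)
            records = [
                make_record(f"S{i}", "SAT", 100.0, rng.normal(90, 5), ssde_5_25=0.37)
                for i in range(14)
            ]
            res = dose_bin_tests(records, rng.normal(90, 5, size=12), bin_edges=(0.35, 0.4))
            ps.append(res[0].p_value)
        assert kstest(ps, "uniform").statistic < 0.1

    def test_power_against_shifted_bin(self):
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            records = [
                make_record(f"S{i}", "SAT", 100.0, rng.normal(84.5, 6.0), ssde_5_25=0.37)
                for i in range(14)
            ]
            res = dose_bin_tests(records, rng.normal(94.5, 6.0, size=12), bin_edges=(0.35, 0.4))
            hits += res[0].p_value < 0.05
        assert hits / 200 > 0.80

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            dose_bin_tests([], [], bin_edges=(0.35, 0.4))


class TestDetermineDoseLimit:
    def test_all_bins_passing_from_lowest_edge(self):
        bins = [
            _bin(0.40, 0.45, 0.886),
            _bin(0.45, 0.50, 1.000),
            _bin(0.50, 0.55, 1.000),
            _bin(0.55, math.inf, 0.999),
        ]
        limit = determine_dose_limit(bins)
        assert limit.limit == pytest.approx(0.40)
        assert limit.source == "fine_bins"

    def test_failing_fine_bins_fall_back_to_coarse_level(self):
        bins = [
            _bin(0.35, 0.40, 0.001, n=9),
            _bin(0.40, 0.45, 0.117, n=5, small=True),
            _bin(0.45, 0.50, 0.013, n=14),
            _bin(0.50, math.inf, 0.027, n=18),
        ]
        fallback = [_bin(1.5, 1.5, 0.957, n=46)]
        limit = determine_dose_limit(bins, fallback)
        assert limit.limit == pytest.approx(1.5)
        assert limit.source == "fallback"

    def test_nothing_passes(self):
        bins = [_bin(0.35, 0.4, 0.001), _bin(0.4, 0.45, 0.002)]
        limit = determine_dose_limit(bins, [_bin(1.5, 1.5, 0.01)])
        assert limit.limit is None
        assert limit.source == "none"

    def test_small_n_bin_cannot_set_the_limit(self):
        bins = [
            _bin(0.35, 0.40, 0.9, n=3, small=True),
            _bin(0.40, 0.45, 0.9, n=14),
            _bin(0.45, math.inf, 0.9, n=14),
        ]
        limit = determine_dose_limit(bins)
        assert limit.limit == pytest.approx(0.40)

    def test_small_n_bin_inside_run_is_tolerated(self):
        bins = [
            _bin(0.40, 0.45, 0.9, n=14),
            _bin(0.45, 0.50, 0.9, n=4, small=True),
            _bin(0.50, math.inf, 0.9, n=14),
        ]
        assert determine_dose_limit(bins).limit == pytest.approx(0.40)

    def test_overlapping_bins_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            determine_dose_limit([_bin(0.35, 0.45, 0.9), _bin(0.40, 0.50, 0.9)])


class TestPlantedThresholdRecovery:
    def test_limit_recovers_planted_bin(self):
        edges = (0.35, 0.40, 0.45, 0.50, math.inf)
        d_star = 0.40
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            records, ref = simulate_threshold_records(d_star, rng, bin_edges=edges)
            bins = dose_bin_tests(records, ref, bin_edges=edges)
            limit = determine_dose_limit(bins)
            if limit.limit is not None and abs(limit.limit - d_star) < 1e-9:
                hits += 1
        assert hits / n_rep >= 0.9
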