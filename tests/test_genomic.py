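import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleosex.core import Certainty, Method, Sex, ThresholdConfig
from paleosex.genomic import (
    Region,
    Statistic,
    classify_interval,
    clopper_pearson_interval,
    compute_rx,
    compute_ry,
    depth_reliability_curve,
    downsample_counts,
)

from conftest import build_counts, realistic_counts


def wald_ci(n_y, n, z=1.96):
    """Independent hand-rolled normal-approximation binomial CI."""
    p = n_y / n
    half = z * math.sqrt(p * (1 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


class TestComputeRy:
    def test_zero_y_degenerate_definitive_female(self, thresholds):
        counts = build_counts(x_reads=5000, y_reads=0)
        result = compute_ry(counts, thresholds)
        assert result.point == 0.0
        assert (result.ci_low, result.ci_high) == (0.0, 0.0)
        assert result.estimate.sex is Sex.XX
        assert result.estimate.is_definitive

    def test_male_above_threshold(self, thresholds):
        counts = build_counts(x_reads=900, y_reads=100)
        result = compute_ry(counts, thresholds)
        lo, hi = wald_ci(100, 1000)
        assert result.point == pytest.approx(0.100)
        assert result.ci_low == pytest.approx(lo)
        assert result.ci_high == pytest.approx(hi)
        assert (lo, hi) == (pytest.approx(0.0814, abs=1e-4), pytest.approx(0.1186, abs=1e-4))
        assert result.estimate.sex is Sex.XY
        assert result.estimate.is_definitive

    def test_interval_between_thresholds_indeterminate(self, thresholds):
        counts = build_counts(x_reads=950, y_reads=50)
        result = compute_ry(counts, thresholds)
        assert result.point == pytest.approx(0.050)
        assert result.ci_low == pytest.approx(0.0365, abs=1e-4)
        assert result.ci_high == pytest.approx(0.0635, abs=1e-4)
        assert result.estimate.sex is Sex.INDETERMINATE

    def test_interval_crossing_female_threshold_conditional(self, thresholds):
        counts = build_counts(x_reads=990, y_reads=10)
        result = compute_ry(counts, thresholds)
        assert result.point == pytest.approx(0.010)
        assert result.ci_low == pytest.approx(0.0038, abs=1e-4)
        assert result.ci_high == pytest.approx(0.0162, abs=1e-4)
        assert result.estimate.sex is Sex.XX
        assert result.estimate.certainty is Certainty.CONDITIONAL

    def test_zero_sex_reads_indeterminate_not_exception(self, thresholds):
        counts = build_counts(x_reads=0, y_reads=0)
        result = compute_ry(counts, thresholds)
        assert result.estimate.sex is Sex.INDETERMINATE
        assert result.estimate.diagnostic
        assert result.n_sex_reads == 0

    def test_monotone_in_y_reads(self, thresholds):
        points = []
        for n_y in (0, 5, 20, 100, 400):
            result = compute_ry(build_counts(x_reads=1000, y_reads=n_y), thresholds)
            points.append(result.point)
        assert points == sorted(points)

    def test_low_data_flag_requires_both_criteria_failing(self):
        config = ThresholdConfig()
        # 22k autosomal + 4k sex reads: total < 100k but sex >= 3000 -> not low
        counts = build_counts(autosome_reads=1000, x_reads=3900, y_reads=100)
        assert not compute_ry(counts, config).estimate.low_data_flag
        # few sex reads and low total -> flagged
        counts = build_counts(autosome_reads=100, x_reads=90, y_reads=10)
        assert compute_ry(counts, config).estimate.low_data_flag

    def test_ci_coverage_near_nominal(self, thresholds):
        # Wald CI should cover the generative Y fraction ~95% of the time
        rng = np.random.default_rng(7)
        p_true, n = 0.0873, 3000
        hits = 0
        reps = 1000
        for _ in range(reps):
            n_y = rng.binomial(n, p_true)
            result = compute_ry(build_counts(x_reads=n - n_y, y_reads=n_y), thresholds)
            hits += result.ci_low <= p_true <= result.ci_high
        assert abs(hits / reps - 0.95) < 0.03


class TestComputeRx:
    def test_equal_rates_definitive_female(self, thresholds):
        counts = build_counts(autosome_reads=1000, x_reads=1000)
        result = compute_rx(counts, thresholds)
        assert result.point == pytest.approx(1.0)
        assert result.ci_low == pytest.approx(1.0)
        assert result.ci_high == pytest.approx(1.0)
        assert result.estimate.sex is Sex.XX
        assert result.estimate.is_definitive
        assert len(result.per_autosome_ratios) == 22

    def test_half_dosage_definitive_male(self, thresholds):
        counts = build_counts(autosome_reads=1000, x_reads=500)
        result = compute_rx(counts, thresholds)
        assert result.point == pytest.approx(0.5)
        assert result.estimate.sex is Sex.XY
        assert result.estimate.is_definitive

    def test_alternating_ratios_hand_oracle(self, thresholds):
        # 11 autosomes at ratio 0.70, 11 at 0.80
        reads = {str(i): 1000 if i % 2 else 875 for i in range(1, 23)}
        counts = build_counts(autosome_reads=reads, x_reads=700)
        result = compute_rx(counts, thresholds)
        ratios = [0.70 if i % 2 else 0.80 for i in range(1, 23)]
        mean = sum(ratios) / 22
        sd = math.sqrt(sum((r - mean) ** 2 for r in ratios) / 21)
        half = 1.96 * sd / math.sqrt(22)
        assert result.point == pytest.approx(mean)
        assert mean == pytest.approx(0.75)
        assert result.ci_low == pytest.approx(mean - half)
        assert result.ci_high == pytest.approx(mean + half)
        assert (result.ci_low, result.ci_high) == (
            pytest.approx(0.729, abs=1e-3),
            pytest.approx(0.771, abs=1e-3),
        )
        assert result.estimate.sex is Sex.INDETERMINATE

    def test_zero_read_autosome_indeterminate(self, thresholds):
        reads = {str(i): 1000 for i in range(1, 23)}
        reads["21"] = 0
        result = compute_rx(build_counts(autosome_reads=reads, x_reads=800), thresholds)
        assert result.estimate.sex is Sex.INDETERMINATE
        assert "21" in result.estimate.diagnostic

    def test_rates_use_lengths(self, thresholds):
        # same reads, half-length X doubles rate_X and the statistic
        counts = build_counts(autosome_reads=1000, x_reads=500, x_length=500_000)
        result = compute_rx(counts, thresholds)
        assert result.point == pytest.approx(1.0)


class TestClassifyInterval:
    MALE_HIGH = dict(
        male_region=Region(0.075, "above"),
        female_region=Region(0.016, "below"),
        method=Method.GENOMIC_RY,
    )

    def test_containment_definitive(self):
        est = classify_interval(0.1, 0.09, 0.12, **self.MALE_HIGH)
        assert (est.sex, est.certainty) == (Sex.XY, Certainty.DEFINITIVE)

    def test_single_crossing_conditional(self):
        est = classify_interval(0.01, 0.004, 0.017, **self.MALE_HIGH)
        assert (est.sex, est.certainty) == (Sex.XX, Certainty.CONDITIONAL)

    def test_spanning_both_indeterminate(self):
        est = classify_interval(0.05, 0.01, 0.10, **self.MALE_HIGH)
        assert est.sex is Sex.INDETERMINATE

    def test_endpoint_on_threshold_is_crossing(self):
        est = classify_interval(0.08, 0.075, 0.09, **self.MALE_HIGH)
        assert est.certainty is Certainty.CONDITIONAL
        est = classify_interval(0.01, 0.005, 0.016, **self.MALE_HIGH)
        assert est.certainty is Certainty.CONDITIONAL

    def test_same_side_regions_rejected(self):
        with pytest.raises(ValueError):
            classify_interval(
                0.5, 0.4, 0.6,
                male_region=Region(0.6, "above"),
                female_region=Region(0.8, "above"),
                method=Method.GENOMIC_RX,
            )

    @staticmethod
    def oracle(lo, hi, t_m, m_side, t_f, f_side):
        """Dense point-sampling re-derivation of the decision rule."""
        points = np.linspace(lo, hi, 201)

        def strictly_in(v, t, side):
            return v > t if side == "above" else v < t

        def in_closure(v, t, side):
            return v >= t if side == "above" else v <= t

        if all(strictly_in(v, t_m, m_side) for v in points):
            return (Sex.XY, Certainty.DEFINITIVE)
        if all(strictly_in(v, t_f, f_side) for v in points):
            return (Sex.XX, Certainty.DEFINITIVE)
        touch_m = any(in_closure(v, t_m, m_side) for v in points)
        touch_f = any(in_closure(v, t_f, f_side) for v in points)
        if touch_m and not touch_f:
            return (Sex.XY, Certainty.CONDITIONAL)
        if touch_f and not touch_m:
            return (Sex.XX, Certainty.CONDITIONAL)
        return (Sex.INDETERMINATE, Certainty.NONE)

    @pytest.mark.parametrize(
        "t_m,m_side,t_f,f_side,method",
        [
            (0.075, "above", 0.016, "below", Method.GENOMIC_RY),
            (0.60, "below", 0.80, "above", Method.GENOMIC_RX),
        ],
    )
    def test_matches_bruteforce_oracle(self, t_m, m_side, t_f, f_side, method):
        rng = np.random.default_rng(11)
        for _ in range(2000):
            a, b = rng.uniform(0, 1.2, size=2)
            lo, hi = min(a, b), max(a, b)
            expected = self.oracle(lo, hi, t_m, m_side, t_f, f_side)
            est = classify_interval(
                (lo + hi) / 2, lo, hi,
                male_region=Region(t_m, m_side),
                female_region=Region(t_f, f_side),
                method=method,
            )
            assert (est.sex, est.certainty) == expected, (lo, hi)


class TestDownsample:
    def test_identity_at_full_depth(self):
        counts = build_counts(autosome_reads=100, x_reads=50, y_reads=10)
        sub = downsample_counts(counts, counts.total_mapped(), seed=1)
        assert sub.entries == counts.entries

    def test_deterministic_under_seed(self):
        counts = build_counts(autosome_reads=1000, x_reads=500, y_reads=100)
        a = downsample_counts(counts, 5000, seed=42)
        b = downsample_counts(counts, 5000, seed=42)
        assert a.entries == b.entries

    def test_target_exceeding_total_rejected(self):
        counts = build_counts(autosome_reads=10, x_reads=5, y_reads=1)
        with pytest.raises(ValueError, match="exceeds"):
            downsample_counts(counts, counts.total_mapped() + 1, seed=0)

    def test_total_is_exact(self):
        counts = build_counts(autosome_reads=1000, x_reads=500, y_reads=100)
        sub = downsample_counts(counts, 1234, seed=3)
        assert sub.total_mapped() == 1234

    def test_proportions_preserved_in_expectation(self):
        # sampling-theory oracle: hypergeometric mean = n*K/N, sd known
        rng = np.random.default_rng(5)
        counts = realistic_counts(rng, total=200_000, y_fraction_of_sex=0.1)
        target = 20_000
        reps = 200
        sub_rng = np.random.default_rng(17)
        fractions = np.zeros(reps)
        for i in range(reps):
            sub = downsample_counts(counts, target, sub_rng)
            fractions[i] = sub.mapped("X") / target
        p = counts.mapped("X") / counts.total_mapped()
        n_total = counts.total_mapped()
        se_one = math.sqrt(p * (1 - p) / target * (n_total - target) / (n_total - 1))
        mc_se = se_one / math.sqrt(reps)
        assert abs(fractions.mean() - p) < 3 * mc_se


class TestDepthReliabilityCurve:
    def test_single_full_depth_matches_direct_classification(self, thresholds):
        rng = np.random.default_rng(9)
        counts = realistic_counts(rng, total=1_000_000, y_fraction_of_sex=0.35)
        table = depth_reliability_curve(
            counts, [counts.total_mapped()], replicates=1, seed=0,
            config=thresholds, statistics=(Statistic.RY,),
        )
        direct = compute_ry(counts, thresholds).estimate
        row = table.iloc[0]
        assert row["frac_definitive"] == float(direct.is_definitive)

    def test_high_depth_male_always_definitive(self, thresholds):
        rng = np.random.default_rng(13)
        counts = realistic_counts(rng, total=2_000_000, y_fraction_of_sex=0.35)
        table = depth_reliability_curve(
            counts, [1_000_000], replicates=50, seed=2,
            config=thresholds, true_sex=Sex.XY, statistics=(Statistic.RY,),
        )
        row = table.iloc[0]
        assert row["frac_definitive"] == 1.0
        assert row["frac_conflict"] == 0.0

    def test_low_depth_female_mostly_uncertain(self, thresholds):
        # ~3% sex reads: at depth 200 a female yields ~6 sex reads
        rng = np.random.default_rng(15)
        counts = realistic_counts(rng, total=500_000, y_fraction_of_sex=0.02)
        table = depth_reliability_curve(
            counts, [200], replicates=100, seed=4,
            config=thresholds, statistics=(Statistic.RX,),
        )
        row = table.iloc[0]
        assert row["frac_conditional"] + row["frac_indeterminate"] > row["frac_definitive"]

    def test_empty_grid_rejected(self, thresholds):
        counts = build_counts()
        with pytest.raises(ValueError, match="empty"):
            depth_reliability_curve(counts, [], replicates=5, seed=0, config=thresholds)


class TestClopperPearson:
    def test_contains_wald_point(self):
        lo, hi = clopper_pearson_interval(10, 1000)
        assert lo < 10 / 1000 < hi

    def test_degenerate_zero(self):
        lo, hi = clopper_pearson_interval(0, 50)
        assert lo == 0.0
        assert 0 < hi < 0.1


@settings(max_examples=50, deadline=None)
@given(
    n_y=st.integers(min_value=0, max_value=500),
    n_x=st.integers(min_value=1, max_value=5000),
)
def test_ry_point_in_unit_interval_and_ci_ordered(n_y, n_x):
    result = compute_ry(build_counts(x_reads=n_x, y_reads=n_y))
    assert 0.0 <= result.point <= 1.0
    assert result.ci_low <= result.point <= result.ci_high
    assert 0.0 <= result.ci_low and result.ci_high <= 1.0
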