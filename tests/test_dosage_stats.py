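import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from zdosage import dosage_stats as ds


def mwu_enumeration_oracle(x, y, alternative="two_sided"):
    """Exact MWU p-value by full enumeration of rank assignments.

    For tie-free pooled data, every C(n1+n2, n1) assignment of the pooled
    ranks to the x-sample is equally likely under the null; tail
    probabilities are counted directly.
    """
    x, y = list(x), list(y)
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    pooled = sorted(x + y)
    us = []
    for positions in itertools.combinations(range(n1 + n2), n1):
        xs = {pooled[i] for i in positions}
        us.append(sum(1 for xi in xs for yj in pooled if yj not in xs and xi > yj))
    total = len(us)
    p_le = sum(1 for u in us if u <= u_obs) / total
    p_ge = sum(1 for u in us if u >= u_obs) / total
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestMwu:
    def test_worked_example_low_tail(self):
        r = ds.mwu_test([1, 2], [3, 4])
        assert r.u == 0
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / 6)

    def test_worked_example_interleaved(self):
        r = ds.mwu_test([1, 3, 5], [2, 4, 6])
        assert r.u == 3
        assert r.p_value == pytest.approx(0.7)  # P(U<=3) = 7/20, doubled

    def test_identical_samples_give_p_one(self):
        r = ds.mwu_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.p_value == 1.0

    def test_u_range_and_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=15)
        rx = ds.mwu_test(x, y)
        ry = ds.mwu_test(y, x)
        assert 0 <= rx.u <= 10 * 15
        assert rx.u + ry.u == 10 * 15
        assert rx.p_value == pytest.approx(ry.p_value)

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 7) for n2 in range(n1, 7)])
    def test_exact_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(100 * n1 + n2)
        for _ in range(3):
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = pooled[:n1], pooled[n1:]
            for alt in ("two_sided", "less", "greater"):
                r = ds.mwu_test(x, y, alt)
                assert r.method == "exact"
                assert r.p_value == pytest.approx(
                    mwu_enumeration_oracle(x, y, alt), abs=1e-12
                )

    def test_large_sample_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0.3, 1, 60)
        y = rng.normal(0.0, 1, 80)
        r = ds.mwu_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.method == "normal_approx"
        assert r.u == ref.statistic
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_tie_correction_agrees_with_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 6, 40).astype(float)
        y = rng.integers(1, 7, 50).astype(float)
        r = ds.mwu_test(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert r.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ds.mwu_test([], [1.0])


class TestZaSummary:
    def test_printed_means_reproduce_mean_ratio(self):
        s = ds.za_summary([26.34339], [13.55054], "m78h")
        assert s.mean_za == pytest.approx(0.514381, abs=5e-7)

    def test_printed_medians_reproduce_median_ratio(self):
        s = ds.za_summary([3.99718], [1.567086], "m78h")
        assert s.median_za == pytest.approx(0.392048, abs=5e-7)

    def test_identity(self):
        v = [1.0, 2.0, 3.0]
        s = ds.za_summary(v, v, "x")
        assert s.mean_za == 1.0
        assert s.median_za == 1.0

    def test_hand_computed_median_ratio(self):
        s = ds.za_summary([1, 2, 4], [1, 2], "x")
        assert s.median_za == pytest.approx(1.5 / 2)

    def test_internal_consistency_of_ratios(self):
        rng = np.random.default_rng(1)
        a, z = rng.lognormal(1, 1, 101), rng.lognormal(0.5, 1, 51)
        s = ds.za_summary(a, z, "x")
        assert s.mean_za == pytest.approx(s.mean_Z / s.mean_A, abs=1e-9)
        assert s.median_za == pytest.approx(s.median_Z / s.median_A, abs=1e-9)

    def test_median_ratio_monotone_transform_for_odd_lengths(self):
        # with odd lengths the median commutes with monotone transforms:
        # computing on log2 and back-transforming matches the linear scale
        rng = np.random.default_rng(2)
        a, z = rng.lognormal(1, 1, 101), rng.lognormal(0, 1, 51)
        s = ds.za_summary(a, z, "x")
        log_ratio = 2.0 ** (np.median(np.log2(z)) - np.median(np.log2(a)))
        assert s.median_za == pytest.approx(log_ratio, rel=1e-12)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            ds.za_summary([], [1.0], "x")

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="true-expression"):
            ds.za_summary([0.0, 1.0], [1.0], "x")


class TestMfRatios:
    def test_closed_form(self):
        r, lr = ds.mf_ratios([2.0], [1.0])
        assert r[0] == 2.0 and lr[0] == 1.0

    def test_identity(self):
        v = np.array([1.0, 5.0, 9.0])
        r, _ = ds.mf_ratios(v, v)
        np.testing.assert_allclose(r, 1.0)

    def test_hand_computed_median(self):
        r, _ = ds.mf_ratios([2, 3, 8, 5], [1, 3, 4, 10])
        assert np.median(r) == pytest.approx((1 + 2) / 2)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            ds.mf_ratios([1, 2], [1])


class TestMfSummary:
    @pytest.mark.parametrize(
        "med_z,med_a,expected",
        [(2.039096, 1.359739, 1.499623), (0.884246, 0.997452, 0.886504)],
    )
    def test_printed_medians_reproduce_ratio_of_medians(self, med_z, med_a, expected):
        # tolerance = one unit in the last printed decimal of the source table
        s = ds.mf_summary([med_z], [med_a], "stage")
        assert s.za_ratio_of_medians == pytest.approx(expected, abs=1e-6)

    def test_equal_medians_give_one(self):
        s = ds.mf_summary([1.0, 2.0, 3.0], [2.0], "x")
        assert s.za_ratio_of_medians == 1.0

    @given(st.lists(st.floats(0.01, 100.0), min_size=1, max_size=20))
    def test_same_ratios_give_unit_ratio_of_medians(self, ratios):
        s = ds.mf_summary(ratios, ratios, "x")
        assert s.za_ratio_of_medians == pytest.approx(1.0)

    def test_consistency_invariant(self):
        rng = np.random.default_rng(3)
        s = ds.mf_summary(rng.lognormal(0.3, 1, 40), rng.lognormal(0, 1, 60), "x")
        assert s.za_ratio_of_medians == pytest.approx(
            s.median_mf_Z / s.median_mf_A, abs=1e-9
        )

    def test_scaling_both_sexes_leaves_statistics_unchanged(self):
        rng = np.random.default_rng(4)
        mz, fz = rng.lognormal(1, 1, 30), rng.lognormal(1, 1, 30)
        ma, fa = rng.lognormal(1, 1, 50), rng.lognormal(1, 1, 50)
        base = ds.mf_summary(mz / fz, ma / fa, "x", pairs_Z=(mz, fz), pairs_A=(ma, fa))
        c = 17.3
        scaled = ds.mf_summary(
            (c * mz) / (c * fz), (c * ma) / (c * fa), "x",
            pairs_Z=(c * mz, c * fz), pairs_A=(c * ma, c * fa),
        )
        assert scaled.median_mf_Z == pytest.approx(base.median_mf_Z)
        assert scaled.za_ratio_of_medians == pytest.approx(base.za_ratio_of_medians)
        assert scaled.p_Z_MvsF == pytest.approx(base.p_Z_MvsF)
        assert scaled.p_AvsZ_dist == pytest.approx(base.p_AvsZ_dist)


class TestDeltaCt:
    @pytest.mark.parametrize(
        "cts,expected",
        [((20, 18, 22, 20), 1.0), ((20, 18, 21, 18), 2.0), ((22, 18, 20, 18), 0.25)],
    )
    def test_closed_form(self, cts, expected):
        assert ds.delta_ct_fold(*cts) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            ds.delta_ct_fold(math.nan, 18, 20, 18)
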