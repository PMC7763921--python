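import numpy as np
import pytest

import entroprof as ep
from conftest import quantized_series


class TestDistanceSets:
    def test_constant_series_all_zero(self):
        dist = ep.build_distance_sets([2.0] * 10, 2)
        assert np.all(dist.d_m == 0) and np.all(dist.d_m1 == 0)
        assert dist.n_templates == 8 and not dist.self_matches_included

    def test_alternating_series_binary_distances(self):
        dist = ep.build_distance_sets([0, 1, 0, 1, 0, 1, 0, 1], 2)
        assert set(np.unique(dist.d_m)) <= {0.0, 1.0}
        assert set(np.unique(dist.d_m1)) <= {0.0, 1.0}

    def test_ramp_distances_equal_index_gap(self):
        dist = ep.build_distance_sets(np.arange(1.0, 11.0), 2)
        n = dist.n_templates
        full = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :]).astype(float)
        expected = full[~np.eye(n, dtype=bool)].reshape(n, n - 1)
        assert np.array_equal(dist.d_m, expected)


class TestRangeSet:
    def test_constant_series_single_bin(self):
        rset = ep.build_range(ep.build_distance_sets([1.0] * 8, 2))
        assert rset.values.tolist() == [0.0] and rset.nbin == 1

    def test_alternating_series_two_bins(self):
        rset = ep.build_range(ep.build_distance_sets([0, 1, 0, 1, 0, 1, 0, 1], 2))
        assert rset.values.tolist() == [0.0, 1.0]

    def test_distinct_pool_keeps_every_value(self):
        pool = np.array([0.5, 0.1, 0.9, 0.3])
        assert ep.build_range(pool).nbin == 4

    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            ep.RangeSet(np.array([0.1, 0.1, 0.2]))


class TestCdfMatrix:
    def test_alternating_counting_example(self):
        # 8 templates of parity classes 4/4: each row has three 0-distances
        # and four 1-distances among its 7 entries
        x = [0, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        dist = ep.build_distance_sets(x, 2)
        rset = ep.build_range(dist)
        cdf = ep.cdf_matrix(dist.d_m, rset)
        assert cdf.shape == (8, 2)
        assert np.allclose(cdf[:, 0], 3 / 7) and np.all(cdf[:, 1] == 1.0)

    def test_rows_nondecreasing_last_column_one(self, rng):
        dist = ep.build_distance_sets(rng.normal(size=40), 2)
        cdf = ep.cdf_matrix(dist.d_m, ep.build_range(dist))
        assert np.all(np.diff(cdf, axis=1) >= 0)
        assert np.all(cdf[:, -1] == 1.0)

    def test_range_must_cover_distances(self):
        rset = ep.RangeSet(np.array([0.5]))
        with pytest.raises(ValueError, match="range"):
            ep.cdf_matrix(np.array([[0.2, 0.9]]), rset)


class TestThetaCurves:
    def test_single_template_theta_is_row(self):
        cdf = np.array([[0.25, 1.0]])
        tm, tm1 = ep.theta_curves(cdf, cdf)
        assert np.array_equal(tm, cdf[0]) and np.array_equal(tm1, cdf[0])

    def test_matches_explicit_column_loop(self, rng):
        a, b = rng.uniform(size=(5, 7)), rng.uniform(size=(5, 7))
        tm, tm1 = ep.theta_curves(a, b)
        for q in range(7):
            assert tm[q] == pytest.approx(sum(a[i, q] for i in range(5)) / 5)
            assert tm1[q] == pytest.approx(sum(b[i, q] for i in range(5)) / 5)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            ep.theta_curves(np.ones((2, 3)), np.ones((2, 4)))


class TestProfile:
    def test_constant_series_trivial_profile(self):
        prof = ep.sampen_profile([5.0] * 15, 2)
        assert prof.nbin == 1 and prof.n_undefined == 0
        assert prof.sampen.tolist() == [0.0]

    def test_equals_traditional_sampen_at_every_defined_bin(self, rng):
        x = rng.uniform(size=100)
        prof = ep.sampen_profile(x, 2)
        for q in np.flatnonzero(prof.defined)[:: max(1, prof.nbin // 60)]:
            assert ep.sampen(x, 2, r=prof.range.values[q]) == pytest.approx(
                prof.sampen[q], abs=1e-12
            )

    def test_matrix_route_matches_pooled_route(self, rng):
        # cdf_matrix/theta_curves (materialised) vs sampen_profile (pooled)
        x = quantized_series("uniform", 60, seed=3)
        dist = ep.build_distance_sets(x, 2)
        rset = ep.build_range(dist)
        tm, tm1 = ep.theta_curves(
            ep.cdf_matrix(dist.d_m, rset), ep.cdf_matrix(dist.d_m1, rset)
        )
        prof = ep.sampen_profile(x, 2)
        assert np.allclose(tm, prof.theta_m, atol=1e-14)
        assert np.allclose(tm1, prof.theta_m1, atol=1e-14)

    def test_undefined_bins_are_exactly_below_min_m1_distance(self, rng):
        x = rng.normal(size=60)
        dist = ep.build_distance_sets(x, 2)
        prof = ep.sampen_profile(x, 2)
        expected_undefined = prof.range.values < dist.d_m1.min()
        assert np.array_equal(~prof.defined, expected_undefined)

    def test_bin_carries_its_tolerance(self, rng):
        prof = ep.sampen_profile(rng.uniform(size=50), 2)
        assert prof.range.nbin == prof.nbin == len(prof.sampen)


class TestSummaries:
    def _profile_with(self, values, defined):
        values = np.asarray(values, dtype=float)
        defined = np.asarray(defined, dtype=bool)
        nbin = len(values)
        return ep.EntropyProfile(
            range=ep.RangeSet(np.arange(1.0, nbin + 1)),
            theta_m=np.ones(nbin),
            theta_m1=np.where(defined, 0.5, 0.0),
            sampen=np.where(defined, values, np.nan),
            defined=defined,
            m=2,
            n=50,
        )

    def test_total_and_avg_arithmetic(self):
        prof = self._profile_with([1.0, 2.0, 3.0], [True, True, True])
        assert ep.total_sampen(prof) == 6.0
        assert ep.avg_sampen(prof) == 2.0

    def test_undefined_bins_excluded_from_sum_and_divisor(self):
        prof = self._profile_with([9.9, 1.0, 3.0], [False, True, True])
        assert ep.total_sampen(prof) == 4.0
        assert ep.avg_sampen(prof) == 2.0
        assert ep.avg_sampen(prof, strict_nbin=True) == pytest.approx(4.0 / 3.0)

    def test_degenerate_profile_rejected(self):
        prof = self._profile_with([1.0], [False])
        with pytest.raises(ValueError, match="degenerate"):
            ep.total_sampen(prof)

    def test_summary_counts(self, rng):
        prof = ep.sampen_profile(rng.normal(size=80), 2)
        summary = ep.summarize(prof)
        assert summary.n_defined_bins + summary.n_undefined_bins == prof.nbin
        assert summary.avg_sampen == pytest.approx(
            summary.total_sampen / summary.n_defined_bins
        )
        assert summary.total_sampen >= 0

    def test_constant_series_summary_zero(self):
        summary = ep.summarize(ep.sampen_profile([1.0] * 12, 2))
        assert summary.total_sampen == 0.0 and summary.avg_sampen == 0.0


def test_tolerances_between_range_values_change_nothing(rng):
    """SampEn is a step function of r with steps only at range values."""
    x = quantized_series("uniform", 80, seed=11)
    prof = ep.sampen_profile(x, 2)
    values = prof.range.values
    for _ in range(10):
        j = rng.integers(0, prof.nbin - 1)
        r_mid = rng.uniform(values[j], values[j + 1])
        if r_mid in (values[j], values[j + 1]):
            continue
        lhs, rhs = ep.sampen(x, 2, r=r_mid), ep.sampen(x, 2, r=values[j])
        assert (lhs == rhs) or (np.isnan(lhs) and np.isnan(rhs))


def test_surrogate_shuffling_raises_avg_sampen():
    """Randomisation destroys temporal structure, increasing irregularity."""
    wins = 0
    for seed in range(10):
        x = ep.powerlaw_noise(200, 1.0, seed=seed)
        surr = ep.shuffle_surrogate(x, seed=1000 + seed)
        orig = ep.avg_sampen(ep.sampen_profile(x, 2))
        shuf = ep.avg_sampen(ep.sampen_profile(surr, 2))
        wins += shuf > orig
    assert wins >= 9
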