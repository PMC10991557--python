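"""Bhattacharyya coefficient, centroid-difference probability, temporal split."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import isoniche as iso
from isoniche.compare import ComparisonError


class TestBhattacharyya:
    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(size=5000)
        assert iso.bhattacharyya(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_supports(self):
        assert iso.bhattacharyya(np.linspace(0, 1, 500),
                                 np.linspace(10, 11, 500)) == 0.0

    def test_equal_variance_normal_closed_form(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 100_000)
        b = rng.normal(2, 1, 100_000)
        # BC for N(0,1) vs N(Δ,1) is exp(−Δ²/8)
        assert iso.bhattacharyya(a, b, 100) == pytest.approx(np.exp(-0.5), abs=0.02)

    def test_degenerate_range_convention(self):
        assert iso.bhattacharyya(np.full(10, 2.0), np.full(20, 2.0)) == 1.0

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000), st.sampled_from([10, 50, 100]))
    def test_symmetry_and_bounds(self, seed, n_bins):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, 400)
        b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), 300)
        ab = iso.bhattacharyya(a, b, n_bins)
        assert ab == iso.bhattacharyya(b, a, n_bins)
        assert 0.0 <= ab <= 1.0

    def test_bin_count_sensitivity_is_small_on_smooth_posteriors(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 50_000)
        b = rng.normal(1, 1.2, 50_000)
        values = [iso.bhattacharyya(a, b, nb) for nb in (50, 100, 200)]
        assert max(values) - min(values) <= 0.03


class TestCentroidDifferenceTest:
    def test_hand_enumerated_separated_case(self):
        mu_a = np.zeros((4, 1))
        mu_b = np.full((4, 1), 5.0)
        p, dist = iso.centroid_difference_test(mu_a, mu_b, seed=0)
        assert p == 1.0
        assert dist == pytest.approx(5.0)

    def test_null_calibration(self):
        ps = []
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            mu_a = rng.normal(size=(10_000, 2))
            mu_b = rng.normal(size=(10_000, 2))
            p, _ = iso.centroid_difference_test(mu_a, mu_b, seed=seed)
            ps.append(p)
        assert max(ps) < 0.2

    def test_strong_separation_detected(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            mu_a = rng.normal(0, 1, size=(10_000, 2))
            mu_b = rng.normal(0, 1, size=(10_000, 2)) + [10.0, 0.0]
            p, dist = iso.centroid_difference_test(mu_a, mu_b, seed=seed)
            assert p > 0.99
            assert dist == pytest.approx(10.0, rel=0.05)

    def test_tight_posteriors_far_apart(self):
        rng = np.random.default_rng(5)
        mu_a = rng.normal(0, 0.01, size=(2000, 3))
        mu_b = rng.normal(0, 0.01, size=(2000, 3)) + [10, 0, 0]
        p, _ = iso.centroid_difference_test(mu_a, mu_b, seed=1)
        assert p > 0.999

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 1000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        mu_a = rng.normal(size=(500, 3))
        mu_b = rng.normal(size=(500, 3)) + 0.5
        rot = stats.ortho_group.rvs(3, random_state=rng)
        shift = rng.normal(size=3)
        p1, d1 = iso.centroid_difference_test(mu_a, mu_b, seed=7)
        p2, d2 = iso.centroid_difference_test(mu_a @ rot.T + shift,
                                              mu_b @ rot.T + shift, seed=7)
        assert p1 == pytest.approx(p2, abs=1e-10)
        assert d1 == pytest.approx(d2, abs=1e-10)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ComparisonError):
            iso.centroid_difference_test(np.zeros((3, 1)), np.zeros((3, 1)))


class TestCompareGroups:
    def test_self_comparison(self, two_group_posteriors):
        post, _ = two_group_posteriors
        res = iso.compare_groups(post, post, seed=3)
        assert all(v == pytest.approx(1.0, abs=1e-12) for v in res.bc_per_axis.values())
        assert res.bc_size == pytest.approx(1.0, abs=1e-12)
        assert res.p_centroid_diff == 0.0
        assert res.centroid_distance == 0.0

    def test_planted_single_axis_separation(self):
        rng = np.random.default_rng(9)
        K, d = 20_000, 5
        mu_a = rng.normal(size=(K, d)) * 0.1
        mu_b = rng.normal(size=(K, d)) * 0.1
        mu_b[:, 2] += 10 * 0.1  # 10 posterior sd on axis 3 only
        names = tuple(f"ax{i}" for i in range(d))
        post_a = iso.NichePosterior("a", names, mu_a, np.tile(np.eye(d), (K, 1, 1)))
        post_b = iso.NichePosterior("b", names, mu_b, np.tile(np.eye(d), (K, 1, 1)))
        res = iso.compare_groups(post_a, post_b, seed=2)
        for i, name in enumerate(names):
            if i == 2:
                assert res.bc_per_axis[name] < 0.05
            else:
                assert res.bc_per_axis[name] > 0.9

    def test_identical_data_size_posteriors(self, two_group_posteriors):
        post, _ = two_group_posteriors
        sizes = iso.niche_size(post.sigma_draws)
        assert iso.bhattacharyya(sizes, sizes) > 0.98

    def test_axis_mismatch_rejected(self, two_group_posteriors):
        post_a, _ = two_group_posteriors
        other = iso.NichePosterior.from_fixed([0.0, 0.0], np.eye(2),
                                              K=post_a.K, axis_names=("u", "v"))
        with pytest.raises(ComparisonError, match="axis mismatch"):
            iso.compare_groups(post_a, other)


class TestPeriodSplit:
    def test_boundary_years(self):
        split = iso.PeriodSplit()
        assert split.label(1989) == "period1"
        assert split.label(1990) == "period2"
        assert split.label(1969) is None

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ComparisonError, match="overlap"):
            iso.PeriodSplit((1970, 1990), (1990, 2006))


@pytest.fixture(scope="module")
def exchangeable():
    specs = [
        iso.SpeciesSpec("sp", 60, np.zeros(5), 0.6 * np.eye(5),
                        period_shift=np.zeros(5), period_cov_scale=1.0),
        iso.SpeciesSpec("other", 30, [2, 0, -1, 1, 0], 0.6 * np.eye(5)),
    ]
    return iso.generate_community(specs, iso.default_tracer_map(), seed=5)


class TestTemporalAnalysis:
    def test_exchangeable_periods_look_identical(self, exchangeable):
        res = iso.temporal_analysis(exchangeable, "sp", K=4000, n_mc=500,
                                    seed=3, approaches=("2D",))
        r = res.per_approach["2D"]
        assert r.comparison.p_centroid_diff < 0.15
        assert all(ov.summary.mean > 0.6 for ov in r.overlaps.values())

    def test_shrunken_period2_niche(self):
        specs = [
            iso.SpeciesSpec("sp", 80, np.zeros(5), 0.8 * np.eye(5),
                            period_shift=np.zeros(5), period_cov_scale=0.25),
            iso.SpeciesSpec("other", 30, [2, 0, -1, 1, 0], 0.6 * np.eye(5)),
        ]
        ds = iso.generate_community(specs, iso.default_tracer_map(), seed=6)
        res = iso.temporal_analysis(ds, "sp", K=4000, n_mc=500, seed=3)
        for approach, r in res.per_approach.items():
            assert r.estimable, approach
            p1, p2 = "1970-1989", "1990-2006"
            assert r.sizes[p2].summary.mode < r.sizes[p1].summary.mode
            assert (r.overlaps[(p2, p1)].summary.mean
                    > r.overlaps[(p1, p2)].summary.mean)

    def test_small_period_flagged_not_estimable(self, exchangeable):
        # "other" has no period machinery but few post-1990 samples in 5D? force it:
        keep = (exchangeable.species != "sp") | (exchangeable.year <= 1992)
        ds = exchangeable.subset(keep.to_numpy())
        res = iso.temporal_analysis(ds, "sp", K=1000, n_mc=500, seed=1,
                                    approaches=("5D",))
        r = res.per_approach["5D"]
        if not r.estimable:
            assert "n=" in r.reason
        else:  # enough 1990-1992 samples survived; result must be complete
            assert r.comparison is not None

    def test_deterministic_tables(self, exchangeable):
        r1 = iso.temporal_analysis(exchangeable, "sp", K=1500, n_mc=500,
                                   seed=11, approaches=("2D",))
        r2 = iso.temporal_analysis(exchangeable, "sp", K=1500, n_mc=500,
                                   seed=11, approaches=("2D",))
        assert r1.sizes_table().equals(r2.sizes_table())
        assert r1.overlap_table().equals(r2.overlap_table())
        assert r1.tests_table().equals(r2.tests_table())
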