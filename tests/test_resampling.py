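"""Bootstrap CIs and accumulation curves: determinism, limits, coverage."""

import numpy as np
import pytest

from endevs.decomposition import PooledSample, beta_heterogeneity
from endevs.errors import ValidationError
from endevs.resampling import accumulation_curve, bootstrap_endevs


def disjoint_cohort(n, copies=1, magnitude=2.0):
    """n distinct single-feature deviation patterns, each repeated `copies` times."""
    Z = np.kron(np.eye(n), np.ones((copies, 1))) * magnitude
    Z = Z + 0.001  # strictly positive so every feature ranks
    return Z


class TestBootstrap:
    def test_identical_subjects_mean_one_zero_width(self):
        Z = np.tile([1.0, 2.0, 3.0], (10, 1))
        res = bootstrap_endevs(Z, c=1.0, q=1.0, B=50, seed=0)
        assert res.mean == pytest.approx(1.0, rel=1e-9)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_single_replicate_degenerate_interval(self, rng):
        Z = rng.standard_normal((6, 5))
        res = bootstrap_endevs(Z, c=0.5, B=1, seed=3)
        assert res.ci_low == res.ci_high == res.mean == res.replicates[0]

    def test_reproducibility_and_stream_extension(self, rng):
        Z = rng.standard_normal((12, 8))
        a = bootstrap_endevs(Z, c=0.3, B=40, seed=9)
        b = bootstrap_endevs(Z, c=0.3, B=40, seed=9)
        np.testing.assert_array_equal(a.replicates, b.replicates)
        # growing B extends the replicate stream without reshuffling it
        c = bootstrap_endevs(Z, c=0.3, B=80, seed=9)
        np.testing.assert_array_equal(c.replicates[:40], a.replicates)
        assert bootstrap_endevs(Z, c=0.3, B=40, seed=10).mean != a.mean

    def test_disjoint_point_estimate_and_downward_bootstrap_bias(self):
        """Brute-force enumeration oracle at N=3: resampling duplicates
        subjects, so the bootstrap mean lies strictly below the point
        estimate N."""
        n = 3
        Z = disjoint_cohort(n)
        res = bootstrap_endevs(Z, c=0.01, q=1.0, B=4000, seed=1)
        assert res.point_estimate == pytest.approx(float(n), rel=1e-9)
        # enumerate all 27 equally likely index triples
        from endevs.deviance import deviant_patterns

        psi, _ = deviant_patterns(Z, "absolute-top", 0.01)
        betas = [
            beta_heterogeneity(PooledSample(psi[[i, j, k]]), 1.0).beta
            for i in range(n)
            for j in range(n)
            for k in range(n)
        ]
        exact_mean = np.mean(betas)
        assert exact_mean < n
        mc_se = np.std(betas) / np.sqrt(res.B)
        assert res.mean == pytest.approx(exact_mean, abs=4 * mc_se)

    def test_degenerate_rows_dropped_before_resampling(self):
        Z = np.vstack([disjoint_cohort(4), np.zeros((2, 4))])
        res = bootstrap_endevs(Z, c=1.0, B=10, seed=0)
        assert res.n == 4

    def test_validation(self, rng):
        with pytest.raises(ValidationError):
            bootstrap_endevs(rng.standard_normal((5, 4)), B=0)
        with pytest.raises(ValidationError):
            bootstrap_endevs(rng.standard_normal((1, 4)), B=10)


class TestAccumulation:
    def test_flat_curve_for_identical_subjects(self):
        Z = np.tile([0.5, 1.5, 2.5], (30, 1))
        curve = accumulation_curve(Z, c=1.0, sizes=[5, 15, 25], B=30, seed=2)
        assert all(r.mean == pytest.approx(1.0, rel=1e-9) for r in curve.results)

    def test_full_size_matches_bootstrap_seed_policy(self, rng):
        Z = rng.standard_normal((20, 10))
        curve = accumulation_curve(Z, c=0.3, sizes=[5, 20], B=25, seed=7)
        boot = bootstrap_endevs(Z, c=0.3, B=25, seed=7)
        np.testing.assert_array_equal(curve.results[-1].replicates, boot.replicates)

    def test_expected_curve_non_decreasing(self):
        """With many distinct patterns, larger subsamples discover more of
        them; checked in expectation over seeds."""
        Z = disjoint_cohort(30)
        means = np.zeros(3)
        for seed in range(20):
            curve = accumulation_curve(Z, c=0.01, sizes=[5, 15, 30], B=40, seed=seed)
            means += [r.mean for r in curve.results]
        means /= 20
        assert means[0] < means[1] < means[2]

    def test_without_replacement_exceeds_bootstrap_at_full_size(self):
        # drawing all N subjects without replacement reproduces the point estimate
        Z = disjoint_cohort(10)
        curve = accumulation_curve(Z, c=0.01, sizes=[10], B=15, seed=0, replace=False)
        assert curve.results[0].mean == pytest.approx(10.0, rel=1e-9)

    def test_size_validation(self, rng):
        Z = rng.standard_normal((10, 5))
        with pytest.raises(ValidationError):
            accumulation_curve(Z, sizes=[5, 5], B=2)
        with pytest.raises(ValidationError):
            accumulation_curve(Z, sizes=[5, 50], B=2)
        with pytest.raises(ValidationError):
            accumulation_curve(Z, sizes=[], B=2)

    def test_tidy_frame(self, rng):
        Z = rng.standard_normal((15, 6))
        frame = accumulation_curve(Z, c=0.5, sizes=[5, 15], B=10, seed=4).to_frame()
        assert list(frame.columns) == [
            "mode", "c", "q", "n", "mean", "ci_low", "ci_high", "B", "seed",
        ]
        assert list(frame["n"]) == [5, 15]


def test_ci_coverage_of_estimator_plateau():
    """Percentile-interval sanity on a design with a known-by-construction
    number of deviation patterns: 6 disjoint patterns x 10 subjects each.
    The interval from a single seed should cover the estimator's cross-seed
    plateau value in most runs (loosely: bootstrap-of-beta is biased
    downward at finite n)."""
    Z = disjoint_cohort(6, copies=10)
    assert bootstrap_endevs(Z, c=0.01, B=5, seed=0).point_estimate == pytest.approx(6.0)
    results = [bootstrap_endevs(Z, c=0.01, q=1.0, B=100, seed=s) for s in range(50)]
    plateau = np.mean([r.mean for r in results])
    covered = sum(r.ci_low <= plateau <= r.ci_high for r in results)
    assert covered >= 40  # >= 80% of 50 seeded runs
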