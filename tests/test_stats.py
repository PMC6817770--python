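"""Rank-test correctness against brute force, scipy and invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselmorph import (
    DomainError,
    below_threshold_retest,
    mann_whitney_u,
    summarize,
)


def brute_force_two_sided_p(x, y):
    """Independent oracle: permutation null with pair-counting U.

    U is recomputed for every label arrangement by counting (x > y)
    pairs plus half-ties — a different route than the implementation's
    rank sums — and the two-sided p is the fraction of arrangements at
    least as far from n1·n2/2 as the observed statistic.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(
            1.0 if xi > yi else (0.5 if xi == yi else 0.0)
            for xi in xs for yi in ys
        )

    mu = n1 * len(y) / 2.0
    u_obs = u_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mu) >= abs(u_obs - mu) - 1e-9:
            count += 1
    return count / total


class TestSummarize:
    def test_basic_summary(self):
        s = summarize([1, 2, 3], "g", "metric")
        assert (s.n, s.mean, s.min, s.max) == (3, 2.0, 1.0, 3.0)

    def test_single_value(self):
        s = summarize([4.2], "g", "metric")
        assert s.mean == s.min == s.max == 4.2

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            summarize([], "g", "metric")


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.U == 0
        assert res.method == "exact_enumeration"
        assert res.p_two_sided == pytest.approx(0.1, abs=1e-12)

    def test_identical_two_point_samples(self):
        res = mann_whitney_u([1, 2], [1, 2])
        assert res.U == pytest.approx(2.0)  # n1·n2/2
        assert res.p_two_sided == 1.0

    def test_degenerate_constant_data_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = mann_whitney_u([5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p_two_sided == 1.0

    def test_u_antisymmetry_with_and_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            x = rng.integers(0, 6, size=7).astype(float)
            y = rng.integers(0, 6, size=5).astype(float)
            uxy = mann_whitney_u(x, y).U
            uyx = mann_whitney_u(y, x).U
            assert uxy + uyx == pytest.approx(len(x) * len(y))

    @pytest.mark.parametrize("n1,n2", [(1, 1), (2, 3), (3, 3), (4, 4), (5, 5), (4, 6)])
    def test_exact_p_equals_brute_force(self, n1, n2):
        """Enumeration p matches an independent pair-counting oracle,
        with and without ties, for every small sample-size pair."""
        rng = np.random.default_rng(n1 * 10 + n2)
        for trial in range(4):
            if trial % 2:
                x = rng.integers(0, 4, size=n1).astype(float)  # ties likely
                y = rng.integers(0, 4, size=n2).astype(float)
            else:
                x = rng.normal(size=n1)
                y = rng.normal(1.0, size=n2)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # tiny all-tied draws
                res = mann_whitney_u(x, y, mode="exact")
            if res.method == "degenerate":
                assert res.p_two_sided == 1.0
            else:
                assert res.p_two_sided == pytest.approx(
                    brute_force_two_sided_p(x, y), abs=1e-12
                )

    def test_exact_agrees_with_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(8)
        from scipy.stats import mannwhitneyu

        for _ in range(5):
            x = rng.normal(size=6)
            y = rng.normal(0.8, size=7)
            ours = mann_whitney_u(x, y, mode="exact")
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.U == pytest.approx(ref.statistic)
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-9)

    def test_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            x = rng.normal(size=8)
            y = rng.normal(0.7, size=8)
            p_exact = mann_whitney_u(x, y, mode="exact").p_two_sided
            p_approx = mann_whitney_u(x, y, mode="approx").p_two_sided
            assert abs(p_exact - p_approx) < 0.02

    @given(shift=st.floats(min_value=-2, max_value=2))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, shift):
        rng = np.random.default_rng(abs(hash(round(shift, 6))) % 2**31)
        x = rng.normal(shift, size=6)
        y = rng.normal(size=8)
        p0 = mann_whitney_u(x, y).p_two_sided
        p1 = mann_whitney_u(np.exp(x), np.exp(y)).p_two_sided
        assert p0 == pytest.approx(p1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(DomainError):
            mann_whitney_u([], [1.0])

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(5)
        res = mann_whitney_u(rng.normal(size=40), rng.normal(0.2, size=30))
        assert res.method == "normal_approx"
        assert 0.0 <= res.p_two_sided <= 1.0


class TestBelowThresholdRetest:
    @staticmethod
    def _records(diameter_ratios):
        from vesselmorph import MorphometryRecord

        return [
            MorphometryRecord(
                vessel_id=f"v{i}", lumen_area=1.0, wall_area=1.0, total_area=2.0,
                area_ratio=1.0, equiv_diameter=d, mean_thickness=1.0,
                diameter_ratio=d, excluded=False, exclusion_reason="none",
            )
            for i, d in enumerate(diameter_ratios)
        ]

    def test_threshold_below_all_observations_is_domain_error(self):
        g1 = self._records([5.0, 6.0])
        g2 = self._records([5.5])
        with pytest.raises(DomainError):
            below_threshold_retest(g1, g2, threshold=1.0)

    def test_threshold_above_all_matches_unrestricted_test(self):
        g1 = self._records([2.0, 3.0, 4.0])
        g2 = self._records([2.5, 3.5])
        full = mann_whitney_u([2.0, 3.0, 4.0], [2.5, 3.5])
        restricted = below_threshold_retest(g1, g2, threshold=100.0)
        assert restricted.p_two_sided == full.p_two_sided
        assert restricted.U == full.U

    def test_overlapping_supports_rarely_significant(self):
        """When both restricted samples come from the same law, the
        re-test should usually be non-significant (the published
        below-threshold comparison gave p = 0.817)."""
        rng = np.random.default_rng(123)
        n_significant = 0
        n_runs = 60
        for _ in range(n_runs):
            g1 = self._records(rng.uniform(1.5, 5.0, size=12))
            g2 = self._records(rng.uniform(1.5, 5.0, size=10))
            res = below_threshold_retest(g1, g2, threshold=4.97)
            n_significant += res.p_two_sided < 0.05
        assert n_significant < 0.2 * n_runs
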