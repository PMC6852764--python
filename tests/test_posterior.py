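"""Dirichlet posterior over frequencies and one-sided credible bounds."""

import math

import numpy as np
import pytest

from raredetect import (
    CountsTable,
    CountsTableError,
    dirichlet_posterior_draws,
    posterior_probability_lower_bound,
    posterior_required_n_upper_bound,
    retrospective_report,
)


class TestCountsTable:
    def test_rejects_zero_counts(self):
        with pytest.raises(CountsTableError):
            CountsTable([5, 0])

    def test_rejects_duplicate_names(self):
        with pytest.raises(CountsTableError):
            CountsTable([2, 3], names=["a", "a"])

    def test_empirical_frequencies(self):
        ct = CountsTable([30, 70])
        np.testing.assert_allclose(ct.empirical_frequencies().probs, [0.3, 0.7])
        assert ct.total == 100


class TestDirichletDraws:
    def test_single_population_is_degenerate(self):
        draws = dirichlet_posterior_draws(CountsTable([5]), 50, seed=0)
        np.testing.assert_allclose(draws, 1.0)

    def test_moments_match_closed_form(self):
        """Dirichlet(50,50): mean 0.5, var 0.25/101, checked within 3 SE."""
        draws = dirichlet_posterior_draws(CountsTable([50, 50]), 10_000, seed=3)
        mean = draws[:, 0].mean()
        var = 0.25 / 101
        se_mean = math.sqrt(var / 10_000)
        assert abs(mean - 0.5) < 3 * se_mean
        # variance of the draws against the Dirichlet variance (3 SE, normal
        # approximation to the sampling distribution of a variance)
        se_var = var * math.sqrt(2 / (10_000 - 1))
        assert abs(draws[:, 0].var(ddof=1) - var) < 3 * se_var

    def test_rows_sum_to_one(self):
        draws = dirichlet_posterior_draws(CountsTable([3, 4, 5]), 100, seed=1)
        np.testing.assert_allclose(draws.sum(axis=1), 1.0, atol=1e-12)

    def test_identical_seed_identical_draws(self):
        ct = CountsTable([10, 20])
        a = dirichlet_posterior_draws(ct, 100, seed=42)
        b = dirichlet_posterior_draws(ct, 100, seed=42)
        assert np.array_equal(a, b)

    def test_invalid_draw_count(self):
        with pytest.raises(ValueError):
            dirichlet_posterior_draws(CountsTable([1, 1]), 0, seed=0)


class TestProbabilityLowerBound:
    def test_no_cells_drawn_gives_zero(self):
        s = posterior_probability_lower_bound(
            CountsTable([10, 10]), c=1, n=0, n_draws=50, seed=0
        )
        assert s.point_estimate == 0.0
        assert s.one_sided_bound == 0.0

    def test_concentrated_posterior_gives_tight_bound(self):
        s = posterior_probability_lower_bound(
            CountsTable([500, 500]), c=10, n=30, n_draws=2000, seed=1
        )
        assert s.point_estimate - s.one_sided_bound < 0.02

    def test_point_estimate_at_empirical_frequencies(self):
        """Counts (42,42) give empirical frequencies (0.5,0.5): 30 cells reach 95%."""
        s = posterior_probability_lower_bound(
            CountsTable([42, 42]), c=10, n=30, n_draws=20, seed=0
        )
        assert s.point_estimate >= 0.95


class TestRequiredNUpperBound:
    def test_point_estimate_from_empirical_frequencies(self):
        s = posterior_required_n_upper_bound(
            CountsTable([42, 42]), c=10, p_star=0.95, n_draws=50, seed=0
        )
        assert s.point_estimate == 30

    def test_posterior_concentration_brings_bound_to_point(self):
        s = posterior_required_n_upper_bound(
            CountsTable([10_000, 10_000]), c=10, p_star=0.95, n_draws=400, seed=2
        )
        assert abs(s.one_sided_bound - 30) <= 1

    def test_level_zero_is_minimum_over_draws(self):
        ct = CountsTable([20, 30])
        draws = dirichlet_posterior_draws(ct, 100, seed=5)
        s = posterior_required_n_upper_bound(
            ct, c=2, p_star=0.9, level=0.0, seed=5, draws=draws
        )
        full = posterior_required_n_upper_bound(
            ct, c=2, p_star=0.9, level=1.0, seed=5, draws=draws
        )
        assert s.one_sided_bound <= full.one_sided_bound

    def test_bounds_tighten_as_counts_scale(self):
        """Scaling every count x10 and x100 shrinks the credible gap."""
        gaps = []
        for scale in (1, 10, 100):
            s = posterior_required_n_upper_bound(
                CountsTable([6 * scale, 14 * scale]),
                c=5,
                p_star=0.95,
                n_draws=400,
                seed=11,
            )
            gaps.append(s.one_sided_bound - s.point_estimate)
        assert gaps[0] > gaps[1] > gaps[2] >= 0


class TestRetrospectiveReport:
    def test_oversampled_experiment_detected(self):
        rep = retrospective_report(
            CountsTable([42, 42]), c=10, p_star=0.95, n_draws=100, seed=1,
            curve_points=10,
        )
        assert rep.cells_sequenced == 84
        assert rep.n_star.point_estimate == 30
        assert rep.oversampled

    def test_two_singleton_counts_give_wide_interval(self):
        """Dirichlet(1,1) is uniform on the simplex: huge n* uncertainty."""
        rep = retrospective_report(
            CountsTable([1, 1]), c=1, p_star=0.95, n_draws=2000, seed=3,
            curve_points=5,
        )
        assert rep.n_star.one_sided_bound >= 2 * rep.n_star.point_estimate

    def test_fixed_seed_reproducible(self):
        kwargs = dict(c=5, p_star=0.9, n_draws=80, seed=9, curve_points=8)
        a = retrospective_report(CountsTable([12, 30]), **kwargs)
        b = retrospective_report(CountsTable([12, 30]), **kwargs)
        assert a.n_star == b.n_star
        assert a.prob_at_sequenced == b.prob_at_sequenced
        assert np.array_equal(a.curve, b.curve)

    def test_curve_lower_bound_monotone_in_n(self):
        rep = retrospective_report(
            CountsTable([25, 25, 50]), c=3, p_star=0.9, n_draws=150, seed=4,
            curve_points=12,
        )
        lower = rep.curve[:, 2]
        assert np.all(np.diff(lower) >= -1e-12)
        assert np.all((rep.curve[:, 1:] >= 0) & (rep.curve[:, 1:] <= 1))
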