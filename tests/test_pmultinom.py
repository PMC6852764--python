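"""Rectangular multinomial probabilities via the truncated-Poisson product."""

import numpy as np
import pytest
from scipy.stats import binom

from raredetect import (
    BoundsSpec,
    FrequencyVector,
    brute_force_pmultinom,
    pmultinom,
    random_scenario,
)


class TestFrequencyVector:
    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            FrequencyVector([0.5, -0.5, 1.0])
        with pytest.raises(ValueError):
            FrequencyVector([0.5, 0.4])

    def test_accepts_within_tolerance(self):
        fv = FrequencyVector([0.3, 0.7 + 5e-10])
        assert len(fv) == 2


class TestBoundsSpec:
    def test_missing_side_defaults_to_unbounded(self):
        b = BoundsSpec(lower=[1, -1])
        assert np.all(np.isinf(b.upper))
        b2 = BoundsSpec(upper=[5, 5])
        assert np.all(b2.lower == -1)

    def test_rejects_crossed_bounds(self):
        with pytest.raises(ValueError):
            BoundsSpec(lower=[3], upper=[3])

    def test_requires_some_bound(self):
        with pytest.raises(ValueError):
            BoundsSpec()

    def test_at_least_encoding(self):
        b = BoundsSpec.at_least(10, 3)
        assert np.all(b.lower == 9)
        assert b.lower_only


class TestPmultinomExamples:
    def test_both_categories_at_least_one_of_two_draws(self, half_half):
        """Only (1,1) of the 4 equally likely ordered outcomes qualifies."""
        b = BoundsSpec(lower=[0, 0])
        assert pmultinom(b, 2, half_half) == pytest.approx(0.5, abs=1e-12)

    def test_binomial_closed_form(self, half_half):
        """Both >= 2 of 4 fair draws: C(4,2)/2^4 = 0.375."""
        b = BoundsSpec(lower=[1, 1])
        assert pmultinom(b, 4, half_half) == pytest.approx(0.375, abs=1e-12)

    def test_unbounded_event_is_certain(self, half_half):
        b = BoundsSpec(lower=[-1, -1])
        for n in (0, 1, 17):
            assert pmultinom(b, n, half_half) == 1.0

    def test_detection_threshold_brackets_095(self, half_half):
        """Two half-frequency subpopulations at c=10 cross 95% at n=30."""
        b = BoundsSpec.at_least(10, 2)
        assert pmultinom(b, 30, half_half) >= 0.95
        assert pmultinom(b, 29, half_half) < 0.95

    def test_zero_frequency_constrained_category(self):
        fv = FrequencyVector([0.0, 1.0])
        assert pmultinom(BoundsSpec(lower=[0, 0]), 5, fv) == 0.0
        # unconstrained zero category: reduces to the other one
        assert pmultinom(BoundsSpec(lower=[-1, 2]), 5, fv) == pytest.approx(1.0)

    def test_single_category_deterministic(self):
        fv = FrequencyVector([1.0])
        assert pmultinom(BoundsSpec(lower=[2]), 5, fv) == pytest.approx(1.0)
        assert pmultinom(BoundsSpec(lower=[5]), 5, fv) == pytest.approx(0.0)

    def test_n_zero_membership(self, half_half):
        assert pmultinom(BoundsSpec(lower=[-1, -1]), 0, half_half) == 1.0
        assert pmultinom(BoundsSpec(lower=[0, -1]), 0, half_half) == 0.0

    def test_dimension_mismatch_rejected(self, half_half):
        with pytest.raises(ValueError):
            pmultinom(BoundsSpec(lower=[0, 0, 0]), 5, half_half)


class TestPmultinomInvariants:
    def test_oracle_equivalence_randomized(self):
        """Product-formula result matches exhaustive enumeration."""
        for seed in range(50):
            probs, bounds, n = random_scenario(seed, k_max=3, n_max=40)
            fast = pmultinom(bounds, n, probs, method="exact")
            slow = brute_force_pmultinom(bounds, n, probs)
            assert fast == pytest.approx(slow, abs=1e-9), f"seed={seed}"

    def test_complement_consistency_k2(self):
        """P(E) plus the disjoint rectangles covering not-E sums to 1."""
        fv = FrequencyVector([0.35, 0.65])
        n, a1, a2 = 25, 4, 7
        p_event = pmultinom(BoundsSpec(lower=[a1, a2]), n, fv)
        # not-E = {N1 <= a1} ∪ {N1 > a1, N2 <= a2}, disjoint rectangles
        p_low1 = pmultinom(BoundsSpec(lower=[-1, -1], upper=[a1, np.inf]), n, fv)
        p_rest = pmultinom(BoundsSpec(lower=[a1, -1], upper=[np.inf, a2]), n, fv)
        assert p_event + p_low1 + p_rest == pytest.approx(1.0, abs=1e-9)

    def test_binomial_reduction(self):
        """k=2 with one constrained category equals a binomial CDF difference."""
        fv = FrequencyVector([0.23, 0.77])
        n, a, b = 40, 3, 12
        got = pmultinom(BoundsSpec(lower=[a, -1], upper=[b, np.inf]), n, fv)
        expected = binom.cdf(b, n, 0.23) - binom.cdf(a, n, 0.23)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_n_for_lower_only_events(self):
        fv = FrequencyVector([0.1, 0.3, 0.6])
        b = BoundsSpec(lower=[2, 4, -1])
        probs = [pmultinom(b, n, fv) for n in range(0, 120)]
        assert all(q >= p - 1e-12 for p, q in zip(probs, probs[1:]))

    def test_alpha_invariance(self):
        """The Poissonization constant cancels: alpha=n and alpha=n/2 agree."""
        fv = FrequencyVector([0.3, 0.7])
        b = BoundsSpec(lower=[2, 4])
        full = pmultinom(b, 20, fv, method="exact")
        halved = pmultinom(b, 20, fv, method="exact", _alpha=10.0)
        assert full == pytest.approx(halved, abs=1e-8)

    def test_backend_agreement_on_fixed_events(self):
        fv = FrequencyVector([0.01] * 6 + [0.94])
        b = BoundsSpec.at_least(10, 7)
        for n in (1000, 10_000):
            exact = pmultinom(b, n, fv, method="exact")
            approx = pmultinom(b, n, fv, method="approximate")
            assert approx == pytest.approx(exact, abs=1e-5)

    def test_result_in_unit_interval(self):
        for seed in range(30):
            probs, bounds, n = random_scenario(seed + 1000)
            p = pmultinom(bounds, n, probs)
            assert 0.0 <= p <= 1.0
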