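"""Weibull observer model and synthetic choice simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acuityfit import (
    ChoiceData,
    PsychometricParams,
    generate_dog_session,
    make_study_fixture,
    params_for_threshold,
    performance_axis,
    psi,
    simulate_choices,
    weibull_quantile,
)
from acuityfit.observer import STUDY_PROFILES


class TestPsi:
    def test_lower_asymptote_is_guess_rate(self):
        p = PsychometricParams(a=3.0, b=2.0)
        assert psi(0.0, p) == pytest.approx(0.5)

    def test_at_scale_parameter(self):
        # x = a makes the exponent exactly -1 regardless of b
        for b in (0.5, 1.0, 4.0):
            p = PsychometricParams(a=7.0, b=b, lambda_=0.0)
            assert psi(7.0, p) == pytest.approx(0.5 + 0.5 * (1 - math.exp(-1)), abs=1e-12)

    def test_upper_asymptote_is_one_minus_lapse(self):
        p = PsychometricParams(a=1.0, b=2.0, lambda_=0.1)
        assert psi(1e6, p) == pytest.approx(0.9)

    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(0.2, 10.0),
        lam=st.floats(0.0, 0.2),
        x1=st.floats(0.0, 100.0),
        x2=st.floats(0.0, 100.0),
    )
    @settings(max_examples=150, derandomize=True)
    def test_monotone_and_bounded(self, a, b, lam, x1, x2):
        p = PsychometricParams(a=a, b=b, lambda_=lam)
        lo, hi = sorted((x1, x2))
        assert psi(lo, p) <= psi(hi, p) + 1e-12
        assert 0.5 - 1e-12 <= psi(lo, p) <= 1 - lam + 1e-12

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            psi(-1.0, PsychometricParams(a=1.0, b=1.0))


class TestQuantileInverse:
    def test_round_trip_through_psi(self):
        p = PsychometricParams(a=6.3, b=2.7, lambda_=0.12)
        for level in (0.5, 0.6, 0.75, 0.87):
            x = weibull_quantile(p, level)
            assert psi(x, p) == pytest.approx(level, abs=1e-10)

    def test_level_at_guess_rate_is_origin(self):
        assert weibull_quantile(PsychometricParams(a=2.0, b=3.0), 0.5) == 0.0

    def test_unattainable_level_rejected(self):
        p = PsychometricParams(a=1.0, b=1.0, lambda_=0.2)
        with pytest.raises(ValueError):
            weibull_quantile(p, 0.85)

    def test_params_for_threshold_places_crossing(self):
        prm = params_for_threshold(12.0, axis_origin=30.0, b=3.0, lambda_=0.05)
        x = performance_axis(12.0, 30.0)
        assert psi(x, prm) == pytest.approx(0.75, abs=1e-12)

    def test_threshold_at_origin_impossible(self):
        with pytest.raises(ValueError):
            params_for_threshold(10.0, axis_origin=10.0)


class TestSimulateChoices:
    def test_perfect_observer_always_correct(self):
        sched = generate_dog_session([2, 4, 8], 10, seed=0)
        prm = PsychometricParams(a=1e-6, b=1.0, lambda_=0.0)
        data = simulate_choices(sched, prm, seed=1, axis_origin=16.0)
        assert np.all(data.n_correct == data.n_total)

    def test_hopeless_observer_at_chance(self):
        sched = generate_dog_session([2, 4, 8], 20, seed=0)
        prm = PsychometricParams(a=1e9, b=1.0, lambda_=0.0)
        data = simulate_choices(sched, prm, seed=1)
        pooled = data.n_correct.sum() / data.n_total.sum()
        # binomial 99.9% interval around 1/2 at 60 trials
        assert abs(pooled - 0.5) < 3.3 * 0.5 / math.sqrt(data.n_total.sum())

    def test_bit_reproducible_from_seed(self):
        sched = generate_dog_session([2, 4, 8, 16], 20, seed=9)
        prm = PsychometricParams(a=10.0, b=3.0, lambda_=0.05)
        d1 = simulate_choices(sched, prm, seed=77)
        d2 = simulate_choices(sched, prm, seed=77)
        assert d1 == d2

    def test_first_20_rule_truncates_extra_trials(self):
        sched = generate_dog_session([2.0, 4.0, 8.0], 30, seed=2)
        prm = PsychometricParams(a=10.0, b=3.0)
        data = simulate_choices(sched, prm, seed=3, max_scored_per_freq=20)
        assert np.all(data.n_total == 20)

    def test_monte_carlo_mean_matches_analytic_at_threshold(self):
        """Mean correct fraction at the 75% point converges to 0.75.

        The canonical example observer: threshold 10 cpd on the 2-30 cpd
        grid, b = 3, lapse 0.05, 20 trials per frequency.
        """
        origin = 30.0
        prm = params_for_threshold(10.0, origin, b=3.0, lambda_=0.05)
        freqs = list(range(2, 31, 2))
        hits = trials = 0
        for seed in range(500):
            sched = generate_dog_session(freqs, 20, seed=seed)
            data = simulate_choices(sched, prm, seed=10_000 + seed, axis_origin=origin)
            i = list(data.frequencies).index(10.0)
            hits += data.n_correct[i]
            trials += data.n_total[i]
        assert hits / trials == pytest.approx(0.75, abs=0.02)

    def test_law_of_large_numbers_convergence(self):
        """Per-frequency proportions converge to psi at 10^4 trials."""
        prm = PsychometricParams(a=8.0, b=2.0, lambda_=0.1)
        sched = generate_dog_session([4.0, 10.0], 10_000, seed=0)
        data = simulate_choices(sched, prm, seed=5, max_scored_per_freq=None)
        for f, k, n in data.records:
            expected = psi(performance_axis(f, 10.0), prm)
            assert k / n == pytest.approx(expected, abs=0.01)


class TestStudyFixture:
    @pytest.mark.parametrize(
        "profile,threshold,expected_grid",
        [
            ("dog_bright", 8.0, tuple(float(f) for f in range(2, 17, 2))),
            ("dog_bright", 19.5, tuple(float(f) for f in range(2, 31, 2))),
            ("dog_dim", 1.8, (0.5, 2.0, 4.0, 6.0, 8.0, 10.0)),
            ("human_bright", 44.2, (30.0, 39.0, 44.0, 50.0, 64.0, 70.0, 78.0)),
            ("human_dim", 7.0, (0.5, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0)),
        ],
    )
    def test_study_grids(self, profile, threshold, expected_grid):
        data = make_study_fixture(profile, threshold, seed=0)
        assert tuple(data.frequencies) == expected_grid
        assert np.all(data.n_total == 20)

    def test_bright_dog_grid_extends_for_high_acuity(self):
        low = make_study_fixture("dog_bright", 8.0, seed=0)
        high = make_study_fixture("dog_bright", 19.5, seed=0)
        assert len(low.records) == 8
        assert len(high.records) == 15

    def test_easy_frequencies_score_near_upper_asymptote(self):
        """At the easiest frequency a high-acuity dog scores near 1 - lapse."""
        pooled = []
        for seed in range(30):
            d = make_study_fixture("dog_bright", 19.5, seed=seed, lambda_=0.15)
            pooled.append(d.n_correct[0] / d.n_total[0])
        assert np.mean(pooled) == pytest.approx(0.85, abs=0.04)

    def test_threshold_outside_span_flagged(self):
        data = make_study_fixture("dog_dim", 0.3, seed=0)
        assert "true_threshold_outside_grid_span" in data.notes

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError, match="profile"):
            make_study_fixture("cat_bright", 5.0, seed=0)

    def test_species_condition_metadata(self):
        for profile, meta in STUDY_PROFILES.items():
            d = make_study_fixture(profile, 0.6 * max(meta["grid"]), seed=1)
            assert d.species == meta["species"]
            assert d.condition == meta["condition"]


class TestChoiceDataInvariants:
    def test_counts_must_be_consistent(self):
        with pytest.raises(ValueError):
            ChoiceData("x", "dog", "bright", ((2.0, 21, 20),))

    def test_frequencies_distinct_and_positive(self):
        with pytest.raises(ValueError):
            ChoiceData("x", "dog", "bright", ((2.0, 1, 20), (2.0, 2, 20)))
        with pytest.raises(ValueError):
            ChoiceData("x", "dog", "bright", ((-2.0, 1, 20),))
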