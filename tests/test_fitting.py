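"""Maximum-likelihood fitting, threshold interpolation, cohort summaries."""

import math

import numpy as np
import pytest

from acuityfit import (
    ChoiceData,
    PsychometricParams,
    fit_all,
    fit_ml,
    make_study_fixture,
    neg_log_likelihood,
    psi,
    threshold_at,
)
from conftest import grid_oracle_min_nll


def _data(records, **kw):
    defaults = dict(subject_id="t", species="dog", condition="bright")
    defaults.update(kw)
    return ChoiceData(records=tuple(records), **defaults)


class TestNegLogLikelihood:
    def test_single_frequency_at_chance(self):
        """k=10 of n=20 under psi = 1/2 gives exactly 20 ln 2 nats."""
        data = _data([(5.0, 10, 20)], axis_origin=5.0)  # x' = 0 -> psi = gamma
        prm = PsychometricParams(a=3.0, b=2.0)
        assert neg_log_likelihood(prm, data) == pytest.approx(20 * math.log(2), abs=1e-9)

    def test_invariant_to_record_order(self):
        recs = [(2.0, 18, 20), (6.0, 14, 20), (10.0, 11, 20)]
        prm = PsychometricParams(a=5.0, b=2.0, lambda_=0.1)
        a = neg_log_likelihood(prm, _data(recs, axis_origin=12.0))
        b = neg_log_likelihood(prm, _data(recs[::-1], axis_origin=12.0))
        assert a == pytest.approx(b, abs=1e-12)

    def test_saturated_fit_is_optimal(self):
        """Data lying exactly on a psi curve make those params the optimum."""
        prm = PsychometricParams(a=6.0, b=2.0, lambda_=0.1)
        origin = 12.0
        n = 1000
        recs = []
        for f in (2.0, 4.0, 6.0, 8.0, 10.0):
            p = psi(origin - f, prm)
            recs.append((f, round(p * n), n))
        data = _data(recs, axis_origin=origin)
        nll_true = neg_log_likelihood(prm, data)
        for a_alt, b_alt, l_alt in [(4.0, 2.0, 0.1), (6.0, 3.0, 0.1), (6.0, 2.0, 0.0)]:
            alt = PsychometricParams(a=a_alt, b=b_alt, lambda_=l_alt)
            assert neg_log_likelihood(alt, data) >= nll_true - 1e-6

    def test_clamping_keeps_nll_finite(self):
        data = _data([(1.0, 20, 20), (2.0, 0, 20), (3.0, 10, 20)], axis_origin=20.0)
        prm = PsychometricParams(a=1e-4, b=8.0, lambda_=0.0)  # psi ~ 1 everywhere
        assert math.isfinite(neg_log_likelihood(prm, data))


class TestThresholdAt:
    def test_closed_form_b_one(self):
        """b=1, a=10, no lapse: the 75% point sits at a ln 2 on the axis."""
        prm = PsychometricParams(a=10.0, b=1.0, lambda_=0.0)
        origin = 30.0
        thr = threshold_at(prm, origin, level=0.75)
        assert origin - thr == pytest.approx(10 * math.log(2), abs=1e-10)

    def test_round_trip_through_psi(self):
        prm = PsychometricParams(a=7.7, b=3.3, lambda_=0.18)
        origin = 16.0
        thr = threshold_at(prm, origin, level=0.75)
        assert psi(origin - thr, prm) == pytest.approx(0.75, abs=1e-10)

    def test_level_outside_range_rejected(self):
        prm = PsychometricParams(a=1.0, b=1.0, lambda_=0.2)
        with pytest.raises(ValueError):
            threshold_at(prm, 10.0, level=0.9)


class TestFitML:
    def test_parameter_recovery_large_n(self):
        """With many trials per frequency the 12 cpd truth is recovered closely."""
        origin = 16.0
        prm = PsychometricParams(a=5.0, b=3.0, lambda_=0.05)
        # analytic threshold of this observer
        from acuityfit import weibull_quantile

        true_thr = origin - weibull_quantile(prm, 0.75)
        rng = np.random.default_rng(4)
        recs = []
        for f in (2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0):
            p = psi(origin - f, prm)
            n = 400
            recs.append((f, int(rng.binomial(n, p)), n))
        fr = fit_ml(_data(recs, axis_origin=origin))
        assert fr.converged
        assert fr.threshold_cpd == pytest.approx(true_thr, abs=0.5)

    def test_all_chance_data_not_converged(self):
        recs = [(f, 10, 20) for f in (2.0, 6.0, 10.0, 14.0)]
        fr = fit_ml(_data(recs))
        assert not fr.converged
        assert math.isnan(fr.threshold_cpd)

    def test_below_three_frequencies_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_ml(_data([(2.0, 15, 20), (4.0, 12, 20)]))

    def test_lapse_bound_respected(self):
        for seed in range(10):
            d = make_study_fixture("dog_bright", 10.0, seed=seed)
            fr = fit_ml(d)
            assert 0.0 <= fr.params.lambda_ <= 0.2
            assert 0.8 <= fr.upper_asymptote <= 1.0

    def test_fitted_function_monotone_on_performance_axis(self, dog_bright_fixture):
        fr = fit_ml(dog_bright_fixture)
        xs = np.linspace(0, fr.axis_origin, 50)
        ys = psi(xs, fr.params)
        assert np.all(np.diff(ys) >= -1e-12)

    def test_optimizer_not_worse_than_grid_oracle(self):
        """Multistart ML matches a dense brute-force grid search in NLL."""
        rng = np.random.default_rng(12)
        for _ in range(8):
            freqs = np.array([2.0, 4.0, 6.0, 8.0, 12.0])
            origin = 12.0
            truth = PsychometricParams(
                a=float(rng.uniform(2, 10)),
                b=float(rng.uniform(0.5, 6)),
                lambda_=float(rng.uniform(0, 0.2)),
            )
            ks = rng.binomial(20, psi(origin - freqs, truth))
            data = _data(
                [(f, int(k), 20) for f, k in zip(freqs, ks)], axis_origin=origin
            )
            fr = fit_ml(data)
            nll_fit = -fr.log_likelihood
            nll_grid = grid_oracle_min_nll(freqs, ks, np.full(5, 20), origin)
            assert nll_fit <= nll_grid + 1e-3

    def test_deterministic(self, dog_bright_fixture):
        f1 = fit_ml(dog_bright_fixture)
        f2 = fit_ml(dog_bright_fixture)
        assert f1 == f2


class TestFitAll:
    def test_cohort_cardinality(self):
        cohort = [
            make_study_fixture("dog_bright", thr, seed=i, subject_id=f"dog{i}")
            for i, thr in enumerate(np.linspace(6, 18, 7))
        ] + [
            make_study_fixture("human_bright", thr, seed=i, subject_id=f"hum{i}")
            for i, thr in enumerate(np.linspace(33, 44, 7))
        ]
        table = fit_all(cohort)
        assert len(table) == 14
        assert set(table["species"]) == {"dog", "human"}

    def test_empty_dataset(self):
        table = fit_all([])
        assert len(table) == 0

    def test_failures_flagged_not_raised(self):
        bad = _data([(f, 10, 20) for f in (2.0, 6.0, 10.0)])  # pure chance
        good = make_study_fixture("dog_bright", 10.0, seed=0)
        table = fit_all([bad, good])
        assert len(table) == 2
        assert not table.iloc[0]["converged"]
        assert table.iloc[1]["converged"]

    def test_recovered_range_tracks_truth(self):
        """Bright-light dog cohort thresholds in [5.5, 19.5] fit back within [4.5, 21].

        Uses the canonical example observer (b = 3, lapse 0.05) at 20 trials
        per frequency.
        """
        rng = np.random.default_rng(7)
        cohort = [
            make_study_fixture(
                "dog_bright", float(rng.uniform(5.5, 19.5)), seed=100 + i,
                subject_id=f"d{i}", b=3.0, lambda_=0.05,
            )
            for i in range(60)
        ]
        table = fit_all(cohort)
        fitted = table.loc[table["converged"], "threshold_cpd"].dropna()
        assert len(fitted) >= 50
        # rare single-subject outliers just beyond the band are sampling noise
        assert fitted.between(4.5, 21.0).mean() >= 0.95
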