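import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meropk import (
    classify_acceptance,
    evaluate_records,
    mape,
    mpe,
    mpe_confidence_interval,
    prediction_error,
)
from meropk.forecast import PredictionRecord
from meropk.metrics import EvaluationResult


def rec(pe, subject_id="S1", obs=10.0, **kw):
    """Record with a prescribed symmetric prediction error."""
    pred = obs * (2.0 + pe) / (2.0 - pe)
    return PredictionRecord(
        subject_id=subject_id,
        time=kw.get("time", 1.0),
        observed=obs,
        predicted=pred,
        prediction_type="a_priori",
        occasion_index=1,
    )


class TestPredictionError:
    def test_worked_example(self):
        assert prediction_error(12.0, 8.0) == pytest.approx(0.4)

    def test_identity_case(self):
        assert prediction_error(10.0, 10.0) == 0.0

    def test_limit_is_plus_200_percent(self):
        assert prediction_error(10.0, 1e-12) == pytest.approx(2.0, abs=1e-9)

    def test_undefined_for_nonpositive_sum(self):
        with pytest.raises(ValueError):
            prediction_error(0.0, 0.0)

    @given(
        st.floats(0.01, 1e4),
        st.floats(0.01, 1e4),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetric_and_bounded(self, a, b):
        pe = prediction_error(a, b)
        assert pe == pytest.approx(-prediction_error(b, a), rel=1e-9, abs=1e-12)
        assert -2.0 < pe < 2.0

    @given(st.floats(0.01, 1e3), st.floats(0.01, 1e3), st.floats(0.001, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_scale_free(self, a, b, s):
        assert prediction_error(a * s, b * s) == pytest.approx(
            prediction_error(a, b), rel=1e-9, abs=1e-12
        )


class TestMedianStatistics:
    def test_mpe_odd_count_median(self):
        assert mpe([rec(-0.1), rec(0.0), rec(0.3)]) == pytest.approx(0.0, abs=1e-9)

    def test_mpe_even_count_interpolates(self):
        assert mpe([rec(0.1), rec(0.3)]) == pytest.approx(20.0)

    def test_mpe_zero_when_predictions_match(self):
        assert mpe([rec(0.0) for _ in range(5)]) == 0.0

    def test_mape_median_of_absolute_errors(self):
        assert mape([rec(-0.2), rec(0.1), rec(0.4)]) == pytest.approx(20.0)

    def test_mape_all_zero(self):
        assert mape([rec(0.0), rec(0.0)]) == 0.0

    def test_mape_half_normal_median(self):
        """For PE ~ N(0, 0.1), MAPE -> 100 * 0.1 * Phi^-1(0.75) ~= 6.745%."""
        rng = np.random.default_rng(0)
        pes = np.clip(rng.normal(0.0, 0.1, 100_000), -1.9, 1.9)
        records = [rec(p, subject_id=f"S{i}") for i, p in enumerate(pes[:2000])]
        # large-sample check done directly on the PE draws
        assert np.median(np.abs(pes)) * 100 == pytest.approx(6.745, abs=0.15)
        assert mape(records) == pytest.approx(6.745, abs=0.6)

    def test_empty_records_error(self):
        with pytest.raises(ValueError):
            mpe([])

    def test_order_invariance(self):
        records = [rec(p, subject_id=f"S{i}") for i, p in enumerate([0.3, -0.2, 0.1])]
        assert mpe(records) == mpe(records[::-1])
        assert mape(records) == mape(records[::-1])

    def test_stratified_partition_preserves_record_multiset(self):
        records = [
            rec(p, subject_id=f"S{i}") for i, p in enumerate([-0.3, -0.1, 0.0, 0.2, 0.4])
        ]
        strata = [records[:2], records[2:]]
        recombined = [r for part in strata for r in part]
        assert sorted(r.predicted for r in recombined) == sorted(
            r.predicted for r in records
        )
        assert mpe(recombined) == mpe(records)


class TestBootstrapCI:
    def test_identical_pes_give_degenerate_interval(self):
        records = [rec(0.1, subject_id=f"S{i}") for i in range(10)]
        assert mpe_confidence_interval(records, n_boot=200, seed=0) == (
            pytest.approx(10.0),
            pytest.approx(10.0),
        )

    def test_seed_determinism(self):
        rng = np.random.default_rng(3)
        records = [
            rec(p, subject_id=f"S{i}")
            for i, p in enumerate(rng.normal(0, 0.2, 50))
        ]
        ci1 = mpe_confidence_interval(records, n_boot=300, seed=7)
        ci2 = mpe_confidence_interval(records, n_boot=300, seed=7)
        assert ci1 == ci2

    def test_zero_centered_distribution_ci_usually_covers_zero(self):
        """Coverage: ~95% of replicate experiments include zero (reduced reps)."""
        rng = np.random.default_rng(11)
        covered = 0
        n_exp = 40
        for e in range(n_exp):
            records = [
                rec(p, subject_id=f"S{i}")
                for i, p in enumerate(np.clip(rng.normal(0, 0.3, 200), -1.9, 1.9))
            ]
            lo, hi = mpe_confidence_interval(records, n_boot=300, seed=e)
            covered += lo <= 0.0 <= hi
        assert covered >= 0.85 * n_exp


class TestAcceptanceClassification:
    @pytest.mark.parametrize(
        "mpe_p,ci,mape_p,acc,prec",
        [
            (0.13, (-7.1, 9.9), 29.4, True, True),  # clinically acceptable
            (5.0, (-3.0, 12.0), 92.0, True, False),  # precision failure
            (12.7, (7.6, 18.0), 28.0, False, True),  # CI excludes zero
            (25.0, (-1.0, 40.0), 28.0, False, True),  # MPE outside +/-20
            (-20.0, (-30.0, 5.0), 30.0, True, True),  # boundary values included
        ],
    )
    def test_verdicts(self, mpe_p, ci, mape_p, acc, prec):
        result = EvaluationResult(
            mpe_percent=mpe_p, mape_percent=mape_p, mpe_ci95=ci, n_records=100
        )
        result = classify_acceptance(result)
        assert result.acceptable_accuracy is acc
        assert result.acceptable_precision is prec

    def test_evaluate_records_end_to_end(self):
        rng = np.random.default_rng(5)
        draws = np.clip(rng.normal(0.0, 0.15, 120), -1.9, 1.9)
        draws -= np.median(draws)  # exactly zero-centered PE distribution
        records = [
            rec(p, subject_id=f"S{i % 30}", time=float(i))
            for i, p in enumerate(draws)
        ]
        res = evaluate_records(records, n_boot=300, seed=1)
        assert res.n_records == 120
        assert res.acceptable_accuracy and res.acceptable_precision
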