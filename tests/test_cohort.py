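import numpy as np
import pytest

from meropk import (
    DoseEvent,
    Observation,
    Subject,
    apply_inclusion_filter,
    assign_occasions,
    egfr_ckdepi,
    egfr_cockcroft_gault,
    impute_missing_covariates,
    load_bundled_model,
    map_residual_diuresis_category,
    read_dataset,
    write_dataset,
)
from meropk.synthetic import default_recipe, generate_cohort

from conftest import make_ii_subject


class TestOccasions:
    def test_doses_without_intervening_observation_merge(self):
        s = Subject(
            subject_id="A",
            doses=[DoseEvent(t, 1000, 0.5) for t in (0.0, 8.0, 16.0)],
            observations=[Observation(7.5, 10.0), Observation(23.0, 8.0)],
        )
        part = assign_occasions(s)
        assert part.n_occasions == 2
        assert part.boundaries[0] == (0.0, 8.0)
        assert part.boundaries[1][0] == 8.0  # doses at 8 and 16 merged
        assert part.observation_occasions == [1, 2]

    def test_single_dose_single_observation(self):
        s = Subject(
            subject_id="B",
            doses=[DoseEvent(0.0, 1000, 0.5)],
            observations=[Observation(6.0, 10.0)],
        )
        part = assign_occasions(s)
        assert part.n_occasions == 1
        assert part.observation_occasions == [1]

    def test_continuous_infusion_splits_at_sample_midpoints(self):
        s = Subject(
            subject_id="C",
            dosing_strategy="CI",
            doses=[DoseEvent(0.0, 6000.0, 48.0)],
            observations=[Observation(10.0, 12.0), Observation(30.0, 11.0)],
        )
        part = assign_occasions(s)
        assert part.n_occasions == 2
        assert part.boundaries[0] == (0.0, 20.0)
        assert part.observation_occasions == [1, 2]

    def test_continuous_infusion_with_bag_changes_uses_dose_rule(self):
        s = Subject(
            subject_id="C2",
            dosing_strategy="CI",
            doses=[DoseEvent(0.0, 3000.0, 24.0), DoseEvent(24.0, 3000.0, 24.0)],
            observations=[Observation(20.0, 12.0), Observation(44.0, 11.0)],
        )
        part = assign_occasions(s)
        assert part.n_occasions == 2
        assert part.boundaries[0] == (0.0, 24.0)

    def test_observation_before_first_dose_flagged(self):
        s = Subject(
            subject_id="D",
            doses=[DoseEvent(2.0, 1000, 0.5)],
            observations=[Observation(1.0, 5.0), Observation(6.0, 10.0)],
        )
        part = assign_occasions(s)
        assert part.has_predose_observations
        assert part.observation_occasions == [0, 1]

    def test_stable_under_appending_later_observations(self):
        s1 = make_ii_subject(obs=((7.75, 12.0),), n_doses=3)
        s2 = make_ii_subject(obs=((7.75, 12.0), (23.0, 8.0)), n_doses=3)
        p1, p2 = assign_occasions(s1), assign_occasions(s2)
        assert p2.boundaries[0] == p1.boundaries[0]
        assert p2.observation_occasions[0] == p1.observation_occasions[0]
        # idempotent
        assert assign_occasions(s2).boundaries == p2.boundaries


class TestInclusionFilter:
    def test_two_observations_in_one_occasion_excluded(self):
        s = make_ii_subject(obs=((6.0, 12.0), (7.5, 10.0)), n_doses=1)
        _, excluded = apply_inclusion_filter([s])
        assert excluded[0][1] == "observations_span_fewer_than_2_occasions"

    def test_short_crrt_excluded(self):
        s = make_ii_subject(crrt_hours_after_first_dose=23.0)
        _, excluded = apply_inclusion_filter([s])
        assert excluded[0][1] == "crrt_duration<24h"

    def test_single_observation_excluded(self):
        s = make_ii_subject(obs=((7.75, 12.0),))
        _, excluded = apply_inclusion_filter([s])
        assert excluded[0][1] == "fewer_than_2_observations"

    def test_generated_cohort_passes_by_construction(self, small_cohort):
        included, excluded = apply_inclusion_filter(small_cohort)
        assert len(included) == len(small_cohort) and not excluded


class TestCovariates:
    @pytest.mark.parametrize("category,expected", [(1, 1000.0), (2, 500.0), (3, 0.0)])
    def test_residual_diuresis_category_lower_limits(self, category, expected):
        assert map_residual_diuresis_category(category) == expected

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            map_residual_diuresis_category(4)

    def test_imputation_uses_model_population_median(self, ojeanson):
        s = make_ii_subject(residual_diuresis=None)
        s2 = impute_missing_covariates(s, ojeanson)
        assert s2.residual_diuresis == 845.0

    def test_imputation_never_overwrites_and_is_idempotent(self, ojeanson):
        s = make_ii_subject(residual_diuresis=200.0)
        s2 = impute_missing_covariates(s, ojeanson)
        assert s2.residual_diuresis == 200.0
        s3 = impute_missing_covariates(impute_missing_covariates(s, ojeanson), ojeanson)
        assert s3.residual_diuresis == 200.0

    def test_imputed_value_differs_per_model(self):
        oj = load_bundled_model("ojeanson2021")
        ull = load_bundled_model("ulldemolins2015")
        s = make_ii_subject(residual_diuresis=None)
        assert (
            impute_missing_covariates(s, oj).residual_diuresis
            != impute_missing_covariates(s, ull).residual_diuresis
        )

    def test_missing_median_raises(self, minimal_spec, ojeanson):
        spec = ojeanson.model_copy(update={"population_medians": {}})
        s = make_ii_subject(residual_diuresis=None)
        with pytest.raises(KeyError, match="residual_diuresis"):
            impute_missing_covariates(s, spec)


class TestEgfr:
    def test_cockcroft_gault_hand_computed(self):
        # ((140-60)*77)/(72*2.1) = 40.74 mL/min
        assert egfr_cockcroft_gault(60, 77, 2.1, "male") == pytest.approx(40.74, abs=0.01)

    def test_female_factor_is_085(self):
        m = egfr_cockcroft_gault(60, 77, 2.1, "male")
        f = egfr_cockcroft_gault(60, 77, 2.1, "female")
        assert f / m == pytest.approx(0.85)

    def test_ckdepi_monotone_decreasing_in_creatinine(self):
        grid = np.linspace(0.4, 8.0, 40)
        for sex in ("male", "female"):
            vals = [egfr_ckdepi(60, scr, sex) for scr in grid]
            assert np.all(np.diff(vals) < 0)

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            egfr_cockcroft_gault(60, 77, 0.0, "male")


class TestDatasetIO:
    def test_round_trip_lossless(self, small_cohort, tmp_path):
        ev, cov = tmp_path / "events.csv", tmp_path / "covariates.csv"
        write_dataset(small_cohort, ev, cov)
        back = read_dataset(ev, cov)
        assert len(back) == len(small_cohort)
        for a, b in zip(small_cohort, back):
            assert a.subject_id == b.subject_id
            assert a.dosing_strategy == b.dosing_strategy
            assert a.age == pytest.approx(b.age)
            assert a.residual_diuresis == pytest.approx(b.residual_diuresis)
            assert len(a.doses) == len(b.doses)
            np.testing.assert_allclose(
                [o.concentration for o in a.observations],
                [o.concentration for o in b.observations],
            )

    def test_missing_covariates_survive_round_trip(self, tmp_path):
        s = make_ii_subject(residual_diuresis=None)
        ev, cov = tmp_path / "e.csv", tmp_path / "c.csv"
        write_dataset([s], ev, cov)
        back = read_dataset(ev, cov)[0]
        assert back.residual_diuresis is None
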