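import math

import numpy as np
import pytest

from pulsim.synthdata import (
    DynamicsParams,
    TreatmentSchedule,
    default_study_config,
    generate_study,
    schedules_from_json,
    schedules_to_json,
    simulate_animal,
    summaries_from_frame,
    summaries_to_frame,
    summarize_group,
    survival_fraction,
)

from conftest import small_designs

NOISELESS = DynamicsParams(noise_cv=0.0)
NO_IMMUNE = DynamicsParams(kappa=0.0, kappa_bare=0.0, noise_cv=0.0)


def untreated(n_steps=18, measurement_steps=(1, 18)):
    return TreatmentSchedule(n_steps=n_steps, measurement_steps=measurement_steps)


class TestDynamicsParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rho": 0.0},
            {"rho": -0.1},
            {"alpha": -0.1},
            {"kappa": 0.1, "kappa_bare": 0.2},
            {"kappa_bare": -0.01},
            {"immune_duration": 0.0},
            {"noise_cv": -1.0},
            {"rho": float("nan")},
            {"rho": float("inf")},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DynamicsParams(**kwargs)


class TestTreatmentSchedule:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"radiation": ((0, 10.0),)},
            {"radiation": ((19, 10.0),)},
            {"radiation": ((3, 0.0),)},
            {"radiation": ((3, -5.0),)},
            {"drug": ((3, "aspirin"),)},
            {"drug": ((25, "isotype"),)},
            {"measurement_steps": (1, 1, 4)},
            {"measurement_steps": (4, 1)},
            {"measurement_steps": (1, 2, 3, 4, 5, 6, 7)},
        ],
    )
    def test_invalid_schedule_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TreatmentSchedule(**kwargs)

    def test_json_round_trip(self):
        sch = TreatmentSchedule(
            radiation=((3, 20.0), (13, 20.0)),
            drug=tuple((s, "anti_pdl1") for s in range(1, 19, 2)),
        )
        back = schedules_from_json(schedules_to_json({"g": sch}))
        assert back["g"] == sch


class TestSimulateAnimal:
    def test_untreated_matches_exponential_closed_form(self):
        series = simulate_animal(NOISELESS, untreated(), seed=5)
        v0 = series[0] / math.exp(NOISELESS.rho)
        assert 150 <= v0 <= 200
        t = np.arange(1, 19)
        np.testing.assert_allclose(series, v0 * np.exp(NOISELESS.rho * t), rtol=1e-12)

    def test_untreated_growth_is_strictly_increasing(self):
        series = simulate_animal(NOISELESS, untreated(), seed=0)
        assert np.all(np.diff(series) > 0)

    def test_single_pulse_drops_volume_by_survival_fraction(self):
        dose, step = 6.0, 5
        plain = untreated()
        pulsed = TreatmentSchedule(
            radiation=((step, dose),), measurement_steps=(1, 18)
        )
        a = simulate_animal(NO_IMMUNE, plain, seed=7)
        b = simulate_animal(NO_IMMUNE, pulsed, seed=7)
        sf = survival_fraction(dose, NO_IMMUNE.alpha, NO_IMMUNE.beta)
        np.testing.assert_allclose(b[: step - 1], a[: step - 1], rtol=1e-12)
        np.testing.assert_allclose(b[step - 1 :], a[step - 1 :] * sf, rtol=1e-12)

    def test_disabled_immune_term_makes_drug_irrelevant(self):
        rt = ((3, 6.0),)
        with_drug = TreatmentSchedule(
            radiation=rt,
            drug=tuple((s, "anti_pdl1") for s in range(1, 19, 2)),
            measurement_steps=(1, 18),
        )
        without = TreatmentSchedule(radiation=rt, measurement_steps=(1, 18))
        a = simulate_animal(NO_IMMUNE, with_drug, seed=11)
        b = simulate_animal(NO_IMMUNE, without, seed=11)
        np.testing.assert_array_equal(a, b)

    def test_pulse_never_increases_later_volume_without_immunity(self):
        plain = untreated()
        pulsed = TreatmentSchedule(radiation=((8, 15.0),), measurement_steps=(1, 18))
        a = simulate_animal(NO_IMMUNE, plain, seed=3)
        b = simulate_animal(NO_IMMUNE, pulsed, seed=3)
        assert np.all(b <= a + 1e-12)

    def test_anti_pdl1_arm_controls_tumor_at_least_as_well_as_isotype(self):
        params = DynamicsParams(noise_cv=0.0)  # kappa > kappa_bare
        rt = ((3, 6.0),)
        drug_days = tuple(range(1, 19, 2))
        anti = TreatmentSchedule(
            radiation=rt,
            drug=tuple((s, "anti_pdl1") for s in drug_days),
            measurement_steps=(1, 18),
        )
        iso = TreatmentSchedule(
            radiation=rt,
            drug=tuple((s, "isotype") for s in drug_days),
            measurement_steps=(1, 18),
        )
        a = simulate_animal(params, anti, seed=13)
        b = simulate_animal(params, iso, seed=13)
        assert a[-1] <= b[-1]

    def test_volumes_positive_and_deterministic(self):
        params = DynamicsParams()
        sch = TreatmentSchedule(radiation=((3, 20.0),), measurement_steps=(1, 18))
        a = simulate_animal(params, sch, seed=21)
        b = simulate_animal(params, sch, seed=21)
        assert np.all(a > 0)
        np.testing.assert_array_equal(a, b)


class TestSummarizeGroup:
    def test_mean_of_two_animals(self):
        t1 = np.full(18, 100.0)
        t2 = np.full(18, 200.0)
        summ = summarize_group([t1, t2], (1, 10))
        assert summ.means.tolist() == [150.0, 150.0]
        # sample SD with ddof=1: sqrt(((50)^2 + (50)^2)/1)
        np.testing.assert_allclose(summ.sds, np.sqrt(5000.0))

    def test_identical_trajectories_have_zero_sd(self):
        t = np.linspace(100, 400, 18)
        summ = summarize_group([t, t, t], (1, 9, 18))
        np.testing.assert_array_equal(summ.sds, 0.0)

    def test_count_preserved(self):
        trajs = [np.full(18, 100.0 + i) for i in range(8)]
        assert summarize_group(trajs, (1, 18)).n_animals == 8

    def test_too_few_trajectories_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], (1, 18))
        with pytest.raises(ValueError):
            summarize_group([np.full(18, 1.0)], (1, 18))


class TestGenerateStudy:
    def test_default_config_yields_26_groups(self):
        study = generate_study(seed=0)
        assert len(study) == 26
        assert all(s.n_animals in (7, 8) for s in study.summaries.values())

    def test_control_only_config_has_no_radiation(self):
        designs = [d for d in default_study_config() if not d.radiation]
        study = generate_study(designs, seed=0)
        assert len(study) == 2
        assert all(not s.radiation for s in study.schedules.values())

    def test_same_seed_is_bit_identical(self):
        a = generate_study(small_designs(), seed=9)
        b = generate_study(small_designs(), seed=9)
        for gid in a.group_ids:
            assert a.summaries[gid] == b.summaries[gid]

    def test_duplicate_group_ids_rejected(self):
        d = small_designs(2)
        dup = [d[0], d[0]]
        with pytest.raises(ValueError, match="duplicate"):
            generate_study(dup, seed=0)

    def test_summary_frame_round_trip(self, tiny_study):
        frame = summaries_to_frame(tiny_study)
        assert set(frame.columns) == {"group_id", "n_animals", "step", "mean_mm3", "sd_mm3"}
        back = summaries_from_frame(frame)
        assert back == tiny_study.summaries
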