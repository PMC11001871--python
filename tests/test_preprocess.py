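import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsim.preprocess import (
    Dataset,
    LQConfig,
    augment_group,
    build_dataset,
    compute_volume_changes,
    encode_inputs,
    lq_effect,
    tumor_volume,
)
from pulsim.synthdata import GroupSummary, TreatmentSchedule, generate_study

from conftest import small_designs


class TestLQEffect:
    def test_zero_dose_gives_zero_effect(self):
        assert lq_effect(0.0, 0.3, 0.03) == 0.0

    def test_hand_computed_value(self):
        # alpha*d + beta*d^2 = 0.3*20 + 0.03*400
        assert lq_effect(20.0, 0.3, 0.03) == pytest.approx(18.0)

    @given(st.floats(0.1, 50.0), st.floats(0.01, 1.0), st.floats(0.0, 0.2))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_dose(self, d, alpha, beta):
        assert lq_effect(2 * d, alpha, beta) > lq_effect(d, alpha, beta)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_effect(-1.0, 0.3, 0.03)

    def test_encoding_variants(self):
        d = 20.0
        assert LQConfig(encoding="log_kill").effect(d) == pytest.approx(18.0)
        assert LQConfig(encoding="one_minus_sf").effect(d) == pytest.approx(
            1.0 - np.exp(-18.0)
        )
        assert LQConfig(encoding="raw_dose").effect(d) == 20.0
        with pytest.raises(ValueError):
            LQConfig(encoding="bogus")


class TestTumorVolume:
    @pytest.mark.parametrize(
        "xyz,expected",
        [((2, 2, 2), 4.0), ((0, 5, 5), 0.0), ((1.0, 0.8, 0.5), 0.2)],
    )
    def test_caliper_formula(self, xyz, expected):
        assert tumor_volume(*xyz) == pytest.approx(expected)

    def test_negative_dimension_rejected(self):
        with pytest.raises(ValueError):
            tumor_volume(-1, 1, 1)


def make_summary(means, sds, steps=None):
    steps = steps or tuple(range(1, len(means) + 1))
    return GroupSummary(
        "g", 8, tuple(zip(steps, means, sds))
    )


class TestAugmentGroup:
    def test_default_sample_count_is_50(self):
        draws = augment_group(make_summary([100, 200], [10, 20]), seed=0)
        assert draws.shape == (50, 2)

    def test_zero_sd_reproduces_the_mean_series(self):
        draws = augment_group(make_summary([100, 250, 400], [0, 0, 0]), seed=1)
        np.testing.assert_array_equal(draws, np.tile([100, 250, 400], (50, 1)))

    def test_moments_match_shrunken_gaussian(self):
        mean, sd = 500.0, 100.0
        draws = augment_group(
            make_summary([mean], [sd]), n_samples=50_000, sd_shrink=5.0, seed=2
        )
        assert draws.mean() == pytest.approx(mean, rel=0.01)
        assert draws.std(ddof=1) == pytest.approx(sd / 5.0, rel=0.03)

    def test_negative_draws_clipped_at_floor(self):
        draws = augment_group(
            make_summary([2.0], [50.0]), n_samples=1000, sd_shrink=1.0, seed=3
        )
        assert draws.min() >= 1.0

    def test_deterministic_given_seed(self):
        s = make_summary([100, 200], [10, 20])
        np.testing.assert_array_equal(
            augment_group(s, seed=4), augment_group(s, seed=4)
        )

    def test_empty_summary_rejected(self):
        with pytest.raises(ValueError):
            augment_group(GroupSummary("g", 8, ()), seed=0)


class TestEncodeInputs:
    def test_empty_schedule_is_all_zero(self):
        mat = encode_inputs(TreatmentSchedule(measurement_steps=(1, 18)))
        assert mat.shape == (18, 2)
        assert not mat.any()

    def test_isotype_on_odd_steps(self):
        sch = TreatmentSchedule(
            drug=tuple((s, "isotype") for s in range(1, 19, 2)),
            measurement_steps=(1, 18),
        )
        mat = encode_inputs(sch)
        assert np.array_equal(mat[::2, 1], np.ones(9))
        assert not mat[1::2, 1].any()
        assert not mat[:, 0].any()

    def test_anti_pdl1_coded_as_2(self):
        sch = TreatmentSchedule(drug=((4, "anti_pdl1"),), measurement_steps=(1, 18))
        assert encode_inputs(sch)[3, 1] == 2.0

    def test_radiation_channel_carries_lq_effect_on_pulse_day_only(self):
        sch = TreatmentSchedule(radiation=((3, 20.0),), measurement_steps=(1, 18))
        mat = encode_inputs(sch, LQConfig())
        assert mat[2, 0] == pytest.approx(lq_effect(20.0, 0.3, 0.03))
        assert np.count_nonzero(mat[:, 0]) == 1


class TestComputeVolumeChanges:
    def test_six_measurements_give_five_defined_changes(self):
        targets, mask = compute_volume_changes([100, 120, 150, 200, 300, 500])
        assert mask.sum() == 5
        assert mask.all()

    def test_constant_series_gives_zero_changes(self):
        targets, mask = compute_volume_changes([250.0] * 4)
        assert not targets[mask].any()

    def test_hand_computed_differences_and_mask(self):
        targets, mask = compute_volume_changes([100, 150, 130])
        np.testing.assert_array_equal(targets, [50, -20, 0, 0, 0])
        np.testing.assert_array_equal(mask, [True, True, False, False, False])

    @given(
        st.lists(st.floats(1.0, 2000.0), min_size=2, max_size=6)
    )
    @settings(max_examples=100, deadline=None)
    def test_cumulative_sum_round_trips_the_series(self, volumes):
        targets, mask = compute_volume_changes(volumes)
        recovered = volumes[0] + np.cumsum(targets[mask])
        np.testing.assert_allclose(recovered, volumes[1:], rtol=1e-12, atol=1e-9)

    def test_too_many_or_no_measurements_rejected(self):
        with pytest.raises(ValueError):
            compute_volume_changes([])
        with pytest.raises(ValueError):
            compute_volume_changes(list(range(1, 9)))


class TestBuildDataset:
    def test_samples_per_group_and_sequence_length(self, tiny_study):
        ds = build_dataset(tiny_study, n_samples=7, seed=0)
        assert len(ds) == len(tiny_study) * 7
        assert ds.inputs.shape[1:] == (18, 2)
        assert ds.targets.shape == (len(ds), 5)
        assert ds.mask.dtype == bool

    def test_radiation_channel_zero_except_pulses(self, tiny_study):
        ds = build_dataset(tiny_study, n_samples=2, seed=0)
        assert set(np.unique(ds.inputs[:, :, 1])) <= {0.0, 1.0, 2.0}
        for i in range(len(ds)):
            gid = str(ds.group_ids[i])
            pulses = {s - 1 for s in tiny_study.schedules[gid].pulse_steps}
            nonzero = set(np.flatnonzero(ds.inputs[i, :, 0]))
            assert nonzero == pulses

    def test_deterministic_given_seed(self, tiny_study):
        a = build_dataset(tiny_study, n_samples=3, seed=5)
        b = build_dataset(tiny_study, n_samples=3, seed=5)
        np.testing.assert_array_equal(a.inputs, b.inputs)
        np.testing.assert_array_equal(a.targets, b.targets)

    def test_group_with_single_measurement_skipped_with_warning(self):
        study = generate_study(small_designs(2), seed=0)
        crippled = GroupSummary("g1", 4, (study.summaries["g1"].records[0],))
        study.summaries["g1"] = crippled
        with pytest.warns(UserWarning, match="skipped"):
            ds = build_dataset(study, n_samples=3, seed=0)
        assert set(ds.unique_groups) == {"g2"}

    def test_npz_round_trip(self, tiny_study, tmp_path):
        ds = build_dataset(tiny_study, n_samples=2, seed=1)
        path = tmp_path / "ds.npz"
        ds.save(path)
        back = Dataset.load(path)
        np.testing.assert_array_equal(back.inputs, ds.inputs)
        np.testing.assert_array_equal(back.targets, ds.targets)
        np.testing.assert_array_equal(back.mask, ds.mask)
        assert list(back.group_ids) == list(ds.group_ids)
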