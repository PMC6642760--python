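"""EMG / pressure / accelerometer chain operations and full feature builds."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harkit import (DegenerateSubjectError, DegenerateVectorError,
                    FeatureParams, HarkitError, WindowSpec, acc_remove_offset,
                    build_biosignal_feature, compute_normalizer,
                    default_pressure_layout, extract_window, moving_average,
                    pressure_region_average, rectify, resample_25hz,
                    subject_max_normalize, unit_interval_normalize)


class TestStageOperations:
    def test_rectify_is_absolute_value_and_idempotent(self):
        x = np.array([-1.0, 2.0, -3.0])
        assert np.array_equal(rectify(x), [1.0, 2.0, 3.0])
        assert np.array_equal(rectify(np.zeros(4)), np.zeros(4))
        assert np.array_equal(rectify(rectify(x)), rectify(x))

    def test_moving_average_center_value_and_shrinking_edges(self):
        x = np.array([0.0, 0.0, 4.0, 0.0, 0.0])
        out = moving_average(x, 3.0, 1.0)
        assert out[2] == pytest.approx(4.0 / 3.0)
        assert out[0] == pytest.approx(0.0)  # shrunk 2-sample edge window
        assert out.shape == x.shape

    @given(m=st.integers(1, 9), n=st.integers(10, 40), seed=st.integers(0, 10))
    @settings(max_examples=25, deadline=None)
    def test_moving_average_matches_bruteforce_shrinking_mean(self, m, n, seed):
        x = np.random.default_rng(seed).standard_normal(n)
        out = moving_average(x, float(m), 1.0)
        hl = (m - 1) // 2
        hr = m - 1 - hl
        expected = np.array([x[max(i - hl, 0):min(i + hr + 1, n)].mean()
                             for i in range(n)])
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_moving_average_conserves_interior_impulse_mass(self):
        x = np.zeros(31)
        x[15] = 7.0
        out = moving_average(x, 5.0, 1.0)
        assert out.sum() == pytest.approx(7.0)

    @given(c=st.floats(-5, 5), m=st.integers(1, 7))
    @settings(max_examples=20, deadline=None)
    def test_moving_average_preserves_constants(self, c, m):
        np.testing.assert_allclose(
            moving_average(np.full(20, c), float(m), 1.0), c, atol=1e-12)

    def test_moving_average_rejects_subsample_width(self):
        with pytest.raises(HarkitError):
            moving_average(np.zeros(10), 0.001, 100.0)

    def test_subject_max_normalize_is_subject_specific(self):
        x = np.array([5.0, 10.0])
        np.testing.assert_allclose(subject_max_normalize(x, 10.0), [0.5, 1.0])
        np.testing.assert_allclose(subject_max_normalize(np.full(3, 4.0), 4.0), 1.0)
        a = subject_max_normalize(x, 10.0)
        b = subject_max_normalize(x, 20.0)
        assert not np.allclose(a, b)
        with pytest.raises(DegenerateSubjectError):
            subject_max_normalize(x, 0.0)

    def test_unit_interval_normalize_sets_the_maximum_to_one(self):
        np.testing.assert_allclose(unit_interval_normalize(np.array([2.0, 4.0])), [0.5, 1.0])
        np.testing.assert_allclose(unit_interval_normalize(np.ones(3)), 1.0)
        out = unit_interval_normalize(np.random.default_rng(0).random(50) + 0.1)
        assert out.max() == 1.0
        with pytest.raises(DegenerateVectorError):
            unit_interval_normalize(np.array([-1.0, 0.0]))

    def test_resample_constant_ramp_and_length(self):
        np.testing.assert_allclose(resample_25hz(np.full(160, 5.0), 100.0), 5.0)
        assert resample_25hz(np.zeros(3200), 2000.0).shape == (40,)
        rate = 100.0
        t = np.arange(160) / rate
        ramp = 3.0 * t
        out = resample_25hz(ramp, rate)
        np.testing.assert_allclose(out, 3.0 * np.arange(40) / 25.0, atol=1e-12)
        with pytest.raises(HarkitError):
            resample_25hz(np.zeros(10), 10.0)

    def test_pressure_region_average_matches_bruteforce(self, rng):
        layout = default_pressure_layout()
        frame = rng.random(64)
        out = pressure_region_average(frame)
        for r in range(6):
            assert out[r] == pytest.approx(frame[layout == r].mean())
        np.testing.assert_allclose(pressure_region_average(np.full(64, 2.5)), 2.5)
        only_left_heel = np.where(layout == 0, 3.0, 0.0)
        out = pressure_region_average(only_left_heel)
        assert out[0] > 0 and np.all(out[1:] == 0)

    def test_pressure_layout_must_be_a_partition(self):
        with pytest.raises(HarkitError):
            pressure_region_average(np.zeros(64), np.zeros(32, dtype=int))
        with pytest.raises(HarkitError):
            pressure_region_average(np.zeros(64), np.zeros(64, dtype=int))  # empty regions
        with pytest.raises(HarkitError):
            pressure_region_average(np.zeros(32))

    def test_acc_remove_offset_centers_gravity(self, rng):
        sig = np.zeros((3, 100))
        sig[2] = 9.81
        out = acc_remove_offset(sig, np.array([0.0, 0.0, 9.81]))
        np.testing.assert_allclose(out, 0.0)
        x = rng.standard_normal((3, 50))
        np.testing.assert_allclose(acc_remove_offset(x, np.zeros(3)), x)
        noise = 0.1 * rng.standard_normal((3, 1000)) + 2.0
        resid = acc_remove_offset(noise, noise.mean(axis=1))
        assert np.all(np.abs(resid.mean(axis=1)) < 0.1 / np.sqrt(1000) * 5)


@pytest.fixture(scope="module")
def normalized(tiny_recordings):
    rec = tiny_recordings[0]
    return rec, compute_normalizer(rec)


class TestFullChains:
    @pytest.mark.parametrize("sensor,stream,dim", [
        ("B", "emg", 320), ("C", "pressure", 240), ("E", "acc", 120)])
    def test_feature_dimensions_and_unit_range(self, normalized, tiny_segments,
                                               sensor, stream, dim):
        rec, norm = normalized
        row = tiny_segments[tiny_segments["subject"] == rec.subject_id].iloc[0]
        rate = rec.rates[stream]
        clip = extract_window(getattr(rec, stream), rate,
                              row["t_start"], row["t_end"], WindowSpec())
        fv = build_biosignal_feature(clip, rate, sensor, norm,
                                     activity=row["activity"])
        assert fv.dimension == dim
        assert fv.values.min() >= 0.0
        assert fv.values.max() <= 1.0 + 1e-12
        assert fv.values.max() > 0.9  # resampling may only nudge the max below 1

    def test_scaling_a_subjects_raw_emg_leaves_features_unchanged(
            self, normalized, tiny_segments):
        rec, norm = normalized
        row = tiny_segments[tiny_segments["subject"] == rec.subject_id].iloc[3]
        rate = rec.rates["emg"]
        clip = extract_window(rec.emg, rate, row["t_start"], row["t_end"], WindowSpec())
        fv = build_biosignal_feature(clip, rate, "B", norm)
        import dataclasses
        norm_scaled = dataclasses.replace(norm, emg_max=norm.emg_max * 3.0)
        fv_scaled = build_biosignal_feature(clip * 3.0, rate, "B", norm_scaled)
        np.testing.assert_allclose(fv.values, fv_scaled.values, atol=1e-12)

    def test_unknown_sensor_is_rejected(self, normalized):
        rec, norm = normalized
        with pytest.raises(HarkitError):
            build_biosignal_feature(np.zeros((8, 3200)), 2000.0, "A", norm)

    def test_normalizer_requires_a_long_enough_lead_in(self, tiny_recordings):
        import dataclasses
        rec = dataclasses.replace(tiny_recordings[0], lead_in_s=12.0)
        short = dataclasses.replace(rec, lead_in_s=10.0)
        compute_normalizer(short)  # exactly 10 s is acceptable
        with pytest.raises(HarkitError):
            dataclasses.replace(rec, lead_in_s=4.0)


class TestChainRegression:
    """The per-stage outputs of the EMG chain are pinned on a frozen clip:
    any change to the chain order or edge rules shows up here."""

    def test_stage_outputs_match_frozen_values(self):
        rng = np.random.default_rng(77)
        t = np.arange(3200) / 2000.0
        clip = (np.sin(2 * np.pi * 3 * t)[None, :]
                * (0.2 + np.linspace(0.1, 1.0, 8))[:, None]
                + 0.05 * rng.standard_normal((8, 3200)))
        s1 = rectify(clip)
        s2 = moving_average(s1, 0.1, 2000.0)
        s3 = subject_max_normalize(s2, 1.3)
        s4 = unit_interval_normalize(s3)
        s5 = resample_25hz(s4, 2000.0)
        expected = [
            (s1, 0.48113475666377714, 1.3816589541874222, (8, 3200)),
            (s2, 0.4820390682715147, 1.135161955730937, (8, 3200)),
            (s3, 0.37079928328578055, 0.873201504408413, (8, 3200)),
            (s4, 0.42464343157195317, 1.0, (8, 3200)),
            (s5, 0.4203230107480948, 0.9022843304411174, (8, 40)),
        ]
        for stage, mean, peak, shape in expected:
            assert stage.shape == shape
            assert stage.mean() == pytest.approx(mean, abs=1e-12)
            assert stage.max() == pytest.approx(peak, abs=1e-12)
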