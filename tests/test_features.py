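import numpy as np
import pytest
from sklearn.base import clone
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline

from conftest import compose_channels, make_session
from limbid.features import (
    FINGER_PAIRS,
    LIMB_TRIPLES,
    RATIO_COMBOS,
    RatiometricFeatures,
    RawFingerFeatures,
    UpperLimbFeatures,
    build_vector,
    channel,
    extract_features,
    ratiometric_features,
    raw_finger_features,
    upper_limb_features,
    upper_limb_impedance,
)
from limbid.records import DEFAULT_FREQUENCIES, SessionRecord
from limbid.synth import GeneratorConfig, simulate_study


class TestCanonicalSets:
    def test_six_limb_triples_in_listing_order(self):
        assert LIMB_TRIPLES == (
            (0, 1, 2), (0, 1, 3), (0, 1, 4), (0, 2, 3), (0, 2, 4), (0, 3, 4),
        )

    def test_ratio_combos_use_each_pair_once_per_side(self):
        nums = [n for n, _ in RATIO_COMBOS]
        dens = [d for _, d in RATIO_COMBOS]
        assert sorted(nums) == sorted(FINGER_PAIRS)
        assert sorted(dens) == sorted(FINGER_PAIRS)
        assert all(n != d for n, d in RATIO_COMBOS)


class TestChannel:
    def test_pair_is_unordered(self, flat_session):
        np.testing.assert_array_equal(
            channel(flat_session, 1, 0), channel(flat_session, 0, 1)
        )

    def test_identical_electrodes_rejected(self, flat_session):
        with pytest.raises(ValueError):
            channel(flat_session, 2, 2)

    def test_missing_pair_is_an_error(self):
        pairs = {
            (a, b): np.full(25, 10.0)
            for a, b in [(0, 1), (0, 2), (0, 3), (0, 4), (1, 2), (1, 3), (1, 4),
                         (2, 3), (2, 4)]  # (3,4) missing
        }
        with pytest.raises(ValueError, match=r"\(3, 4\)"):
            SessionRecord.from_pairs(pairs, DEFAULT_FREQUENCIES)


class TestUpperLimb:
    def test_flat_arithmetic_identity(self, flat_session):
        # (150 + 160 - 110)/2 = 100 at every frequency
        limb = upper_limb_impedance(flat_session, (0, 1, 2))
        np.testing.assert_array_equal(limb, np.full(25, 100.0))

    def test_noiseless_session_recovers_ground_truth_for_all_triples(self):
        import dataclasses

        cfg = dataclasses.replace(GeneratorConfig(), noise_rel=0.0,
                                  sigma_day_finger=0.0, sigma_day_limb=0.0)
        data, truths = simulate_study(3, 1, 1, config=cfg, seed=21)
        for i in range(data.n_sessions):
            sess = data.session(i)
            expected = truths[i].limb_spectrum(cfg.frequencies)
            for triple in LIMB_TRIPLES:
                np.testing.assert_allclose(
                    upper_limb_impedance(sess, triple), expected, rtol=1e-10
                )

    def test_single_finger_perturbation_cancels(self):
        rng = np.random.default_rng(2)
        limb = rng.uniform(100, 200, 25)
        fingers = [rng.uniform(300, 800, 25) for _ in range(4)]
        base = make_session(limb, fingers)
        for c in (0.5, 0.90, 1.12, 2.0):
            pert = make_session(limb, [fingers[0] * c] + fingers[1:])
            for triple in LIMB_TRIPLES:
                np.testing.assert_allclose(
                    upper_limb_impedance(pert, triple),
                    upper_limb_impedance(base, triple),
                    rtol=1e-12,
                )
        # triples not involving finger 1 are bit-identical trivially
        pert = make_session(limb, [fingers[0] * 1.12] + fingers[1:])
        for triple in ((0, 2, 3), (0, 2, 4), (0, 3, 4)):
            np.testing.assert_array_equal(
                upper_limb_impedance(pert, triple), upper_limb_impedance(base, triple)
            )

    def test_invalid_triple_rejected(self, flat_session):
        with pytest.raises(ValueError):
            upper_limb_impedance(flat_session, (1, 2, 3))

    def test_non_positive_output_warns_not_fails(self):
        # heavy "noise": finger-finger channel exceeds the wrist sums
        pairs = {(a, b): np.full(25, 100.0) for a, b in
                 [(0, 1), (0, 2), (0, 3), (0, 4), (1, 3), (1, 4), (2, 3), (2, 4),
                  (3, 4)]}
        pairs[(1, 2)] = np.full(25, 500.0)
        sess = SessionRecord.from_pairs(pairs, DEFAULT_FREQUENCIES)
        with pytest.warns(RuntimeWarning):
            limb = upper_limb_impedance(sess, (0, 1, 2))
        assert np.all(limb == -150.0)  # kept, not clipped


class TestRatiometric:
    def test_identical_finger_channels_give_unit_ratios(self):
        sess = make_session(100.0, (50.0, 50.0, 50.0, 50.0))
        fs = ratiometric_features(sess)
        np.testing.assert_array_equal(fs.values, np.ones((6, 25)))

    def test_flat_example(self, flat_session):
        # (e1,e2)/(e3,e4) = 110/150
        fs = ratiometric_features(flat_session)
        np.testing.assert_allclose(fs.values[0], np.full(25, 110.0 / 150.0))
        sess = make_session(100.0, (60.0, 50.0, 40.0, 60.0))
        # channels: (1,2)=110, (3,4)=100 -> ratio 1.1
        np.testing.assert_allclose(
            ratiometric_features(sess).values[0], np.full(25, 1.1)
        )

    def test_common_scale_invariance(self):
        rng = np.random.default_rng(5)
        fingers = [rng.uniform(300, 800, 25) for _ in range(4)]
        base = ratiometric_features(make_session(150.0, fingers)).values
        for c in (2.0, 0.5):  # powers of two scale exactly in binary FP
            scaled = ratiometric_features(
                make_session(150.0, [f * c for f in fingers])
            ).values
            np.testing.assert_array_equal(scaled, base)
        scaled = ratiometric_features(
            make_session(150.0, [f * 1.37 for f in fingers])
        ).values
        np.testing.assert_allclose(scaled, base, rtol=1e-14)

    def test_zero_denominator_is_hard_error(self, flat_session):
        bad = flat_session.channels.copy()
        bad[-1] = 0.0  # pair (3,4), denominator of combo 0
        sess = SessionRecord("S01", 1, 1, DEFAULT_FREQUENCIES, bad)
        with pytest.raises(ZeroDivisionError):
            ratiometric_features(sess)


class TestRawFinger:
    def test_flat_example_and_shape(self, flat_session):
        fs = raw_finger_features(flat_session)
        assert fs.values.shape == (6, 25)
        np.testing.assert_array_equal(fs.values[0], np.full(25, 110.0))  # (e1,e2)
        np.testing.assert_array_equal(fs.values[5], np.full(25, 150.0))  # (e3,e4)

    def test_storage_order_does_not_change_output_order(self, flat_session):
        pairs = {
            (a, b): flat_session.channel(a, b)
            for a, b in [(3, 4), (0, 2), (1, 2), (0, 4), (2, 4), (1, 4), (0, 1),
                         (2, 3), (0, 3), (1, 3)]
        }
        shuffled = SessionRecord.from_pairs(pairs, DEFAULT_FREQUENCIES)
        np.testing.assert_array_equal(
            raw_finger_features(shuffled).values, raw_finger_features(flat_session).values
        )


class TestBuildVector:
    def test_single_family_flat_length_150(self, flat_session):
        v = build_vector([raw_finger_features(flat_session)], layout="flat")
        assert v.shape == (150,)

    def test_two_families_channel_layout(self, flat_session):
        sets = [ratiometric_features(flat_session), upper_limb_features(flat_session)]
        v = build_vector(sets, layout="channels")
        assert v.shape == (25, 1, 12)
        flat = build_vector(sets, layout="flat")
        assert flat.shape == (300,)
        # same order: channel c of the stack is combo c of the flat concatenation
        np.testing.assert_array_equal(v[:, 0, 3], flat[3 * 25:4 * 25])

    def test_flat_length_is_grid_times_combos(self, flat_session):
        for sets, n in [
            ([raw_finger_features(flat_session)], 6),
            ([ratiometric_features(flat_session), upper_limb_features(flat_session)], 12),
        ]:
            assert build_vector(sets).size == 25 * n

    def test_empty_and_mismatched_inputs_rejected(self, flat_session):
        with pytest.raises(ValueError):
            build_vector([])
        other = make_session(100.0, (50.0, 60.0, 70.0, 80.0))
        other.frequencies = other.frequencies[:24]
        other.channels = other.channels[:, :24]
        with pytest.raises(ValueError):
            build_vector([raw_finger_features(flat_session),
                          raw_finger_features(other)])


class TestTransformers:
    def test_transformers_match_per_session_functions(self, small_study):
        data, _ = small_study
        for cls, fn in [
            (RawFingerFeatures, raw_finger_features),
            (RatiometricFeatures, ratiometric_features),
            (UpperLimbFeatures, upper_limb_features),
        ]:
            got = cls().fit_transform(data.channels)
            expected = np.stack(
                [fn(data.session(i)).values.reshape(-1) for i in range(data.n_sessions)]
            )
            np.testing.assert_array_equal(got, expected)

    def test_flat_2d_input_equivalent_to_3d(self, small_study):
        data, _ = small_study
        tr = UpperLimbFeatures()
        np.testing.assert_array_equal(
            tr.fit_transform(data.channels),
            tr.fit_transform(data.channels.reshape(data.n_sessions, -1)),
        )

    def test_composes_with_sklearn_pipeline(self, small_study):
        data, _ = small_study
        pipe = make_pipeline(UpperLimbFeatures(), LogisticRegression(max_iter=500))
        X = data.channels.reshape(data.n_sessions, -1)
        y = data.meta.subject_id.to_numpy()
        pipe.fit(X, y)
        assert pipe.score(X, y) > 0.9
        clone(pipe)  # get_params/set_params round trip

    def test_extract_features_selections(self, small_study):
        data, _ = small_study
        assert extract_features(data, "finger").shape == (data.n_sessions, 150)
        assert extract_features(data, "ratio+limb").shape == (data.n_sessions, 300)
        assert extract_features(data, "limb", layout="channels").shape == (
            data.n_sessions, 25, 6,
        )
        with pytest.raises(ValueError):
            extract_features(data, "palm")
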