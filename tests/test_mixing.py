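"""Mixture assembly: power exactness, FIR statistics, crops, curriculum."""

import numpy as np
import pytest

from neosep.audio import AudioSignal
from neosep.mixing import (FINETUNE, PRETRAIN, MixOptions, apply_convolutive,
                           build_training_set, compose_mixture, partition_for,
                           random_crop, random_fir, rescale_relative_power,
                           sample_relative_db)


def sig(x):
    return AudioSignal(np.asarray(x, dtype=float), 4000)


def rel_db(x, ref):
    return 10.0 * np.log10(x.power() / ref.power())


class TestRescale:
    def test_equal_power_at_zero_db_is_identity(self, rng):
        x = sig(rng.standard_normal(1000))
        ref = x.replace(rng.permutation(x.samples))
        out = rescale_relative_power(x, ref, 0.0)
        assert np.allclose(out.samples, x.samples)

    def test_minus_twenty_db_means_power_ratio_one_hundredth(self, rng):
        x = sig(rng.standard_normal(1000))
        ref = sig(rng.standard_normal(1000))
        out = rescale_relative_power(x, ref, -20.0)
        assert np.isclose(out.power() / ref.power(), 0.01, rtol=1e-9)

    def test_zero_signal_raises(self):
        with pytest.raises(ValueError):
            rescale_relative_power(sig(np.zeros(10)), sig(np.ones(10)), 0.0)


class TestSampling:
    def test_uniform_db_draws_have_midrange_mean(self):
        r = np.random.default_rng(0)
        draws = [sample_relative_db((-20.0, 0.0), r) for _ in range(10_000)]
        assert abs(np.mean(draws) + 10.0) < 0.5
        assert min(draws) >= -20.0 and max(draws) <= 0.0

    def test_degenerate_and_inverted_ranges(self):
        r = np.random.default_rng(0)
        assert sample_relative_db((5.0, 5.0), r) == 5.0
        with pytest.raises(ValueError):
            sample_relative_db((10.0, -10.0), r)


class TestRandomFir:
    def test_lengths_uniform_over_3_4_5(self):
        r = np.random.default_rng(0)
        lengths = [len(random_fir((3, 5), r)) for _ in range(3000)]
        for L in (3, 4, 5):
            assert abs(lengths.count(L) / 3000 - 1 / 3) < 0.03

    def test_unit_energy_and_single_tap(self):
        r = np.random.default_rng(1)
        taps = random_fir((3, 5), r)
        assert np.isclose(np.sum(taps ** 2), 1.0, atol=1e-9)
        single = random_fir((1, 1), r)
        assert single.shape == (1,) and np.isclose(abs(single[0]), 1.0)


class TestConvolutive:
    def test_identity_tap(self, rng):
        x = sig(rng.standard_normal(100))
        assert np.allclose(apply_convolutive(x, [1.0]).samples, x.samples)

    def test_impulse_reveals_taps(self):
        taps = np.array([0.5, -0.3, 0.2])
        x = sig(np.r_[1.0, np.zeros(9)])
        out = apply_convolutive(x, taps)
        assert np.allclose(out.samples[:3], taps)

    def test_unit_energy_taps_preserve_white_noise_power(self, rng):
        x = sig(rng.standard_normal(50_000))
        r = np.random.default_rng(5)
        taps = random_fir((3, 5), r)
        out = apply_convolutive(x, taps)
        assert abs(out.power() / x.power() - 1.0) < 0.1


class TestRandomCrop:
    def test_eight_seconds_of_forty_thousand_gives_32000(self, rng):
        xs = [sig(rng.standard_normal(40_000)) for _ in range(3)]
        r = np.random.default_rng(2)
        outs = random_crop(xs, 8.0, r)
        assert all(len(o) == 32_000 for o in outs)
        # alignment: shared offset
        i = np.flatnonzero(xs[0].samples == outs[0].samples[0])[0]
        assert np.array_equal(xs[1].samples[i:i + 32_000], outs[1].samples)

    def test_full_length_crop_is_identity(self, rng):
        x = sig(rng.standard_normal(4000))
        out = random_crop([x], 1.0, np.random.default_rng(0))[0]
        assert np.array_equal(out.samples, x.samples)

    def test_too_short_input_raises(self, rng):
        x = sig(rng.standard_normal(7 * 4000))
        with pytest.raises(ValueError):
            random_crop([x], 8.0, np.random.default_rng(0))


class TestCompose:
    def test_no_noise_mixture_is_exact_sum_of_references(self, small_bank):
        sources, _ = small_bank[0]
        ex = compose_mixture(sources, None, PRETRAIN,
                             rng=np.random.default_rng(3))
        resid = ex.mixture.samples - (ex.references.heart.samples
                                      + ex.references.lung.samples)
        assert ex.partition == "no_noise"
        assert np.max(np.abs(resid)) < 1e-9

    def test_realized_relative_powers_match_drawn_values(self, small_bank):
        for i, (sources, noise) in enumerate(small_bank):
            ex = compose_mixture(sources, noise, FINETUNE,
                                 rng=np.random.default_rng(10 + i))
            heart = ex.references.heart
            assert np.isclose(rel_db(ex.references.lung, heart),
                              ex.lung_rel_db, atol=1e-6)
            assert np.isclose(rel_db(ex.noise_reference, heart),
                              ex.noise_rel_db, atol=1e-6)

    def test_partition_follows_noise_class(self):
        assert partition_for(None) == "no_noise"
        assert partition_for("cry") == "general_noise"
        assert partition_for("stethoscope_movement") == "general_noise"
        assert partition_for("bubble_cpap") == "respiratory_support"
        assert partition_for("ventilator_cpap") == "respiratory_support"
        with pytest.raises(ValueError):
            partition_for("tv_noise")


class TestBuildSets:
    def test_training_build_never_contains_stethoscope_noise(self, small_bank):
        exs = build_training_set(small_bank * 10, PRETRAIN, seed=0,
                                 training=True)
        assert all(ex.noise_class != "stethoscope_movement" for ex in exs)

    def test_test_build_keeps_stethoscope_noise(self, small_bank):
        exs = build_training_set(small_bank * 10, PRETRAIN, seed=0,
                                 training=False)
        assert any(ex.noise_class == "stethoscope_movement" for ex in exs)

    def test_pretrain_noise_levels_stay_in_curriculum_range(self, small_bank):
        exs = build_training_set(small_bank * 5, PRETRAIN, seed=1,
                                 training=True)
        for ex in exs:
            if ex.noise_rel_db is not None:
                assert -20.0 <= ex.noise_rel_db <= 0.0

    def test_same_seed_reproduces_identical_examples(self, small_bank):
        a = build_training_set(small_bank, PRETRAIN, seed=4, training=True)
        b = build_training_set(small_bank, PRETRAIN, seed=4, training=True)
        for x, y in zip(a, b):
            assert np.array_equal(x.mixture.samples, y.mixture.samples)
            assert x.noise_class == y.noise_class

    def test_empty_bank_raises(self):
        with pytest.raises(ValueError):
            build_training_set([], PRETRAIN)
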