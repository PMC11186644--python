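"""Distortion measures against independently coded brute-force oracles."""

import numpy as np
import pytest

from neosep.metrics import (Decomposition, bss_decompose, improvement,
                            results_frame, sdr, sdr_from_signals, si_sdr,
                            summarize, EvalResult)


def brute_force_si_sdr(est, tgt):
    """Direct transcription of the defining equations (independent of
    the library implementation)."""
    alpha = np.dot(est, tgt) / np.dot(tgt, tgt)
    e_noise = alpha * tgt - est
    val = 10.0 * np.log10(np.dot(alpha * tgt, alpha * tgt)
                          / np.dot(e_noise, e_noise))
    return float(np.clip(val, -60.0, 60.0))


class TestSiSdr:
    @pytest.mark.parametrize("c", [0.01, 1.0, 42.0, -3.0])
    def test_scaled_copy_hits_positive_clamp(self, rng, c):
        t = rng.standard_normal(500)
        assert si_sdr(c * t, t) == 60.0

    @pytest.mark.parametrize("c", [0.5, 1.0, 9.0])
    def test_orthogonal_tenth_power_noise_gives_ten_db(self, rng, c):
        t = rng.standard_normal(1000)
        n = rng.standard_normal(1000)
        n -= (n @ t) / (t @ t) * t
        n *= np.sqrt(0.1 * (t @ t) / (n @ n))
        assert np.isclose(si_sdr(c * (t + n), t), 10.0, atol=1e-9)

    def test_agrees_with_brute_force_on_100_random_pairs(self):
        r = np.random.default_rng(77)
        for _ in range(100):
            e = r.standard_normal(1000)
            t = r.standard_normal(1000)
            assert np.isclose(si_sdr(e, t), brute_force_si_sdr(e, t),
                              atol=1e-9)

    def test_zero_target_rejected(self, rng):
        with pytest.raises(ValueError):
            si_sdr(rng.standard_normal(10), np.zeros(10))


class TestDecomposition:
    def test_perfect_estimate_has_zero_error_components(self, rng):
        t = rng.standard_normal(400)
        o = rng.standard_normal(400)
        n = rng.standard_normal(400)
        d = bss_decompose(t, t, [o], n)
        for comp in (d.e_interf, d.e_noise, d.e_artif):
            assert np.linalg.norm(comp) < 1e-9

    def test_orthonormal_two_source_worked_case(self):
        """estimate = u + 0.1 v with orthonormal u, v: the interference
        component is exactly 0.1 v and SDR = 20 dB."""
        u = np.zeros(64)
        v = np.zeros(64)
        u[0] = 1.0
        v[1] = 1.0
        d = bss_decompose(u + 0.1 * v, u, [v])
        assert np.allclose(d.s_target_component, u, atol=1e-12)
        assert np.allclose(d.e_interf, 0.1 * v, atol=1e-12)
        assert np.isclose(sdr(d), 20.0, atol=1e-9)

    def test_components_sum_to_estimate_on_random_instances(self):
        r = np.random.default_rng(5)
        for _ in range(100):
            e = r.standard_normal(300)
            t = r.standard_normal(300)
            o = r.standard_normal(300)
            n = r.standard_normal(300)
            d = bss_decompose(e, t, [o], n)
            assert np.linalg.norm(d.reassembled() - e) < 1e-9 * np.linalg.norm(e)

    def test_first_three_components_mutually_orthogonal(self, rng):
        e = rng.standard_normal(300)
        t = rng.standard_normal(300)
        o = rng.standard_normal(300)
        n = rng.standard_normal(300)
        d = bss_decompose(e, t, [o], n)
        assert abs(d.s_target_component @ d.e_interf) < 1e-8
        assert abs(d.s_target_component @ d.e_noise) < 1e-8
        assert abs(d.e_interf @ d.e_noise) < 1e-8

    def test_collinear_interferer_handled_by_pseudoinverse(self, rng):
        t = rng.standard_normal(100)
        d = bss_decompose(t * 2.0, t, [t * 3.0])   # dependent spanning set
        assert np.linalg.norm(d.e_interf) < 1e-9
        assert np.isclose(sdr(d), 60.0)

    def test_zero_target_rejected(self, rng):
        with pytest.raises(ValueError):
            bss_decompose(rng.standard_normal(10), np.zeros(10))

    def test_clamps(self):
        d = Decomposition(np.ones(4), np.zeros(4), np.zeros(4), np.zeros(4))
        assert sdr(d) == 60.0
        d2 = Decomposition(np.zeros(4), np.ones(4), np.zeros(4), np.zeros(4))
        assert sdr(d2) == -60.0


class TestImprovement:
    def test_self_baseline_is_zero(self):
        assert improvement(7.3, 7.3) == 0.0

    def test_perfect_estimate_vs_baseline(self, rng):
        t = rng.standard_normal(200)
        mix = t + rng.standard_normal(200)
        base = si_sdr(mix, t)
        assert np.isclose(improvement(si_sdr(t, t), base), 60.0 - base)

    @pytest.mark.parametrize("scale", [0.1, 2.0, 30.0])
    def test_si_sdri_invariant_to_target_rescaling(self, rng, scale):
        t = rng.standard_normal(300)
        e = t + 0.3 * rng.standard_normal(300)
        mix = t + rng.standard_normal(300)
        a = improvement(si_sdr(e, t), si_sdr(mix, t))
        b = improvement(si_sdr(e, scale * t), si_sdr(mix, scale * t))
        assert np.isclose(a, b, atol=1e-9)


class TestSummaries:
    @staticmethod
    def _result(i, part, src, v):
        return EvalResult(example_id=str(i), partition=part, source=src,
                          sdr_db=v, si_sdr_db=v, sdri_db=v, si_sdri_db=v)

    def test_single_result_median_is_the_value(self):
        s = summarize([self._result(0, "no_noise", "heart", 4.2)])
        assert len(s) == 1
        assert np.isclose(s.loc[0, "median_sdri_db"], 4.2)

    def test_hand_computed_quartiles_with_linear_interpolation(self):
        rs = [self._result(i, "no_noise", "lung", v)
              for i, v in enumerate([1.0, 2.0, 3.0])]
        s = summarize(rs)
        assert np.isclose(s.loc[0, "median_si_sdri_db"], 2.0)
        assert np.isclose(s.loc[0, "q1_si_sdri_db"], 1.5)
        assert np.isclose(s.loc[0, "q3_si_sdri_db"], 2.5)

    def test_groups_partition_the_results(self):
        rs = ([self._result(i, "no_noise", "heart", 1.0) for i in range(3)]
              + [self._result(i, "general_noise", "lung", 2.0)
                 for i in range(4)])
        s = summarize(rs)
        assert int(s["n"].sum()) == 7

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            results_frame([])
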