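import numpy as np
import pytest

from emgdx import build_lifting_scheme, lwt_decompose, lwt_reconstruct

from conv_dwt import conv_dwt_level, conv_dwt_multilevel


class TestLiftingScheme:
    def test_structure(self, scheme):
        kinds = {s.kind for s in scheme.steps}
        assert "predict" in kinds and "update" in kinds
        assert scheme.k_e != 0 and scheme.k_o != 0

    def test_unsupported_wavelet_rejected(self):
        with pytest.raises(ValueError, match="unsupported wavelet"):
            build_lifting_scheme("not-a-wavelet")

    @pytest.mark.parametrize("name", ["rbio3.7", "db2", "bior2.2", "haar"])
    def test_factorization_works_across_wavelets(self, name, rng):
        sch = build_lifting_scheme(name)  # construction self-verifies
        x = rng.standard_normal(256)
        rec = lwt_reconstruct(lwt_decompose(x, 3, sch), sch)
        assert np.max(np.abs(rec - x)) <= 1e-8 * np.max(np.abs(x))


class TestAnalysis:
    def test_level5_gives_six_subbands(self, scheme, rng):
        sb = lwt_decompose(rng.standard_normal(512), 5, scheme)
        assert len(sb.subbands) == 6
        assert sb.subband_names == ["a5", "d1", "d2", "d3", "d4", "d5"]

    def test_minimal_length_level1(self, scheme):
        sb = lwt_decompose(np.array([1.0, 2.0]), 1, scheme)
        assert len(sb.approx) == 1 and len(sb.details[0]) == 1

    def test_lengths_halve_with_rounding(self, scheme, rng):
        sb = lwt_decompose(rng.standard_normal(556), 5, scheme)
        expected = []
        n = 556
        for _ in range(5):
            n = (n + 1) // 2
            expected.append(n)
        assert [len(d) for d in sb.details] == expected
        assert len(sb.approx) == expected[-1]

    def test_too_short_signal_rejected(self, scheme, rng):
        with pytest.raises(ValueError, match="too short"):
            lwt_decompose(rng.standard_normal(31), 5, scheme)

    def test_constant_signal_has_zero_details(self, scheme):
        """Any analysis wavelet with one vanishing moment annihilates a
        constant; under periodization every detail coefficient vanishes."""
        sb = lwt_decompose(np.full(128, 3.25), 1, scheme)
        assert np.max(np.abs(sb.details[0])) < 1e-10

    def test_single_level_matches_convolution_oracle(self, scheme, rng):
        for n in (64, 128, 250, 512):
            y = rng.standard_normal(n)
            sb = lwt_decompose(y, 1, scheme)
            a_ref, d_ref = conv_dwt_level(y)
            scale = max(np.max(np.abs(a_ref)), np.max(np.abs(d_ref)))
            assert np.max(np.abs(sb.approx - a_ref)) <= 1e-8 * scale
            assert np.max(np.abs(sb.details[0] - d_ref)) <= 1e-8 * scale

    def test_multilevel_matches_convolution_oracle(self, scheme, rng):
        for n in (64, 200, 512):
            y = rng.standard_normal(n)
            sb = lwt_decompose(y, 3, scheme)
            a_ref, details_ref = conv_dwt_multilevel(y, 3)
            scale = np.max(np.abs(y)) * 10
            assert np.max(np.abs(sb.approx - a_ref)) <= 1e-8 * scale
            for d, d_ref in zip(sb.details, details_ref):
                assert np.max(np.abs(d - d_ref)) <= 1e-8 * scale


class TestPerfectReconstruction:
    def test_random_vectors_random_lengths(self, scheme):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(64, 8193))
            x = rng.standard_normal(n)
            rec = lwt_reconstruct(lwt_decompose(x, 5, scheme), scheme)
            assert len(rec) == n
            assert np.max(np.abs(rec - x)) <= 1e-8 * np.max(np.abs(x))

    def test_symmetric_extension_also_reconstructs(self, scheme, rng):
        x = rng.standard_normal(500)
        sb = lwt_decompose(x, 5, scheme, extension_mode="symmetric")
        rec = lwt_reconstruct(sb, scheme)
        assert np.max(np.abs(rec - x)) <= 1e-8 * np.max(np.abs(x))

    def test_zero_subbands_give_zero_signal(self, scheme, rng):
        sb = lwt_decompose(rng.standard_normal(256), 5, scheme)
        sb.approx = np.zeros_like(sb.approx)
        sb.details = [np.zeros_like(d) for d in sb.details]
        assert np.max(np.abs(lwt_reconstruct(sb, scheme))) == 0.0

    def test_linearity(self, scheme, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        sx = lwt_decompose(x, 4, scheme)
        sy = lwt_decompose(y, 4, scheme)
        sxy = lwt_decompose(2.0 * x - 0.5 * y, 4, scheme)
        for bx, by, bxy in zip(sx.subbands, sy.subbands, sxy.subbands):
            assert np.allclose(2.0 * bx - 0.5 * by, bxy, atol=1e-9 * np.max(np.abs(bxy) + 1))

    def test_mismatched_scheme_rejected(self, scheme, rng):
        sb = lwt_decompose(rng.standard_normal(256), 3, scheme)
        other = build_lifting_scheme("db2")
        with pytest.raises(ValueError, match="does not match"):
            lwt_reconstruct(sb, other)
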