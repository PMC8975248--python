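import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emgdx import FeatureVector, HiguchiConfig, Signal, extract_features, higuchi_fd, lbp_histogram
from emgdx.features import lbp_codes


class TestHiguchiFd:
    def test_straight_line_has_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0), k_max=8) == pytest.approx(1.0, abs=0.01)

    def test_white_noise_has_dimension_two(self):
        fds = [higuchi_fd(np.random.default_rng(s).standard_normal(10_000), 8) for s in range(20)]
        assert np.mean(fds) == pytest.approx(2.0, abs=0.05)

    def test_constant_series_defined_as_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert higuchi_fd(np.full(100, 5.0), 8) == 1.0

    def test_noise_rougher_than_its_random_walk(self):
        """Integrating a series smooths it: FD(noise) > FD(cumsum(noise))."""
        diffs = []
        for s in range(20):
            w = np.random.default_rng(s).standard_normal(2000)
            diffs.append(higuchi_fd(w, 8) - higuchi_fd(np.cumsum(w), 8))
        assert np.mean(diffs) > 0
        assert min(diffs) > 0

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            higuchi_fd(np.arange(15.0), k_max=8)


class TestLbp:
    def test_histogram_mass(self, rng):
        x = rng.normal(size=200)
        assert lbp_histogram(x, normalize=False).sum() == 192  # N - 8 codes
        assert lbp_histogram(x, normalize=True).sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_all_bits_set(self):
        h = lbp_histogram(np.ones(50), normalize=False)
        assert h[255] == 42 and h.sum() == 42

    def test_strictly_increasing_series_hits_bin_240(self):
        # left neighbors below the center (bits 0-3 clear), right above (bits 4-7 set)
        h = lbp_histogram(np.arange(100.0), normalize=False)
        assert h[0b11110000] == 92 and h.sum() == 92

    def test_minimum_length(self):
        with pytest.raises(ValueError, match="at least 9"):
            lbp_histogram(np.arange(8.0))
        assert lbp_histogram(np.arange(9.0), normalize=False).sum() == 1

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**16), c=st.floats(-1e3, 1e3), a=st.floats(0.01, 100.0))
    def test_offset_and_positive_scale_invariance(self, seed, c, a):
        x = np.random.default_rng(seed).normal(size=64)
        base = lbp_codes(x)
        assert np.array_equal(base, lbp_codes(x + c))
        assert np.array_equal(base, lbp_codes(a * x))


class TestExtractFeatures:
    def _signal(self, rng, n=556):
        return Signal(samples=rng.standard_normal(n), fs_hz=1111.0, label="healthy",
                      signal_id="p0#d0", parent_id="p0", offset=0)

    def test_fused_length_262(self, scheme, rng):
        fv = extract_features(self._signal(rng), scheme=scheme)
        assert len(fv.fused) == 262
        assert len(fv.fd) == 6
        assert len(fv.lbp) == 256
        assert fv.parent_id == "p0" and fv.offset == 0

    def test_deterministic(self, scheme, rng):
        sig = self._signal(rng)
        a = extract_features(sig, scheme=scheme)
        b = extract_features(sig, scheme=scheme)
        assert np.array_equal(a.fused, b.fused)

    def test_kmax_reduced_for_short_subbands(self, scheme, rng):
        sig = self._signal(rng, n=128)  # a5 has only 4 coefficients
        with pytest.warns(UserWarning, match="reducing Higuchi k_max"):
            fv = extract_features(sig, scheme=scheme, higuchi=HiguchiConfig(k_max=8))
        assert np.all(np.isfinite(fv.fused))

    def test_unusably_short_subband_raises(self, scheme, rng):
        with pytest.raises(ValueError, match="at least 4"):
            extract_features(self._signal(rng, n=96), scheme=scheme)

    def test_fd_order_is_coarse_to_fine_details(self, scheme, rng):
        """The fd block is pinned to (a5, d1 ... d5): a5 of a smooth signal
        is smooth (low FD) while d1 of noise stays rough."""
        t = np.linspace(0, 4 * np.pi, 2000)
        sig = Signal(samples=np.sin(t) + 0.01 * rng.standard_normal(2000), fs_hz=1000.0,
                     label="healthy", signal_id="p#d0", parent_id="p", offset=0)
        fv = extract_features(sig, scheme=scheme)
        assert fv.fd[0] < 1.3  # a5 tracks the smooth sinusoid

    def test_invalid_lbp_block_rejected(self):
        with pytest.raises(ValueError, match="256"):
            FeatureVector(fd=np.ones(6), lbp=np.ones(255))
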