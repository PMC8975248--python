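"""Feature extraction: Higuchi fractal dimensions of the six LWT subbands
fused with a 256-bin one-dimensional local binary pattern histogram.

The fused vector has length 6 + 256 = 262.  The fractal dimensions are
computed on the subband *coefficient* vectors (not on reconstructed
band-limited signals); the LBP histogram is computed on the downsampled
signal itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .lwt import LiftingScheme, build_lifting_scheme, lwt_decompose
from .simulate import Signal

#: neighbor offsets for the 1-D LBP code: 4 samples before and 4 after the
#: center; bit j (LSB first) corresponds to offsets[j], so the farthest-left
#: neighbor is the least significant bit.
LBP_OFFSETS: tuple[int, ...] = (-4, -3, -2, -1, 1, 2, 3, 4)

FEATURE_LENGTH = 262


@dataclass(frozen=True)
class HiguchiConfig:
    """k_max is the largest stride of the curve-length sum; the dimension
    is the slope of ln L(k) versus ln(1/k) over k = 1 … k_max."""

    k_max: int = 8

    def __post_init__(self):
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


@dataclass
class FeatureVector:
    """Fused descriptor of one downsampled signal: 6 subband fractal
    dimensions (order a5, d1 … d5) followed by the 256 LBP bins."""

    fd: np.ndarray
    lbp: np.ndarray
    signal_id: str = ""
    parent_id: str | None = None
    offset: int | None = None
    label: str = "unknown"

    def __post_init__(self):
        self.fd = np.asarray(self.fd, dtype=float)
        self.lbp = np.asarray(self.lbp, dtype=float)
        if len(self.lbp) != 256:
            raise ValueError("LBP block must have 256 bins")
        if np.any(self.lbp < 0):
            raise ValueError("LBP histogram entries must be non-negative")
        if not np.all(np.isfinite(self.fd)):
            raise ValueError("fractal dimensions must be finite")

    @property
    def fused(self) -> np.ndarray:
        return np.concatenate([self.fd, self.lbp])


def higuchi_fd(series: np.ndarray, k_max: int = 8) -> float:
    """Higuchi's fractal dimension of a 1-D series.

    For each stride k and start phase m (1-based, m = 1 … k) the
    normalized curve length is

        L_m(k) = [(N-1) / (floor((N-m)/k) * k)] * (1/k)
                 * sum_{i=1}^{floor((N-m)/k)} |X(m+ik) - X(m+(i-1)k)|

    and L(k) is the mean over m.  The dimension is the least-squares
    slope of ln L(k) against ln(1/k).  A smooth curve gives ~1, white
    noise ~2.  A constant series has zero curve length at every scale;
    by convention it gets dimension 1 (with a warning).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if n < 2 * k_max:
        raise ValueError(f"series of length {n} too short for k_max={k_max} (need >= {2 * k_max})")
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite")

    lk = np.empty(k_max)
    for k in range(1, k_max + 1):
        lengths = np.empty(k)
        for m in range(1, k + 1):
            seg = x[m - 1 :: k]  # X(m), X(m+k), X(m+2k), ...
            n_i = (n - m) // k
            if n_i < 1:
                lengths[m - 1] = np.nan
                continue
            dist = np.sum(np.abs(np.diff(seg[: n_i + 1])))
            lengths[m - 1] = dist * (n - 1) / (n_i * k) / k
        lk[k - 1] = np.nanmean(lengths)
    if np.any(lk <= 0):
        warnings.warn("degenerate (constant) series; Higuchi FD defined as 1.0")
        return 1.0
    k_vals = np.arange(1, k_max + 1)
    slope, _ = np.polyfit(np.log(1.0 / k_vals), np.log(lk), 1)
    return float(slope)


def lbp_codes(series: np.ndarray) -> np.ndarray:
    """8-bit local binary pattern code of every interior sample.

    Each center is compared (neighbor >= center, so ties set the bit)
    against its 4 preceding and 4 following samples; bit order is LSB at
    the farthest-left neighbor through MSB at the farthest-right.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 9:
        raise ValueError(f"need at least 9 samples for the 1-D LBP, got {n}")
    center = x[4 : n - 4]
    codes = np.zeros(n - 8, dtype=np.int64)
    for bit, off in enumerate(LBP_OFFSETS):
        codes |= (x[4 + off : n - 4 + off] >= center).astype(np.int64) << bit
    return codes


def lbp_histogram(series: np.ndarray, normalize: bool = True) -> np.ndarray:
    """256-bin histogram of the 1-D LBP codes.

    With ``normalize`` the bins are relative frequencies (they sum to 1);
    otherwise raw counts summing to N - 8.  The histogram is invariant to
    adding a constant to the series and to positive rescaling, since the
    codes only depend on pairwise comparisons.
    """
    codes = lbp_codes(series)
    hist = np.bincount(codes, minlength=256).astype(float)
    if normalize:
        hist /= len(codes)
    return hist


def extract_features(
    signal: Signal,
    levels: int = 5,
    scheme: LiftingScheme | None = None,
    extension_mode: str = "periodization",
    higuchi: HiguchiConfig = HiguchiConfig(),
    lbp_normalize: bool = True,
) -> FeatureVector:
    """Fused 262-length feature vector of one downsampled signal.

    The signal is decomposed to ``levels`` subbands whose coefficient
    vectors each get a Higuchi fractal dimension (a_J first, then
    d_1 … d_J); the LBP histogram is computed on the signal samples.  If a
    subband is too short for the configured k_max, k_max is reduced to
    floor(len/2) for that subband (with a warning) rather than failing.
    """
    if scheme is None:
        scheme = build_lifting_scheme()
    subbands = lwt_decompose(signal.samples, levels=levels, scheme=scheme, extension_mode=extension_mode)
    fds = np.empty(levels + 1)
    for i, coeffs in enumerate(subbands.subbands):
        k_max = higuchi.k_max
        if len(coeffs) < 2 * k_max:
            if len(coeffs) < 4:
                raise ValueError(
                    f"subband {subbands.subband_names[i]} has {len(coeffs)} coefficients; "
                    "at least 4 are needed for a fractal-dimension fit — use a longer "
                    "signal or fewer decomposition levels"
                )
            k_max = len(coeffs) // 2
            warnings.warn(
                f"subband {subbands.subband_names[i]} has only {len(coeffs)} coefficients; "
                f"reducing Higuchi k_max to {k_max}"
            )
        fds[i] = higuchi_fd(coeffs, k_max=k_max)
    lbp = lbp_histogram(signal.samples, normalize=lbp_normalize)
    return FeatureVector(
        fd=fds,
        lbp=lbp,
        signal_id=signal.signal_id,
        parent_id=signal.parent_id,
        offset=signal.offset,
        label=signal.label,
    )
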