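"""Lifting wavelet transform (LWT).

A single analysis level follows the classic four-step lifting scheme:

1. *split* the input y[n] into even and odd polyphase components
   y_e[n] = y[2n], y_o[n] = y[2n+1];
2. *predict* — high-pass lifting steps that modify the odd lane from the
   even lane;
3. *update* — low-pass lifting steps that modify the even lane from the
   odd lane;
4. *normalize* — scale (and possibly shift) the two lanes by k_e and k_o
   to obtain the approximation a[n] and detail d[n] coefficients.

The steps for a given biorthogonal wavelet are obtained at run time by a
Euclidean (continued-fraction) factorization of the analysis polyphase
matrix into elementary Laurent-matrix factors.  Because every lifting
step is trivially invertible, the synthesis side is exact: the transform
reconstructs the input to floating-point precision.  The factorization is
verified on construction against direct polyphase filtering, so a wrong
factorization can never be used silently.

The cascade is equivalent (for the default periodization mode) to a
circular-convolution DWT with the same analysis filters, with the
convention  a[n] = sum_k h[k] y[(2n+1-k) mod N]  (likewise d with g).

Level-J decomposition re-analyzes the approximation lane recursively and
yields J+1 subbands a_J, d_1 ... d_J; the default here is J = 5 with the
reverse-biorthogonal rbio3.7 wavelet, i.e. six subbands a5, d1 ... d5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from ._laurent import LaurentPoly, laurent_divmod

EXTENSION_MODES = ("periodization", "symmetric")


@dataclass(frozen=True)
class LiftingStep:
    """One elementary lifting step: ``lane += poly(other lane)``.

    ``kind`` is "predict" when the odd (detail) lane is modified and
    "update" when the even (approximation) lane is modified.
    """

    kind: str
    poly: LaurentPoly


@dataclass(frozen=True)
class LiftingScheme:
    """Factored analysis scheme for one wavelet.

    ``k_e``/``k_o`` scale the even/odd lanes after the lifting steps;
    ``shift_e``/``shift_o`` are the integer delays that complete the
    normalization (the polyphase determinant is a monomial, not
    necessarily a constant).
    """

    wavelet_name: str
    steps: tuple[LiftingStep, ...]
    k_e: float
    k_o: float
    shift_e: int
    shift_o: int
    dec_lo: np.ndarray = field(repr=False)
    dec_hi: np.ndarray = field(repr=False)


@dataclass
class SubbandSet:
    """Level-J LWT coefficients: approximation ``a_J`` plus details
    ``d_1 … d_J`` (d_1 = finest).  ``level_lengths[j]`` is the input
    length at level j+1 before any odd-length padding, which is what
    reconstruction needs to undo the padding."""

    approx: np.ndarray
    details: list[np.ndarray]  # d1 first
    wavelet_name: str
    extension_mode: str
    level_lengths: list[int]

    @property
    def levels(self) -> int:
        return len(self.details)

    @property
    def subbands(self) -> list[np.ndarray]:
        """Coefficient vectors in the fixed feature order a_J, d_1 … d_J."""
        return [self.approx, *self.details]

    @property
    def subband_names(self) -> list[str]:
        j = self.levels
        return [f"a{j}", *[f"d{i}" for i in range(1, j + 1)]]


def _polyphase_row(h: np.ndarray) -> tuple[LaurentPoly, LaurentPoly]:
    """Row [p_e, p_o] of the analysis polyphase matrix acting on (y_e, y_o)
    under the convention c[n] = sum_k h[k] y[2n+1-k]."""
    h = np.asarray(h, dtype=float)
    return LaurentPoly(h[1::2]), LaurentPoly(h[0::2])


def build_lifting_scheme(wavelet_name: str = "rbio3.7") -> LiftingScheme:
    """Factor a discrete wavelet's analysis filter pair into lifting steps.

    Works for any orthogonal or biorthogonal wavelet known to PyWavelets
    (whose filters are the single standard source here; the lifting
    cascade itself never calls PyWavelets).  The returned scheme is
    numerically verified against direct polyphase filtering on a random
    vector; a mismatch raises instead of returning a broken scheme.
    """
    try:
        w = pywt.Wavelet(wavelet_name)
    except ValueError as exc:
        raise ValueError(f"unsupported wavelet {wavelet_name!r}: {exc}") from None
    dec_lo = np.asarray(w.dec_lo, dtype=float)
    dec_hi = np.asarray(w.dec_hi, dtype=float)

    B = [list(_polyphase_row(dec_lo)), list(_polyphase_row(dec_hi))]
    steps: list[LiftingStep] = []

    def col0_minus_q_col1(q: LaurentPoly) -> None:
        # right-multiplication by [[1,0],[-q,1]]; its inverse (applied to the
        # lanes, in order) is the predict step  v_o += q(v_e)
        for r in range(2):
            B[r][0] = B[r][0] - q * B[r][1]
        steps.append(LiftingStep("predict", q))

    def col1_minus_q_col0(q: LaurentPoly) -> None:
        # inverse is the update step  v_e += q(v_o)
        for r in range(2):
            B[r][1] = B[r][1] - q * B[r][0]
        steps.append(LiftingStep("update", q))

    # Euclidean algorithm on the low-pass row: its two polyphase entries
    # have a monomial gcd (it divides the monomial polyphase determinant),
    # so the reduction terminates with one entry exactly zero.
    guard = 0
    while not (B[0][0].is_zero() or B[0][1].is_zero()):
        guard += 1
        if guard > 200:
            raise RuntimeError(f"lifting factorization did not terminate for {wavelet_name!r}")
        if B[0][0].span() >= B[0][1].span():
            q, _ = laurent_divmod(B[0][0], B[0][1])
            col0_minus_q_col1(q)
        else:
            q, _ = laurent_divmod(B[0][1], B[0][0])
            col1_minus_q_col0(q)
    if B[0][0].is_zero():
        # move the surviving entry into the diagonal position
        col0_minus_q_col1(LaurentPoly([-1.0]))
        col1_minus_q_col0(LaurentPoly([1.0]))
    if not (B[0][0].is_monomial() and B[0][1].is_zero()):
        raise RuntimeError(f"lifting factorization failed for {wavelet_name!r}")
    # det = B00 * B11 is a monomial, hence B11 is too; one exact division
    # clears the remaining off-diagonal entry.
    b11 = B[1][1]
    if not b11.is_monomial():
        raise RuntimeError(
            f"{wavelet_name!r} does not have a monomial polyphase determinant; "
            "is it a perfect-reconstruction filter bank?"
        )
    if not B[1][0].is_zero():
        q = LaurentPoly(B[1][0].c / b11.c[0], B[1][0].lo - b11.lo)
        col0_minus_q_col1(q)
    if not B[1][0].is_zero():
        raise RuntimeError(f"lifting factorization failed for {wavelet_name!r}")
    b00 = B[0][0]

    scheme = LiftingScheme(
        wavelet_name=wavelet_name,
        steps=tuple(steps),
        k_e=float(b00.c[0]),
        k_o=float(b11.c[0]),
        shift_e=int(b00.lo),
        shift_o=int(b11.lo),
        dec_lo=dec_lo,
        dec_hi=dec_hi,
    )
    _verify_scheme(scheme)
    return scheme


def _polyphase_filter(h: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct circular filtering c[n] = sum_k h[k] y[(2n+1-k) mod N]."""
    n_half = len(y) // 2
    idx = (2 * np.arange(n_half)[:, None] + 1 - np.arange(len(h))[None, :]) % len(y)
    return y[idx] @ h


def _verify_scheme(scheme: LiftingScheme, n: int = 64, tol: float = 1e-8) -> None:
    rng = np.random.default_rng(12345)
    y = rng.standard_normal(n)
    a, d = _analyze_one_level(y, scheme, "periodization")
    a_ref = _polyphase_filter(scheme.dec_lo, y)
    d_ref = _polyphase_filter(scheme.dec_hi, y)
    scale = max(np.max(np.abs(a_ref)), np.max(np.abs(d_ref)), 1.0)
    err = max(np.max(np.abs(a - a_ref)), np.max(np.abs(d - d_ref))) / scale
    if err > tol:
        raise RuntimeError(
            f"lifting factorization of {scheme.wavelet_name!r} disagrees with the "
            f"filter bank (relative error {err:.2e})"
        )


def _apply(poly: LaurentPoly, x: np.ndarray, mode: str) -> np.ndarray:
    if mode == "periodization":
        return poly.apply_circular(x)
    return poly.apply_symmetric(x)


def _analyze_one_level(y: np.ndarray, scheme: LiftingScheme, mode: str) -> tuple[np.ndarray, np.ndarray]:
    """Split / predict / update / normalize on an even-length vector."""
    v_e = y[0::2].astype(float).copy()
    v_o = y[1::2].astype(float).copy()
    for step in scheme.steps:
        if step.kind == "predict":
            v_o += _apply(step.poly, v_e, mode)
        else:
            v_e += _apply(step.poly, v_o, mode)
    a = scheme.k_e * np.roll(v_e, scheme.shift_e)
    d = scheme.k_o * np.roll(v_o, scheme.shift_o)
    return a, d


def _synthesize_one_level(a: np.ndarray, d: np.ndarray, scheme: LiftingScheme, mode: str) -> np.ndarray:
    """Exact inverse of :func:`_analyze_one_level`."""
    v_e = np.roll(a / scheme.k_e, -scheme.shift_e)
    v_o = np.roll(d / scheme.k_o, -scheme.shift_o)
    for step in reversed(scheme.steps):
        if step.kind == "predict":
            v_o -= _apply(step.poly, v_e, mode)
        else:
            v_e -= _apply(step.poly, v_o, mode)
    y = np.empty(len(a) + len(d))
    y[0::2] = v_e
    y[1::2] = v_o
    return y


def lwt_decompose(
    samples: np.ndarray,
    levels: int = 5,
    scheme: LiftingScheme | None = None,
    extension_mode: str = "periodization",
) -> SubbandSet:
    """Level-J lifting analysis: a_J plus d_1 … d_J.

    Odd-length inputs at any level are extended by one sample (repeating
    the last one) before splitting; the pre-padding length is recorded so
    reconstruction can truncate back.  Coefficient counts therefore halve
    (rounding up) at each level.
    """
    if extension_mode not in EXTENSION_MODES:
        raise ValueError(f"extension_mode must be one of {EXTENSION_MODES}")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise ValueError("samples must be 1-D")
    if len(x) < 2**levels:
        raise ValueError(f"signal of length {len(x)} is too short for {levels} levels (need >= {2**levels})")
    if scheme is None:
        scheme = build_lifting_scheme()
    details: list[np.ndarray] = []
    level_lengths: list[int] = []
    cur = x
    for _ in range(levels):
        level_lengths.append(len(cur))
        if len(cur) % 2:
            cur = np.append(cur, cur[-1])
        a, d = _analyze_one_level(cur, scheme, extension_mode)
        details.append(d)
        cur = a
    return SubbandSet(
        approx=cur,
        details=details,
        wavelet_name=scheme.wavelet_name,
        extension_mode=extension_mode,
        level_lengths=level_lengths,
    )


def lwt_reconstruct(subbands: SubbandSet, scheme: LiftingScheme | None = None) -> np.ndarray:
    """Invert :func:`lwt_decompose`; exact to floating-point round-off."""
    if scheme is None:
        scheme = build_lifting_scheme(subbands.wavelet_name)
    elif scheme.wavelet_name != subbands.wavelet_name:
        raise ValueError(
            f"scheme wavelet {scheme.wavelet_name!r} does not match subbands "
            f"({subbands.wavelet_name!r})"
        )
    if len(subbands.level_lengths) != subbands.levels:
        raise ValueError("inconsistent level bookkeeping in SubbandSet")
    cur = subbands.approx
    for d, n_orig in zip(reversed(subbands.details), reversed(subbands.level_lengths)):
        if len(cur) != len(d):
            raise ValueError("inconsistent subband lengths; not a valid decomposition")
        cur = _synthesize_one_level(cur, d, scheme, subbands.extension_mode)[:n_orig]
    return cur
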