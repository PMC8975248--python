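"""Laurent polynomials in the delay operator, used to factor wavelet
filter banks into lifting steps.

A polynomial ``p`` with coefficient array ``c`` and lowest exponent ``lo``
represents ``sum_i c[i] * D**(lo + i)`` where ``D`` is a one-sample delay
of a (periodized) sequence.  Negative exponents are advances, so these are
genuine Laurent polynomials.
"""

from __future__ import annotations

import numpy as np

#: coefficients smaller than this (relative to the largest one) are zeroed
_TRIM_TOL = 1e-10


class LaurentPoly:
    __slots__ = ("c", "lo")

    def __init__(self, c, lo: int = 0):
        c = np.atleast_1d(np.asarray(c, dtype=float))
        self.c = c
        self.lo = int(lo)
        self._trim()

    def _trim(self) -> None:
        c = self.c
        peak = np.max(np.abs(c)) if c.size else 0.0
        tol = _TRIM_TOL * max(peak, 1.0)
        nz = np.nonzero(np.abs(c) > tol)[0]
        if nz.size == 0:
            self.c, self.lo = np.zeros(0), 0
        else:
            self.c = c[nz[0] : nz[-1] + 1].copy()
            self.c[np.abs(self.c) <= tol] = 0.0
            self.lo += int(nz[0])

    # -- structure -------------------------------------------------------
    @property
    def hi(self) -> int:
        return self.lo + len(self.c) - 1

    def is_zero(self) -> bool:
        return len(self.c) == 0

    def span(self) -> int:
        """Number of terms between the lowest and highest exponent."""
        return len(self.c)

    def is_monomial(self) -> bool:
        return len(self.c) == 1

    # -- ring operations -------------------------------------------------
    def __add__(self, other: "LaurentPoly") -> "LaurentPoly":
        if self.is_zero():
            return LaurentPoly(other.c, other.lo)
        if other.is_zero():
            return LaurentPoly(self.c, self.lo)
        lo = min(self.lo, other.lo)
        hi = max(self.hi, other.hi)
        c = np.zeros(hi - lo + 1)
        c[self.lo - lo : self.lo - lo + len(self.c)] += self.c
        c[other.lo - lo : other.lo - lo + len(other.c)] += other.c
        return LaurentPoly(c, lo)

    def __neg__(self) -> "LaurentPoly":
        return LaurentPoly(-self.c, self.lo)

    def __sub__(self, other: "LaurentPoly") -> "LaurentPoly":
        return self + (-other)

    def __mul__(self, other: "LaurentPoly") -> "LaurentPoly":
        if self.is_zero() or other.is_zero():
            return LaurentPoly([])
        return LaurentPoly(np.convolve(self.c, other.c), self.lo + other.lo)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"LaurentPoly({self.c!r}, lo={self.lo})"

    # -- evaluation on periodized sequences ------------------------------
    def apply_circular(self, x: np.ndarray) -> np.ndarray:
        """Apply the polynomial to a sequence with periodic boundary."""
        y = np.zeros(len(x))
        for j, cj in enumerate(self.c):
            if cj != 0.0:
                y += cj * np.roll(x, self.lo + j)
        return y

    def apply_symmetric(self, x: np.ndarray) -> np.ndarray:
        """Apply the polynomial with half-sample symmetric extension."""
        n = len(x)
        taps = [(self.lo + j, cj) for j, cj in enumerate(self.c) if cj != 0.0]
        if not taps:
            return np.zeros(n)
        pad = max(abs(d) for d, _ in taps)
        xe = np.pad(x, pad, mode="symmetric") if pad else x
        y = np.zeros(n)
        for d, cj in taps:
            y += cj * xe[pad - d : pad - d + n]
        return y


def laurent_divmod(a: LaurentPoly, b: LaurentPoly) -> tuple[LaurentPoly, LaurentPoly]:
    """Division with remainder: ``a = q*b + r`` with ``span(r) < span(b)``.

    Terms are cancelled from the highest-exponent end.  Like ordinary
    polynomial division over the reals this is exact up to rounding; the
    trimming tolerance removes the cancelled leading terms.
    """
    if b.is_zero():
        raise ZeroDivisionError("division by the zero Laurent polynomial")
    q = LaurentPoly([])
    r = LaurentPoly(a.c, a.lo)
    while not r.is_zero() and r.span() >= b.span():
        t = LaurentPoly([r.c[-1] / b.c[-1]], r.hi - b.hi)
        q = q + t
        r2 = r - t * b
        if not r2.is_zero() and r2.hi >= r.hi and r2.span() >= b.span():
            # the leading term must have cancelled; drop residual round-off
            r2.c[-1] = 0.0
            r2._trim()
        r = r2
    return q, r
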