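"""Independent convolution-based DWT used as an oracle for the lifting
cascade.  Deliberately implemented as plain circular filtering with the
wavelet's analysis filters — no lifting, no polyphase factorization —
under the shared convention c[n] = sum_k h[k] y[(2n+1-k) mod N] with
periodic extension, padding odd lengths by repeating the last sample.
"""

import numpy as np
import pywt


def conv_dwt_level(y, wavelet="rbio3.7"):
    w = pywt.Wavelet(wavelet)
    h = np.asarray(w.dec_lo)
    g = np.asarray(w.dec_hi)
    y = np.asarray(y, dtype=float)
    if len(y) % 2:
        y = np.append(y, y[-1])
    n = len(y)
    a = np.zeros(n // 2)
    d = np.zeros(n // 2)
    for m in range(n // 2):
        for k in range(len(h)):
            ym = y[(2 * m + 1 - k) % n]
            a[m] += h[k] * ym
            d[m] += g[k] * ym
    return a, d


def conv_dwt_multilevel(y, levels, wavelet="rbio3.7"):
    """Approximation a_J and details [d1 ... dJ], finest first."""
    details = []
    cur = np.asarray(y, dtype=float)
    for _ in range(levels):
        cur, d = conv_dwt_level(cur, wavelet)
        details.append(d)
    return cur, details
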