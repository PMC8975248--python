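"""Preprocessing and polyphase decimation.

An iEMG recording of length N decimated by a factor M yields M "disjoint"
downsampled signals: child m holds samples x[m], x[m+M], x[m+2M], ...
The children partition the parent's samples exactly — there is no
anti-alias filtering, because any pre-filter would leak information
across children and the partition property is the point.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .simulate import Signal


@dataclass(frozen=True)
class PreprocessConfig:
    normalize: bool = True
    bandpass_hz: tuple[float, float] | None = None
    decimation_factor: int = 9

    def __post_init__(self):
        if self.decimation_factor < 1:
            raise ValueError("decimation factor M must be >= 1")


@dataclass
class DecimationResult:
    children: list[Signal]
    parent_id: str
    M: int


def preprocess(signal: Signal, config: PreprocessConfig = PreprocessConfig()) -> Signal:
    """Optionally band-pass (zero-phase) then z-score a signal.

    With ``normalize`` the output has sample mean 0 and SD 1; a constant
    signal cannot be normalized and is rejected.
    """
    if len(signal.samples) < 2:
        raise ValueError("need at least 2 samples to preprocess")
    x = signal.samples
    if config.bandpass_hz is not None:
        low, high = config.bandpass_hz
        nyq = signal.fs_hz / 2.0
        if not (0.0 < low < high < nyq):
            raise ValueError(f"band edges must satisfy 0 < {low} < {high} < fs/2 = {nyq}")
        sos = butter(4, [low, high], btype="bandpass", fs=signal.fs_hz, output="sos")
        x = sosfiltfilt(sos, x)
    if config.normalize:
        sd = np.std(x)
        if sd == 0:
            raise ValueError("cannot z-score a zero-variance signal")
        x = (x - np.mean(x)) / sd
    elif x is signal.samples:
        x = x.copy()
    return replace(signal, samples=x)


def polyphase_decimate(signal: Signal, M: int) -> DecimationResult:
    """Split a signal into M interleaved children (pure sample selection).

    Child m has sampling rate fs/M, inherits the parent's label, and
    records its parent id and offset so the per-parent label sequence can
    be reassembled after classification.
    """
    n = len(signal.samples)
    if M < 1 or M > n:
        raise ValueError(f"decimation factor M={M} must be in [1, {n}]")
    children = []
    for m in range(M):
        children.append(
            Signal(
                samples=signal.samples[m::M].copy(),
                fs_hz=signal.fs_hz / M,
                label=signal.label,
                signal_id=f"{signal.signal_id}#d{m}",
                parent_id=signal.signal_id,
                offset=m,
            )
        )
    return DecimationResult(children=children, parent_id=signal.signal_id, M=M)


def interleave(result: DecimationResult) -> np.ndarray:
    """Inverse of :func:`polyphase_decimate`: merge children back by offset."""
    n = sum(len(c.samples) for c in result.children)
    out = np.empty(n)
    for child in result.children:
        out[child.offset :: result.M] = child.samples
    return out
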