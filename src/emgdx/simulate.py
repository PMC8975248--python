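"""Synthetic intramuscular EMG (iEMG) generation.

Needle EMG records a superposition of motor unit action potentials
(MUAPs).  Neuromuscular disease changes MUAP morphology in opposite
directions: myopathic MUAPs are short, small and polyphasic (spectrum
shifted toward high frequencies), neurogenic MUAPs are long, large and
polyphasic (spectrum shifted low), while healthy MUAPs have 2-4 phases
and intermediate size.  This module emulates those contrasts with a
simple renewal-process model: each motor unit fires with Gamma-
distributed inter-spike intervals and contributes a fixed MUAP kernel
built from alternating-sign Gaussian lobes; channel noise is additive
white Gaussian.  It makes no attempt at volume-conductor realism — the
point is a labeled, reproducible dataset whose class contrasts match
the clinical phenomenology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import fftconvolve

HEALTHY = "healthy"
MYOPATHY = "myopathy"
NEUROPATHY = "neuropathy"

#: fixed class order used everywhere (one-hot targets, tie-breaking, reports)
CLASSES: tuple[str, str, str] = (HEALTHY, MYOPATHY, NEUROPATHY)

#: per-class MUAP parameter ranges: amplitude (µV), duration (ms), phases.
#: Deliberately disjoint so the qualitative clinical contrasts
#: (myopathy < healthy < neuropathy in amplitude and duration) always hold.
CLASS_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    HEALTHY: {"amplitude_uV": (200.0, 600.0), "duration_ms": (6.0, 12.0), "n_phases": (2, 4)},
    MYOPATHY: {"amplitude_uV": (50.0, 200.0), "duration_ms": (2.0, 6.0), "n_phases": (5, 8)},
    NEUROPATHY: {"amplitude_uV": (600.0, 1500.0), "duration_ms": (12.0, 25.0), "n_phases": (5, 8)},
}

#: default channel noise SD: 5% of the healthy amplitude midpoint (400 µV)
DEFAULT_NOISE_SD_UV = 20.0


@dataclass(frozen=True)
class MuapTemplate:
    """One motor unit's action potential kernel.

    ``waveform`` is sampled at ``fs_hz``, has unit energy before scaling
    by ``amplitude_uV``, and sums to (numerically) zero: a real MUAP is
    at least biphasic and carries no DC.
    """

    n_phases: int
    duration_ms: float
    amplitude_uV: float
    fs_hz: float
    waveform: np.ndarray

    def __post_init__(self):
        if self.n_phases < 2:
            raise ValueError("a MUAP has at least 2 phases")
        if self.duration_ms <= 0 or self.amplitude_uV <= 0:
            raise ValueError("duration_ms and amplitude_uV must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic iEMG recording."""

    class_label: str
    fs_hz: float = 10_000.0
    duration_s: float = 5.0
    n_motor_units: int = 15
    firing_rate_hz: float = 10.0
    firing_jitter: float = 0.15  # CV of inter-spike intervals
    noise_sd_uV: float = DEFAULT_NOISE_SD_UV
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ValueError(f"unknown class label {self.class_label!r}; expected one of {CLASSES}")
        if self.fs_hz < 2000.0:
            raise ValueError("fs_hz must be at least 2 kHz")
        if self.duration_s * self.fs_hz < 9 * 512:
            raise ValueError(
                "recording too short: need duration_s*fs_hz >= 4608 samples so that "
                "each of the 9 default decimated signals supports a level-5 transform"
            )
        if not (0.0 <= self.firing_jitter < 1.0):
            raise ValueError("firing_jitter is a coefficient of variation in [0, 1)")
        if self.noise_sd_uV < 0 or self.firing_rate_hz <= 0 or self.n_motor_units < 1:
            raise ValueError("invalid firing/noise configuration")


@dataclass
class Signal:
    """A sampled iEMG trace (µV) with provenance.

    ``offset`` and ``parent_id`` are set only on decimated children: child
    ``m`` of a parent decimated by ``M`` holds parent samples ``m, m+M, …``.
    """

    samples: np.ndarray
    fs_hz: float
    label: str = "unknown"
    signal_id: str = ""
    parent_id: str | None = None
    offset: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if (self.offset is None) != (self.parent_id is None):
            raise ValueError("offset must be set iff parent_id is set")


def make_muap_template(
    class_label: str, rng: np.random.Generator, fs_hz: float = 10_000.0
) -> MuapTemplate:
    """Draw a MUAP kernel for one motor unit of the given class.

    The kernel is a train of ``n_phases`` alternating-sign Gaussian lobes
    spread over the drawn duration.  Positive and negative lobe groups are
    rebalanced so the kernel sums to zero even for odd phase counts, then
    normalized to unit energy and scaled to the drawn amplitude.
    """
    try:
        ranges = CLASS_RANGES[class_label]
    except KeyError:
        raise ValueError(f"unknown class label {class_label!r}; expected one of {CLASSES}")
    p_lo, p_hi = ranges["n_phases"]
    n_phases = int(rng.integers(p_lo, p_hi + 1))
    duration_ms = float(rng.uniform(*ranges["duration_ms"]))
    amplitude_uV = float(rng.uniform(*ranges["amplitude_uV"]))

    t_total = duration_ms / 1000.0
    sigma = t_total / (3.0 * n_phases)
    # extend the support by 3 sigma on both sides so the lobes decay smoothly
    t = np.arange(-3 * sigma, t_total + 3 * sigma, 1.0 / fs_hz)
    centers = (np.arange(n_phases) + 0.5) * t_total / n_phases
    pos = np.zeros_like(t)
    neg = np.zeros_like(t)
    for j, c in enumerate(centers):
        lobe = np.exp(-0.5 * ((t - c) / sigma) ** 2)
        if j % 2 == 0:
            pos += lobe
        else:
            neg += lobe
    # rebalance so the kernel integrates to zero (pure AC waveform)
    w = pos / pos.sum() - neg / neg.sum()
    w /= np.sqrt(np.sum(w**2))
    return MuapTemplate(
        n_phases=n_phases,
        duration_ms=duration_ms,
        amplitude_uV=amplitude_uV,
        fs_hz=fs_hz,
        waveform=amplitude_uV * w,
    )


def _spike_times(rng: np.random.Generator, rate_hz: float, cv: float, duration_s: float) -> np.ndarray:
    """Gamma-renewal firing times in [0, duration); cv == 0 gives a periodic train."""
    mean_isi = 1.0 / rate_hz
    times = [rng.uniform(0.0, mean_isi)]
    while times[-1] < duration_s:
        if cv == 0.0:
            isi = mean_isi
        else:
            shape = 1.0 / cv**2
            isi = rng.gamma(shape, mean_isi / shape)
        times.append(times[-1] + isi)
    return np.asarray(times[:-1])


def generate_iemg(config: SimConfig) -> Signal:
    """Simulate one labeled iEMG recording.

    Each motor unit gets its own MUAP template and an independent Gamma-
    renewal spike train; the channel is their superposition plus white
    Gaussian noise.  Bit-reproducible for a fixed config (incl. seed).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s * config.fs_hz))
    x = np.zeros(n)
    for _ in range(config.n_motor_units):
        tpl = make_muap_template(config.class_label, rng, config.fs_hz)
        spikes = _spike_times(rng, config.firing_rate_hz, config.firing_jitter, config.duration_s)
        impulses = np.zeros(n)
        idx = np.floor(spikes * config.fs_hz).astype(int)
        np.add.at(impulses, idx[idx < n], 1.0)
        x += fftconvolve(impulses, tpl.waveform)[:n]
    if config.noise_sd_uV > 0:
        x += rng.normal(0.0, config.noise_sd_uV, n)
    return Signal(
        samples=x,
        fs_hz=config.fs_hz,
        label=config.class_label,
        signal_id=f"{config.class_label}-s{config.seed}",
    )


def _derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def generate_dataset(
    n_per_class: Mapping[str, int],
    base_config: SimConfig | None = None,
    seed: int = 0,
) -> list[Signal]:
    """Generate a labeled collection of iEMG recordings.

    Per-signal seeds are derived deterministically from ``seed`` and the
    (class, index) pair, so two calls with the same arguments return
    bit-identical signals with identical ids.
    """
    for cls, count in n_per_class.items():
        if cls not in CLASSES:
            raise ValueError(f"unknown class label {cls!r}")
        if count < 1:
            raise ValueError("per-class counts must be >= 1")
    if base_config is None:
        base_config = SimConfig(class_label=HEALTHY, seed=0)
    signals: list[Signal] = []
    for ci, cls in enumerate(CLASSES):
        for i in range(n_per_class.get(cls, 0)):
            cfg = replace(base_config, class_label=cls, seed=_derive_seed(seed, ci, i))
            sig = generate_iemg(cfg)
            sig.signal_id = f"{cls}-{i:04d}"
            signals.append(sig)
    return signals


def spectral_centroid(signal: Signal) -> float:
    """Power-weighted mean frequency (Hz) from the periodogram; a quick
    check that myopathic signals sit higher in frequency than neurogenic."""
    from scipy.signal import periodogram

    f, p = periodogram(signal.samples, fs=signal.fs_hz)
    total = np.sum(p)
    if total == 0:
        warnings.warn("zero-power signal has no spectral centroid; returning 0")
        return 0.0
    return float(np.sum(f * p) / total)
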