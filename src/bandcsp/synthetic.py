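"""Two-class synthetic motor-imagery-like EEG.

Each source is band-limited Gaussian noise (unit variance after filtering)
scaled by a class-dependent amplitude and a per-trial lognormal-free jitter
factor, mixed linearly into the channels through a fixed unit-norm-column
mixing matrix, with white and pink (1/f) background noise added per channel.
The defaults mirror the desk-scale study conditions used throughout the
package: 8 channels, 100 trials per class, 100 Hz sampling, 200-sample
(2 s) epochs, one 10–14 Hz source whose amplitude is 1.0 for class 1 and
2.0 for class 2, and a moderate background (white and pink noise of std 1.0
relative to the unit-std sources, so the in-band background power is of the
same order as the planted rhythm — as it is in real sensorimotor EEG, where
µ/β modulations ride on comparable-power background activity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .epochs import EpochSet
from .filterbank import BandSpec, FeatureSetSpec, butter_sos, make_filterbank

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate",
    "planted_band_power",
    "default_config",
    "high_snr_config",
    "chance_config",
    "spectral_contrast_config",
]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; see the module docstring for the default regime.

    ``sources`` is a list of ``(low_hz, high_hz, class1_amp, class2_amp)``
    tuples. ``shared_mixing=True`` projects every source through the same
    spatial pattern (used to create class differences that only spectral
    weighting — CSSP — can resolve).
    """

    n_channels: int = 8
    trials_per_class: int = 100
    fs: float = 100.0
    epoch_samples: int = 200
    sources: tuple = (((10.0, 14.0), 1.0, 2.0),)
    mixing_seed: int = 12345
    white_std: float = 1.0
    pink_std: float = 1.0
    trial_jitter: float = 0.1
    shared_mixing: bool = False
    source_order: int = 4

    def __post_init__(self):
        if self.trials_per_class < 1:
            raise ValueError("trials_per_class must be >= 1")
        for (lo, hi), a1, a2 in self.sources:
            if not 0 < lo < hi < self.fs / 2:
                raise ValueError(
                    f"source band ({lo}, {hi}) outside (0, {self.fs / 2}) Hz"
                )
            if a1 < 0 or a2 < 0:
                raise ValueError("source amplitudes must be >= 0")
        if min(self.white_std, self.pink_std, self.trial_jitter) < 0:
            raise ValueError("noise and jitter levels must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: the mixing matrix, the source table and which
    default feature sets are informative (their band overlaps a source whose
    class amplitudes differ)."""

    mixing: np.ndarray
    sources: list
    informative_sets: list[int] = field(default_factory=list)


def _pink_noise(rng: np.random.Generator, shape: tuple, fs: float) -> np.ndarray:
    """1/f-amplitude noise via spectral shaping, flat below 1 Hz, unit std."""
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(shape[-1], d=1 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(freqs, 1.0))
    spec *= shaping
    x = np.fft.irfft(spec, n=shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_source(rng: np.random.Generator, n: int, T: int, band: BandSpec,
                 fs: float, order: int) -> np.ndarray:
    """Unit-std band-limited noise; generated with padding to reach the
    filter's steady state before trimming to the epoch length."""
    pad = int(2 * fs)
    sos = butter_sos(band, fs, order)
    x = signal.sosfilt(sos, rng.standard_normal((n, T + 2 * pad)), axis=-1)
    x = x[:, pad : pad + T]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _mixing(config: SimConfig) -> np.ndarray:
    mrng = np.random.default_rng(config.mixing_seed)
    n_src = len(config.sources)
    if config.shared_mixing:
        col = mrng.standard_normal((config.n_channels, 1))
        A = np.repeat(col, n_src, axis=1)
    else:
        A = mrng.standard_normal((config.n_channels, n_src))
    return A / np.linalg.norm(A, axis=0, keepdims=True)


def generate(config: SimConfig, seed: int) -> tuple[EpochSet, GroundTruth]:
    """Draw one balanced two-class epoch set; deterministic in (config, seed)."""
    rng = np.random.default_rng(seed)
    A = _mixing(config)
    n = 2 * config.trials_per_class
    T = config.epoch_samples
    labels = np.repeat([1, 2], config.trials_per_class)
    perm = rng.permutation(n)
    labels = labels[perm]

    X = np.zeros((n, config.n_channels, T))
    src_list = []
    for s, ((lo, hi), a1, a2) in enumerate(config.sources):
        band = BandSpec(lo, hi)
        S = _band_source(rng, n, T, band, config.fs, config.source_order)
        amp = np.where(labels == 1, a1, a2).astype(float)
        if config.trial_jitter > 0:
            amp = amp * np.clip(
                1.0 + config.trial_jitter * rng.standard_normal(n), 0.0, None
            )
        X += amp[:, None, None] * A[:, s][None, :, None] * S[:, None, :]
        src_list.append({"band": (lo, hi), "amps": (a1, a2)})
    if config.white_std > 0:
        X += config.white_std * rng.standard_normal(X.shape)
    if config.pink_std > 0:
        X += config.pink_std * _pink_noise(rng, X.shape, config.fs)

    informative = _informative_sets(config)
    return (
        EpochSet(X, labels, config.fs),
        GroundTruth(mixing=A, sources=src_list, informative_sets=informative),
    )


def _informative_sets(config: SimConfig) -> list[int]:
    try:
        bank = make_filterbank(config.fs)
    except ValueError:
        return []
    out = []
    for s in bank:
        for (lo, hi), a1, a2 in config.sources:
            if a1 != a2 and lo < s.band.high and hi > s.band.low:
                out.append(s.index)
                break
    return out


def planted_band_power(
    config: SimConfig,
    feature_set: FeatureSetSpec | BandSpec,
    seed: int | None = None,
    n_grid: int = 4001,
) -> float:
    """Expected class-2 / class-1 power ratio inside a query band.

    The expectation integrates each source's Butterworth magnitude response
    against the query band's response over a fine frequency grid, weights by
    the squared class amplitude (jitter has the same second moment in both
    classes and cancels), and adds the white and pink noise power that falls
    in the query band. ``seed`` is accepted for interface symmetry; the value
    is analytic and does not depend on it.
    """
    band = feature_set.band if isinstance(feature_set, FeatureSetSpec) else feature_set
    f = np.linspace(0, config.fs / 2, n_grid)
    qsos = butter_sos(band, config.fs, 4)
    _, hq = signal.sosfreqz(qsos, worN=f, fs=config.fs)
    q2 = np.abs(hq) ** 4  # zero-phase application squares the magnitude

    def band_fraction(src_band: BandSpec) -> float:
        sos = butter_sos(src_band, config.fs, config.source_order)
        _, h = signal.sosfreqz(sos, worN=f, fs=config.fs)
        p = np.abs(h) ** 2  # one-pass generation filter
        total = np.trapezoid(p, f)
        inside = np.trapezoid(p * q2, f)
        return inside / total

    num = den = 0.0
    for (lo, hi), a1, a2 in config.sources:
        frac = band_fraction(BandSpec(lo, hi))
        num += a2**2 * frac  # unit-norm mixing column: total power = amp^2
        den += a1**2 * frac
    # channel noise, summed over channels
    if config.white_std > 0:
        w_psd = config.white_std**2 / (config.fs / 2)
        p_noise = np.trapezoid(np.full_like(f, w_psd) * q2, f)
        num += config.n_channels * p_noise
        den += config.n_channels * p_noise
    if config.pink_std > 0:
        shape = 1.0 / np.maximum(f, 1.0)
        shape /= np.trapezoid(shape, f)
        p_noise = config.pink_std**2 * np.trapezoid(shape * q2, f)
        num += config.n_channels * p_noise
        den += config.n_channels * p_noise
    if den == 0:
        return 1.0 if num == 0 else np.inf
    return float(num / den)


# ---------------------------------------------------------------------------
# study-condition presets

def default_config(**overrides) -> SimConfig:
    """Moderate-SNR planted-band regime (the band-recovery condition)."""
    return replace(SimConfig(), **overrides) if overrides else SimConfig()


def high_snr_config(**overrides) -> SimConfig:
    """Low-noise regime used for the near-separable classification checks."""
    cfg = SimConfig(white_std=0.1, pink_std=0.1)
    return replace(cfg, **overrides) if overrides else cfg


def chance_config(**overrides) -> SimConfig:
    """No class effect: both classes share every source amplitude."""
    cfg = SimConfig(sources=(((10.0, 14.0), 1.0, 1.0),))
    return replace(cfg, **overrides) if overrides else cfg


def ablation_config(**overrides) -> SimConfig:
    """Planted source at 4.5–6.5 Hz: inside the first 4–8 Hz sub-band but
    below the 7–30 Hz wide band, so the selected set that captures it is not
    duplicated by the wide-band sets — the non-redundant structure the
    leave-one-band-out analysis presumes."""
    cfg = SimConfig(sources=(((4.5, 6.5), 1.0, 2.0),))
    return replace(cfg, **overrides) if overrides else cfg


def spectral_contrast_config(**overrides) -> SimConfig:
    """Two sources through one shared spatial pattern with opposite class
    modulation and equal total wide-band power, so wide-band CSP sees no
    variance difference but spectral weighting (CSSP) does."""
    cfg = SimConfig(
        sources=(
            ((8.0, 12.0), 1.0, np.sqrt(2.0)),
            ((18.0, 22.0), np.sqrt(2.0), 1.0),
        ),
        shared_mixing=True,
        white_std=0.3,
        pink_std=0.3,
    )
    return replace(cfg, **overrides) if overrides else cfg
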