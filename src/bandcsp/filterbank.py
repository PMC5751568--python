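"""Filter-bank construction and Butterworth band-pass filtering.

The default bank is 12 overlapping sub-bands of 4 Hz width with 2 Hz overlap
covering 4–30 Hz (4–8, 6–10, …, 26–30 Hz) plus one wide 7–30 Hz band that is
used twice: once with CSP features and once with CSSP (delay-embedded)
features, giving 14 feature sets in total. Sub-bands use m=1 spatial-filter
pair, the wide band m=3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .epochs import EpochSet

__all__ = [
    "BandSpec",
    "FeatureSetSpec",
    "make_bands",
    "make_filterbank",
    "butter_sos",
    "bandpass",
    "band_gain",
]

#: sub-band roles
SUB_BAND = "sub_band"
WIDE_BAND = "wide_band"


@dataclass(frozen=True)
class BandSpec:
    """A pass band in Hz with its role in the bank."""

    low: float
    high: float
    role: str = SUB_BAND

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"need 0 < low < high; got ({self.low}, {self.high})")
        if self.role not in (SUB_BAND, WIDE_BAND):
            raise ValueError(f"unknown band role {self.role!r}")

    def validate_for(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise ValueError(
                f"band ({self.low}, {self.high}) Hz exceeds Nyquist for fs={fs}"
            )


@dataclass(frozen=True)
class FeatureSetSpec:
    """One feature set of the bank: a band, a feature mode and a pair count.

    ``index`` runs 1..14 in the default configuration; sets 13 and 14 are the
    wide band with CSP and CSSP features, conventionally labelled 13a and 13b.
    """

    band: BandSpec
    mode: str  # "csp" | "cssp"
    m: int
    index: int

    def __post_init__(self):
        if self.mode not in ("csp", "cssp"):
            raise ValueError(f"mode must be 'csp' or 'cssp', got {self.mode!r}")
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.mode == "cssp" and self.band.role != WIDE_BAND:
            raise ValueError("CSSP features are only used for the wide band")

    @property
    def label(self) -> str:
        if self.band.role == WIDE_BAND:
            return "13a" if self.mode == "csp" else "13b"
        return str(self.index)


def make_bands(
    f_min: float, f_max: float, width: float, overlap: float
) -> list[BandSpec]:
    """Generate overlapping sub-bands [f_min, f_min+width], stepping by
    width − overlap, up to f_max."""
    if not 0 <= overlap < width:
        raise ValueError("need 0 <= overlap < width")
    step = width - overlap
    bands = []
    low = f_min
    while low + width <= f_max + 1e-9:
        bands.append(BandSpec(low, low + width, SUB_BAND))
        low += step
    if not bands:
        raise ValueError(f"no bands fit in [{f_min}, {f_max}] at width {width}")
    return bands


def make_filterbank(
    fs: float,
    f_min: float = 4.0,
    f_max: float = 30.0,
    width: float = 4.0,
    overlap: float = 2.0,
    wide: tuple[float, float] | None = (7.0, 30.0),
    m_sub: int = 1,
    m_wide: int = 3,
    wide_modes: tuple[str, ...] = ("csp", "cssp"),
) -> list[FeatureSetSpec]:
    """Build the ordered list of feature sets.

    Defaults give the 14-set configuration: 12 sub-bands (CSP, m=1) and the
    7–30 Hz wide band with both CSP and CSSP features (m=3). Set ``wide=None``
    for sub-bands-only banks (the DFBCSP baselines).
    """
    top = max(f_max, wide[1] if wide else 0.0)
    if fs / 2 <= top:
        raise ValueError(
            f"fs={fs} too low: the bank reaches {top} Hz, need fs/2 > {top}"
        )
    sets = [
        FeatureSetSpec(band=b, mode="csp", m=m_sub, index=i + 1)
        for i, b in enumerate(make_bands(f_min, f_max, width, overlap))
    ]
    if wide is not None:
        wb = BandSpec(wide[0], wide[1], WIDE_BAND)
        for j, mode in enumerate(wide_modes):
            sets.append(
                FeatureSetSpec(band=wb, mode=mode, m=m_wide, index=len(sets) + 1)
            )
    return sets


def butter_sos(band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """Design the Butterworth band-pass (second-order sections).

    ``order`` is the design order of the analogue prototype; the resulting
    band-pass has 2*order poles.
    """
    band.validate_for(fs)
    sos = signal.butter(order, [band.low, band.high], btype="band", fs=fs, output="sos")
    if not np.isfinite(sos).all():
        raise ValueError(
            f"unstable filter design for band ({band.low}, {band.high}) at fs={fs}"
        )
    return sos


def _filtfilt(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    # zero-phase forward-backward filtering with odd-reflection padding;
    # short 2-s epochs need the explicit padding to tame edge transients
    padlen = min(x.shape[-1] - 1, 3 * (2 * sos.shape[0] + 1))
    return signal.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def bandpass(epochs: EpochSet, band: BandSpec, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth band-pass of every channel of every trial."""
    sos = butter_sos(band, epochs.fs, order)
    return EpochSet(_filtfilt(sos, epochs.data), epochs.labels, epochs.fs)


def bandpass_array(x: np.ndarray, band: BandSpec, fs: float, order: int = 4) -> np.ndarray:
    """As :func:`bandpass` but on a bare array (filtering along the last axis)."""
    return _filtfilt(butter_sos(band, fs, order), np.asarray(x, dtype=float))


def band_gain(band: BandSpec, fs: float, freq_hz: float, order: int = 4) -> float:
    """Magnitude gain of the zero-phase filter at one frequency.

    Forward-backward application squares the magnitude response, so this is
    |H(f)|^2 of the underlying one-pass design.
    """
    sos = butter_sos(band, fs, order)
    w, h = signal.sosfreqz(sos, worN=[freq_hz], fs=fs)
    return float(np.abs(h[0]) ** 2)
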