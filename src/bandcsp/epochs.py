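"""Epoched EEG container and basic preprocessing.

Trials are stored as a dense ``(n_trials, n_channels, n_samples)`` array in
microvolts with binary class labels in ``{1, 2}`` and a sampling rate in Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EpochSet", "extract_window", "common_average_reference"]


@dataclass
class EpochSet:
    """Two-class epoched EEG.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
        Epoched signal in µV. All trials share one (channels, samples) shape.
    labels : ndarray, shape (n_trials,)
        Per-trial class labels, values in ``{1, 2}``.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float = field(default=100.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be (trials, channels, samples); got shape {self.data.shape}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"labels length {len(self.labels)} != trial count {self.data.shape[0]}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite values")
        if not float(self.fs) > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        bad = set(np.unique(self.labels)) - {1, 2}
        if bad:
            raise ValueError(f"labels must be in {{1, 2}}; found {sorted(bad)}")
        self.labels = self.labels.astype(int)
        self.fs = float(self.fs)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def class_split(self) -> tuple["EpochSet", "EpochSet"]:
        """Return the class-1 and class-2 sub-sets (views of the data)."""
        out = []
        for c in (1, 2):
            mask = self.labels == c
            out.append(EpochSet(self.data[mask], self.labels[mask], self.fs))
        return out[0], out[1]

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(self.data[idx], self.labels[idx], self.fs)


def extract_window(
    continuous: np.ndarray,
    cue_sample: int,
    start_s: float,
    end_s: float,
    fs: float,
    trial: int | None = None,
) -> np.ndarray:
    """Cut a cue-aligned epoch out of a continuous recording.

    The window is half-open, ``[cue + round(start_s*fs), cue + round(end_s*fs))``
    with 0-based sample indexing, so a 0.5–2.5 s window at 100 Hz is exactly
    200 samples and at 250 Hz exactly 500.
    """
    continuous = np.asarray(continuous)
    if continuous.ndim != 2:
        raise ValueError("continuous recording must be (channels, samples)")
    if not start_s < end_s:
        raise ValueError(f"start_s ({start_s}) must be < end_s ({end_s})")
    i0 = int(cue_sample) + int(round(start_s * fs))
    i1 = int(cue_sample) + int(round(end_s * fs))
    n = continuous.shape[1]
    if i0 < 0 or i1 > n:
        which = f" (trial {trial})" if trial is not None else ""
        raise IndexError(
            f"epoch window [{i0}, {i1}) exceeds recording of {n} samples{which}"
        )
    return continuous[:, i0:i1]


def common_average_reference(epochs: EpochSet) -> EpochSet:
    """Subtract the across-channel mean from every channel at each sample.

    Idempotent; requires at least two channels (on a single channel CAR would
    zero the signal).
    """
    if epochs.n_channels < 2:
        raise ValueError("common average reference requires >= 2 channels")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return EpochSet(data, epochs.labels, epochs.fs)
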