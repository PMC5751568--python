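"""Epoch containers on disk, run configuration, and label coercion.

Two interchange formats are supported:

* a MAT-file (v5) with variables ``X`` (trials × channels × samples,
  double), ``y`` (trials × 1, values 1/2) and ``fs`` (scalar Hz) — also the
  layout used for epoched exports of the public BCI competition recordings;
* a plain-text mirror: a JSON manifest (``fs``, per-trial labels and file
  names) plus one whitespace-delimited channels × samples text file per
  trial.

Labels on disk may use {1,2}, {0,1} or {−1,+1}; anything else is rejected.
Non-{1,2} conventions are remapped (lower value → class 1) and the mapping is
logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy.io import loadmat, savemat

from .epochs import EpochSet
from .pipeline import FilterBankCSP

__all__ = ["read_epochs", "write_epochs", "RunConfig", "load_config", "ConfigError"]

log = logging.getLogger("bandcsp")


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _coerce_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).ravel()
    vals = set(np.unique(y).tolist())
    if vals <= {1, 2}:
        return y.astype(int)
    for src in ({0, 1}, {-1, 1}):
        if vals <= src:
            lo, hi = sorted(vals) if len(vals) == 2 else (min(src), max(src))
            mapping = {min(src): 1, max(src): 2}
            log.info("remapping labels %s -> {1, 2} (%s)", sorted(vals), mapping)
            return np.array([mapping[v] for v in y], dtype=int)
    raise ValueError(
        f"labels must use {{1,2}}, {{0,1}} or {{-1,+1}}; found {sorted(vals)}"
    )


def write_epochs(epochs: EpochSet, path, fmt: str = "mat") -> None:
    """Write an epoch container (``fmt`` = ``"mat"`` or ``"manifest"``)."""
    if epochs.n_trials == 0:
        raise ValueError("refusing to write an empty EpochSet")
    path = Path(path)
    if fmt == "mat":
        savemat(
            path,
            {
                "X": epochs.data,
                "y": epochs.labels.astype(float)[:, None],
                "fs": float(epochs.fs),
            },
        )
    elif fmt == "manifest":
        path.parent.mkdir(parents=True, exist_ok=True)
        stem = path.stem
        trials = []
        for i in range(epochs.n_trials):
            fname = f"{stem}_trial_{i:04d}.txt"
            np.savetxt(path.parent / fname, epochs.data[i])
            trials.append({"file": fname, "label": int(epochs.labels[i])})
        with open(path, "w") as fh:
            json.dump({"fs": epochs.fs, "trials": trials}, fh, indent=1)
    else:
        raise ValueError(f"unknown epoch format {fmt!r}")


def read_epochs(path, fmt: str | None = None) -> EpochSet:
    """Read an epoch container; format inferred from the suffix when not
    given (``.mat`` → MAT, ``.json`` → manifest)."""
    path = Path(path)
    if fmt is None:
        fmt = "mat" if path.suffix.lower() == ".mat" else "manifest"
    if fmt == "mat":
        try:
            d = loadmat(path)
        except FileNotFoundError:
            raise FileNotFoundError(f"epoch file not found: {path}") from None
        missing = [k for k in ("X", "y", "fs") if k not in d]
        if missing:
            raise ValueError(f"{path}: missing MAT variable(s) {missing}")
        X = np.asarray(d["X"], dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"{path}: X must be trials × channels × samples, got {X.shape}"
            )
        y = _coerce_labels(d["y"])
        fs = float(np.asarray(d["fs"]).ravel()[0])
        return EpochSet(X, y, fs)
    if fmt == "manifest":
        with open(path) as fh:
            man = json.load(fh)
        data, labels = [], []
        for t in man["trials"]:
            f = path.parent / t["file"]
            if not f.exists():
                raise FileNotFoundError(f"manifest trial file missing: {f}")
            data.append(np.atleast_2d(np.loadtxt(f)))
            labels.append(t["label"])
        return EpochSet(
            np.stack(data), _coerce_labels(np.array(labels)), float(man["fs"])
        )
    raise ValueError(f"unknown epoch format {fmt!r}")


@dataclass
class RunConfig:
    """Validated run settings mapping 1:1 onto :class:`FilterBankCSP`
    parameters plus windowing and CV protocol fields."""

    method: str = "proposed"
    window_start_s: float = 0.5
    window_end_s: float = 2.5
    filter_order: int = 4
    f_min: float = 4.0
    f_max: float = 30.0
    width: float = 4.0
    overlap: float = 2.0
    wide_low: float = 7.0
    wide_high: float = 30.0
    m_sub: int = 1
    m_wide: int = 3
    r: int = 4
    mi_estimator: str = "quantile"
    band_score: str = "max"
    tau: int | None = None
    tau_folds: int = 10
    fr_channel: int | None = None
    svm_C: float = 1.0
    svm_kernel: str = "linear"
    lda_eps: float = 1e-6
    csp_eps: float = 1e-8
    car: bool = True
    folds: int = 10
    repetitions: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("proposed", "csp", "cssp", "dfbcsp-fr", "dfbcsp-mi"):
            raise ConfigError(f"unknown method {self.method!r}")
        if not self.window_start_s < self.window_end_s:
            raise ConfigError("window_start_s must be < window_end_s")
        for name in ("filter_order", "m_sub", "m_wide", "r", "folds",
                     "repetitions", "tau_folds"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive integer")
        if not 0 <= self.overlap < self.width:
            raise ConfigError("need 0 <= overlap < width")
        if self.mi_estimator not in ("quantile", "parzen"):
            raise ConfigError(f"unknown mi_estimator {self.mi_estimator!r}")
        if self.band_score not in ("max", "sum"):
            raise ConfigError(f"unknown band_score {self.band_score!r}")
        if self.svm_C <= 0:
            raise ConfigError("svm_C must be > 0")

    def estimator(self, fs: float, random_state: int | None = None) -> FilterBankCSP:
        return FilterBankCSP(
            method=self.method, fs=fs, f_min=self.f_min, f_max=self.f_max,
            width=self.width, overlap=self.overlap, wide_low=self.wide_low,
            wide_high=self.wide_high, m_sub=self.m_sub, m_wide=self.m_wide,
            r=self.r, filter_order=self.filter_order,
            mi_estimator=self.mi_estimator, band_score=self.band_score,
            tau=self.tau, tau_folds=self.tau_folds, fr_channel=self.fr_channel,
            svm_C=self.svm_C, svm_kernel=self.svm_kernel,
            lda_eps=self.lda_eps, csp_eps=self.csp_eps, car=self.car,
            random_state=self.seed if random_state is None else random_state,
        )


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {unknown}")
    try:
        return RunConfig(**raw)
    except TypeError as e:
        raise ConfigError(f"{path}: {e}") from None
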