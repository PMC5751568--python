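"""End-to-end calibration and prediction.

The central object is :class:`FilterBankCSP`, a scikit-learn style binary
classifier over epoched EEG arrays ``(n_trials, n_channels, n_samples)``.
With ``method="proposed"`` calibration runs: common average reference → the
13-filter bank (12 overlapping 4 Hz sub-bands + the 7–30 Hz wide band) →
CSP (m=1 per sub-band) and CSP/CSSP (m=3, τ by inner 10-fold CV) on the wide
band → normalised log-variance features → mutual-information ranking of the
14 feature sets → top-r selection → one Fisher LDA score per selected set →
linear SVM on the fused score vector. All parameters are learned from the
training data only; prediction applies the stored transforms without any
refitting.

Baselines share the surface: ``method="csp"`` / ``"cssp"`` (wide band only,
features straight to the SVM) and ``method="dfbcsp-fr"`` / ``"dfbcsp-mi"``
(sub-band bank, Fisher-ratio on single-channel band power or MI on all-channel
features for selection, concatenated CSP features to the SVM).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .epochs import EpochSet, common_average_reference
from .filterbank import BandSpec, FeatureSetSpec, bandpass, make_filterbank
from .spatial import (
    SpatialFilterModel,
    class_covariance,
    features_from_trials,
    fit_csp,
    select_tau,
    trial_covariances,
)
from .bandselect import FeatureMatrix, rank_bands, rank_bands_fisher

__all__ = [
    "LDAProjection",
    "SVMModel",
    "fit_lda",
    "lda_scores",
    "fuse_scores",
    "fit_svm",
    "svm_decision",
    "svm_predict",
    "FilterBankCSP",
    "calibrate",
    "predict",
    "save_model",
    "load_model",
]

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# LDA score projection

@dataclass
class LDAProjection:
    """Fisher discriminant direction reducing one band's features to a score."""

    w: np.ndarray
    b: float
    feature_set: int | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float).ravel()
        if not np.isfinite(self.w).all() or not np.any(self.w):
            raise ValueError("LDA weight vector must be finite and non-zero")


def fit_lda(features: np.ndarray, labels: np.ndarray, eps: float = 1e-6,
            feature_set: int | None = None) -> LDAProjection:
    """Fisher LDA: w = S_w⁻¹ (μ2 − μ1) with a ridge on the pooled
    within-class scatter; the offset centres the score between the class
    means and the orientation makes class-2 mean scores positive."""
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    y = np.asarray(labels).ravel()
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("LDA needs exactly two classes present")
    X1, X2 = F[y == classes[0]], F[y == classes[1]]
    mu1, mu2 = X1.mean(axis=0), X2.mean(axis=0)
    d = F.shape[1]
    Sw = np.zeros((d, d))
    for Xc, mu in ((X1, mu1), (X2, mu2)):
        R = Xc - mu
        Sw += R.T @ R
    Sw /= max(len(y) - 2, 1)
    Sw += eps * (np.trace(Sw) / d + 1e-30) * np.eye(d)
    w = np.linalg.solve(Sw, mu2 - mu1)
    if not np.any(w):  # identical class means: fall back to a fixed direction
        w = np.zeros(d)
        w[0] = 1.0
    b = -float(w @ (mu1 + mu2) / 2)
    if float(w @ mu2 + b) < float(w @ mu1 + b):
        w, b = -w, -b
    return LDAProjection(w=w, b=b, feature_set=feature_set)


def lda_scores(proj: LDAProjection, features: np.ndarray) -> np.ndarray:
    F = np.asarray(features, dtype=float)
    if F.ndim == 1:
        F = F[:, None]
    return F @ proj.w + proj.b


def fuse_scores(scores_by_set: dict[int, np.ndarray],
                selected: list[int]) -> np.ndarray:
    """Concatenate per-band LDA scores in ascending feature-set-index order.

    Returns (n_trials, r); a missing band is an error.
    """
    missing = [b for b in selected if b not in scores_by_set]
    if missing:
        raise KeyError(f"missing scores for feature set(s) {missing}")
    cols = [np.asarray(scores_by_set[b], dtype=float).ravel()
            for b in sorted(selected)]
    return np.stack(cols, axis=1)


# ---------------------------------------------------------------------------
# SVM on fused scores

@dataclass
class SVMModel:
    """Trained max-margin classifier stored as bare arrays.

    Internal labels are −1 (class 1) and +1 (class 2); the decision function
    is evaluated from the stored support vectors so that a serialised and
    reloaded model predicts bit-identically.
    """

    kernel: str
    C: float
    gamma: float | None
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.kernel == "linear":
            K = X @ self.support_vectors.T
        elif self.kernel == "rbf":
            d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
            K = np.exp(-self.gamma * d2)
        else:
            raise ValueError(f"unsupported kernel {self.kernel!r}")
        return K @ self.dual_coef + self.intercept


def fit_svm(scores: np.ndarray, labels: np.ndarray, C: float = 1.0,
            kernel: str = "linear") -> SVMModel:
    """Fit the binary SVM on fused scores (labels in {1, 2})."""
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).ravel()
    if len(np.unique(y)) != 2:
        raise ValueError("SVM needs both classes present")
    y_pm = np.where(y == 2, 1, -1)
    clf = SVC(kernel=kernel, C=C, gamma="scale")
    clf.fit(X, y_pm)
    gamma = float(clf._gamma) if kernel == "rbf" else None
    return SVMModel(
        kernel=kernel,
        C=float(C),
        gamma=gamma,
        support_vectors=np.array(clf.support_vectors_, dtype=float),
        dual_coef=np.array(clf.dual_coef_[0], dtype=float),
        intercept=float(clf.intercept_[0]),
    )


def svm_decision(model: SVMModel, scores: np.ndarray) -> np.ndarray:
    return model.decision(scores)


def svm_predict(model: SVMModel, scores: np.ndarray) -> np.ndarray:
    """Predicted labels in {1, 2}; a zero decision value maps to class 1."""
    return np.where(model.decision(scores) > 0, 2, 1)


# ---------------------------------------------------------------------------
# The estimator

_METHODS = ("proposed", "csp", "cssp", "dfbcsp-fr", "dfbcsp-mi")


class FilterBankCSP(BaseEstimator, ClassifierMixin):
    """Filter-bank CSP/CSSP motor-imagery classifier with MI band selection.

    Parameters
    ----------
    method : {"proposed", "csp", "cssp", "dfbcsp-fr", "dfbcsp-mi"}
        Pipeline variant (see module docstring).
    fs : float
        Sampling rate of the input epochs in Hz.
    f_min, f_max, width, overlap : float
        Sub-band generator: bands [f, f+width] stepping by width − overlap
        from f_min while staying within f_max.
    wide_low, wide_high : float
        Wide band edges (used by "proposed", "csp" and "cssp").
    m_sub, m_wide : int
        CSP pair count for sub-bands and for the wide band.
    r : int
        Number of feature sets selected ("proposed" and the dfbcsp variants).
    filter_order : int
        Butterworth design order (zero-phase application).
    mi_estimator : {"quantile", "parzen"}
        Mutual-information estimator for band ranking.
    band_score : {"max", "sum"}
        Aggregation of per-feature MI into a band score.
    tau : int or None
        Fixed CSSP delay in samples; ``None`` searches 1..15 by inner CV.
    tau_folds : int
        Folds of the inner CV for the τ search.
    fr_channel : int or None
        Channel index whose band power drives the Fisher-ratio selection
        (required for method="dfbcsp-fr").
    svm_C : float, svm_kernel : str
        SVM hyperparameters (linear kernel by default).
    lda_eps, csp_eps : float
        Ridge strengths of the LDA scatter and the CSP composite covariance.
    car : bool
        Apply common average referencing before filtering.
    random_state : int
        Seed for the inner τ-search CV shuffling (the only randomness).

    Attributes
    ----------
    classes_ : ndarray of the two original labels (sorted).
    feature_sets_ : list of FeatureSetSpec.
    spatial_ : dict feature-set index → SpatialFilterModel.
    tau_ : selected CSSP delay (or None when no CSSP set is fitted).
    mi_per_feature_, mi_per_band_ : MI scores (selection-based methods).
    selected_ : list of selected feature-set indices.
    lda_ : dict feature-set index → LDAProjection (method="proposed").
    svm_ : SVMModel.
    audit_hashes_ : frozenset of SHA-256 digests of every training trial
        consumed during fit (leakage audit).
    """

    def __init__(
        self,
        method: str = "proposed",
        fs: float = 100.0,
        f_min: float = 4.0,
        f_max: float = 30.0,
        width: float = 4.0,
        overlap: float = 2.0,
        wide_low: float = 7.0,
        wide_high: float = 30.0,
        m_sub: int = 1,
        m_wide: int = 3,
        r: int = 4,
        filter_order: int = 4,
        mi_estimator: str = "quantile",
        band_score: str = "max",
        tau: int | None = None,
        tau_folds: int = 10,
        fr_channel: int | None = None,
        svm_C: float = 1.0,
        svm_kernel: str = "linear",
        lda_eps: float = 1e-6,
        csp_eps: float = 1e-8,
        car: bool = True,
        random_state: int = 0,
    ):
        self.method = method
        self.fs = fs
        self.f_min = f_min
        self.f_max = f_max
        self.width = width
        self.overlap = overlap
        self.wide_low = wide_low
        self.wide_high = wide_high
        self.m_sub = m_sub
        self.m_wide = m_wide
        self.r = r
        self.filter_order = filter_order
        self.mi_estimator = mi_estimator
        self.band_score = band_score
        self.tau = tau
        self.tau_folds = tau_folds
        self.fr_channel = fr_channel
        self.svm_C = svm_C
        self.svm_kernel = svm_kernel
        self.lda_eps = lda_eps
        self.csp_eps = csp_eps
        self.car = car
        self.random_state = random_state

    # -- plumbing ----------------------------------------------------------

    def _make_bank(self) -> list[FeatureSetSpec]:
        if self.method in ("dfbcsp-fr", "dfbcsp-mi"):
            return make_filterbank(
                self.fs, self.f_min, self.f_max, self.width, self.overlap,
                wide=None, m_sub=self.m_sub,
            )
        if self.method in ("csp", "cssp"):
            mode = "csp" if self.method == "csp" else "cssp"
            wb = BandSpec(self.wide_low, self.wide_high, "wide_band")
            return [FeatureSetSpec(band=wb, mode=mode, m=self.m_wide, index=1)]
        return make_filterbank(
            self.fs, self.f_min, self.f_max, self.width, self.overlap,
            wide=(self.wide_low, self.wide_high),
            m_sub=self.m_sub, m_wide=self.m_wide,
        )

    def _validate_X(self, X: np.ndarray, fitted: bool = False) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(
                f"X must be (trials, channels, samples); got shape {X.shape}"
            )
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")
        if fitted and X.shape[1] != self.n_channels_:
            raise ValueError(
                f"channel count {X.shape[1]} does not match the fitted model "
                f"({self.n_channels_})"
            )
        return X

    def _filtered(self, epochs: EpochSet, cache: dict, band: BandSpec) -> EpochSet:
        key = (band.low, band.high)
        if key not in cache:
            cache[key] = bandpass(epochs, band, self.filter_order)
        return cache[key]

    def _fit_set(self, fs_spec: FeatureSetSpec, filt: EpochSet) -> SpatialFilterModel:
        data = filt.data
        tau = None
        if fs_spec.mode == "cssp":
            tau = self.tau_
            from .spatial import delay_embed_trials

            data = delay_embed_trials(data, tau)
        covs = trial_covariances(data)
        y = filt.labels
        c1 = covs[y == 1].mean(axis=0)
        c2 = covs[y == 2].mean(axis=0)
        c1 = 0.5 * (c1 + c1.T)
        c2 = 0.5 * (c2 + c2.T)
        return fit_csp(c1, c2, fs_spec.m, eps=self.csp_eps,
                       feature_set=fs_spec, tau=tau)

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y):
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        X = self._validate_X(X)
        y = np.asarray(y).ravel()
        if len(y) != X.shape[0]:
            raise ValueError("y length does not match the trial count")
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError(
                f"exactly two classes required; got {self.classes_.tolist()}"
            )
        y12 = np.where(y == self.classes_[0], 1, 2)
        if np.bincount(y12, minlength=3)[1:].min() < 2:
            raise ValueError("need >= 2 trials per class")
        self.n_channels_ = X.shape[1]
        self.audit_hashes_ = frozenset(
            hashlib.sha256(np.ascontiguousarray(t).tobytes()).hexdigest()
            for t in X
        )
        epochs = EpochSet(X, y12, self.fs)
        if self.car:
            epochs = common_average_reference(epochs)
        self.feature_sets_ = self._make_bank()
        cache: dict = {}

        # CSSP delay: searched once per calibration on the training data only
        self.tau_ = None
        cssp_sets = [s for s in self.feature_sets_ if s.mode == "cssp"]
        if cssp_sets:
            if self.tau is not None:
                self.tau_ = int(self.tau)
            else:
                wide_filt = self._filtered(epochs, cache, cssp_sets[0].band)
                self.tau_ = select_tau(
                    wide_filt, cssp_sets[0], folds=self.tau_folds,
                    seed=self.random_state, svm_C=self.svm_C, prefiltered=True,
                )

        self.spatial_ = {}
        feats: dict[int, np.ndarray] = {}
        for s in self.feature_sets_:
            filt = self._filtered(epochs, cache, s.band)
            model = self._fit_set(s, filt)
            self.spatial_[s.index] = model
            feats[s.index] = features_from_trials(model, filt.data)

        self.mi_per_feature_ = None
        self.mi_per_band_ = None
        self.lda_ = {}
        if self.method in ("proposed", "dfbcsp-mi"):
            cols, owner = [], []
            for s in self.feature_sets_:
                cols.append(feats[s.index])
                owner.extend([s.index] * feats[s.index].shape[1])
            FM = FeatureMatrix(np.concatenate(cols, axis=1), np.array(owner))
            self.selected_, scores = rank_bands(
                FM, y12, self.r, estimator=self.mi_estimator,
                band_score=self.band_score,
            )
            self.mi_per_feature_ = scores.per_feature
            self.mi_per_band_ = scores.per_band
        elif self.method == "dfbcsp-fr":
            if self.fr_channel is None:
                raise ValueError(
                    "method='dfbcsp-fr' requires fr_channel (the single channel "
                    "whose band power drives the Fisher-ratio selection)"
                )
            bp = np.stack(
                [
                    self._filtered(epochs, cache, s.band)
                    .data[:, self.fr_channel, :]
                    .var(axis=1)
                    for s in self.feature_sets_
                ],
                axis=1,
            )
            self.selected_ = rank_bands_fisher(bp, y12, self.r)
        else:  # csp / cssp: the single wide-band set
            self.selected_ = [self.feature_sets_[0].index]

        if self.method == "proposed":
            score_cols = {}
            for b in self.selected_:
                self.lda_[b] = fit_lda(feats[b], y12, eps=self.lda_eps,
                                       feature_set=b)
                score_cols[b] = lda_scores(self.lda_[b], feats[b])
            train_scores = fuse_scores(score_cols, self.selected_)
        else:
            train_scores = np.concatenate(
                [feats[b] for b in sorted(self.selected_)], axis=1
            )
        self.svm_ = fit_svm(train_scores, y12, C=self.svm_C,
                            kernel=self.svm_kernel)
        return self

    def _transform_scores(self, X: np.ndarray) -> np.ndarray:
        """Apply the stored preprocessing, spatial filters and (for the
        proposed method) LDA projections; returns the SVM input matrix."""
        epochs = EpochSet(X, np.ones(X.shape[0], dtype=int), self.fs)
        # placeholder labels: preprocessing is label-free
        if self.car:
            epochs = common_average_reference(epochs)
        cache: dict = {}
        by_index = {s.index: s for s in self.feature_sets_}
        feats = {}
        for b in self.selected_:
            s = by_index[b]
            filt = self._filtered(epochs, cache, s.band)
            feats[b] = features_from_trials(self.spatial_[b], filt.data)
        if self.method == "proposed":
            score_cols = {b: lda_scores(self.lda_[b], feats[b])
                          for b in self.selected_}
            return fuse_scores(score_cols, self.selected_)
        return np.concatenate([feats[b] for b in sorted(self.selected_)], axis=1)

    def decision_function(self, X):
        self._check_fitted()
        X = self._validate_X(X, fitted=True)
        if X.shape[0] == 0:
            return np.zeros(0)
        return self.svm_.decision(self._transform_scores(X))

    def predict(self, X):
        d = self.decision_function(np.asarray(X, dtype=float))
        y12 = np.where(d > 0, 2, 1)
        return self.classes_[y12 - 1]

    def _check_fitted(self):
        if not hasattr(self, "svm_"):
            raise AttributeError("this FilterBankCSP instance is not fitted yet")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        """Model bundle as a JSON-serialisable dict (versioned schema)."""
        self._check_fitted()

        def fs_dict(s: FeatureSetSpec) -> dict:
            return {
                "low": s.band.low, "high": s.band.high, "role": s.band.role,
                "mode": s.mode, "m": s.m, "index": s.index,
            }

        return {
            "schema_version": SCHEMA_VERSION,
            "params": {k: v for k, v in self.get_params().items()},
            "classes": np.asarray(self.classes_).tolist(),
            "n_channels": int(self.n_channels_),
            "feature_sets": [fs_dict(s) for s in self.feature_sets_],
            "tau": self.tau_,
            "selected": list(self.selected_),
            "mi_per_band": (
                {str(k): v for k, v in self.mi_per_band_.items()}
                if self.mi_per_band_ is not None else None
            ),
            "spatial": {
                str(i): {"W": m.W.tolist(), "m": m.m, "tau": m.tau}
                for i, m in self.spatial_.items()
            },
            "lda": {
                str(i): {"w": p.w.tolist(), "b": p.b}
                for i, p in self.lda_.items()
            },
            "svm": {
                "kernel": self.svm_.kernel,
                "C": self.svm_.C,
                "gamma": self.svm_.gamma,
                "support_vectors": self.svm_.support_vectors.tolist(),
                "dual_coef": self.svm_.dual_coef.tolist(),
                "intercept": self.svm_.intercept,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FilterBankCSP":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported model bundle schema {d.get('schema_version')!r}"
            )
        est = cls(**d["params"])
        est.classes_ = np.asarray(d["classes"])
        est.n_channels_ = int(d["n_channels"])
        by_index = {}
        sets = []
        for sd in d["feature_sets"]:
            s = FeatureSetSpec(
                band=BandSpec(sd["low"], sd["high"], sd["role"]),
                mode=sd["mode"], m=sd["m"], index=sd["index"],
            )
            sets.append(s)
            by_index[s.index] = s
        est.feature_sets_ = sets
        est.tau_ = d["tau"]
        est.selected_ = list(d["selected"])
        est.mi_per_band_ = (
            {int(k): v for k, v in d["mi_per_band"].items()}
            if d.get("mi_per_band") else None
        )
        est.mi_per_feature_ = None
        est.spatial_ = {
            int(i): SpatialFilterModel(
                W=np.array(sd["W"], dtype=float), m=sd["m"], tau=sd["tau"],
                feature_set=by_index.get(int(i)),
            )
            for i, sd in d["spatial"].items()
        }
        est.lda_ = {
            int(i): LDAProjection(w=np.array(pd["w"]), b=pd["b"], feature_set=int(i))
            for i, pd in d["lda"].items()
        }
        sv = d["svm"]
        est.svm_ = SVMModel(
            kernel=sv["kernel"], C=sv["C"], gamma=sv["gamma"],
            support_vectors=np.array(sv["support_vectors"], dtype=float),
            dual_coef=np.array(sv["dual_coef"], dtype=float),
            intercept=sv["intercept"],
        )
        est.audit_hashes_ = frozenset()
        return est


def save_model(model: FilterBankCSP, path) -> None:
    """Write the model bundle (single JSON file, versioned schema)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_model(path) -> FilterBankCSP:
    with open(path) as fh:
        return FilterBankCSP.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# thin functional wrappers

def calibrate(train: EpochSet, config: FilterBankCSP | dict | None = None,
              **kwargs) -> FilterBankCSP:
    """Fit a :class:`FilterBankCSP` on an :class:`EpochSet`.

    ``config`` may be an unfitted estimator (cloned settings) or a dict of
    constructor parameters; keyword arguments override either.
    """
    if isinstance(config, FilterBankCSP):
        params = config.get_params()
    elif isinstance(config, dict):
        params = dict(config)
    else:
        params = {}
    params.update(kwargs)
    params.setdefault("fs", train.fs)
    est = FilterBankCSP(**params)
    est.fit(train.data, train.labels)
    return est


def predict(model: FilterBankCSP, test: EpochSet) -> np.ndarray:
    """Predict labels for an :class:`EpochSet` with a calibrated model."""
    if test.fs != model.fs:
        raise ValueError(f"test fs {test.fs} != model fs {model.fs}")
    return model.predict(test.data)
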