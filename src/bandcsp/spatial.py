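"""CSP and CSSP spatial filters and log-variance features.

CSP solves the generalised eigenproblem C1 w = λ (C1 + C2) w on the two
class-average covariance matrices of band-pass filtered epochs; the spatial
filter keeps the m eigenvectors with the largest and the m with the smallest
λ. CSSP is CSP applied to the signal stacked with a τ-sample delayed copy of
itself, which gives every channel an implicit two-tap FIR spectral filter; τ
is picked from 1..15 samples by stratified 10-fold cross-validation of the
single-band pipeline.

The per-trial feature is the log of each projected component's variance
normalised by the summed variance of all 2m retained components, so the
exponentials of one trial's features always sum to 1 and the features are
invariant to global amplitude scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochSet
from .filterbank import FeatureSetSpec, bandpass

__all__ = [
    "SpatialFilterModel",
    "class_covariance",
    "trial_covariances",
    "fit_csp",
    "csp_features",
    "features_from_trials",
    "delay_embed",
    "delay_embed_set",
    "select_tau",
]

TAU_MIN, TAU_MAX = 1, 15


@dataclass
class SpatialFilterModel:
    """A fitted spatial filter: W has one column per retained component (2m)."""

    W: np.ndarray
    m: int
    tau: int | None = None
    feature_set: FeatureSetSpec | None = None
    eigvals: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape[1] != 2 * self.m:
            raise ValueError(
                f"W must have 2m={2 * self.m} columns, got {self.W.shape[1]}"
            )
        if not np.isfinite(self.W).all():
            raise ValueError("spatial filter contains non-finite entries")


def trial_covariances(data: np.ndarray) -> np.ndarray:
    """Per-trial trace-normalised covariances X Xᵀ / trace(X Xᵀ).

    ``data`` is (trials, channels, samples); returns (trials, C, C).
    """
    cov = np.einsum("nct,ndt->ncd", data, data)
    tr = np.trace(cov, axis1=1, axis2=2)
    if np.any(tr <= 0):
        bad = int(np.nonzero(tr <= 0)[0][0])
        raise ValueError(f"trial {bad} has zero signal power (zero-trace covariance)")
    return cov / tr[:, None, None]


def class_covariance(epochs_of_one_class: EpochSet) -> np.ndarray:
    """Mean over trials of the per-trial normalised covariance.

    Symmetric positive semi-definite with unit trace.
    """
    if epochs_of_one_class.n_trials < 1:
        raise ValueError("need at least one trial")
    cov = trial_covariances(epochs_of_one_class.data).mean(axis=0)
    return 0.5 * (cov + cov.T)


def fit_csp(
    C1: np.ndarray,
    C2: np.ndarray,
    m: int,
    eps: float = 1e-8,
    feature_set: FeatureSetSpec | None = None,
    tau: int | None = None,
) -> SpatialFilterModel:
    """Fit the CSP filter from two class covariance matrices.

    Solves C1 w = λ (C1 + C2) w with a small ridge on the composite for
    conditioning, sorts eigenvectors by λ descending (stable under ties) and
    keeps the first m and last m columns. Columns satisfy wᵀ(C1+C2)w = 1 up to
    the ridge and are sign-fixed so the largest-magnitude entry is positive.
    """
    C1 = np.asarray(C1, dtype=float)
    C2 = np.asarray(C2, dtype=float)
    n = C1.shape[0]
    if C1.shape != C2.shape or C1.shape != (n, n):
        raise ValueError("C1 and C2 must be square matrices of the same size")
    if 2 * m > n:
        raise ValueError(f"2m={2 * m} exceeds the {n} available components")
    comp = C1 + C2
    ridge = eps * np.trace(comp) / n
    comp_r = comp + ridge * np.eye(n)
    lam, V = linalg.eigh(C1, comp_r)
    if not (np.isfinite(lam).all() and np.isfinite(V).all()):
        raise np.linalg.LinAlgError("non-finite generalised eigen solution")
    order = np.argsort(-lam, kind="stable")
    lam, V = lam[order], V[:, order]
    W = np.concatenate([V[:, :m], V[:, n - m :]], axis=1)
    keep_lam = np.concatenate([lam[:m], lam[n - m :]])
    # rescale against the unridged composite so wᵀ(C1+C2)w = 1 exactly;
    # directions in a numerically null space of the composite keep the
    # ridged normalisation instead (rank-deficient narrow-band covariances)
    norms = np.einsum("cj,cd,dj->j", W, comp, W)
    ridged = np.einsum("cj,cd,dj->j", W, comp_r, W)
    safe = norms > 1e-10 * ridged
    W = W / np.sqrt(np.where(safe, norms, ridged))
    # sign convention: largest-magnitude entry of each column positive
    signs = np.sign(W[np.argmax(np.abs(W), axis=0), np.arange(2 * m)])
    signs[signs == 0] = 1.0
    W = W * signs
    return SpatialFilterModel(W=W, m=m, tau=tau, feature_set=feature_set, eigvals=keep_lam)


def csp_features(model: SpatialFilterModel, X: np.ndarray) -> np.ndarray:
    """Normalised log-variance feature vector of one (already filtered) epoch."""
    return features_from_trials(model, X[None, ...])[0]


def features_from_trials(model: SpatialFilterModel, data: np.ndarray) -> np.ndarray:
    """Feature matrix (trials × 2m) for a stack of filtered epochs.

    Applies the delay embedding first when the model carries a CSSP τ.
    """
    data = np.asarray(data, dtype=float)
    if model.tau is not None and data.shape[1] * 2 == model.W.shape[0]:
        data = delay_embed_trials(data, model.tau)
    if data.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"epoch has {data.shape[1]} rows but the filter expects {model.W.shape[0]}"
        )
    Z = np.einsum("cf,nct->nft", model.W, data)
    # biased (divide-by-T) variance; the normalisation cancels the divisor
    v = Z.var(axis=2)
    tot = v.sum(axis=1, keepdims=True)
    if np.any(tot <= 0):
        raise ValueError("all projected variances are zero for some trial")
    return np.log(v / tot)


def delay_embed(X: np.ndarray, tau: int) -> np.ndarray:
    """Stack a signal with its τ-sample delayed copy, trimmed to common support.

    Row block 1 is X[:, τ:], row block 2 is X[:, :−τ]; output is
    (2C, T − τ).
    """
    if not TAU_MIN <= tau <= TAU_MAX:
        raise ValueError(f"tau must be in [{TAU_MIN}, {TAU_MAX}], got {tau}")
    X = np.asarray(X)
    if X.shape[-1] <= tau:
        raise ValueError("epoch shorter than the delay")
    return np.concatenate([X[..., :, tau:], X[..., :, :-tau]], axis=-2)


def delay_embed_trials(data: np.ndarray, tau: int) -> np.ndarray:
    """Delay-embed a (trials, C, T) stack into (trials, 2C, T−τ)."""
    return delay_embed(data, tau)


def delay_embed_set(epochs: EpochSet, tau: int) -> EpochSet:
    return EpochSet(delay_embed_trials(epochs.data, tau), epochs.labels, epochs.fs)


def select_tau(
    train: EpochSet,
    feature_set: FeatureSetSpec,
    taus=range(TAU_MIN, TAU_MAX + 1),
    folds: int = 10,
    seed: int = 0,
    filter_order: int = 4,
    svm_C: float = 1.0,
    prefiltered: bool = False,
) -> int:
    """Pick the CSSP delay by stratified k-fold CV of the single-band chain.

    For each candidate τ the full single-band pipeline (delay embedding → CSP
    → log-variance features → LDA score → linear SVM) is cross-validated on
    the training set; the τ with the highest mean validation accuracy wins,
    ties going to the smaller τ. Deterministic given ``seed``.

    Set ``prefiltered=True`` when ``train`` is already band-pass filtered to
    the feature set's band.
    """
    from .pipeline import fit_lda, lda_scores, fit_svm, svm_predict  # cycle guard

    counts = np.bincount(train.labels, minlength=3)[1:]
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} trials per class for stratified {folds}-fold CV; "
            f"got {counts.tolist()}"
        )
    filt = train if prefiltered else bandpass(train, feature_set.band, filter_order)
    y = filt.labels
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    splits = list(skf.split(np.zeros(len(y)), y))
    best_tau, best_acc = None, -np.inf
    for tau in taus:
        emb = delay_embed_trials(filt.data, int(tau))
        covs = trial_covariances(emb)
        accs = []
        for tr_idx, va_idx in splits:
            ytr = y[tr_idx]
            c1 = covs[tr_idx][ytr == 1].mean(axis=0)
            c2 = covs[tr_idx][ytr == 2].mean(axis=0)
            model = fit_csp(c1, c2, feature_set.m, tau=int(tau))
            f_tr = features_from_trials(model, emb[tr_idx])
            f_va = features_from_trials(model, emb[va_idx])
            lda = fit_lda(f_tr, ytr)
            svm = fit_svm(lda_scores(lda, f_tr)[:, None], ytr, C=svm_C)
            pred = svm_predict(svm, lda_scores(lda, f_va)[:, None])
            accs.append(np.mean(pred == y[va_idx]))
        acc = float(np.mean(accs))
        if acc > best_acc + 1e-12:
            best_acc, best_tau = acc, int(tau)
    return best_tau
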