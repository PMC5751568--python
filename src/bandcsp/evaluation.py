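"""Cross-validated evaluation: misclassification rate, Cohen's κ, the
band-count sweep and the leave-one-band-out redundancy analysis.

The headline protocol is 10×10-fold cross-validation: ten repetitions of
stratified 10-fold CV, reshuffled per repetition, with the *entire*
calibration (filter bank, spatial filters, τ search, band selection, LDA,
SVM) refitted inside every training fold. Mean and standard deviation are
taken over all folds × repetitions fold-level values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochSet
from .pipeline import FilterBankCSP, fit_svm, fuse_scores, lda_scores, svm_predict

__all__ = [
    "misclassification_rate",
    "cohen_kappa",
    "EvaluationResult",
    "cross_validate",
    "band_ablation",
    "band_count_sweep",
    "selected_band_frequencies",
]


def misclassification_rate(predicted, actual) -> float:
    """Percentage of incorrectly classified trials (0–100)."""
    p = np.asarray(predicted).ravel()
    a = np.asarray(actual).ravel()
    if len(p) == 0:
        raise ValueError("empty input")
    if len(p) != len(a):
        raise ValueError("predicted and actual lengths differ")
    return 100.0 * float(np.mean(p != a))


def cohen_kappa(predicted, actual) -> float:
    """Chance-corrected agreement κ = (p_a − p_e) / (1 − p_e).

    p_a is the observed agreement and p_e the expected chance agreement from
    the marginal label frequencies. When p_e = 1 (both raters constant and
    equal marginals) κ is defined as 1 for perfect agreement and 0 otherwise.
    """
    p = np.asarray(predicted).ravel()
    a = np.asarray(actual).ravel()
    if len(p) == 0:
        raise ValueError("empty input")
    if len(p) != len(a):
        raise ValueError("predicted and actual lengths differ")
    labels = np.unique(np.concatenate([p, a]))
    p_a = float(np.mean(p == a))
    p_e = 0.0
    for c in labels:
        p_e += float(np.mean(p == c)) * float(np.mean(a == c))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_a >= 1.0 - 1e-15 else 0.0
    return (p_a - p_e) / (1.0 - p_e)


@dataclass
class EvaluationResult:
    """Aggregate and per-fold cross-validation outcomes.

    ``per_fold`` has one row per (repetition, fold) with the fold error (%),
    κ and the feature-set labels selected in that fold's calibration.
    """

    error_mean: float
    error_std: float
    kappa_mean: float
    kappa_std: float
    per_fold: pd.DataFrame

    def summary(self) -> str:
        return (
            f"error {self.error_mean:.2f} ± {self.error_std:.2f} %, "
            f"kappa {self.kappa_mean:.3f} ± {self.kappa_std:.3f} "
            f"({len(self.per_fold)} folds)"
        )


def _fold_seed(seed: int, rep: int) -> int:
    # one master seed; repetition k shuffles with seed + k
    return (seed + rep) % (2**31)


def cross_validate(
    data: EpochSet,
    estimator: FilterBankCSP | None = None,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
    **estimator_kwargs,
) -> EvaluationResult:
    """Repeated stratified k-fold CV with full per-fold recalibration."""
    est0 = estimator if estimator is not None else FilterBankCSP(fs=data.fs)
    if estimator_kwargs:
        est0 = clone(est0).set_params(**estimator_kwargs)
    counts = np.bincount(data.labels, minlength=3)[1:]
    if counts.min() < folds:
        raise ValueError(
            f"need >= {folds} trials per class for stratified {folds}-fold CV"
        )
    rows = []
    for rep in range(repetitions):
        rs = _fold_seed(seed, rep)
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        for fold, (tr, te) in enumerate(
            skf.split(np.zeros(data.n_trials), data.labels)
        ):
            est = clone(est0)
            est.set_params(random_state=rs)
            est.fit(data.data[tr], data.labels[tr])
            pred = est.predict(data.data[te])
            truth = data.labels[te]
            rows.append(
                {
                    "repetition": rep,
                    "fold": fold,
                    "error": misclassification_rate(pred, truth),
                    "kappa": cohen_kappa(pred, truth),
                    "selected": ",".join(
                        _set_label(est, b) for b in sorted(est.selected_)
                    ),
                }
            )
    per_fold = pd.DataFrame(rows)
    return EvaluationResult(
        error_mean=float(per_fold["error"].mean()),
        error_std=float(per_fold["error"].std(ddof=1)),
        kappa_mean=float(per_fold["kappa"].mean()),
        kappa_std=float(per_fold["kappa"].std(ddof=1)),
        per_fold=per_fold,
    )


def _set_label(est: FilterBankCSP, index: int) -> str:
    for s in est.feature_sets_:
        if s.index == index:
            return s.label
    return str(index)


def selected_band_frequencies(result: EvaluationResult) -> pd.Series:
    """How often each feature-set label was selected across folds (for the
    'mostly selected bands' style of summary)."""
    counts: dict[str, int] = {}
    for cell in result.per_fold["selected"]:
        for lab in cell.split(","):
            if lab:
                counts[lab] = counts.get(lab, 0) + 1
    return pd.Series(counts).sort_values(ascending=False)


@dataclass
class AblationResult:
    full_error: float
    ablations: list  # (feature-set label, error with that set removed)


def band_ablation(
    train: EpochSet,
    test: EpochSet,
    estimator: FilterBankCSP | None = None,
    **estimator_kwargs,
) -> AblationResult:
    """Leave-one-band-out redundancy analysis.

    A model is calibrated on ``train``; then for each selected feature set
    the score-fusion stage and the SVM are refitted without that set
    (spatial filters, LDA projections and the selection itself unchanged)
    and the test error of the reduced model is measured.
    """
    est0 = estimator if estimator is not None else FilterBankCSP(fs=train.fs)
    est = clone(est0)
    if estimator_kwargs:
        est.set_params(**estimator_kwargs)
    est.fit(train.data, train.labels)
    if len(est.selected_) < 2:
        raise ValueError("nothing to ablate: fewer than 2 selected bands")
    full_pred = est.predict(test.data)
    full_err = misclassification_rate(full_pred, test.labels)

    # per-set features/scores for train and test, computed once
    y12 = np.where(np.asarray(train.labels) == est.classes_[0], 1, 2)
    tr_cols = _per_set_columns(est, train.data)
    te_cols = _per_set_columns(est, test.data)
    out = []
    for b in est.selected_:
        keep = [k for k in est.selected_ if k != b]
        tr = _stack_columns(est, tr_cols, keep)
        te = _stack_columns(est, te_cols, keep)
        svm = fit_svm(tr, y12, C=est.svm_C, kernel=est.svm_kernel)
        pred12 = svm_predict(svm, te)
        pred = est.classes_[pred12 - 1]
        out.append((_set_label(est, b), misclassification_rate(pred, test.labels)))
    return AblationResult(full_error=full_err, ablations=out)


def _per_set_columns(est: FilterBankCSP, X: np.ndarray) -> dict[int, np.ndarray]:
    """Per-selected-set SVM input columns: LDA scores for the proposed
    method, raw feature blocks otherwise."""
    from .epochs import common_average_reference
    from .spatial import features_from_trials

    epochs = EpochSet(np.asarray(X, dtype=float),
                      np.ones(np.asarray(X).shape[0], dtype=int), est.fs)
    if est.car:
        epochs = common_average_reference(epochs)
    cache: dict = {}
    by_index = {s.index: s for s in est.feature_sets_}
    cols = {}
    for b in est.selected_:
        filt = est._filtered(epochs, cache, by_index[b].band)
        feats = features_from_trials(est.spatial_[b], filt.data)
        if est.method == "proposed":
            cols[b] = lda_scores(est.lda_[b], feats)[:, None]
        else:
            cols[b] = feats
    return cols


def _stack_columns(est: FilterBankCSP, cols: dict[int, np.ndarray],
                   keep: list[int]) -> np.ndarray:
    return np.concatenate([cols[b] for b in sorted(keep)], axis=1)


def band_count_sweep(
    data: EpochSet,
    estimator: FilterBankCSP | None = None,
    r_values=range(1, 15),
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated error as a function of the number of selected bands."""
    est0 = estimator if estimator is not None else FilterBankCSP(fs=data.fs)
    rows = []
    for r in r_values:
        res = cross_validate(
            data, clone(est0).set_params(r=int(r)),
            folds=folds, repetitions=repetitions, seed=seed,
        )
        rows.append({"r": int(r), "error_mean": res.error_mean,
                     "error_std": res.error_std, "kappa_mean": res.kappa_mean})
    return pd.DataFrame(rows)
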