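# Methods

## Problem and model

Two-class motor-imagery brain–computer interfaces decode which of two
imagined movements a subject performs from short epochs of multichannel EEG.
The discriminative signal is a class-dependent modulation of band power
(event-related desynchronisation/synchronisation) whose frequency band is
subject-specific, which makes the choice of filter band the main design
problem for common-spatial-pattern (CSP) feature extraction.

The classifier implemented here addresses that with a discriminative filter
bank. Each 2-s epoch X ∈ R^{C×T} is common-average referenced and passed
through 13 zero-phase Butterworth band-pass filters: 12 overlapping sub-bands
of 4 Hz width with 2 Hz overlap covering 4–30 Hz (4–8, 6–10, …, 26–30 Hz) and
one wide 7–30 Hz band. The wide band is used twice — once with CSP features
and once with CSSP features (the epoch stacked with a τ-sample delayed copy
of itself, which equips every channel with an implicit two-tap FIR spectral
filter) — giving 14 feature sets.

Per feature set, CSP solves the generalised eigenproblem

    C1 w = λ (C1 + C2) w,

where C_c is the class-average of per-trial trace-normalised covariances
X Xᵀ / tr(X Xᵀ). The m eigenvectors with the largest and the m with the
smallest λ form the spatial filter W (m = 1 for sub-bands, m = 3 for the
wide band). The trial feature vector is the normalised log variance

    f_i = log( var(Z_i) / Σ_{j=1}^{2m} var(Z_j) ),   Z = Wᵀ X,

so Σ_i exp(f_i) = 1 and the features are invariant to global amplitude
scaling.

Band selection concatenates the features of all 14 sets into a trial ×
feature matrix, estimates the mutual information (MI, in bits) between each
feature column and the class label, takes the per-set maximum to form a
14-vector of band scores, and keeps the r = 4 highest-scoring sets (ties to
the lower set index). Each selected set's features are reduced to a single
Fisher-LDA score; the r scores are concatenated in ascending set order and
classified with a linear soft-margin SVM (C = 1). Calibration uses training
trials only; prediction applies the stored filters, projections and SVM
without refitting.

Baselines sharing this surface: wide-band CSP and CSSP (m = 3, features
straight to the SVM), and the discriminative filter-bank variants that
select sub-bands either by the Fisher ratio of a single channel's band power
(`dfbcsp-fr`; the channel is a required configuration choice) or by MI on
all-channel features (`dfbcsp-mi`), then feed the selected sets'
concatenated CSP features to the SVM.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| sub-band generator | 4–30 Hz, width 4, overlap 2 | covers θ/µ/β rhythms; parametric so baseline banks (e.g. 6–40 Hz) are expressible |
| wide band | 7–30 Hz | µ+β range; captures broadband class structure the narrow bands split |
| m (pairs) | 1 sub-band, 3 wide | narrow bands are near rank-1 after filtering; the wide band supports more components |
| Butterworth order | 4 | standard in CSP work; applied forward–backward (zero phase) so band power is undistorted; odd-reflection padding tames 200-sample-epoch edges |
| τ grid | 1..15 samples | CSSP delay searched by stratified 10-fold CV of the single-band chain (delay-embed → CSP → LDA → SVM), ties to the smaller τ |
| r | 4 | number of selected sets; configurable 1..14 |
| MI bins | ⌈log₂N⌉+1 equal-frequency | Sturges' count keeps the plug-in chance bias (bins−1)/(2N ln2) ≈ 0.03 bits at N = 200 while staying deterministic and monotone-invariant; a Parzen-window estimator is available via `mi_estimator="parzen"` |
| band score | max over columns | per-set maximum MI; `band_score="sum"` as alternative |
| SVM | linear, C = 1 | 4-D fused scores rarely benefit from kernels; keeps calibration deterministic |
| LDA ridge | 1e−6·tr(S_w)/d | 2-D per-band features with few trials can have singular scatter |
| CSP ridge | 1e−8·tr(C1+C2)/C | rank-deficient narrow-band covariances; retained columns are rescaled against the unridged composite so wᵀ(C1+C2)w = 1 exactly wherever that form is numerically positive |

Class labels are {1, 2} externally (files also accept {0,1} and {−1,+1},
remapped with a logged mapping) and {−1, +1} inside the SVM.

## Evaluation protocol

Misclassification rate is 100·(#mismatches)/N; Cohen's κ is
(p_a − p_e)/(1 − p_e) with p_e from the marginal frequencies (for balanced
truth and predictions κ = 1 − 2·error exactly). The headline protocol is
10×10-fold cross-validation: ten repetitions of stratified 10-fold CV,
reshuffled per repetition (repetition k shuffles with master seed + k), with
the entire calibration — including τ search and band selection — refitted
inside every training fold so no test information leaks. Mean ± std are
computed over all 100 fold-level values. Supporting analyses: a top-r sweep
(CV error as a function of r; r = 14 is the no-selection pipeline) and a
leave-one-band-out redundancy analysis (refit score fusion + SVM on the
remaining r−1 sets, spatial filters and selection unchanged).

Calibration additionally records a SHA-256 fingerprint of every trial array
it consumed; the leakage test asserts these are disjoint from the test
trials' fingerprints.

## Synthetic data: what it emulates and what it does not

The generator emulates the epoched shape of public motor-imagery recordings
at desk scale: 100 Hz sampling, 200-sample (0.5–2.5 s cue-aligned) epochs,
8 channels, 100 trials per class. Each source is band-limited Gaussian noise
(unit variance after filtering, generated with 2-s padding so the filter is
in steady state) scaled by a class amplitude and 10 % per-trial jitter,
mixed through a fixed unit-norm-column matrix drawn once from
`mixing_seed`; channel noise is white plus 1/f-shaped pink noise (flat below
1 Hz), both std 1.0.

The background level is the one genuinely free choice and was set on
physiological grounds: real sensorimotor rhythms ride on background activity
of comparable in-band power. This matters methodologically — with a
near-silent background a pure amplitude modulation drives the
trace-normalised covariances of the exactly-matching band toward rank-1
equality across classes and saturates the normalised log-variance feature,
so discriminability migrates to half-overlapping neighbour bands; an
order-1 in-band background keeps the matching band the most informative, as
it is in practice. Presets: `high_snr_config` (white/pink 0.1, used for the
near-separable classification checks), `chance_config` (no class effect),
`ablation_config` (a 4.5–6.5 Hz source inside the first sub-band but below
the wide band, giving the non-redundant selection the leave-one-band-out
analysis presumes), and `spectral_contrast_config` (two sources through one
shared spatial pattern with opposite class modulation and equal total
wide-band power — invisible to wide-band CSP, resolvable by CSSP's spectral
weighting).

`planted_band_power` returns the analytic class-2/class-1 expected power
ratio inside a query band by integrating the source filters' magnitude
responses against the query band's zero-phase response (jitter has equal
second moments in both classes and cancels; amplitudes enter squared, so
amplitudes (1, 2) give a ratio of 4 in a fully covering band without noise).

What the generator does **not** model: volume-conduction head geometry,
within-trial ERD/ERS time courses, artifacts (EOG/EMG), non-stationarity
across a session, and realistic channel covariance of the background.
Passing the synthetic checks therefore demonstrates correctness of the
machinery (band selection finds planted structure, chance data yields chance
performance, CSSP exploits spectral structure CSP cannot) — not expected
accuracy on any real recording.

## Numerical choices and degenerate inputs

Eigen-sorting is stable under ties; each filter column's sign is fixed so
its largest-magnitude entry is positive (features are sign-invariant but
serialisation is reproducible). Variances use the biased (divide-by-T)
estimator — the normalisation cancels the divisor. MI uses log base 2 with
0·log 0 = 0; features with no more distinct values than bins are treated as
categorical, which makes discrete inputs exact. Constant features score MI
0; a constant feature with distinct class means is a Fisher-ratio error
unless the means also agree (then 0). Zero-power trials, single-class
labels, single-channel CAR, out-of-Nyquist bands, and channel-count
mismatches at prediction all raise descriptive errors. The model bundle is
a single versioned JSON file; prediction always evaluates the decision
function from the stored support-vector arrays, so a reloaded model predicts
bit-identically.

Problem sizes throughout (100 trials/class, 20 seeds for recovery, 10 for
the ablation majority, 10×10 folds for the chance control) are the package's
desk-scale study conditions: large enough for stable statistics, small
enough that the whole suite and the acceptance script each run in minutes on
one core.

## Known limitations

* Binary classification only; no multiclass extension or online operation.
* The τ grid is re-searched inside every training fold by default (no
  leakage); fixing τ across folds is possible via the `tau` parameter.
* The Parzen MI estimator is provided but not used by default; its bandwidth
  (Silverman) is not tuned.
* Reproducing published benchmark tables requires the external BCI
  competition recordings, which are deliberately outside the tested core;
  `read_epochs` accepts epoched MAT exports of those datasets.
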