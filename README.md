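# bandcsp

Discriminative filter-bank CSP/CSSP with mutual-information band selection
for two-class motor-imagery EEG.

Motor-imagery brain–computer interfaces decode imagined movements from
band-power changes in multichannel EEG, but the informative frequency band is
subject-specific. `bandcsp` implements a filter-bank solution: epochs are
common-average referenced and decomposed by 12 overlapping 4 Hz sub-bands
(4–30 Hz, 2 Hz overlap) plus a 7–30 Hz wide band; common spatial patterns
(CSP, and on the wide band also the delay-embedded CSSP variant) extract
normalised log-variance features

    f_i = log( var(Z_i) / Σ_j var(Z_j) ),   Z = Wᵀ X,

with W from the generalised eigenproblem C1 w = λ(C1+C2) w on the class
covariances; the mutual information I(feature; class) ranks the 14 feature
sets and the top 4 are kept; each kept set is reduced to one Fisher-LDA
score and a linear SVM classifies the fused score vector. Wide-band CSP/CSSP
and Fisher-ratio/MI filter-bank baselines, Cohen's κ and 10×10-fold
cross-validation, a leave-one-band-out redundancy analysis, a top-r band
sweep and a synthetic EEG generator are included, so the whole pipeline is
testable without downloading any recordings.

Intended users: BCI/EEG researchers comparing band-selection strategies, and
anyone who needs a scikit-learn-compatible CSP filter-bank classifier for
epoched two-class EEG.

## Worked example

```python
import numpy as np
from bandcsp import FilterBankCSP, cross_validate
from bandcsp.synthetic import SimConfig, generate

# 8-channel synthetic EEG, 100 trials/class, one 10–14 Hz source whose
# amplitude is 1.0 in class 1 and 2.0 in class 2
epochs, truth = generate(SimConfig(), seed=1)

clf = FilterBankCSP(fs=epochs.fs, random_state=1)
clf.fit(epochs.data, epochs.labels)
print("selected feature sets:",
      [s.label for s in clf.feature_sets_ if s.index in clf.selected_])
print("CSSP delay tau:", clf.tau_)

res = cross_validate(epochs, clf, folds=10, repetitions=2, seed=1)
print(res.summary())
```

Output:

```
selected feature sets: ['3', '4', '13a', '13b']
CSSP delay tau: 1
error 1.25 ± 2.22 %, kappa 0.975 ± 0.044 (20 folds)
```

The selection finds the planted 10–14 Hz band (feature set 4, with its
8–12 Hz neighbour and the wide band in both CSP and CSSP form, labels 13a
and 13b), and the cross-validated misclassification rate is near zero with a
correspondingly high chance-corrected agreement κ.

The same workflow runs from the shell:

```
bandcsp simulate --out epochs.mat --seed 1
bandcsp evaluate --input epochs.mat --method proposed --folds 10 --reps 2 --seed 1
bandcsp calibrate --input epochs.mat --out model.json --seed 1
bandcsp predict --model model.json --input epochs.mat --out labels.csv
```

`sweep-bands` and `ablate` expose the band-count sweep and the
leave-one-band-out analysis. Real recordings enter through the documented
MAT epoch container (`X` trials × channels × samples, `y` in {1,2}, `fs`) or
a plain-text manifest; see `docs/methods.md` for the model, parameter and
protocol details.

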