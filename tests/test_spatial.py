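"""CSP/CSSP estimation, log-variance features, delay embedding, τ search."""

import numpy as np
import pytest
from scipy import linalg

from bandcsp.epochs import EpochSet, common_average_reference
from bandcsp.filterbank import bandpass, make_filterbank
from bandcsp.spatial import (
    class_covariance,
    csp_features,
    delay_embed,
    delay_embed_trials,
    features_from_trials,
    fit_csp,
    select_tau,
    trial_covariances,
)
from bandcsp.synthetic import SimConfig, generate

from conftest import spd


class TestClassCovariance:
    def test_orthogonal_equal_power_rows(self):
        X = np.array([[1.0, 1, -1, -1], [1.0, -1, 1, -1]])  # orthogonal rows
        cov = class_covariance(EpochSet(X[None], [1], 100.0))
        assert np.allclose(cov, np.eye(2) / 2)

    def test_duplicating_trials_invariant(self, tiny_epochs):
        c1 = class_covariance(tiny_epochs)
        doubled = EpochSet(
            np.concatenate([tiny_epochs.data] * 2),
            np.concatenate([tiny_epochs.labels] * 2),
            100.0,
        )
        assert np.allclose(c1, class_covariance(doubled))

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((2, 3, 50))
        cov = class_covariance(EpochSet(X, [1, 1], 100.0))
        acc = np.zeros((3, 3))
        for n in range(2):  # independent loop-based evaluation
            c = X[n] @ X[n].T
            acc += c / np.trace(c)
        assert np.allclose(cov, acc / 2)
        assert np.allclose(np.trace(cov), 1.0)
        assert np.all(np.linalg.eigvalsh(cov) > -1e-12)

    def test_zero_trial_rejected(self):
        with pytest.raises(ValueError, match="trial 1"):
            trial_covariances(np.stack([np.ones((2, 4)), np.zeros((2, 4))]))


class TestFitCSP:
    def test_diagonal_case(self):
        model = fit_csp(np.diag([4.0, 1.0]), np.diag([1.0, 4.0]), m=1)
        W = model.W
        # columns proportional to e1 and e2 (sign-fixed positive)
        assert abs(W[0, 0]) > 1e3 * abs(W[1, 0])
        assert abs(W[1, 1]) > 1e3 * abs(W[0, 1])
        assert np.allclose(sorted(model.eigvals), [0.2, 0.8], atol=1e-6)

    def test_swap_reverses_columns(self):
        rng = np.random.default_rng(1)
        C1, C2 = spd(rng, 4), spd(rng, 4)
        a = fit_csp(C1, C2, m=1).W
        b = fit_csp(C2, C1, m=1).W
        assert np.allclose(np.abs(a), np.abs(b[:, ::-1]), atol=1e-8)

    def test_first_column_beats_random_directions(self):
        rng = np.random.default_rng(2)
        C1, C2 = spd(rng, 4), spd(rng, 4)
        w = fit_csp(C1, C2, m=1).W[:, 0]
        ratio = (w @ C1 @ w) / (w @ (C1 + C2) @ w)
        U = rng.standard_normal((100_000, 4))
        U /= np.linalg.norm(U, axis=1, keepdims=True)
        rand = np.einsum("ij,jk,ik->i", U, C1, U) / np.einsum(
            "ij,jk,ik->i", U, C1 + C2, U
        )
        assert ratio >= rand.max() - 1e-10

    def test_eigen_pairing_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            C1, C2 = spd(rng, 5), spd(rng, 5)
            W = fit_csp(C1, C2, m=2).W
            for j in range(W.shape[1]):
                w = W[:, j]
                assert w @ C1 @ w + w @ C2 @ w == pytest.approx(1.0, abs=1e-6)

    def test_agrees_with_whitening_reference(self):
        # two-step reference: whiten the composite, then diagonalise C1
        rng = np.random.default_rng(5)
        C1, C2 = spd(rng, 5), spd(rng, 5)
        comp = C1 + C2
        d, U = np.linalg.eigh(comp)
        P = U @ np.diag(d**-0.5)
        lam_ref, V = np.linalg.eigh(P.T @ C1 @ P)
        W_ref = P @ V  # ascending eigenvalues
        model = fit_csp(C1, C2, m=2, eps=0.0)
        lam = np.array([w @ C1 @ w for w in model.W.T])
        expect = np.concatenate([lam_ref[::-1][:2], lam_ref[::-1][-2:]])
        assert np.allclose(lam, expect, atol=1e-8)
        for j, col in enumerate(model.W.T):
            ref = W_ref[:, np.argmin(np.abs(lam_ref - lam[j]))]
            assert np.allclose(np.abs(col), np.abs(ref), atol=1e-6)

    def test_too_many_pairs_rejected(self):
        with pytest.raises(ValueError):
            fit_csp(np.eye(3), np.eye(3), m=2)


class TestFeatures:
    def _model(self, C):
        return fit_csp(np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), m=1)

    def test_equal_variances(self):
        rng = np.random.default_rng(0)
        model = fit_csp(np.eye(2) * 2, np.eye(2), m=1)
        model.W = np.eye(2)  # identity projection for a controlled input
        X = np.stack([rng.standard_normal(500), rng.standard_normal(500)])
        X = X / X.std(axis=1, keepdims=True)
        f = csp_features(model, X)
        assert np.allclose(f, np.log(0.5), atol=1e-12)

    def test_three_to_one_variances(self):
        model = fit_csp(np.eye(2) * 2, np.eye(2), m=1)
        model.W = np.eye(2)
        rng = np.random.default_rng(1)
        X = np.stack([rng.standard_normal(400), rng.standard_normal(400)])
        X = X / X.std(axis=1, keepdims=True)
        X[0] *= np.sqrt(3.0)
        f = csp_features(model, X)
        assert np.allclose(f, [np.log(0.75), np.log(0.25)], atol=1e-12)

    def test_normalisation_and_scale_invariance(self, tiny_epochs):
        rng = np.random.default_rng(2)
        C1, C2 = spd(rng, 4), spd(rng, 4)
        model = fit_csp(C1, C2, m=2)
        F = features_from_trials(model, tiny_epochs.data)
        assert np.allclose(np.exp(F).sum(axis=1), 1.0, atol=1e-12)
        F10 = features_from_trials(model, 10.0 * tiny_epochs.data)
        assert np.allclose(F, F10, atol=1e-12)

    def test_zero_projection_rejected(self):
        model = fit_csp(np.eye(2), np.eye(2), m=1)
        with pytest.raises(ValueError):
            csp_features(model, np.zeros((2, 10)))


class TestDelayEmbed:
    def test_example(self):
        out = delay_embed(np.array([[1.0, 2, 3, 4]]), tau=1)
        assert out.tolist() == [[2, 3, 4], [1, 2, 3]]

    @pytest.mark.parametrize("tau", [1, 5, 15])
    def test_shape(self, tau):
        X = np.random.default_rng(0).standard_normal((3, 200))
        out = delay_embed(X, tau)
        assert out.shape == (6, 200 - tau)

    def test_tau_range_enforced(self):
        X = np.zeros((2, 50))
        for bad in (0, 16, -1):
            with pytest.raises(ValueError):
                delay_embed(X, bad)


@pytest.fixture(scope="module")
def contrast_train():
    from bandcsp.synthetic import spectral_contrast_config

    cfg = spectral_contrast_config(trials_per_class=30)
    ep, _ = generate(cfg, seed=11)
    return common_average_reference(ep)


class TestSelectTau:
    def test_range_and_determinism(self, contrast_train):
        bank = make_filterbank(100.0)
        cssp = [s for s in bank if s.mode == "cssp"][0]
        t1 = select_tau(contrast_train, cssp, folds=5, seed=3)
        t2 = select_tau(contrast_train, cssp, folds=5, seed=3)
        assert 1 <= t1 <= 15
        assert t1 == t2

    def test_too_few_trials_rejected(self, tiny_epochs):
        bank = make_filterbank(100.0)
        cssp = [s for s in bank if s.mode == "cssp"][0]
        with pytest.raises(ValueError):
            select_tau(tiny_epochs, cssp, folds=10)

    def test_selected_tau_not_worse_than_tau_one(self):
        """On narrow-band class contrast the CV-selected delay should do at
        least as well as τ=1 on held-out data, on average over seeds."""
        from bandcsp.pipeline import FilterBankCSP
        from bandcsp.synthetic import spectral_contrast_config

        cfg = spectral_contrast_config(trials_per_class=30)
        diffs = []
        for seed in range(6):
            tr, _ = generate(cfg, seed)
            te, _ = generate(cfg, 100 + seed)
            accs = {}
            for tau in ("search", 1):
                est = FilterBankCSP(method="cssp", fs=100.0, tau_folds=5,
                                    tau=None if tau == "search" else tau,
                                    random_state=seed)
                est.fit(tr.data, tr.labels)
                accs[tau] = np.mean(est.predict(te.data) == te.labels)
            diffs.append(accs["search"] - accs[1])
        assert np.mean(diffs) >= -0.01
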