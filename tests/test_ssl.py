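"""Semi-supervised generative classifier: gradients, learning, controls."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from npscreen.nn import MLP, softmax
from npscreen.ssl import SemiSupervisedVAEClassifier


class _FixedEps:
    """Stands in for the rng inside a step so eps draws are reproducible."""

    def __init__(self, eps_list):
        self.eps = list(eps_list)

    def standard_normal(self, shape):
        out = self.eps.pop(0)
        assert out.shape == tuple(shape)
        return out

    def integers(self, lo, hi=None, size=None):
        # deterministic unlabeled batch: first rows
        n = size if isinstance(size, int) else size[0]
        return np.arange(n)


def _toy_model(d=4, K=3, L=2, seed=0):
    m = SemiSupervisedVAEClassifier(latent_dim=L, hidden=(6, 5), seed=seed)
    rng = np.random.default_rng(seed)
    m.n_classes_ = K
    m.classes_ = np.arange(K)
    m.trunk_ = MLP([d, 6, 5], rng)
    m.clf_head_ = MLP([L, 5, K], rng)
    m.enc_head_ = MLP([5, 2 * L], rng)
    m.dec_ = MLP([L + K, 5, 6, d], rng)
    return m


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Exactness of the manual backprop through the full objective
        (labeled ELBO + weighted CE + label-marginalized unlabeled ELBO)."""
        d, K, L = 4, 3, 2
        m = _toy_model(d, K, L)
        rng = np.random.default_rng(1)
        nb, nu = 6, 5
        xb = rng.standard_normal((nb, d))
        yb = rng.integers(0, K, nb)
        Xu = rng.standard_normal((nu, d))
        eps_l = rng.standard_normal((nb, L))
        eps_u = rng.standard_normal((nu, L))
        alpha, eyeK = 2.0, np.eye(K)

        def loss_fn():
            h = np.tanh(m.trunk_.forward(xb)[0])
            enc = m.enc_head_.forward(h)[0]
            mu, logv = enc[:, :L], np.clip(enc[:, L:], -8, 8)
            z = mu + eps_l * np.exp(0.5 * logv)
            xhat = m.dec_.forward(np.hstack([z, eyeK[yb]]))[0]
            recon = 0.5 * ((xb - xhat) ** 2).sum(1)
            kl = -0.5 * (1 + logv - mu**2 - np.exp(logv)).sum(1)
            q = softmax(m.clf_head_.forward(mu)[0])
            ce = -np.log(q[np.arange(nb), yb])
            total = (recon + kl).mean() + alpha * ce.mean()

            hu = np.tanh(m.trunk_.forward(Xu)[0])
            encu = m.enc_head_.forward(hu)[0]
            mu_u, logv_u = encu[:, :L], np.clip(encu[:, L:], -8, 8)
            zu = mu_u + eps_u * np.exp(0.5 * logv_u)
            qu = softmax(m.clf_head_.forward(mu_u)[0])
            xhat_u = m.dec_.forward(
                np.hstack([np.tile(zu, (K, 1)), np.repeat(eyeK, nu, axis=0)])
            )[0]
            recon_u = (
                0.5 * ((np.tile(Xu, (K, 1)) - xhat_u) ** 2).sum(1).reshape(K, nu).T
            )
            kl_u = -0.5 * (1 + logv_u - mu_u**2 - np.exp(logv_u)).sum(1)
            logq = np.log(qu)
            total += ((qu * recon_u).sum(1) + kl_u + (qu * logq).sum(1)).mean()
            return total

        _, grads = m._step_grads(
            xb, yb, Xu, _FixedEps([eps_l, eps_u]), alpha, eyeK, bs=nb
        )
        params = m._all_params()
        h = 1e-6
        rng2 = np.random.default_rng(2)
        for pi, p in enumerate(params):
            flat = p.reshape(-1)
            for ix in rng2.choice(flat.size, size=min(4, flat.size), replace=False):
                old = flat[ix]
                flat[ix] = old + h
                lp = loss_fn()
                flat[ix] = old - h
                lm = loss_fn()
                flat[ix] = old
                fd = (lp - lm) / (2 * h)
                assert grads[pi].reshape(-1)[ix] == pytest.approx(fd, rel=1e-4, abs=1e-7)


def _blobs(rng, n_per, d=6, sep=4.0):
    X, y = [], []
    for k in range(3):
        center = np.zeros(d)
        center[k] = sep
        X.append(rng.standard_normal((n_per, d)) + center)
        y.append(np.full(n_per, k))
    return np.vstack(X), np.concatenate(y)


class TestTraining:
    def test_separable_blobs_reach_high_auc(self):
        rng = np.random.default_rng(0)
        X, y = _blobs(rng, 80)
        Xte, yte = _blobs(rng, 60)
        m = SemiSupervisedVAEClassifier(epochs=60, seed=0).fit(X, y)
        auc = roc_auc_score(yte, m.predict_proba(Xte), multi_class="ovr", average="macro")
        assert auc > 0.95

    def test_empty_unlabeled_pool_degenerates_to_supervised(self):
        rng = np.random.default_rng(1)
        X, y = _blobs(rng, 50)
        m = SemiSupervisedVAEClassifier(epochs=20, seed=0)
        m.fit(X, y, X_unlabeled=np.empty((0, X.shape[1])))
        assert m.predict_proba(X).shape == (len(X), 3)

    def test_single_class_labels_rejected(self):
        X = np.random.default_rng(2).standard_normal((30, 4))
        with pytest.raises(ValueError, match="single class"):
            SemiSupervisedVAEClassifier(epochs=5).fit(X, np.zeros(30))

    def test_unfitted_predict_rejected(self):
        with pytest.raises(RuntimeError):
            SemiSupervisedVAEClassifier().predict_proba(np.zeros((2, 3)))

    def test_fit_is_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X, y = _blobs(rng, 40)
        Xu = rng.standard_normal((100, X.shape[1]))
        p1 = SemiSupervisedVAEClassifier(epochs=15, seed=7).fit(X, y, Xu).predict_proba(X)
        p2 = SemiSupervisedVAEClassifier(epochs=15, seed=7).fit(X, y, Xu).predict_proba(X)
        np.testing.assert_array_equal(p1, p2)

    def test_label_permutation_destroys_auc(self):
        """Per-permutation AUC is noisy (predictions are cluster-constant),
        so the chance check averages over permutations and contrasts with
        the intact-label model."""
        rng = np.random.default_rng(4)
        X, y = _blobs(rng, 80, sep=3.0)
        Xte, yte = _blobs(rng, 80, sep=3.0)
        real = roc_auc_score(
            yte,
            SemiSupervisedVAEClassifier(epochs=40, seed=1).fit(X, y).predict_proba(Xte),
            multi_class="ovr", average="macro",
        )
        perm_aucs = []
        for s in range(6):
            m = SemiSupervisedVAEClassifier(epochs=40, seed=s).fit(X, rng.permutation(y))
            perm_aucs.append(
                roc_auc_score(yte, m.predict_proba(Xte), multi_class="ovr", average="macro")
            )
        assert real > 0.95
        assert abs(np.mean(perm_aucs) - 0.5) < 0.2
        assert np.mean(perm_aucs) < real - 0.2

    def test_unlabeled_pool_improves_low_label_accuracy(self):
        """With ~10% labels, training with the unlabeled pool yields at
        least the supervised-only mean AUC over 10 seeded cohorts (the
        shared representation is shaped by unlabeled reconstruction)."""
        import pandas as pd

        from npscreen import CohortConfig, apply_inclusion_filters, generate_cohort, load_labels
        from npscreen.cohort import FeaturePreprocessor
        from npscreen.prediction import macro_ovr_auc

        diffs = []
        for seed in range(10):
            cfg = CohortConfig(n_unlabeled=1500, n_labeled=420, seed=60_000 + seed)
            cohort = generate_cohort(cfg)
            labels, _ = load_labels(cohort.neuropathology)
            t_minus = apply_inclusion_filters(cohort, "t_minus", seed=seed)
            gen = apply_inclusion_filters(cohort, "generalized", seed=seed)
            sv = (
                t_minus.groupby("participant_id")
                .sample(1, random_state=seed)
                .set_index("participant_id")
            )
            common = labels.index.intersection(sv.index)
            y = labels.loc[common, "total_level"].to_numpy()
            sv = sv.loc[common]
            rng = np.random.default_rng(seed)
            lab = rng.choice(len(y), size=42, replace=False)
            te = np.setdiff1d(np.arange(len(y)), lab)
            pp = FeaturePreprocessor(tiers=frozenset({1, 2})).fit(sv.iloc[lab])
            Xl, Xt = pp.transform(sv.iloc[lab]), pp.transform(sv.iloc[te])
            Xu = pp.transform(gen)
            classes = np.unique(y[lab])

            def auc(model):
                proba = model.predict_proba(Xt)
                order = [list(model.classes_).index(c) for c in classes]
                return macro_ovr_auc(y[te], proba[:, order], classes)

            with_pool = auc(
                SemiSupervisedVAEClassifier(epochs=100, seed=seed).fit(Xl, y[lab], Xu)
            )
            without = auc(
                SemiSupervisedVAEClassifier(epochs=100, seed=seed).fit(Xl, y[lab], None)
            )
            diffs.append(with_pool - without)
        assert np.mean(diffs) >= 0.0

    def test_string_labels_roundtrip(self):
        rng = np.random.default_rng(5)
        X, y = _blobs(rng, 40)
        names = np.array(["low", "medium", "high"])
        m = SemiSupervisedVAEClassifier(epochs=20, seed=0).fit(X, names[y])
        assert set(m.predict(X)) <= set(names)
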