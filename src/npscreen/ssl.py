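"""Semi-supervised deep generative classifier for neuropathology load.

A two-latent-variable generative model in the spirit of the classic
semi-supervised VAE: each feature vector ``x`` is generated from a
continuous latent ``z ~ N(0, I)`` together with the class label ``y`` (the
3-level load),

* generation (decoder) ``p(x | z, y)`` — class-conditional Gaussian mean,
* inference (encoder)  ``q(z | x)``   — diagonal Gaussian,
* classifier           ``q(y | x)``   — softmax head.

The encoder and classifier share one inference trunk, and the encoder is
label-free: unlabeled reconstruction therefore shapes the very
representation the classifier reads, which is what makes participants
without autopsy informative even when the class boundaries cut through a
continuous clinical spectrum.  Labeled rows contribute the evidence lower
bound at the observed label plus a weighted cross-entropy on ``q(y | x)``;
unlabeled rows contribute the label-marginalized bound (the
``q(y | x)``-weighted reconstruction over all classes, the KL term, and
the classifier-entropy term of the variational objective).  The
classification weight scales with the unlabeled:labeled ratio so
supervision is not drowned out by a large pool.

Gradients are exact manual backprop through the reparameterized sample and
are verified against finite differences in the test suite.  Training uses
Adam with early stopping on a validation split carved from the training
data only.
"""

from __future__ import annotations

import numpy as np

from .nn import MLP, Adam, softmax

__all__ = ["SemiSupervisedVAEClassifier"]


class SemiSupervisedVAEClassifier:
    """Sklearn-style estimator: ``fit(X, y, X_unlabeled)`` / ``predict_proba``.

    Parameters
    ----------
    latent_dim, hidden
        Continuous latent size; ``hidden`` are the trunk widths (the
        decoder mirrors them).
    alpha_scale
        Classification-loss weight is ``alpha_scale * (1 + n_unlabeled /
        n_labeled)``.
    epochs, patience, val_fraction
        Fixed epoch budget with early stopping on held-out cross-entropy.
    """

    def __init__(
        self,
        latent_dim: int = 16,
        hidden: tuple[int, ...] = (64, 32),
        epochs: int = 60,
        batch_size: int = 128,
        lr: float = 2e-3,
        alpha_scale: float = 1.0,
        weight_decay: float = 1e-5,
        val_fraction: float = 0.15,
        patience: int = 12,
        seed: int = 0,
    ):
        self.latent_dim = latent_dim
        self.hidden = tuple(hidden)
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.alpha_scale = alpha_scale
        self.weight_decay = weight_decay
        self.val_fraction = val_fraction
        self.patience = patience
        self.seed = seed

    # ------------------------------------------------------------------

    def _trunk_forward(self, x: np.ndarray):
        t, cache = self.trunk_.forward(x)
        h = np.tanh(t)
        return h, (cache, h)

    def _trunk_backward(self, tcache, d_h: np.ndarray):
        cache, h = tcache
        _, grads = self.trunk_.backward(cache, d_h * (1.0 - h**2))
        return grads

    def _all_params(self):
        return (
            self.trunk_.params + self.clf_head_.params + self.enc_head_.params
            + self.dec_.params
        )

    # ------------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray, X_unlabeled: np.ndarray | None = None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        self.n_classes_ = K = len(self.classes_)
        if K < 2:
            raise ValueError("labels contain a single class; cannot train a classifier")
        Xu = None
        if X_unlabeled is not None and len(X_unlabeled) > 0:
            Xu = np.asarray(X_unlabeled, dtype=float)
        n_l, d = X.shape
        n_u = 0 if Xu is None else Xu.shape[0]
        L = self.latent_dim
        rng = np.random.default_rng(self.seed)

        self.trunk_ = MLP([d, *self.hidden], rng)
        # the classifier reads the (deterministic) encoder mean, so the
        # unlabeled reconstruction objective shapes its input space
        self.clf_head_ = MLP([L, self.hidden[-1], K], rng)
        self.enc_head_ = MLP([self.hidden[-1], 2 * L], rng)
        self.dec_ = MLP([L + K, *reversed(self.hidden), d], rng)
        params = self._all_params()
        opt = Adam(params, lr=self.lr, weight_decay=self.weight_decay)
        alpha = self.alpha_scale * (1.0 + n_u / max(n_l, 1))
        eyeK = np.eye(K)

        # early stopping needs a stable validation estimate; with fewer than
        # 30 held-out rows the stopping point is a lottery, so fall back to
        # the fixed epoch budget
        n_val = int(round(self.val_fraction * n_l))
        if n_val < 30:
            n_val = 0
        perm = rng.permutation(n_l)
        val_ix, tr_ix = perm[:n_val], perm[n_val:]
        Xtr, ytr = X[tr_ix], y_idx[tr_ix]
        Xval, yval = X[val_ix], y_idx[val_ix]
        if len(np.unique(ytr)) < 2:  # tiny-data edge: keep all rows
            Xtr, ytr = X, y_idx
            Xval = np.empty((0, d))
        n_tr = Xtr.shape[0]
        bs = min(self.batch_size, n_tr)

        best_val, best_params, since_best = np.inf, None, 0
        for epoch in range(self.epochs):
            order = rng.permutation(n_tr)
            for start in range(0, n_tr, bs):
                bix = order[start : start + bs]
                loss, grads = self._step_grads(
                    Xtr[bix], ytr[bix], Xu, rng, alpha, eyeK, bs
                )
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged (non-finite loss) at epoch {epoch}; "
                        f"lr={self.lr}, alpha={alpha:.2f}"
                    )
                opt.step(grads)

            if Xval.shape[0]:
                qv = self.predict_proba(Xval)
                val_ce = float(
                    -np.log(np.clip(qv[np.arange(len(yval)), yval], 1e-12, None)).mean()
                )
                if val_ce < best_val - 1e-6:
                    best_val, since_best = val_ce, 0
                    best_params = [p.copy() for p in params]
                else:
                    since_best += 1
                    if since_best >= self.patience:
                        break
        if best_params is not None:
            for p, bp in zip(params, best_params):
                p[...] = bp
        return self

    # ------------------------------------------------------------------

    def _step_grads(self, xb, yb, Xu, rng, alpha, eyeK, bs):
        """Loss and parameter gradients for one minibatch (labeled + unlabeled)."""
        K, L = self.n_classes_, self.latent_dim
        nb = xb.shape[0]
        nt = len(self.trunk_.params)
        nch = len(self.clf_head_.params)
        neh = len(self.enc_head_.params)
        grads = [np.zeros_like(p) for p in self._all_params()]

        def accumulate(offset, gs):
            for j, g in enumerate(gs):
                grads[offset + j] += g

        # ---- labeled: ELBO at the observed label + weighted CE ----
        Yb = eyeK[yb]
        h, tcache = self._trunk_forward(xb)
        enc_out, ecache = self.enc_head_.forward(h)
        mu, logv = enc_out[:, :L], np.clip(enc_out[:, L:], -8.0, 8.0)
        eps = rng.standard_normal(mu.shape)
        z = mu + eps * np.exp(0.5 * logv)
        xhat, dcache = self.dec_.forward(np.hstack([z, Yb]))
        recon = 0.5 * ((xb - xhat) ** 2).sum(axis=1)
        kl = -0.5 * (1.0 + logv - mu**2 - np.exp(logv)).sum(axis=1)
        logits, ccache = self.clf_head_.forward(mu)
        q = softmax(logits)
        ce = -np.log(np.clip(q[np.arange(nb), yb], 1e-12, None))
        loss = float((recon + kl).mean() + alpha * ce.mean())

        d_xhat = (xhat - xb) / nb
        d_dec_in, dec_g = self.dec_.backward(dcache, d_xhat)
        d_z = d_dec_in[:, :L]
        d_logits = alpha * (q - Yb) / nb
        d_mu_clf, clf_g = self.clf_head_.backward(ccache, d_logits)
        d_mu = d_z + mu / nb + d_mu_clf
        d_logv = d_z * eps * 0.5 * np.exp(0.5 * logv) + 0.5 * (np.exp(logv) - 1.0) / nb
        d_h_enc, enc_g = self.enc_head_.backward(ecache, np.hstack([d_mu, d_logv]))
        trunk_g = self._trunk_backward(tcache, d_h_enc)
        accumulate(0, trunk_g)
        accumulate(nt, clf_g)
        accumulate(nt + nch, enc_g)
        accumulate(nt + nch + neh, dec_g)

        # ---- unlabeled: label-marginalized ELBO ----
        if Xu is not None:
            nu_take = min(bs, Xu.shape[0])
            xu = Xu[rng.integers(0, Xu.shape[0], size=nu_take)]
            nu = xu.shape[0]
            hu, tcache_u = self._trunk_forward(xu)
            enc_out_u, ecache_u = self.enc_head_.forward(hu)
            mu_u, logv_u = enc_out_u[:, :L], np.clip(enc_out_u[:, L:], -8.0, 8.0)
            eps_u = rng.standard_normal(mu_u.shape)
            zu = mu_u + eps_u * np.exp(0.5 * logv_u)
            logits_u, ccache_u = self.clf_head_.forward(mu_u)
            qu = softmax(logits_u)
            # decode all K label hypotheses in one stacked pass (z shared)
            z_rep = np.tile(zu, (K, 1))
            Y_rep = np.repeat(eyeK, nu, axis=0)
            xhat_u, dcache_u = self.dec_.forward(np.hstack([z_rep, Y_rep]))
            x_rep = np.tile(xu, (K, 1))
            recon_u = 0.5 * ((x_rep - xhat_u) ** 2).sum(axis=1).reshape(K, nu).T
            kl_u = -0.5 * (1.0 + logv_u - mu_u**2 - np.exp(logv_u)).sum(axis=1)
            logq = np.log(np.clip(qu, 1e-12, None))
            loss += float(
                ((qu * recon_u).sum(axis=1) + kl_u + (qu * logq).sum(axis=1)).mean()
            )

            w_u = qu.T.reshape(-1) / nu  # branch weight per stacked row
            d_xhat_u = w_u[:, None] * (xhat_u - x_rep)
            d_dec_in_u, dec_gu = self.dec_.backward(dcache_u, d_xhat_u)
            d_zu = d_dec_in_u[:, :L].reshape(K, nu, L).sum(axis=0)
            s = recon_u + logq
            d_logits_u = qu * (s - (qu * s).sum(axis=1, keepdims=True)) / nu
            d_mu_clf_u, clf_gu = self.clf_head_.backward(ccache_u, d_logits_u)
            d_mu_u = d_zu + mu_u / nu + d_mu_clf_u
            d_logv_u = (
                d_zu * eps_u * 0.5 * np.exp(0.5 * logv_u)
                + 0.5 * (np.exp(logv_u) - 1.0) / nu
            )
            d_h_enc_u, enc_gu = self.enc_head_.backward(
                ecache_u, np.hstack([d_mu_u, d_logv_u])
            )
            trunk_gu = self._trunk_backward(tcache_u, d_h_enc_u)
            accumulate(0, trunk_gu)
            accumulate(nt, clf_gu)
            accumulate(nt + nch, enc_gu)
            accumulate(nt + nch + neh, dec_gu)
        return loss, grads

    # ------------------------------------------------------------------

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "clf_head_"):
            raise RuntimeError("model is not fitted")
        h, _ = self._trunk_forward(np.asarray(X, dtype=float))
        enc_out, _ = self.enc_head_.forward(h)
        logits, _ = self.clf_head_.forward(enc_out[:, : self.latent_dim])
        return softmax(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
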