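"""Conditional mixture density network.

A small fully connected network maps a conditioning vector x to the weights,
means and diagonal scales of a K-component Gaussian mixture over the target
y, trained by maximum conditional likelihood with minibatch Adam and
early stopping on a held-out split.  Exposes exact log-density, ancestral
sampling, and the analytic gradient of log q(y|x) with respect to y (used by
MAP refinement).  Implemented directly in NumPy with hand-derived
backpropagation; everything is deterministic given the seed.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

__all__ = ["MixtureDensityNetwork"]

_LOG2PI = np.log(2.0 * np.pi)
_LOGSIG_MIN, _LOGSIG_MAX = -7.0, 5.0


def _logsumexp(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


class MixtureDensityNetwork(BaseEstimator):
    """Conditional density estimator q(y | x).

    Parameters
    ----------
    n_components : mixture components K.
    hidden : sizes of the two tanh hidden layers.
    learning_rate, batch_size, max_epochs, patience, val_fraction :
        Adam / early-stopping schedule.
    seed : controls initialization, the train/validation split and batch
        order; fitting twice with the same seed gives identical models.
    """

    def __init__(self, n_components: int = 8, hidden=(50, 50),
                 learning_rate: float = 1e-3, batch_size: int = 256,
                 max_epochs: int = 200, patience: int = 20,
                 val_fraction: float = 0.1, seed: int = 0):
        self.n_components = n_components
        self.hidden = hidden
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.seed = seed

    # -- forward ------------------------------------------------------------

    def _forward(self, X):
        W1, b1, W2, b2, Wg, bg, Wm, bm, Ws, bs = self.weights_
        h1 = np.tanh(X @ W1 + b1)
        h2 = np.tanh(h1 @ W2 + b2)
        logits = h2 @ Wg + bg
        K, D = self.n_components, self.dy_
        mu = (h2 @ Wm + bm).reshape(-1, K, D)
        logsig = np.clip((h2 @ Ws + bs).reshape(-1, K, D), _LOGSIG_MIN, _LOGSIG_MAX)
        return h1, h2, logits, mu, logsig

    @staticmethod
    def _mixture_logpdf(Y, logits, mu, logsig):
        lp = logits - _logsumexp(logits, axis=1)[:, None]
        z = (Y[:, None, :] - mu) / np.exp(logsig)
        comp = -0.5 * np.sum(z * z + _LOG2PI, axis=2) - np.sum(logsig, axis=2)
        return _logsumexp(lp + comp, axis=1)

    # -- training -----------------------------------------------------------

    def _init_weights(self, dx, dy, rng):
        K = self.n_components
        h1, h2 = self.hidden
        def glorot(a, b):
            return rng.normal(0.0, np.sqrt(2.0 / (a + b)), (a, b))
        self.weights_ = [
            glorot(dx, h1), np.zeros(h1),
            glorot(h1, h2), np.zeros(h2),
            glorot(h2, K), np.zeros(K),
            glorot(h2, K * dy) * 0.1, rng.normal(0.0, 0.5, K * dy),
            glorot(h2, K * dy) * 0.1, np.zeros(K * dy),
        ]

    def _loss_and_grads(self, X, Y):
        W1, b1, W2, b2, Wg, bg, Wm, bm, Ws, bs = self.weights_
        B = X.shape[0]
        K, D = self.n_components, self.dy_
        h1, h2, logits, mu, logsig = self._forward(X)

        lp = logits - _logsumexp(logits, axis=1)[:, None]
        sig = np.exp(logsig)
        z = (Y[:, None, :] - mu) / sig
        comp = -0.5 * np.sum(z * z + _LOG2PI, axis=2) - np.sum(logsig, axis=2)
        joint = lp + comp
        logq = _logsumexp(joint, axis=1)
        loss = -np.mean(logq)

        r = np.exp(joint - logq[:, None])              # responsibilities
        pi = np.exp(lp)
        d_logits = (pi - r) / B
        d_mu = (-r[:, :, None] * z / sig) / B
        d_logsig = (-r[:, :, None] * (z * z - 1.0)) / B
        # clip boundary: no gradient where logsig saturated
        at_edge = (logsig <= _LOGSIG_MIN) | (logsig >= _LOGSIG_MAX)
        d_logsig[at_edge] = 0.0

        d_mu_f = d_mu.reshape(B, K * D)
        d_ls_f = d_logsig.reshape(B, K * D)
        d_h2 = d_logits @ Wg.T + d_mu_f @ Wm.T + d_ls_f @ Ws.T
        d_pre2 = d_h2 * (1 - h2 * h2)
        d_h1 = d_pre2 @ W2.T
        d_pre1 = d_h1 * (1 - h1 * h1)

        grads = [
            X.T @ d_pre1, d_pre1.sum(0),
            h1.T @ d_pre2, d_pre2.sum(0),
            h2.T @ d_logits, d_logits.sum(0),
            h2.T @ d_mu_f, d_mu_f.sum(0),
            h2.T @ d_ls_f, d_ls_f.sum(0),
        ]
        return loss, grads

    def fit(self, X, Y):
        X = np.atleast_2d(np.asarray(X, float))
        Y = np.asarray(Y, float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, dx = X.shape
        self.dx_, self.dy_ = dx, Y.shape[1]
        if n < 1000:
            import warnings
            warnings.warn(f"training on only {n} pairs; the density estimate "
                          "may be unreliable", stacklevel=2)
        rng = np.random.default_rng(self.seed)
        self._init_weights(dx, self.dy_, rng)

        n_val = max(1, int(round(self.val_fraction * n)))
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xt, Yt, Xv, Yv = X[tr_idx], Y[tr_idx], X[val_idx], Y[val_idx]

        m = [np.zeros_like(w) for w in self.weights_]
        v = [np.zeros_like(w) for w in self.weights_]
        b1c = b2c = 1.0
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        best = np.inf
        best_weights = [w.copy() for w in self.weights_]
        bad_epochs = 0
        self.val_curve_ = []

        for epoch in range(self.max_epochs):
            order = rng.permutation(len(Xt))
            for lo in range(0, len(Xt), self.batch_size):
                idx = order[lo:lo + self.batch_size]
                loss, grads = self._loss_and_grads(Xt[idx], Yt[idx])
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch}")
                b1c *= beta1
                b2c *= beta2
                for j, g in enumerate(grads):
                    m[j] = beta1 * m[j] + (1 - beta1) * g
                    v[j] = beta2 * v[j] + (1 - beta2) * g * g
                    mhat = m[j] / (1 - b1c)
                    vhat = v[j] / (1 - b2c)
                    self.weights_[j] -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            val = -np.mean(self._mixture_logpdf(Yv, *self._forward(Xv)[2:]))
            self.val_curve_.append(float(val))
            if val < best - 1e-6:
                best = val
                best_weights = [w.copy() for w in self.weights_]
                bad_epochs = 0
            else:
                bad_epochs += 1
                if bad_epochs >= self.patience:
                    break
        self.weights_ = best_weights
        self.best_val_loss_ = float(best)
        return self

    # -- inference ----------------------------------------------------------

    def log_prob(self, Y, X):
        """log q(y_i | x_i) for paired rows; X may be a single row."""
        Y = np.atleast_2d(np.asarray(Y, float))
        X = np.atleast_2d(np.asarray(X, float))
        if X.shape[0] == 1 and Y.shape[0] > 1:
            X = np.broadcast_to(X, (Y.shape[0], X.shape[1]))
        _, _, logits, mu, logsig = self._forward(X)
        return self._mixture_logpdf(Y, logits, mu, logsig)

    def sample(self, x, n, rng) -> np.ndarray:
        """n ancestral draws from q(y | x) for a single conditioning vector."""
        x = np.atleast_2d(np.asarray(x, float))
        _, _, logits, mu, logsig = self._forward(x)
        p = np.exp(logits[0] - _logsumexp(logits, axis=1)[0])
        comp = rng.choice(self.n_components, size=n, p=p / p.sum())
        eps = rng.standard_normal((n, self.dy_))
        return mu[0, comp] + eps * np.exp(logsig[0, comp])

    def grad_log_prob_y(self, y, x):
        """d log q(y|x) / dy for a single (y, x) pair."""
        y = np.asarray(y, float)[None, :]
        x = np.atleast_2d(np.asarray(x, float))
        _, _, logits, mu, logsig = self._forward(x)
        lp = logits - _logsumexp(logits, axis=1)[:, None]
        sig = np.exp(logsig)
        z = (y[:, None, :] - mu) / sig
        comp = -0.5 * np.sum(z * z + _LOG2PI, axis=2) - np.sum(logsig, axis=2)
        joint = lp + comp
        r = np.exp(joint - _logsumexp(joint, axis=1)[:, None])
        return np.sum(r[:, :, None] * (mu - y[:, None, :]) / sig ** 2, axis=1)[0]
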