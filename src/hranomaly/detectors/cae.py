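"""Convolutional autoencoder + LSTM detector over window embeddings.

A 1-D convolutional encoder (16, 8 and 1 filters; kernel sizes 5, 5 and 1;
all strides 2) compresses non-overlapping standardized windows of length
n = 32 into d = 4 latent embeddings (32 / (2*2*2) positions x 1 filter); the
decoder mirrors it with upsample-by-2 + convolution blocks. After the
autoencoder is trained to minimize reconstruction error ||x - x~||^2, an LSTM
forecaster (32/16/8 cells) is trained over the embedding sequences to predict
the next window's embedding from the previous two; the predicted embedding is
decoded and compared element-wise with the observed next window, assigning a
squared error to each of that window's points.
"""

from __future__ import annotations

import numpy as np

from ..errors import CapacityError, ConfigurationError, DivergenceError
from ..nn import (
    Adam,
    Conv1dSame,
    Dense,
    Module,
    StackedLSTM,
    Tensor,
    UpsampleConv1d,
    minibatches,
    relu,
)
from .base import BaseHRDetector

__all__ = ["Cae", "fit_cae", "CaeLstmDetector"]


class Cae(Module):
    """Convolutional autoencoder for length-``n`` windows.

    Encoder channel plan 1->16->8->1 with strides 2 halves the length three
    times; the final single filter yields a flat d = n/8 embedding. The last
    encoder layer and the decoder output layer are linear so embeddings and
    reconstructions can take either sign; hidden activations are ReLU.
    """

    def __init__(
        self,
        n: int = 32,
        encoder_filters=(16, 8, 1),
        kernel_sizes=(5, 5, 1),
        strides=(2, 2, 2),
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        stride_prod = int(np.prod(strides))
        if n % stride_prod != 0:
            raise ConfigurationError(
                f"window length {n} must be divisible by the stride product {stride_prod}"
            )
        self.n = n
        self.latent_dim = (n // stride_prod) * encoder_filters[-1]
        chans = (1,) + tuple(encoder_filters)
        self.enc_layers = [
            Conv1dSame(chans[i], chans[i + 1], kernel_sizes[i], strides[i], rng)
            for i in range(len(encoder_filters))
        ]
        dec_chans = tuple(reversed(encoder_filters[:-1])) + (1,)
        dec_in = (encoder_filters[-1],) + dec_chans[:-1]
        dec_kernels = tuple(reversed(kernel_sizes[:-1])) + (kernel_sizes[0],)
        self.dec_layers = [
            UpsampleConv1d(dec_in[i], dec_chans[i], dec_kernels[i], rng, factor=strides[i])
            for i in range(len(dec_chans))
        ]

    def encode(self, x: Tensor) -> Tensor:
        h = x
        for i, layer in enumerate(self.enc_layers):
            h = layer(h)
            if i < len(self.enc_layers) - 1:
                h = relu(h)
        return h.reshape(h.shape[0], self.latent_dim)

    def decode(self, z: Tensor) -> Tensor:
        h = z.reshape(z.shape[0], self.latent_dim, 1)
        for i, layer in enumerate(self.dec_layers):
            h = layer(h)
            if i < len(self.dec_layers) - 1:
                h = relu(h)
        return h.reshape(h.shape[0], self.n)

    def reconstruct(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


def fit_cae(
    train_windows: np.ndarray,
    n: int = 32,
    rng: np.random.Generator | None = None,
    learning_rate: float = 1e-3,
    batch_size: int = 32,
    max_epochs: int = 60,
    patience: int = 8,
    val_fraction: float = 0.1,
) -> Cae:
    """Train a convolutional autoencoder on standardized length-``n`` windows."""
    rng = rng if rng is not None else np.random.default_rng(0)
    X = np.asarray(train_windows, dtype=float)
    if X.ndim != 2 or X.shape[1] != n:
        raise ConfigurationError(f"train_windows must be (n_windows, {n})")
    cae = Cae(n=n, rng=rng)
    params = cae.parameters()
    opt = Adam(params, lr=learning_rate)
    order = rng.permutation(len(X))
    n_val = max(1, int(len(X) * val_fraction))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    best, best_state, bad = np.inf, cae.state(), 0
    for _ in range(max_epochs):
        for batch in minibatches(len(tr_idx), batch_size, rng):
            bi = tr_idx[batch]
            xb = Tensor(X[bi, :, None], requires_grad=False)
            recon = cae.reconstruct(xb)
            diff = recon - Tensor(X[bi], requires_grad=False)
            loss = (diff * diff).sum() / len(bi)
            if not np.isfinite(loss.data):
                raise DivergenceError("CAE loss non-finite; lower the learning rate")
            cae.zero_grad()
            loss.backward()
            opt.step()
        val_recon = cae.reconstruct(Tensor(X[val_idx, :, None], requires_grad=False)).data
        val_loss = float(((val_recon - X[val_idx]) ** 2).sum(axis=1).mean())
        if val_loss < best:
            best, best_state, bad = val_loss, cae.state(), 0
        else:
            bad += 1
            if bad >= patience:
                break
    cae.load_state(best_state)
    return cae


def _tumble(x: np.ndarray, n: int) -> np.ndarray:
    k = len(x) // n
    return x[: k * n].reshape(k, n)


class CaeLstmDetector(BaseHRDetector):
    """CAE embeddings forecast by an LSTM, decoded to score the next window."""

    def __init__(
        self,
        window_length: int = 32,
        context_windows: int = 2,
        layer_sizes: tuple[int, ...] = (32, 16, 8),
        dropout: float = 0.2,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 60,
        cae_max_epochs: int = 60,
        patience: int = 8,
        k: float = 3.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.window_length = window_length
        self.context_windows = context_windows
        self.layer_sizes = layer_sizes
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.cae_max_epochs = cae_max_epochs
        self.patience = patience
        self.k = k
        self.standardize = standardize
        self.random_state = random_state

    def _fit_model(self, arrays: list[np.ndarray]) -> None:
        rng = self._rng()
        n = self.window_length
        night_windows = [_tumble(self._to_std(a), n) for a in arrays]
        if min(len(w) for w in night_windows) < self.context_windows + 1:
            raise CapacityError(
                "training nights too short for windowed embedding forecasting"
            )
        allw = np.concatenate(night_windows)
        self.cae_ = fit_cae(
            allw,
            n=n,
            rng=rng,
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.cae_max_epochs,
            patience=self.patience,
        )
        d = self.cae_.latent_dim

        # embedding sequences -> next-embedding training pairs
        ctx = self.context_windows
        Xs, ys = [], []
        for w in night_windows:
            e = self._embed(w)
            for t in range(ctx, len(e)):
                Xs.append(e[t - ctx : t])
                ys.append(e[t])
        X = np.stack(Xs)
        y = np.stack(ys)

        self.forecaster_ = StackedLSTM(
            d, tuple(self.layer_sizes), rng, bidirectional=False, dropout=self.dropout
        )
        self.head_ = Dense(self.forecaster_.out_dim, d, rng)
        params = self.forecaster_.parameters() + self.head_.parameters()
        opt = Adam(params, lr=self.learning_rate)
        best, best_state, bad = np.inf, None, 0
        for _ in range(self.max_epochs):
            ep_loss = 0.0
            for batch in minibatches(len(X), self.batch_size, rng):
                pred = self._forecast_tensor(X[batch], training=True, rng=rng)
                diff = pred - Tensor(y[batch], requires_grad=False)
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise DivergenceError("forecaster loss non-finite")
                for p in params:
                    p.grad = None
                loss.backward()
                opt.step()
                ep_loss += float(loss.data) * len(batch)
            ep_loss /= len(X)
            if ep_loss < best:
                best = ep_loss
                best_state = [p.data.copy() for p in params]
                bad = 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        for p, s in zip(params, best_state):
            p.data = s.copy()

    def _build_models(self, rng) -> None:
        self.cae_ = Cae(n=self.window_length, rng=rng)
        self.forecaster_ = StackedLSTM(
            self.cae_.latent_dim,
            tuple(self.layer_sizes),
            rng,
            bidirectional=False,
            dropout=self.dropout,
        )
        self.head_ = Dense(self.forecaster_.out_dim, self.cae_.latent_dim, rng)

    def _parameters(self):
        return (
            self.cae_.parameters()
            + self.forecaster_.parameters()
            + self.head_.parameters()
        )

    def _embed(self, windows: np.ndarray) -> np.ndarray:
        return self.cae_.encode(
            Tensor(windows[:, :, None], requires_grad=False)
        ).data

    def _forecast_tensor(self, Xctx: np.ndarray, training=False, rng=None) -> Tensor:
        xs = [
            Tensor(Xctx[:, t, :], requires_grad=False)
            for t in range(Xctx.shape[1])
        ]
        outs = self.forecaster_(xs, training=training, rng=rng)
        return self.head_(outs[-1])

    def _score_array(self, bpm: np.ndarray) -> np.ndarray:
        n = self.window_length
        ctx = self.context_windows
        z = self._to_std(bpm)
        windows = _tumble(z, n)
        if len(windows) < ctx + 1:
            raise CapacityError("series too short to score with windowed forecasts")
        e = self._embed(windows)
        Xctx = np.stack([e[t - ctx : t] for t in range(ctx, len(e))])
        z_pred = self._forecast_tensor(Xctx).data
        x_pred = self.cae_.decode(Tensor(z_pred, requires_grad=False)).data
        scores = np.full(len(bpm), np.nan)
        for j, t in enumerate(range(ctx, len(windows))):
            obs = self._from_std(windows[t])
            pred = self._from_std(x_pred[j])
            scores[t * n : (t + 1) * n] = (obs - pred) ** 2
        return scores
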