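"""Stacked (Bi)LSTM one-step-ahead forecasting detectors.

Three recurrent layers (32, 16 and 8 cells) with tanh cell activations read a
window of standardized heart-rate history and a linear head predicts the next
sample. Regularization follows the usual recipe for small recurrent
forecasters: dropout between hidden layers, a max-norm bound of 3 on weights
and biases after every update, Adam, and early stopping. The bidirectional
variant runs each layer over the window in both directions, doubling the
context available per layer.
"""

from __future__ import annotations

import numpy as np

from ..errors import CapacityError, DivergenceError
from ..nn import Adam, Dense, EarlyStopper, StackedLSTM, Tensor, apply_maxnorm, minibatches
from .base import BaseHRDetector

__all__ = ["LstmDetector", "make_forecast_windows"]


def make_forecast_windows(
    x: np.ndarray, input_window: int, stride: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """History windows ``x[i-w:i]`` paired with next-sample targets ``x[i]``."""
    w = input_window
    if len(x) <= w:
        raise CapacityError(f"series of {len(x)} points has no length-{w} windows")
    idx = np.arange(w, len(x), stride)
    X = np.stack([x[i - w : i] for i in idx])
    y = x[idx]
    return X, y


class _ForecastNet:
    def __init__(self, layer_sizes, bidirectional, dropout, rng):
        self.stack = StackedLSTM(
            1, tuple(layer_sizes), rng, bidirectional=bidirectional, dropout=dropout
        )
        self.head = Dense(self.stack.out_dim, 1, rng)

    def parameters(self):
        return self.stack.parameters() + self.head.parameters()

    def state(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state):
        for p, s in zip(self.parameters(), state):
            p.data = s.copy()

    def forward(self, X: np.ndarray, training=False, rng=None) -> Tensor:
        T = X.shape[1]
        xs = [Tensor(X[:, t, None], requires_grad=False) for t in range(T)]
        outs = self.stack(xs, training=training, rng=rng)
        return self.head(outs[-1])


class LstmDetector(BaseHRDetector):
    """One-step-ahead LSTM (or BiLSTM) forecasting detector.

    Parameters
    ----------
    input_window : int
        History length fed to the network (aligned with the convolutional
        autoencoder's sample length so both detector families see the same
        horizon).
    train_stride : int
        Subsampling stride over training windows; scoring is always per
        point.
    """

    def __init__(
        self,
        layer_sizes: tuple[int, ...] = (32, 16, 8),
        bidirectional: bool = False,
        input_window: int = 32,
        dropout: float = 0.2,
        maxnorm: float = 3.0,
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 30,
        patience: int = 5,
        train_stride: int = 2,
        val_fraction: float = 0.1,
        k: float = 3.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.layer_sizes = layer_sizes
        self.bidirectional = bidirectional
        self.input_window = input_window
        self.dropout = dropout
        self.maxnorm = maxnorm
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.train_stride = train_stride
        self.val_fraction = val_fraction
        self.k = k
        self.standardize = standardize
        self.random_state = random_state

    def _fit_model(self, arrays: list[np.ndarray]) -> None:
        rng = self._rng()
        Xs, ys = [], []
        for a in arrays:
            X, y = make_forecast_windows(self._to_std(a), self.input_window, self.train_stride)
            Xs.append(X)
            ys.append(y)
        X = np.concatenate(Xs)
        y = np.concatenate(ys)[:, None]

        self._build_models(rng)
        net = self.net_
        params = net.parameters()
        opt = Adam(params, lr=self.learning_rate)
        apply_maxnorm(params, self.maxnorm)

        # hold out a tail fraction of shuffled windows for early stopping
        order = rng.permutation(len(X))
        n_val = max(1, int(len(X) * self.val_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        stopper = EarlyStopper(net.stack, patience=self.patience)

        self.loss_history_ = []
        self._best_state = net.state()
        for epoch in range(self.max_epochs):
            for batch in minibatches(len(tr_idx), self.batch_size, rng):
                bi = tr_idx[batch]
                pred = net.forward(X[bi], training=True, rng=rng)
                diff = pred - Tensor(y[bi], requires_grad=False)
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise DivergenceError(
                        "training loss is non-finite; lower the learning rate"
                    )
                for p in params:
                    p.grad = None
                loss.backward()
                opt.step()
                apply_maxnorm(params, self.maxnorm)
            val_pred = net.forward(X[val_idx]).data
            val_loss = float(((val_pred - y[val_idx]) ** 2).mean())
            self.loss_history_.append(val_loss)
            if val_loss <= min(self.loss_history_):
                self._best_state = net.state()
            if stopper.update(val_loss):
                break
        net.load_state(self._best_state)
        self.n_epochs_ = len(self.loss_history_)

    def _score_array(self, bpm: np.ndarray) -> np.ndarray:
        z = self._to_std(bpm)
        X, y = make_forecast_windows(z, self.input_window, stride=1)
        preds = np.empty(len(X))
        for start in range(0, len(X), 512):
            preds[start : start + 512] = self.net_.forward(
                X[start : start + 512]
            ).data[:, 0]
        scores = np.full(len(bpm), np.nan)
        pred_bpm = self._from_std(preds)
        obs_bpm = self._from_std(y)
        scores[self.input_window :] = (obs_bpm - pred_bpm) ** 2
        return scores

    def _build_models(self, rng) -> None:
        self.net_ = _ForecastNet(self.layer_sizes, self.bidirectional, self.dropout, rng)

    def _parameters(self):
        return self.net_.parameters()

    def weight_norms(self) -> list[float]:
        """Max per-unit (column) norm of every constrained weight array."""
        norms = []
        for p in self.net_.parameters():
            if p.data.ndim >= 2:
                norms.append(float(np.sqrt((p.data**2).sum(axis=0)).max()))
            else:
                norms.append(float(np.linalg.norm(p.data)))
        return norms
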