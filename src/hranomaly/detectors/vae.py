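"""The proposed detector: a BiLSTM beta-VAE with a latent BiLSTM forecaster.

Non-overlapping windows of n = 10 consecutive standardized heart-rate samples
are encoded by a single 64-unit bidirectional LSTM layer into a latent
Gaussian with mean mu in R^d and variance sigma^2 in R^d (d = 4). Latents are
sampled with the reparameterization trick and decoded by a mirrored 64-unit
bidirectional layer. The training objective is

    L = ||x - x~||^2 + beta * KL(N(mu, diag sigma^2) || N(0, I)),

with beta = 3 by default: up-weighting the KL term encourages a more
disentangled, prior-like latent space at some cost in reconstruction
fidelity. A separate BiLSTM module (32/16/8 cells) is trained over the
embedding sequence to forecast the next embedding z_{t+1} from (z_{t-1},
z_t); the decoder turns the forecast embedding into a predicted window whose
element-wise squared discrepancy with the observed window scores each point.
At inference the embedding of an observed window is its posterior mean mu
(no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import CapacityError, ConfigurationError, DivergenceError
from ..nn import (
    Adam,
    BiLSTMLayer,
    Dense,
    Module,
    StackedLSTM,
    Tensor,
    concat,
    exp,
    minibatches,
)
from .base import BaseHRDetector

__all__ = [
    "WindowBatch",
    "make_windows",
    "reparameterize",
    "vae_loss",
    "VaeBiLstm",
    "VaeBiLstmDetector",
]


@dataclass
class WindowBatch:
    """Non-overlapping windows with exact window-to-point index bookkeeping."""

    windows: np.ndarray  # (n_windows, n)
    window_length: int
    n_points: int

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def remainder(self) -> int:
        """Trailing points excluded from windowing."""
        return self.n_points - self.n_windows * self.window_length

    def point_range(self, w: int) -> tuple[int, int]:
        """Points [start, stop) covered by window ``w``."""
        return w * self.window_length, (w + 1) * self.window_length


def make_windows(series_or_array, n: int = 10) -> WindowBatch:
    """Partition a series into floor(N/n) consecutive disjoint windows.

    The trailing remainder of fewer than ``n`` points is excluded from
    windowing but recorded, so concatenating windows plus remainder
    reproduces the series exactly.
    """
    from .base import as_bpm_array

    x = as_bpm_array(series_or_array)
    if n < 2:
        raise ConfigurationError("window length must be > 1")
    if len(x) < 2 * n:
        raise CapacityError(
            f"series of {len(x)} points is shorter than two windows of {n}"
        )
    k = len(x) // n
    return WindowBatch(
        windows=x[: k * n].reshape(k, n).copy(),
        window_length=n,
        n_points=len(x),
    )


def reparameterize(
    mu: np.ndarray,
    sigma2: np.ndarray,
    epsilon: np.ndarray,
    mode: str = "as-printed",
) -> np.ndarray:
    """Latent sample z from (mu, sigma^2) and external noise epsilon.

    ``mode="as-printed"`` scales the noise by the variance, z = mu +
    sigma^2 o epsilon; ``mode="sigma"`` is the conventional z = mu +
    sigma o epsilon. Either way z = mu when epsilon = 0.
    """
    mu = np.asarray(mu, float)
    sigma2 = np.asarray(sigma2, float)
    epsilon = np.asarray(epsilon, float)
    if mu.shape != sigma2.shape or mu.shape != epsilon.shape:
        raise ConfigurationError("mu, sigma2 and epsilon must share a shape")
    if np.any(sigma2 <= 0):
        raise ConfigurationError("sigma2 must be strictly positive")
    if mode == "as-printed":
        return mu + sigma2 * epsilon
    if mode == "sigma":
        return mu + np.sqrt(sigma2) * epsilon
    raise ConfigurationError("mode must be 'as-printed' or 'sigma'")


def vae_loss(
    x: np.ndarray,
    x_recon: np.ndarray,
    mu: np.ndarray,
    sigma2: np.ndarray,
    beta: float,
) -> tuple[float, float, float]:
    """Total/reconstruction/KL decomposition of the beta-VAE objective.

    The reconstruction term is the squared Euclidean distance ||x - x~||^2;
    the KL term is the closed form for a diagonal Gaussian against N(0, I):

        KL = 1/2 sum_j (sigma2_j + mu_j^2 - 1 - ln sigma2_j) >= 0.
    """
    x = np.asarray(x, float)
    x_recon = np.asarray(x_recon, float)
    mu = np.asarray(mu, float)
    sigma2 = np.asarray(sigma2, float)
    if x.shape != x_recon.shape:
        raise ConfigurationError("x and x_recon must share a shape")
    if mu.shape != sigma2.shape:
        raise ConfigurationError("mu and sigma2 must share a shape")
    if np.any(sigma2 <= 0):
        raise ConfigurationError("sigma2 must be strictly positive")
    recon = float(np.sum((x - x_recon) ** 2))
    kl = float(0.5 * np.sum(sigma2 + mu**2 - 1.0 - np.log(sigma2)))
    return recon + beta * kl, recon, kl


class VaeBiLstm(Module):
    """Encoder/decoder pair; parameterized via log sigma^2 for stability."""

    def __init__(
        self,
        window_length: int,
        latent_dim: int,
        units: int,
        rng: np.random.Generator,
    ):
        self.n = window_length
        self.d = latent_dim
        self.encoder = BiLSTMLayer(1, units, rng)
        self.mu_head = Dense(2 * units, latent_dim, rng)
        self.logvar_head = Dense(2 * units, latent_dim, rng)
        self.decoder = BiLSTMLayer(latent_dim, units, rng)
        self.out_head = Dense(2 * units, 1, rng)

    def encode(self, X: np.ndarray) -> tuple[Tensor, Tensor]:
        """Window batch (B, n) -> (mu, log sigma^2), each (B, d)."""
        xs = [Tensor(X[:, t, None], requires_grad=False) for t in range(X.shape[1])]
        outs = self.encoder(xs)
        state = self.encoder.final_state(outs)
        return self.mu_head(state), self.logvar_head(state)

    def decode(self, z: Tensor) -> Tensor:
        """Latent (B, d) -> reconstructed window (B, n).

        The embedding is repeated n times as the input sequence to the
        mirrored bidirectional layer, with a linear per-step output head.
        """
        xs = [z for _ in range(self.n)]
        outs = self.decoder(xs)
        cols = [self.out_head(o) for o in outs]
        return concat(cols, axis=1)


class VaeBiLstmDetector(BaseHRDetector):
    """beta-VAE-BiLSTM anomaly detector over non-overlapping windows.

    Parameters follow the architecture description: window length n = 10,
    latent dimensionality d = 4, beta = 3, single 64-unit BiLSTM layer in
    encoder and decoder, and a (32, 16, 8)-cell BiLSTM latent forecaster fed
    the previous and current embeddings.
    """

    def __init__(
        self,
        window_length: int = 10,
        latent_dim: int = 4,
        beta: float = 3.0,
        units: int = 64,
        forecaster_layers: tuple[int, ...] = (32, 16, 8),
        forecaster_dropout: float = 0.2,
        context_windows: int = 2,
        reparam_mode: str = "as-printed",
        learning_rate: float = 1e-3,
        batch_size: int = 32,
        max_epochs: int = 100,
        forecaster_max_epochs: int = 150,
        patience: int = 10,
        val_fraction: float = 0.1,
        k: float = 3.0,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.window_length = window_length
        self.latent_dim = latent_dim
        self.beta = beta
        self.units = units
        self.forecaster_layers = forecaster_layers
        self.forecaster_dropout = forecaster_dropout
        self.context_windows = context_windows
        self.reparam_mode = reparam_mode
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.forecaster_max_epochs = forecaster_max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.k = k
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------ validation
    def _validate(self) -> None:
        if self.window_length <= 1:
            raise ConfigurationError("window_length must be > 1")
        if self.latent_dim < 1:
            raise ConfigurationError("latent_dim must be >= 1")
        if self.beta <= 0:
            raise ConfigurationError("beta must be > 0")
        if self.context_windows < 1:
            raise ConfigurationError("context_windows must be >= 1")

    # --------------------------------------------------------------- fitting
    def _fit_model(self, arrays: list[np.ndarray]) -> None:
        self._validate()
        rng = self._rng()
        n = self.window_length
        night_windows = [make_windows(self._to_std(a), n).windows for a in arrays]
        if min(len(w) for w in night_windows) < self.context_windows + 1:
            raise CapacityError("each training night needs at least 3 windows")
        X = np.concatenate(night_windows)

        self.vae_ = VaeBiLstm(n, self.latent_dim, self.units, rng)
        self._train_vae(X, rng)
        self._train_forecaster(night_windows, rng)

    def _train_vae(self, X: np.ndarray, rng: np.random.Generator) -> None:
        vae = self.vae_
        params = vae.parameters()
        opt = Adam(params, lr=self.learning_rate)
        order = rng.permutation(len(X))
        n_val = max(1, int(len(X) * self.val_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]

        def total_loss_value(idx) -> tuple[float, float, float]:
            mu, logvar = vae.encode(X[idx])
            recon = vae.decode(mu).data  # deterministic evaluation
            t, r, kl = 0.0, 0.0, 0.0
            for i in range(len(idx)):
                ti, ri, ki = vae_loss(
                    X[idx][i], recon[i], mu.data[i], np.exp(logvar.data[i]), self.beta
                )
                t, r, kl = t + ti, r + ri, kl + ki
            m = len(idx)
            return t / m, r / m, kl / m

        self.vae_loss_history_ = []
        best, best_state, bad = np.inf, vae.state(), 0
        self.initial_val_loss_ = total_loss_value(val_idx)[0]
        for _ in range(self.max_epochs):
            for batch in minibatches(len(tr_idx), self.batch_size, rng):
                bi = tr_idx[batch]
                mu, logvar = vae.encode(X[bi])
                sigma2 = exp(logvar)
                eps = Tensor(
                    rng.standard_normal(mu.shape), requires_grad=False
                )
                scale = sigma2 if self.reparam_mode == "as-printed" else sigma2**0.5
                z = mu + scale * eps
                recon = vae.decode(z)
                diff = recon - Tensor(X[bi], requires_grad=False)
                recon_term = (diff * diff).sum(axis=1)
                kl_term = 0.5 * (sigma2 + mu * mu - 1.0 - logvar).sum(axis=1)
                loss = (recon_term + self.beta * kl_term).mean()
                if not np.isfinite(loss.data):
                    raise DivergenceError("VAE loss non-finite; lower the learning rate")
                vae.zero_grad()
                loss.backward()
                opt.step()
            val_total, val_recon, val_kl = total_loss_value(val_idx)
            self.vae_loss_history_.append((val_total, val_recon, val_kl))
            if val_total < best:
                best, best_state, bad = val_total, vae.state(), 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        vae.load_state(best_state)
        self.final_val_loss_ = best

    def _train_forecaster(
        self, night_windows: list[np.ndarray], rng: np.random.Generator
    ) -> None:
        embedding_seqs = [self.vae_.encode(w)[0].data for w in night_windows]
        self._fit_forecaster_on_embeddings(embedding_seqs, rng)

    def _fit_forecaster_on_embeddings(
        self, embedding_seqs: list[np.ndarray], rng: np.random.Generator
    ) -> None:
        ctx = self.context_windows
        Xs, ys = [], []
        for e in embedding_seqs:
            for t in range(ctx, len(e)):
                Xs.append(e[t - ctx : t])
                ys.append(e[t])
        X = np.stack(Xs)
        y = np.stack(ys)

        self.forecaster_ = StackedLSTM(
            self.latent_dim,
            tuple(self.forecaster_layers),
            rng,
            bidirectional=True,
            dropout=self.forecaster_dropout,
        )
        self.forecaster_head_ = Dense(self.forecaster_.out_dim, self.latent_dim, rng)
        params = self.forecaster_.parameters() + self.forecaster_head_.parameters()
        opt = Adam(params, lr=self.learning_rate)
        order = rng.permutation(len(X))
        n_val = max(1, int(len(X) * self.val_fraction))
        val_idx, tr_idx = order[:n_val], order[n_val:]
        best, best_state, bad = np.inf, [p.data.copy() for p in params], 0
        self.forecaster_loss_history_ = []
        for _ in range(self.forecaster_max_epochs):
            for batch in minibatches(len(tr_idx), self.batch_size, rng):
                bi = tr_idx[batch]
                pred = self._forecast_tensor(X[bi], training=True, rng=rng)
                diff = pred - Tensor(y[bi], requires_grad=False)
                loss = (diff * diff).mean()
                if not np.isfinite(loss.data):
                    raise DivergenceError("latent forecaster loss non-finite")
                for p in params:
                    p.grad = None
                loss.backward()
                opt.step()
            val_pred = self._forecast_tensor(X[val_idx]).data
            val_loss = float(((val_pred - y[val_idx]) ** 2).mean())
            self.forecaster_loss_history_.append(val_loss)
            if val_loss < best:
                best, best_state, bad = val_loss, [p.data.copy() for p in params], 0
            else:
                bad += 1
                if bad >= self.patience:
                    break
        for p, s in zip(params, best_state):
            p.data = s.copy()

    def _build_models(self, rng) -> None:
        self.vae_ = VaeBiLstm(self.window_length, self.latent_dim, self.units, rng)
        self.forecaster_ = StackedLSTM(
            self.latent_dim,
            tuple(self.forecaster_layers),
            rng,
            bidirectional=True,
            dropout=self.forecaster_dropout,
        )
        self.forecaster_head_ = Dense(self.forecaster_.out_dim, self.latent_dim, rng)

    def _parameters(self):
        return (
            self.vae_.parameters()
            + self.forecaster_.parameters()
            + self.forecaster_head_.parameters()
        )

    def _forecast_tensor(
        self, Xctx: np.ndarray, training: bool = False, rng=None
    ) -> Tensor:
        # residual parameterization: the network predicts the increment over
        # the current embedding, so persistence is the zero-weight baseline
        xs = [Tensor(Xctx[:, t, :], requires_grad=False) for t in range(Xctx.shape[1])]
        outs = self.forecaster_(xs, training=training, rng=rng)
        return self.forecaster_head_(outs[-1]) + Tensor(
            Xctx[:, -1, :], requires_grad=False
        )

    # --------------------------------------------------------------- scoring
    def latent_embeddings(self, night) -> tuple[np.ndarray, np.ndarray]:
        """(mu, sigma^2) posterior parameters of each window of a night."""
        self._check_fitted()
        from .base import as_bpm_array

        wb = make_windows(self._to_std(as_bpm_array(night)), self.window_length)
        mu, logvar = self.vae_.encode(wb.windows)
        return mu.data, np.exp(logvar.data)

    def window_labels(self, mask, n_points: int | None = None) -> np.ndarray:
        """Per-window anomaly labels: a window is abnormal if any point is."""
        flags = mask.flags if hasattr(mask, "flags") else np.asarray(mask, bool)
        k = len(flags) // self.window_length
        return flags[: k * self.window_length].reshape(k, self.window_length).any(axis=1)

    def _score_array(self, bpm: np.ndarray) -> np.ndarray:
        n = self.window_length
        ctx = self.context_windows
        wb = make_windows(self._to_std(bpm), n)
        windows = wb.windows
        if len(windows) < ctx + 1:
            raise CapacityError("series too short to score with windowed forecasts")
        mu = self.vae_.encode(windows)[0].data
        Xctx = np.stack([mu[t - ctx : t] for t in range(ctx, len(mu))])
        z_pred = self._forecast_tensor(Xctx).data
        x_pred = self.vae_.decode(Tensor(z_pred, requires_grad=False)).data
        scores = np.full(len(bpm), np.nan)
        for j, t in enumerate(range(ctx, len(windows))):
            a, b = wb.point_range(t)
            obs = self._from_std(windows[t])
            pred = self._from_std(x_pred[j])
            scores[a:b] = (obs - pred) ** 2
        return scores
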