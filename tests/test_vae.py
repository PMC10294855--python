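"""beta-VAE math, windowing, training behaviour and scoring bookkeeping."""

import numpy as np
import pytest

from hranomaly import NightProfile, simulate_night
from hranomaly.detectors import VaeBiLstmDetector, make_windows, reparameterize, vae_loss
from hranomaly.errors import CapacityError, ConfigurationError


class TestMakeWindows:
    def test_exact_partition(self, rng):
        wb = make_windows(rng.normal(size=360), n=10)
        assert wb.n_windows == 36
        assert wb.remainder == 0

    def test_remainder_recorded(self, rng):
        wb = make_windows(rng.normal(size=365), n=10)
        assert wb.n_windows == 36
        assert wb.remainder == 5

    def test_round_trip_identity(self, rng):
        x = rng.normal(size=367)
        wb = make_windows(x, n=10)
        rebuilt = np.concatenate([wb.windows.ravel(), x[wb.n_windows * 10 :]])
        np.testing.assert_array_equal(rebuilt, x)

    def test_point_range_bookkeeping(self, rng):
        wb = make_windows(rng.normal(size=100), n=10)
        assert wb.point_range(3) == (30, 40)

    def test_too_short_rejected(self, rng):
        with pytest.raises(CapacityError):
            make_windows(rng.normal(size=15), n=10)


class TestReparameterize:
    def test_zero_noise_returns_mu(self, rng):
        mu = rng.normal(size=(5, 4))
        sigma2 = np.abs(rng.normal(size=(5, 4))) + 0.1
        np.testing.assert_array_equal(
            reparameterize(mu, sigma2, np.zeros_like(mu)), mu
        )

    def test_standard_normal_identity(self, rng):
        eps = rng.normal(size=(5, 4))
        out = reparameterize(np.zeros((5, 4)), np.ones((5, 4)), eps)
        np.testing.assert_array_equal(out, eps)

    @pytest.mark.parametrize("mode,scale_fn", [
        ("as-printed", lambda s2: s2),
        ("sigma", lambda s2: np.sqrt(s2)),
    ])
    def test_monte_carlo_moments(self, mode, scale_fn, rng):
        mu = np.array([0.7, -1.2])
        sigma2 = np.array([0.5, 2.0])
        eps = rng.normal(size=(100_000, 2))
        z = reparameterize(
            np.broadcast_to(mu, eps.shape), np.broadcast_to(sigma2, eps.shape),
            eps, mode=mode,
        )
        np.testing.assert_allclose(z.mean(axis=0), mu, atol=0.02)
        np.testing.assert_allclose(z.std(axis=0), scale_fn(sigma2), rtol=0.02)

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ConfigurationError):
            reparameterize(np.zeros(2), np.array([1.0, 0.0]), np.zeros(2))


class TestVaeLoss:
    def test_standard_normal_at_perfect_reconstruction_is_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        total, recon, kl = vae_loss(x, x, np.zeros(4), np.ones(4), beta=3.0)
        assert total == 0.0 and recon == 0.0 and kl == 0.0

    def test_unit_mean_shift_gives_half_nat(self):
        x = np.zeros(3)
        total, recon, kl = vae_loss(
            x, x, np.array([1.0, 0, 0, 0]), np.ones(4), beta=3.0
        )
        assert kl == pytest.approx(0.5)
        assert total == pytest.approx(1.5)

    def test_kl_closed_form_matches_monte_carlo(self, rng):
        """KL(N(mu, diag s2) || N(0,I)) vs a sample estimate of E[log q - log p]."""
        for _ in range(20):
            d = 4
            mu = rng.normal(0, 1.5, d)
            s2 = np.abs(rng.normal(0, 1.0, d)) + 0.05
            _, _, kl = vae_loss(np.zeros(2), np.zeros(2), mu, s2, beta=1.0)
            n = 200_000
            z = mu + np.sqrt(s2) * rng.standard_normal((n, d))
            logq = -0.5 * np.sum((z - mu) ** 2 / s2 + np.log(2 * np.pi * s2), axis=1)
            logp = -0.5 * np.sum(z**2 + np.log(2 * np.pi), axis=1)
            diff = logq - logp
            mc, se = diff.mean(), diff.std(ddof=1) / np.sqrt(n)
            assert abs(kl - mc) < 3 * se + 1e-9

    def test_terms_nonnegative(self, rng):
        for _ in range(50):
            mu = rng.normal(size=4)
            s2 = np.abs(rng.normal(size=4)) + 0.01
            x = rng.normal(size=6)
            xr = rng.normal(size=6)
            total, recon, kl = vae_loss(x, xr, mu, s2, beta=2.0)
            assert recon >= 0 and kl >= -1e-12 and total >= -1e-12

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ConfigurationError):
            vae_loss(np.zeros(2), np.zeros(2), np.zeros(2), np.array([1.0, -0.5]), 1.0)


def _tiny_nights(rng, n_nights=3, length=80, noise=0.3):
    t = np.arange(length)
    return [
        55 + 5 * np.sin(2 * np.pi * t / 40 + rng.uniform(0, 6)) + rng.normal(0, noise, length)
        for _ in range(n_nights)
    ]


class TestFitBetaVae:
    def test_constant_data_reconstructs_constant(self, rng):
        det = VaeBiLstmDetector(max_epochs=30, patience=5, random_state=0)
        nights = [np.full(60, 60.0) + rng.normal(0, 1e-3, 60) for _ in range(3)]
        det.fit(nights)
        mu, _ = det.latent_embeddings(np.full(60, 60.0))
        from hranomaly.nn import Tensor

        recon = det.vae_.decode(Tensor(mu, requires_grad=False)).data
        assert np.all(np.abs(recon) < 0.5)  # standardized units around 0

    def test_validation_loss_improves(self, rng):
        det = VaeBiLstmDetector(max_epochs=25, patience=25, random_state=1)
        det.fit(_tiny_nights(rng))
        assert det.final_val_loss_ < det.initial_val_loss_

    def test_seeded_determinism(self, rng):
        nights = _tiny_nights(rng)
        a = VaeBiLstmDetector(max_epochs=8, patience=8, random_state=3).fit(nights)
        b = VaeBiLstmDetector(max_epochs=8, patience=8, random_state=3).fit(nights)
        for pa, pb in zip(a.vae_.parameters(), b.vae_.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        np.testing.assert_array_equal(
            a.score_samples(nights[0]), b.score_samples(nights[0])
        )

    def test_larger_beta_shrinks_kl_at_convergence(self, rng):
        kls = {}
        for beta in (0.1, 3.0):
            vals = []
            for seed in range(3):
                nights = _tiny_nights(np.random.default_rng(100 + seed))
                det = VaeBiLstmDetector(
                    beta=beta, max_epochs=30, patience=30, random_state=seed
                )
                det.fit(nights)
                vals.append(det.vae_loss_history_[-1][2])  # KL term
            kls[beta] = np.mean(vals)
        assert kls[3.0] < kls[0.1]

    def test_embeddings_pulled_toward_prior(self, rng):
        det = VaeBiLstmDetector(max_epochs=30, patience=8, random_state=2)
        nights = _tiny_nights(rng)
        det.fit(nights)
        mu, s2 = det.latent_embeddings(nights[0])
        assert np.all(np.abs(mu.mean(axis=0)) < 1.0)
        assert np.all(s2.mean(axis=0) > 0.1) and np.all(s2.mean(axis=0) < 10.0)


class TestLatentForecaster:
    def test_learns_alternating_sequence(self, rng):
        """A two-state alternation in the latent stream is perfectly learnable."""
        det = VaeBiLstmDetector(max_epochs=5, patience=5, random_state=0)
        nights = _tiny_nights(rng)
        det.fit(nights)
        # overwrite the latent stream with a synthetic alternation and retrain
        e0, e1 = np.full(4, -0.5), np.full(4, 0.5)
        seq = np.stack([e0 if i % 2 == 0 else e1 for i in range(40)])
        det.forecaster_max_epochs, det.patience = 300, 40
        det._fit_forecaster_on_embeddings([seq], np.random.default_rng(1))
        X = np.stack([seq[t - 2 : t] for t in range(2, 40)])
        pred = det._forecast_tensor(X).data
        target = seq[2:40]
        assert ((pred - target) ** 2).mean() < 0.01

    def test_forecast_dimensionality(self, rng):
        det = VaeBiLstmDetector(max_epochs=5, patience=5, random_state=0)
        det.fit(_tiny_nights(rng))
        mu, _ = det.latent_embeddings(_tiny_nights(rng)[0])
        pred = det._forecast_tensor(mu[None, :2, :]).data
        assert pred.shape == (1, 4)


class TestScoring:
    def test_score_coverage_bookkeeping(self, rng):
        det = VaeBiLstmDetector(max_epochs=8, patience=8, random_state=0)
        nights = _tiny_nights(rng, length=107)
        det.fit(nights)
        scores = det.score_samples(nights[0])
        # windows 0,1 unscored; full windows 2..9 scored; remainder (7) unscored
        assert np.isnan(scores[:20]).all()
        assert np.isfinite(scores[20:100]).all()
        assert np.isnan(scores[100:]).all()

    def test_spike_window_gets_top_score(self):
        hits = 0
        for seed in range(3):
            rng = np.random.default_rng(seed)
            nights = _tiny_nights(rng, n_nights=4, length=120)
            det = VaeBiLstmDetector(max_epochs=40, patience=6, random_state=seed)
            det.fit(nights[:3])
            test = np.array(nights[3])
            spike_at = 65
            test[spike_at] += 6 * test.std()
            scores = det.score_samples(test)
            top_window = int(np.nanargmax(scores) // 10)
            hits += top_window == spike_at // 10
        assert hits >= 2


class TestCheckpoint:
    def test_save_load_round_trip_scores_identical(self, rng, tmp_path):
        nights = _tiny_nights(rng)
        det = VaeBiLstmDetector(max_epochs=8, patience=8, random_state=4).fit(nights)
        det.save(tmp_path / "ckpt")
        restored = VaeBiLstmDetector.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(
            restored.score_samples(nights[0]), det.score_samples(nights[0])
        )
        assert restored.threshold_ == det.threshold_

    def test_embedding_csv_export(self, rng, tmp_path):
        import pandas as pd

        from hranomaly.io import write_embeddings_csv

        nights = _tiny_nights(rng)
        det = VaeBiLstmDetector(max_epochs=5, patience=5, random_state=0).fit(nights)
        mu, s2 = det.latent_embeddings(nights[0])
        write_embeddings_csv(tmp_path / "emb.csv", mu, s2)
        df = pd.read_csv(tmp_path / "emb.csv")
        assert list(df.columns) == (
            ["window_index"] + [f"mu_{j}" for j in (1, 2, 3, 4)]
            + [f"sigma2_{j}" for j in (1, 2, 3, 4)]
        )
        np.testing.assert_allclose(df[["mu_1", "mu_2", "mu_3", "mu_4"]].to_numpy(), mu)
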