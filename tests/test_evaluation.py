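"""Thresholding, point-adjusted metrics, aggregation and latent mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hranomaly.errors import ConfigurationError
from hranomaly.evaluation import (
    adjust_predictions,
    aggregate_runs,
    compute_metrics,
    compute_threshold,
    latent_dispersion,
    map_latent_tsne,
    tune_k,
)

mask_pairs = st.lists(
    st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=300
)


def adjust_oracle(pred, truth):
    """Hand-enumerated point-adjust: walk truth runs, spread any hit."""
    pred = list(pred)
    out = list(pred)
    i = 0
    n = len(truth)
    while i < n:
        if truth[i]:
            j = i
            while j < n and truth[j]:
                j += 1
            if any(pred[i:j]):
                for t in range(i, j):
                    out[t] = True
            i = j
        else:
            i += 1
    return np.array(out, dtype=bool)


class TestThreshold:
    def test_zero_sd_threshold_equals_mean(self):
        rule = compute_threshold(np.full(10, 2.5), k=3.0)
        assert rule.threshold == 2.5

    def test_hand_arithmetic(self):
        rule = compute_threshold(np.array([0.0, 2.0]), k=1.0)
        assert rule.mean_train_sqerr == 1.0
        assert rule.sd_train_sqerr == 1.0
        assert rule.threshold == 2.0

    def test_k_zero_gives_mean(self):
        rule = compute_threshold(np.array([1.0, 3.0, 5.0]), k=0.0)
        assert rule.threshold == pytest.approx(3.0)

    def test_larger_k_never_flags_more(self, rng):
        scores = rng.exponential(1.0, 500)
        rule = compute_threshold(scores, 1.0)
        counts = [
            np.sum(scores > rule.mean_train_sqerr + k * rule.sd_train_sqerr)
            for k in (1.0, 2.0, 3.0, 4.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_scores_rejected(self):
        with pytest.raises(ConfigurationError):
            compute_threshold(np.array([]), 3.0)


class TestAdjustPredictions:
    def test_partial_hit_spreads_over_run(self):
        truth = np.zeros(10, bool)
        truth[3:7] = True
        pred = np.zeros(10, bool)
        pred[4] = True
        out = adjust_predictions(pred, truth)
        assert list(np.flatnonzero(out)) == [3, 4, 5, 6]

    def test_missed_run_stays_unflagged(self):
        truth = np.zeros(10, bool)
        truth[3:7] = True
        pred = np.zeros(10, bool)
        out = adjust_predictions(pred, truth)
        assert not out.any()

    @given(mask_pairs)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_oracle_and_is_monotone_idempotent(self, pairs):
        arr = np.array(pairs, dtype=bool)
        pred, truth = arr[:, 0], arr[:, 1]
        out = adjust_predictions(pred, truth)
        np.testing.assert_array_equal(out, adjust_oracle(pred, truth))
        assert np.all(~pred | out)  # pred subset of adjusted
        np.testing.assert_array_equal(adjust_predictions(out, truth), out)


class TestComputeMetrics:
    def test_printed_confusion_example(self):
        # TP=3, FP=1, FN=1 among 10 points
        truth = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool)
        pred = np.array([1, 1, 1, 0, 1, 0, 0, 0, 0, 0], bool)
        m = compute_metrics(pred, truth)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_perfect_prediction(self):
        truth = np.array([0, 1, 1, 0], bool)
        m = compute_metrics(truth, truth)
        assert (m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0)

    def test_zero_denominators_reported_as_zero_with_flag(self):
        m = compute_metrics(np.zeros(5, bool), np.zeros(5, bool))
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0
        assert set(m.undefined) == {"precision", "recall", "f1"}

    def test_f1_is_harmonic_mean(self, rng):
        for _ in range(20):
            pred = rng.random(50) < 0.3
            truth = rng.random(50) < 0.2
            m = compute_metrics(pred, truth)
            if m.precision + m.recall > 0:
                hm = 2 * m.precision * m.recall / (m.precision + m.recall)
                assert abs(m.f1 - hm) < 1e-12

    @given(mask_pairs)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_recall_and_f1_never_below_raw(self, pairs):
        arr = np.array(pairs, dtype=bool)
        pred, truth = arr[:, 0], arr[:, 1]
        raw = compute_metrics(pred, truth, adjusted=False)
        adj = compute_metrics(pred, truth, adjusted=True)
        assert adj.recall >= raw.recall
        assert adj.f1 >= raw.f1
        assert adj.counts.total == len(pred)


class TestTuneK:
    def test_separable_scores_pick_largest_gap_k(self):
        # training stats mean=1, sd=1; anomalies score 100, normals 0.5
        truth = np.zeros(50, bool)
        truth[10:13] = True
        scores = np.full(50, 0.5)
        scores[truth] = 100.0
        best = tune_k(
            scores, truth, (1.0, 2.0, 3.0, 4.0), mean_sqerr=1.0, sd_sqerr=1.0
        )
        assert best == 4.0

    def test_single_value_grid(self):
        truth = np.array([True, False])
        assert tune_k(np.array([5.0, 0.0]), truth, (2.0,), mean_sqerr=0, sd_sqerr=1) == 2.0

    def test_matches_exhaustive_sweep(self, rng):
        grid = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
        for _ in range(10):
            scores = rng.exponential(1.0, 200)
            truth = rng.random(200) < 0.05
            if not truth.any():
                continue
            mean, sd = 1.0, 1.0
            best = tune_k(scores, truth, grid, mean_sqerr=mean, sd_sqerr=sd)
            f1s = {
                k: compute_metrics(scores > mean + k * sd, truth, adjusted=True).f1
                for k in grid
            }
            assert f1s[best] == max(f1s.values())

    def test_no_anomalies_warns_and_returns_largest(self):
        with pytest.warns(UserWarning):
            k = tune_k(
                np.array([1.0, 2.0]), np.array([False, False]), (1.0, 2.0),
                mean_sqerr=0.0, sd_sqerr=1.0,
            )
        assert k == 2.0


class TestAggregateRuns:
    def test_identical_runs_have_zero_sd(self):
        runs = [{"f1": 0.7}] * 5
        summary = aggregate_runs(runs)
        assert summary.sds["f1"] == 0.0

    def test_mean_of_two_runs(self):
        summary = aggregate_runs([{"f1": 0.6}, {"f1": 0.8}])
        assert summary.means["f1"] == pytest.approx(0.7)

    def test_matches_numpy_on_stochastic_runs(self, rng):
        vals = rng.random(20)
        summary = aggregate_runs([{"m": v} for v in vals])
        assert summary.means["m"] == pytest.approx(vals.mean())
        assert summary.sds["m"] == pytest.approx(vals.std())

    def test_empty_rejected(self):
        with pytest.raises(ConfigurationError):
            aggregate_runs([])


class TestLatentMap:
    def test_bounding_box_is_unit_square(self, rng):
        emb = rng.normal(size=(30, 4))
        coords, _ = map_latent_tsne(emb, seed=0)
        assert coords.min(axis=0) == pytest.approx([0.0, 0.0])
        assert coords.max(axis=0) == pytest.approx([1.0, 1.0])

    def test_deterministic_given_seed(self, rng):
        emb = rng.normal(size=(25, 4))
        a, _ = map_latent_tsne(emb, seed=3)
        b, _ = map_latent_tsne(emb, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_separated_clusters_stay_separated(self, rng):
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            a = r.normal(0, 0.3, size=(20, 4))
            b = r.normal(8, 0.3, size=(20, 4))
            coords, _ = map_latent_tsne(np.vstack([a, b]), seed=seed)
            ca, cb = coords[:20], coords[20:]
            intra = np.linalg.norm(ca - ca.mean(0), axis=1).mean() + np.linalg.norm(
                cb - cb.mean(0), axis=1
            ).mean()
            inter = np.linalg.norm(ca.mean(0) - cb.mean(0))
            hits += inter > intra / 2
        assert hits >= 8

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            map_latent_tsne(rng.normal(size=(3, 4)))

    def test_dispersion_of_uniform_cloud_exceeds_tight_clusters(self, rng):
        tight = np.vstack(
            [rng.normal(0, 0.05, (20, 4)), rng.normal(5, 0.05, (20, 4))]
        )
        spread = rng.uniform(0, 1, (40, 4))
        assert latent_dispersion(spread) > latent_dispersion(tight)
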