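"""Ensemble labeling: trims, detectors, set algebra, cleaning, splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hranomaly import (
    AnomalySpec,
    LabelerConfig,
    LabelMask,
    NightProfile,
    build_split,
    clean_training,
    detect_sliding_window,
    detect_unsupervised,
    label_anomalies,
    simulate_night,
    simulate_participant,
    trim_sleep_edges,
)
from hranomaly.errors import CapacityError, ConfigurationError, DegenerateSeriesError


def sliding_window_oracle(bpm, window_fraction=0.03, k=3.0):
    """Brute-force re-computation over explicitly enumerated tumbling windows."""
    n = len(bpm)
    m = max(3, int(np.floor(window_fraction * n + 0.5)))
    flags = np.zeros(n, dtype=bool)
    starts = list(range(0, (n // m) * m, m))
    for i, start in enumerate(starts):
        stop = start + m if i < len(starts) - 1 else n
        seg = bpm[start:stop]
        mu = sum(seg) / len(seg)
        sd = (sum((v - mu) ** 2 for v in seg) / len(seg)) ** 0.5
        for j in range(start, stop):
            flags[j] = abs(bpm[j] - mu) > k * sd
    return flags


class TestTrim:
    def test_minute_sampling_arithmetic(self, default_profile):
        s = simulate_night(default_profile)  # 420 min at 60 s
        assert len(trim_sleep_edges(s)) == 360

    def test_half_minute_sampling_arithmetic(self):
        s = simulate_night(NightProfile(interval_seconds=30, seed=2))
        assert len(trim_sleep_edges(s)) == 720

    def test_timestamps_reanchored(self, default_profile):
        t = trim_sleep_edges(simulate_night(default_profile)).t
        assert t[0] == 0.0

    def test_short_night_rejected(self):
        s = simulate_night(NightProfile(duration_minutes=50, seed=1))
        with pytest.raises(CapacityError):
            trim_sleep_edges(s)


class TestSlidingWindow:
    def test_constant_series_yields_no_flags(self, series_factory):
        s = series_factory(np.full(200, 60.0))
        assert not detect_sliding_window(s).flags.any()

    def test_printed_toy_segment_not_flagged(self, series_factory):
        """[60]*9 + [100]: mean 64, population SD 12; |100-64| = 36 = 3*12 is
        not strictly above threshold — one extreme point inflates the SD."""
        seg = [60.0] * 9 + [100.0]
        assert np.mean(seg) == 64.0
        assert np.std(seg) == pytest.approx(12.0)
        s = series_factory(seg)
        flags = detect_sliding_window(s, window_fraction=1.0, k=3.0)
        assert not flags.flags.any()

    def test_matches_brute_force_oracle(self, rng, series_factory):
        for _ in range(20):
            n = int(rng.integers(200, 2000))
            bpm = 60 + rng.normal(0, 3, n).cumsum() * 0.05 + rng.normal(0, 2, n)
            bpm = np.abs(bpm) + 30
            s = series_factory(bpm)
            got = detect_sliding_window(s).flags
            np.testing.assert_array_equal(got, sliding_window_oracle(bpm))

    def test_lowering_k_never_removes_flags(self, rng, series_factory):
        s = series_factory(60 + rng.normal(0, 2, 500))
        loose = detect_sliding_window(s, k=2.0).flags
        tight = detect_sliding_window(s, k=3.0).flags
        assert np.all(~tight | loose)  # every k=3 flag survives at k=2

    def test_shorter_than_one_window_rejected(self, series_factory):
        with pytest.raises(CapacityError):
            detect_sliding_window(series_factory([60.0, 61.0]))


class TestUnsupervisedDetectors:
    @pytest.mark.parametrize("method", ["if", "ocsvm", "kde"])
    def test_constant_series_flags_nothing(self, method, series_factory):
        s = series_factory(np.full(300, 60.0))
        mask = detect_unsupervised(s, method)
        assert not mask.flags.any()

    @pytest.mark.parametrize("method", ["if", "ocsvm", "kde"])
    def test_big_spike_flagged_by_every_method(self, method, rng, series_factory):
        bpm = 60 + rng.normal(0, 1.5, 400)
        spike_idx = 200
        bpm[spike_idx] += 6 * bpm.std()
        mask = detect_unsupervised(series_factory(bpm), method)
        assert mask.flags[spike_idx]

    @pytest.mark.parametrize("method", ["if", "kde"])
    def test_flagged_fraction_bounded(self, method, rng, series_factory):
        s = series_factory(60 + rng.normal(0, 2, 500))
        config = LabelerConfig()
        mask = detect_unsupervised(s, method, config)
        bound = config.if_contamination if method == "if" else config.kde_quantile
        assert mask.flags.mean() <= bound + 0.02

    def test_deterministic_given_seed(self, rng, series_factory):
        s = series_factory(60 + rng.normal(0, 2, 400))
        for method in ("if", "ocsvm", "kde"):
            a = detect_unsupervised(s, method).flags
            b = detect_unsupervised(s, method).flags
            np.testing.assert_array_equal(a, b)

    def test_unknown_method_rejected(self, series_factory):
        with pytest.raises(ConfigurationError):
            detect_unsupervised(series_factory(np.full(100, 60.0)), "lof")


class TestEnsembleRule:
    def test_combined_mask_matches_set_algebra(self, rng, series_factory):
        s = series_factory(60 + rng.normal(0, 2, 600))
        mask = label_anomalies(s)
        src = mask.source
        expected = (src["if"] & src["ocsvm"] & src["kde"]) | src["sw"]
        np.testing.assert_array_equal(mask.flags, expected)

    @given(
        data=st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans(), st.booleans()),
            min_size=1,
            max_size=200,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_set_algebra_identity_on_arbitrary_masks(self, data):
        """(IF & OCSVM & KDE) | SW equals the brute-force index-set oracle."""
        arr = np.array(data, dtype=bool)
        a_if, a_oc, a_kde, a_sw = arr.T
        combined = (a_if & a_oc & a_kde) | a_sw
        inter = set(np.flatnonzero(a_if)) & set(np.flatnonzero(a_oc)) & set(
            np.flatnonzero(a_kde)
        )
        oracle = inter | set(np.flatnonzero(a_sw))
        assert set(np.flatnonzero(combined)) == oracle

    def test_labeler_global_recall_on_synthetic_nights(self):
        """Most injected global anomalies are auto-labeled (high-confidence set)."""
        caught = total = 0
        for seed in range(8):
            s, m = simulate_participant(
                NightProfile(seed=seed), AnomalySpec(seed=seed + 100), 7
            )[0]
            s, m = trim_sleep_edges(s, 30, m)
            labeled = label_anomalies(s)
            g = m.source["global"]
            caught += np.sum(labeled.flags & g)
            total += g.sum()
        assert caught / total >= 0.8


class TestCleanTraining:
    def test_single_replacement(self, series_factory):
        s = series_factory([60.0, 61.0, 95.0, 62.0])
        mask = LabelMask([False, False, True, False])
        np.testing.assert_array_equal(
            clean_training(s, mask).bpm, [60.0, 61.0, 61.0, 62.0]
        )

    def test_run_replacement_carries_anchor_forward(self, series_factory):
        s = series_factory([60.0, 95.0, 96.0, 62.0])
        mask = LabelMask([False, True, True, False])
        np.testing.assert_array_equal(
            clean_training(s, mask).bpm, [60.0, 60.0, 60.0, 62.0]
        )

    def test_all_false_mask_is_identity(self, series_factory):
        s = series_factory([60.0, 61.0, 62.0])
        out = clean_training(s, LabelMask([False] * 3))
        np.testing.assert_array_equal(out.bpm, s.bpm)

    def test_flagged_head_backfills(self, series_factory):
        s = series_factory([95.0, 96.0, 61.0, 62.0])
        mask = LabelMask([True, True, False, False])
        np.testing.assert_array_equal(
            clean_training(s, mask).bpm, [61.0, 61.0, 61.0, 62.0]
        )

    def test_all_flagged_rejected(self, series_factory):
        with pytest.raises(DegenerateSeriesError):
            clean_training(series_factory([60.0, 61.0]), LabelMask([True, True]))


class TestBuildSplit:
    def _labeled_nights(self, n=7):
        nights = simulate_participant(NightProfile(seed=3), AnomalySpec(seed=4), n)
        return [
            (trim_sleep_edges(s), m.slice(30, len(s) - 30))
            for s, m in nights
        ]

    def test_five_one_one_by_night_index(self):
        split = build_split(self._labeled_nights())
        assert len(split.train_nights) == 5
        assert split.validation_night.night_index == 5
        assert split.test_night.night_index == 6

    def test_training_values_replaced_at_flagged_positions(self):
        nights = self._labeled_nights()
        split = build_split(nights)
        for (orig, mask), cleaned in zip(nights[:5], split.train_nights):
            flagged = mask.flags
            # flagged points no longer carry their anomalous value
            assert not np.any(cleaned.bpm[flagged] == orig.bpm[flagged])
            np.testing.assert_array_equal(
                cleaned.bpm[~flagged], orig.bpm[~flagged]
            )

    def test_six_nights_rejected(self):
        with pytest.raises(ConfigurationError):
            build_split(self._labeled_nights()[:6])
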