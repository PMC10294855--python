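"""Ensemble auto-labeling of heart-rate anomalies and training-set cleaning.

Because no clinical criteria exist for what counts as an anomaly in wearable
heart-rate data, labels are produced automatically by an ensemble rule: the
*intersection* of three unsupervised outlier detectors (isolation forest,
one-class SVM with an RBF kernel, and Gaussian kernel density estimation) —
which flags high-confidence, mainly global outliers — is *unioned* with a
sliding-window z-score rule (any point more than ``k`` standard deviations
from its segment mean) that adds contextual outliers:

    final = (IF AND OCSVM AND KDE) OR SW

The module also provides the sleep-edge trim (drop the first and last 30
minutes of each night), the 5/1/1 night-wise train/validation/test split, and
"clean training": replacing labeled anomalous points with the previous
non-anomalous value so the forecasting detectors are trained on normal
behaviour only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import IsolationForest
from sklearn.neighbors import KernelDensity
from sklearn.svm import OneClassSVM

from .datatypes import HRSeries, LabelMask
from .errors import CapacityError, ConfigurationError, DegenerateSeriesError

__all__ = [
    "LabelerConfig",
    "SplitDataset",
    "trim_sleep_edges",
    "detect_unsupervised",
    "detect_sliding_window",
    "label_anomalies",
    "clean_training",
    "build_split",
    "EnsembleLabeler",
]

UNSUPERVISED_METHODS = ("if", "ocsvm", "kde")


@dataclass(frozen=True)
class LabelerConfig:
    """Settings for the four labeling detectors.

    Contamination-style parameters default to 0.05. They must bracket the
    anomaly densities the pipeline targets (up to ~4-5% of a night's points):
    the one-class SVM's nu lower-bounds the flaggable outlier fraction, so a
    value below the true anomaly density structurally caps its recall. The
    sliding window spans 3% of the night and flags points more than ``sw_k``
    segment SDs from the segment mean.
    """

    if_n_estimators: int = 100
    if_contamination: float = 0.05
    ocsvm_nu: float = 0.05
    ocsvm_gamma: str | float = "scale"
    kde_bandwidth: str | float = "silverman"
    kde_quantile: float = 0.05
    sw_window_fraction: float = 0.03
    sw_k: float = 3.0
    feature_mode: str = "value"  # "value" or "value+diff"
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.sw_window_fraction < 1:
            raise ConfigurationError("sw_window_fraction must be in (0, 1)")
        if self.sw_k <= 0:
            raise ConfigurationError("sw_k must be > 0")
        for name, v in (
            ("if_contamination", self.if_contamination),
            ("ocsvm_nu", self.ocsvm_nu),
            ("kde_quantile", self.kde_quantile),
        ):
            if not 0 < v < 0.5:
                raise ConfigurationError(f"{name} must be in (0, 0.5)")
        if self.feature_mode not in ("value", "value+diff"):
            raise ConfigurationError("feature_mode must be 'value' or 'value+diff'")


@dataclass
class SplitDataset:
    """Participant-level 5/1/1 bundle with cleaned training nights."""

    train_nights: list[HRSeries]
    train_masks: list[LabelMask]
    validation_night: HRSeries
    validation_mask: LabelMask
    test_night: HRSeries
    test_mask: LabelMask


def trim_sleep_edges(
    series: HRSeries, trim_minutes: int = 30, mask: LabelMask | None = None
):
    """Drop the first and last ``trim_minutes`` of a night.

    Removes the falling-asleep and waking-up phases. Timestamps are
    re-anchored to zero. If ``mask`` is given, it is trimmed identically and
    ``(series, mask)`` is returned.
    """
    interval = series.interval_seconds
    if interval <= 0:
        raise CapacityError("cannot trim a series with fewer than 2 points")
    k = int(trim_minutes * 60 // interval)
    if len(series) <= 2 * k:
        raise CapacityError(
            f"series of {len(series)} samples is too short to trim "
            f"{trim_minutes} min from each edge"
        )
    trimmed = series.slice(k, len(series) - k)
    if mask is None:
        return trimmed
    return trimmed, mask.slice(k, len(series) - k)


def _features(bpm: np.ndarray, mode: str) -> np.ndarray:
    x = bpm[:, None]
    if mode == "value+diff":
        d = np.diff(bpm, prepend=bpm[0])[:, None]
        x = np.hstack([x, d])
    return x


def _silverman_bandwidth(x: np.ndarray) -> float:
    n = len(x)
    sd = x.std()
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    return max(0.9 * spread * n ** (-1 / 5), 1e-3)


def detect_unsupervised(
    series: HRSeries, method: str, config: LabelerConfig | None = None
) -> LabelMask:
    """Flag outliers with one of the three unsupervised detectors.

    ``method`` is one of ``"if"``, ``"ocsvm"``, ``"kde"``. A zero-variance
    series has no point more isolated than another, so nothing is flagged.
    Deterministic given ``config.seed``.
    """
    config = config or LabelerConfig()
    config.validate()
    method = method.lower()
    if method not in UNSUPERVISED_METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; expected one of {UNSUPERVISED_METHODS}"
        )
    bpm = series.bpm
    if bpm.std() == 0:
        return LabelMask(np.zeros(len(bpm), dtype=bool))
    x = _features(bpm, config.feature_mode)

    if method == "if":
        model = IsolationForest(
            n_estimators=config.if_n_estimators,
            contamination=config.if_contamination,
            random_state=config.seed,
        )
        flags = model.fit_predict(x) == -1
    elif method == "ocsvm":
        mu, sd = x.mean(axis=0), x.std(axis=0)
        sd[sd == 0] = 1.0
        model = OneClassSVM(
            kernel="rbf", nu=config.ocsvm_nu, gamma=config.ocsvm_gamma
        )
        flags = model.fit_predict((x - mu) / sd) == -1
    else:  # kde
        bw = (
            _silverman_bandwidth(bpm)
            if config.kde_bandwidth == "silverman"
            else float(config.kde_bandwidth)
        )
        kde = KernelDensity(kernel="gaussian", bandwidth=bw).fit(x)
        logdens = kde.score_samples(x)
        cutoff = np.quantile(logdens, config.kde_quantile)
        flags = logdens < cutoff
    return LabelMask(np.asarray(flags, dtype=bool))


def sliding_window_length(n: int, window_fraction: float) -> int:
    """Window length: round half-up of ``fraction * n``, at least 3 points."""
    return max(3, int(np.floor(window_fraction * n + 0.5)))


def detect_sliding_window(
    series: HRSeries,
    window_fraction: float = 0.03,
    k: float = 3.0,
) -> LabelMask:
    """Flag points more than ``k`` segment SDs from their segment mean.

    The series is partitioned into tumbling (non-overlapping) windows of
    ``round(window_fraction * N)`` points (minimum 3); a trailing remainder
    shorter than one window merges into the last full window. The SD is the
    population SD of the segment, and the inequality is strict, so a
    zero-variance segment flags nothing.
    """
    n = len(series)
    m = sliding_window_length(n, window_fraction)
    if n < m:
        raise CapacityError(f"series of {n} points is shorter than one window ({m})")
    flags = np.zeros(n, dtype=bool)
    n_win = n // m
    for w in range(n_win):
        start = w * m
        stop = (w + 1) * m if w < n_win - 1 else n  # remainder merges into last
        seg = series.bpm[start:stop]
        mu, sd = seg.mean(), seg.std()
        flags[start:stop] = np.abs(seg - mu) > k * sd
    return LabelMask(flags)


def label_anomalies(
    series: HRSeries, config: LabelerConfig | None = None
) -> LabelMask:
    """Run the full ensemble labeling rule on one (trimmed) night.

    Returns the combined mask ``(IF & OCSVM & KDE) | SW`` with the four
    per-detector sub-masks stored under ``mask.source``.
    """
    config = config or LabelerConfig()
    a_if = detect_unsupervised(series, "if", config).flags
    a_ocsvm = detect_unsupervised(series, "ocsvm", config).flags
    a_kde = detect_unsupervised(series, "kde", config).flags
    a_sw = detect_sliding_window(series, config.sw_window_fraction, config.sw_k).flags
    final = (a_if & a_ocsvm & a_kde) | a_sw
    return LabelMask(
        final, {"if": a_if, "ocsvm": a_ocsvm, "kde": a_kde, "sw": a_sw}
    )


def clean_training(series: HRSeries, mask: LabelMask) -> HRSeries:
    """Replace labeled anomalous values with the previous non-anomalous value.

    A flagged run inherits the value of its nearest preceding clean point; a
    flagged series head takes the first subsequent clean value instead.
    """
    flags = mask.flags
    if len(flags) != len(series):
        raise ConfigurationError("mask length does not match series length")
    if flags.all():
        raise DegenerateSeriesError("all points flagged: no clean anchor value")
    bpm = series.bpm.copy()
    clean_idx = np.flatnonzero(~flags)
    # forward fill: index of the most recent clean point at or before i
    last_clean = np.maximum.accumulate(
        np.where(~flags, np.arange(len(flags)), -1)
    )
    head = last_clean < 0  # flagged run at the series head
    bpm[~head] = series.bpm[last_clean[~head]]
    bpm[head] = series.bpm[clean_idx[0]]
    return series.with_bpm(bpm)


def build_split(
    nights: list[tuple[HRSeries, LabelMask]],
) -> SplitDataset:
    """Split labeled nights 5/1/1 by night order and clean the training nights.

    Nights 0-4 are cleaned with their masks and become training data; night 5
    is the validation night and night 6 the test night (their masks are kept
    for evaluation). Extra nights beyond the first 7 are ignored.
    """
    if len(nights) < 7:
        raise ConfigurationError(
            f"need at least 7 labeled nights for a 5/1/1 split, got {len(nights)}"
        )
    nights = sorted(nights, key=lambda sm: sm[0].night_index)[:7]
    train = [(s, m) for s, m in nights[:5]]
    val_s, val_m = nights[5]
    test_s, test_m = nights[6]
    cleaned = [clean_training(s, m) for s, m in train]
    return SplitDataset(
        train_nights=cleaned,
        train_masks=[m for _, m in train],
        validation_night=val_s,
        validation_mask=val_m,
        test_night=test_s,
        test_mask=test_m,
    )


class EnsembleLabeler(BaseEstimator):
    """Estimator-style wrapper around the ensemble labeling rule.

    ``fit`` is stateless (each night is labeled independently);
    ``predict(series)`` returns the combined boolean mask and
    ``label(series)`` the full :class:`LabelMask` with provenance.
    """

    def __init__(
        self,
        if_n_estimators: int = 100,
        if_contamination: float = 0.05,
        ocsvm_nu: float = 0.05,
        ocsvm_gamma="scale",
        kde_bandwidth="silverman",
        kde_quantile: float = 0.05,
        sw_window_fraction: float = 0.03,
        sw_k: float = 3.0,
        feature_mode: str = "value",
        seed: int = 0,
    ):
        self.if_n_estimators = if_n_estimators
        self.if_contamination = if_contamination
        self.ocsvm_nu = ocsvm_nu
        self.ocsvm_gamma = ocsvm_gamma
        self.kde_bandwidth = kde_bandwidth
        self.kde_quantile = kde_quantile
        self.sw_window_fraction = sw_window_fraction
        self.sw_k = sw_k
        self.feature_mode = feature_mode
        self.seed = seed

    def _config(self) -> LabelerConfig:
        return LabelerConfig(
            if_n_estimators=self.if_n_estimators,
            if_contamination=self.if_contamination,
            ocsvm_nu=self.ocsvm_nu,
            ocsvm_gamma=self.ocsvm_gamma,
            kde_bandwidth=self.kde_bandwidth,
            kde_quantile=self.kde_quantile,
            sw_window_fraction=self.sw_window_fraction,
            sw_k=self.sw_k,
            feature_mode=self.feature_mode,
            seed=self.seed,
        )

    def fit(self, X=None, y=None):
        self._config().validate()
        self.n_features_in_ = 1
        return self

    def label(self, series: HRSeries) -> LabelMask:
        return label_anomalies(series, self._config())

    def predict(self, series: HRSeries) -> np.ndarray:
        return self.label(series).flags
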