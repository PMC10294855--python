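"""Thresholding, point-adjusted metrics, run aggregation and latent mapping.

All detectors in this package score a night with per-point squared forecast
errors; a point is alerted when its score exceeds

    threshold = mean(train squared errors) + k * sd(train squared errors),

with ``k`` tuned on the validation night. Performance is summarised with
precision, recall and F1,

    precision = TP/(TP+FP),  recall = TP/(TP+FN),  F1 = 2TP/(2TP+FP+FN),

optionally after *segment adjustment*: for real alerting it is enough to hit
any point of a contiguous anomalous segment, so when a prediction touches a
true segment, every point of that segment counts as detected. False positives
outside true segments remain counted pointwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "ThresholdRule",
    "ConfusionCounts",
    "MetricResult",
    "RunSummary",
    "DEFAULT_K_GRID",
    "compute_threshold",
    "tune_k",
    "adjust_predictions",
    "compute_metrics",
    "aggregate_runs",
    "map_latent_tsne",
    "latent_dispersion",
]

#: default grid for the threshold multiplier k
DEFAULT_K_GRID = (1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class ThresholdRule:
    k: float
    mean_train_sqerr: float
    sd_train_sqerr: float

    @property
    def threshold(self) -> float:
        return self.mean_train_sqerr + self.k * self.sd_train_sqerr


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int
    mode: str = "raw"  # "raw" or "adjusted"

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricResult:
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    undefined: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class RunSummary:
    """Per-metric mean and SD over repeated runs; per-run values retained."""

    means: dict[str, float]
    sds: dict[str, float]
    per_run: dict[str, np.ndarray]
    n_runs: int


def compute_threshold(train_scores: np.ndarray, k: float) -> ThresholdRule:
    """Threshold rule from the squared-error distribution on training data."""
    scores = np.asarray(train_scores, dtype=float)
    scores = scores[np.isfinite(scores)]
    if scores.size < 2:
        raise ConfigurationError("need at least 2 finite training scores")
    return ThresholdRule(
        k=float(k),
        mean_train_sqerr=float(scores.mean()),
        sd_train_sqerr=float(scores.std()),
    )


def adjust_predictions(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Segment-adjust predictions against true anomalous runs.

    For every maximal contiguous run of true anomalies, if the prediction
    flags at least one point inside the run, the whole run becomes flagged.
    Predictions outside true runs are unchanged. Idempotent and monotone
    (``pred`` is a subset of the output).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ConfigurationError("pred and truth must have equal lengths")
    out = pred.copy()
    from .datatypes import _runs

    for a, b in _runs(truth):
        if pred[a:b].any():
            out[a:b] = True
    return out


def compute_metrics(
    pred: np.ndarray, truth: np.ndarray, adjusted: bool = False
) -> MetricResult:
    """Precision/recall/F1 with optional segment adjustment applied first.

    Zero-denominator ratios are reported as 0 and recorded in ``undefined``.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ConfigurationError("pred and truth must have equal lengths")
    if adjusted:
        pred = adjust_predictions(pred, truth)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    undefined = []
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    if tp + fp == 0:
        undefined.append("precision")
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    if tp + fn == 0:
        undefined.append("recall")
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else 0.0
    if 2 * tp + fp + fn == 0:
        undefined.append("f1")
    return MetricResult(
        precision=precision,
        recall=recall,
        f1=f1,
        counts=ConfusionCounts(tp, fp, fn, tn, "adjusted" if adjusted else "raw"),
        undefined=tuple(undefined),
    )


def tune_k(
    validation_scores: np.ndarray,
    validation_mask: np.ndarray,
    k_grid=DEFAULT_K_GRID,
    *,
    mean_sqerr: float,
    sd_sqerr: float,
    adjusted: bool = True,
) -> float:
    """Pick the threshold multiplier maximizing (adjusted) F1 on validation.

    Ties favour the larger ``k`` (fewer alerts). With no anomalies in the
    validation mask the choice is vacuous: a warning is issued and the
    largest ``k`` returned.
    """
    k_grid = sorted(float(k) for k in k_grid)
    if not k_grid:
        raise ConfigurationError("k_grid must be non-empty")
    scores = np.asarray(validation_scores, dtype=float)
    truth = np.asarray(validation_mask, dtype=bool)
    if not truth.any():
        warnings.warn(
            "validation night contains no anomalies; returning largest k",
            stacklevel=2,
        )
        return k_grid[-1]
    best_k, best_f1 = k_grid[-1], -1.0
    for k in k_grid:
        thr = mean_sqerr + k * sd_sqerr
        with np.errstate(invalid="ignore"):
            pred = scores > thr
        pred &= np.isfinite(scores)
        f1 = compute_metrics(pred, truth, adjusted=adjusted).f1
        if f1 >= best_f1:  # ascending grid: later (larger) k wins ties
            best_f1, best_k = f1, k
    return best_k


def aggregate_runs(per_run_metrics: list[dict[str, float]]) -> RunSummary:
    """Mean and SD per metric over repeated runs (population SD)."""
    if not per_run_metrics:
        raise ConfigurationError("no runs to aggregate")
    keys = list(per_run_metrics[0].keys())
    per_run = {k: np.array([m[k] for m in per_run_metrics], float) for k in keys}
    # identical runs must report an exact zero SD (mean subtraction can
    # otherwise leave ~1e-16 residue)
    return RunSummary(
        means={k: float(v.mean()) for k, v in per_run.items()},
        sds={k: 0.0 if np.ptp(v) == 0 else float(v.std()) for k, v in per_run.items()},
        per_run=per_run,
        n_runs=len(per_run_metrics),
    )


def _minmax_scale(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=0, keepdims=True)
    rng = x.max(axis=0, keepdims=True) - lo
    rng = np.where(rng == 0, 1.0, rng)
    return (x - lo) / rng


def map_latent_tsne(
    embeddings: np.ndarray,
    labels: np.ndarray | None = None,
    seed: int = 0,
    perplexity: float = 5.0,
):
    """t-SNE map of latent embeddings, min-max scaled to the unit square.

    Returns ``(coords, labels)`` where coords spans [0, 1] on each axis
    (removing the influence of the original latent scale). Labels, when
    given, are passed through for plotting normal vs abnormal windows.
    """
    from sklearn.manifold import TSNE

    emb = np.asarray(embeddings, dtype=float)
    if emb.ndim != 2 or len(emb) < 5:
        raise ConfigurationError("need at least 5 embedding vectors")
    if perplexity >= len(emb):
        raise ConfigurationError("perplexity must be smaller than the embedding count")
    coords = TSNE(
        n_components=2,
        perplexity=perplexity,
        random_state=seed,
        init="pca",
    ).fit_transform(emb)
    return _minmax_scale(coords), labels


def latent_dispersion(embeddings: np.ndarray) -> float:
    """Mean nearest-neighbour distance of min-max scaled embeddings.

    Measures how dense the latent point cloud is: tight clusters give tiny
    nearest-neighbour distances whatever their separation, while a cloud
    spread evenly through the occupied latent box gives large ones. The
    per-dimension min-max scaling mirrors the unit-square normalization used
    for latent maps, removing the influence of the original latent scale.
    """
    from scipy.spatial.distance import squareform, pdist

    emb = np.asarray(embeddings, dtype=float)
    if len(emb) < 2:
        raise ConfigurationError("need at least 2 embeddings")
    dm = squareform(pdist(_minmax_scale(emb)))
    np.fill_diagonal(dm, np.inf)
    return float(dm.min(axis=1).mean())
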