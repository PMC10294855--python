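"""Common forecasting-detector contract.

Every detector is fitted on cleaned training nights, forecasts the heart-rate
signal (one step or one window ahead), and scores each point of a night with
the squared error between forecast and observation. Points without enough
history are unscorable and carry NaN scores. A point is alerted when its
score exceeds ``mean + k*sd`` of the training-score distribution; ``k`` is
tuned on the validation night by maximizing segment-adjusted F1.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ..datatypes import HRSeries
from ..evaluation import DEFAULT_K_GRID, compute_threshold, tune_k

__all__ = ["BaseHRDetector", "as_bpm_array"]


def as_bpm_array(night) -> np.ndarray:
    """Accept an HRSeries or a bare 1-D array of BPM values."""
    if isinstance(night, HRSeries):
        return night.bpm
    return np.asarray(night, dtype=float)


class BaseHRDetector(BaseEstimator):
    """Template for squared-error forecasting detectors.

    Subclasses implement ``_fit_model(train_arrays)`` and
    ``_score_array(bpm) -> scores`` (NaN where unscorable) and may use the
    fitted standardization helpers ``_to_std`` / ``_from_std``.
    """

    # subclasses define __init__ with their own hyperparameters, including
    # ``k`` (threshold multiplier) and ``random_state``

    def _rng(self) -> np.random.Generator:
        return np.random.default_rng(getattr(self, "random_state", 0))

    # -------------------------------------------------------- normalization
    def _fit_scaler(self, arrays: list[np.ndarray]) -> None:
        if getattr(self, "standardize", True):
            concat = np.concatenate(arrays)
            self.center_ = float(concat.mean())
            sd = float(concat.std())
            self.scale_ = sd if sd > 1e-8 else 1.0
        else:
            self.center_, self.scale_ = 0.0, 1.0

    def _to_std(self, x: np.ndarray) -> np.ndarray:
        return (x - self.center_) / self.scale_

    def _from_std(self, x: np.ndarray) -> np.ndarray:
        return x * self.scale_ + self.center_

    # --------------------------------------------------------------- fitting
    def fit(self, train_nights, validation=None):
        """Fit on cleaned training nights.

        Parameters
        ----------
        train_nights : list of HRSeries or 1-D arrays
            Anomaly-free (cleaned) nights.
        validation : optional (series, truth_mask) pair
            When given, the threshold multiplier ``k`` is tuned on it after
            fitting.
        """
        arrays = [as_bpm_array(n) for n in train_nights]
        self._fit_scaler(arrays)
        self._fit_model(arrays)
        train_scores = np.concatenate([self._score_array(a) for a in arrays])
        self.train_scores_ = train_scores
        rule = compute_threshold(train_scores, getattr(self, "k", 3.0))
        self.k_ = rule.k
        self.mean_train_sqerr_ = rule.mean_train_sqerr
        self.sd_train_sqerr_ = rule.sd_train_sqerr
        self.threshold_ = rule.threshold
        if validation is not None:
            series, mask = validation
            self.tune_threshold(series, mask)
        return self

    # --------------------------------------------------------------- scoring
    def score_samples(self, night) -> np.ndarray:
        """Per-point squared forecast errors (NaN where unscorable)."""
        self._check_fitted()
        return self._score_array(as_bpm_array(night))

    def predict(self, night) -> np.ndarray:
        """Boolean anomaly mask; unscorable points are never flagged."""
        scores = self.score_samples(night)
        with np.errstate(invalid="ignore"):
            flags = scores > self.threshold_
        return flags & np.isfinite(scores)

    def tune_threshold(self, series, mask, k_grid=DEFAULT_K_GRID) -> float:
        """Tune ``k`` on a validation night by segment-adjusted F1."""
        self._check_fitted()
        scores = self.score_samples(series)
        flags = mask.flags if hasattr(mask, "flags") else np.asarray(mask, bool)
        best = tune_k(
            scores,
            flags,
            k_grid,
            mean_sqerr=self.mean_train_sqerr_,
            sd_sqerr=self.sd_train_sqerr_,
        )
        self.k_ = best
        self.threshold_ = self.mean_train_sqerr_ + best * self.sd_train_sqerr_
        return best

    def _check_fitted(self) -> None:
        if not hasattr(self, "threshold_"):
            raise RuntimeError(
                f"{type(self).__name__} is not fitted; call fit() first"
            )

    # --------------------------------------------------------- checkpointing
    #: fitted scalar attributes persisted alongside the weights
    _scalar_state = (
        "center_",
        "scale_",
        "threshold_",
        "k_",
        "mean_train_sqerr_",
        "sd_train_sqerr_",
    )

    def save(self, path) -> None:
        """Write a checkpoint: weights (.npz) plus JSON config/state sidecar."""
        import json
        from pathlib import Path

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        params = self._parameters()
        np.savez(path.with_suffix(".npz"), **{f"w{i}": p.data for i, p in enumerate(params)})
        meta = {
            "class": type(self).__name__,
            "params": self.get_params(),
            "state": {
                k: getattr(self, k) for k in self._scalar_state if hasattr(self, k)
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=float))

    @classmethod
    def load(cls, path):
        """Restore a checkpoint written by :meth:`save`."""
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        init = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in meta["params"].items()
        }
        det = cls(**init)
        for k, v in meta["state"].items():
            setattr(det, k, v)
        det._build_models(det._rng())
        data = np.load(path.with_suffix(".npz"))
        for i, p in enumerate(det._parameters()):
            p.data = data[f"w{i}"]
        return det

    # ------------------------------------------------------------- interface
    def _fit_model(self, arrays: list[np.ndarray]) -> None:  # pragma: no cover
        raise NotImplementedError

    def _score_array(self, bpm: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def _build_models(self, rng) -> None:  # pragma: no cover - nn subclasses only
        raise NotImplementedError

    def _parameters(self):  # pragma: no cover - nn subclasses only
        raise NotImplementedError
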