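"""ARIMA forecasting detector with ADF stationarity check and AIC order search.

The ARIMA(p, d, q) model expresses the d-th difference of the series as a
linear combination of p lagged observations and q lagged innovations. Sleep
heart-rate series pass the augmented Dickey-Fuller (ADF) stationarity test,
so d = 0 and the model reduces to ARMA(p, q); (p, q) is selected by grid
search on the Akaike information criterion. Fitting has no stochastic
component, so repeated runs on the same data give identical scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.arima.model import ARIMA
from statsmodels.tsa.stattools import adfuller

from ..errors import CapacityError, DegenerateSeriesError, ModelFitError
from .base import BaseHRDetector, as_bpm_array

__all__ = ["ArimaOrder", "adf_check", "select_arma_order", "arima_score", "ArimaDetector"]


@dataclass(frozen=True)
class ArimaOrder:
    p: int
    d: int
    q: int
    aic: float = np.nan

    @property
    def order(self) -> tuple[int, int, int]:
        return (self.p, self.d, self.q)


def adf_check(series, alpha: float = 0.05):
    """Augmented Dickey-Fuller unit-root test.

    Returns ``(statistic, p_value, is_stationary)`` where stationarity is
    claimed when the unit-root null is rejected at level ``alpha``; a
    stationary verdict justifies d = 0.
    """
    x = as_bpm_array(series)
    if len(x) < 20:
        raise CapacityError("ADF check needs at least 20 points")
    if np.ptp(x) == 0:
        raise DegenerateSeriesError(
            "constant series: stationarity is undetermined (zero variance)"
        )
    stat, pvalue = adfuller(x, autolag="AIC")[:2]
    return float(stat), float(pvalue), bool(pvalue < alpha)


def select_arma_order(series, max_p: int = 5, max_q: int = 5) -> ArimaOrder:
    """Grid-search (p, q) minimizing AIC for a stationary series.

    Ties favour smaller p+q, then smaller p (candidates are visited in that
    priority order and replaced only on strict AIC improvement).
    """
    x = as_bpm_array(series)
    candidates = sorted(
        ((p, q) for p in range(max_p + 1) for q in range(max_q + 1)),
        key=lambda pq: (pq[0] + pq[1], pq[0]),
    )
    best: ArimaOrder | None = None
    failures: list[str] = []
    for p, q in candidates:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = ARIMA(x, order=(p, 0, q)).fit()
            aic = float(res.aic)
        except Exception as exc:  # statsmodels raises a mix of types
            failures.append(f"({p},0,{q}): {exc}")
            continue
        if not np.isfinite(aic):
            failures.append(f"({p},0,{q}): non-finite AIC")
            continue
        if best is None or aic < best.aic:
            best = ArimaOrder(p, 0, q, aic)
    if best is None:
        raise ModelFitError(
            "all ARMA fits failed:\n" + "\n".join(failures)
        )
    return best


def arima_score(series, fitted_results) -> np.ndarray:
    """Per-point squared one-step-ahead prediction errors under fitted params."""
    x = as_bpm_array(series)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        applied = fitted_results.apply(x, refit=False)
        pred = applied.get_prediction(dynamic=False).predicted_mean
    return (x - np.asarray(pred)) ** 2


class ArimaDetector(BaseHRDetector):
    """ARMA one-step-ahead forecaster scored by squared residuals.

    ``order=None`` triggers AIC order selection on the concatenated cleaned
    training nights (fit once across nights, not per night). Deterministic:
    repeated runs yield identical metrics.
    """

    def __init__(
        self,
        order: tuple[int, int, int] | None = None,
        max_p: int = 5,
        max_q: int = 5,
        adf_alpha: float = 0.05,
        k: float = 3.0,
        random_state: int = 0,
    ):
        self.order = order
        self.max_p = max_p
        self.max_q = max_q
        self.adf_alpha = adf_alpha
        self.k = k
        self.random_state = random_state

    standardize = False  # ARIMA operates on the raw BPM scale

    def _fit_model(self, arrays: list[np.ndarray]) -> None:
        x = np.concatenate(arrays)
        self.adf_ = adf_check(x, self.adf_alpha)
        if self.order is not None:
            self.order_ = ArimaOrder(*self.order)
        else:
            self.order_ = select_arma_order(x, self.max_p, self.max_q)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                self.result_ = ARIMA(x, order=self.order_.order).fit()
        except Exception as exc:
            raise ModelFitError(f"ARIMA{self.order_.order} fit failed: {exc}") from exc

    def _score_array(self, bpm: np.ndarray) -> np.ndarray:
        return arima_score(bpm, self.result_)
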