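"""Forecasting anomaly detectors sharing a common fit/score/predict contract."""

from .arima import ArimaDetector, ArimaOrder, adf_check, arima_score, select_arma_order
from .base import BaseHRDetector
from .cae import Cae, CaeLstmDetector, fit_cae
from .lstm import LstmDetector, make_forecast_windows
from .vae import (
    VaeBiLstm,
    VaeBiLstmDetector,
    WindowBatch,
    make_windows,
    reparameterize,
    vae_loss,
)

__all__ = [
    "BaseHRDetector",
    "ArimaDetector",
    "ArimaOrder",
    "adf_check",
    "select_arma_order",
    "arima_score",
    "LstmDetector",
    "make_forecast_windows",
    "Cae",
    "fit_cae",
    "CaeLstmDetector",
    "VaeBiLstm",
    "VaeBiLstmDetector",
    "WindowBatch",
    "make_windows",
    "reparameterize",
    "vae_loss",
]


def build_detector(name: str, **overrides):
    """Construct a detector by its benchmark name.

    Names: ``arima``, ``lstm``, ``bilstm``, ``cae-lstm``, ``vae-bilstm``.
    """
    name = name.lower()
    if name == "arima":
        return ArimaDetector(**overrides)
    if name == "lstm":
        return LstmDetector(bidirectional=False, **overrides)
    if name == "bilstm":
        return LstmDetector(bidirectional=True, **overrides)
    if name in ("cae-lstm", "cae_lstm"):
        return CaeLstmDetector(**overrides)
    if name in ("vae-bilstm", "vae_bilstm"):
        return VaeBiLstmDetector(**overrides)
    raise ValueError(f"unknown detector {name!r}")
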