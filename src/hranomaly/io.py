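"""CSV/JSON persistence for nights, label masks and anomaly scores.

One night is one CSV with columns ``timestamp_s,bpm[,label]`` plus an optional
JSON sidecar recording the generating profile/spec. Detector provenance masks
are persisted as ``timestamp_s,if,ocsvm,kde,sw,final``; scores as
``timestamp_s,score``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import HRSeries, LabelMask

__all__ = [
    "write_night_csv",
    "read_night_csv",
    "write_mask_csv",
    "read_mask_csv",
    "write_embeddings_csv",
    "write_scores_csv",
    "read_scores_csv",
]


def write_night_csv(
    path: str | Path,
    series: HRSeries,
    mask: LabelMask | None = None,
    profile=None,
    spec=None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {"timestamp_s": series.t, "bpm": series.bpm}
    if mask is not None:
        data["label"] = mask.flags.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)
    if profile is not None or spec is not None:
        sidecar = {
            "participant_id": series.participant_id,
            "night_index": series.night_index,
        }
        if profile is not None:
            sidecar["profile"] = dataclasses.asdict(profile)
        if spec is not None:
            sidecar["spec"] = dataclasses.asdict(spec)
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_night_csv(
    path: str | Path,
    participant_id: str | None = None,
    night_index: int | None = None,
) -> tuple[HRSeries, LabelMask | None]:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    series = HRSeries(
        participant_id=participant_id or meta.get("participant_id", path.stem),
        night_index=night_index if night_index is not None else meta.get("night_index", 0),
        t=df["timestamp_s"].to_numpy(float),
        bpm=df["bpm"].to_numpy(float),
    )
    mask = None
    if "label" in df.columns:
        mask = LabelMask(df["label"].to_numpy(int).astype(bool))
    return series, mask


def write_mask_csv(path: str | Path, series: HRSeries, mask: LabelMask) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {"timestamp_s": series.t}
    for name in ("if", "ocsvm", "kde", "sw"):
        if mask.source and name in mask.source:
            data[name] = mask.source[name].astype(int)
    data["final"] = mask.flags.astype(int)
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def read_mask_csv(path: str | Path) -> LabelMask:
    df = pd.read_csv(path)
    source = {
        c: df[c].to_numpy(int).astype(bool)
        for c in ("if", "ocsvm", "kde", "sw")
        if c in df.columns
    }
    return LabelMask(df["final"].to_numpy(int).astype(bool), source or None)


def write_embeddings_csv(
    path: str | Path,
    mu: np.ndarray,
    sigma2: np.ndarray,
    labels: np.ndarray | None = None,
) -> Path:
    """Persist per-window latent posteriors: window_index, mu_*, sigma2_*."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = mu.shape[1]
    data = {"window_index": np.arange(len(mu))}
    for j in range(d):
        data[f"mu_{j + 1}"] = mu[:, j]
    for j in range(d):
        data[f"sigma2_{j + 1}"] = sigma2[:, j]
    if labels is not None:
        data["label"] = np.asarray(labels).astype(int)
    pd.DataFrame(data).to_csv(path, index=False)
    return path


def write_scores_csv(path: str | Path, t: np.ndarray, scores: np.ndarray) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"timestamp_s": t, "score": scores}).to_csv(path, index=False)
    return path


def read_scores_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["timestamp_s"].to_numpy(float), df["score"].to_numpy(float)
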