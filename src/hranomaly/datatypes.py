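"""Core in-memory containers for nocturnal heart-rate data.

A night of data is a univariate, evenly sampled beats-per-minute (BPM) series.
``HRSeries`` carries the samples with timestamps anchored at the start of the
night; ``LabelMask`` carries per-point boolean anomaly labels, optionally with
per-detector sub-masks recording provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["HRSeries", "LabelMask"]


@dataclass
class HRSeries:
    """One night of evenly sampled heart-rate values.

    Parameters
    ----------
    participant_id : str
        Opaque participant identifier.
    night_index : int
        Zero-based index of the night within the participant's record.
    t : ndarray of float
        Timestamps in seconds from night start; uniform spacing.
    bpm : ndarray of float
        Heart rate in beats per minute, strictly positive and finite.
    """

    participant_id: str
    night_index: int
    t: np.ndarray
    bpm: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.t.ndim != 1 or self.bpm.ndim != 1:
            raise ConfigurationError("t and bpm must be one-dimensional")
        if len(self.t) != len(self.bpm):
            raise ConfigurationError(
                f"t and bpm lengths differ: {len(self.t)} != {len(self.bpm)}"
            )
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if not np.all(steps > 0):
                raise ConfigurationError("timestamps must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ConfigurationError("timestamps must be uniformly spaced")
        if not np.all(np.isfinite(self.bpm)):
            raise ConfigurationError("bpm values must be finite")
        if np.any(self.bpm <= 0):
            raise ConfigurationError("bpm values must be positive")
        if self.night_index < 0:
            raise ConfigurationError("night_index must be >= 0")

    def __len__(self) -> int:
        return len(self.bpm)

    @property
    def interval_seconds(self) -> float:
        """Sampling interval in seconds (0 for a single-point series)."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[1] - self.t[0])

    def with_bpm(self, bpm: np.ndarray) -> "HRSeries":
        return replace(self, bpm=np.asarray(bpm, dtype=float))

    def slice(self, start: int, stop: int) -> "HRSeries":
        """Return points ``[start, stop)`` with timestamps re-anchored to 0."""
        t = self.t[start:stop]
        return replace(self, t=t - (t[0] if len(t) else 0.0), bpm=self.bpm[start:stop])


@dataclass
class LabelMask:
    """Per-point boolean anomaly labels with optional per-detector provenance."""

    flags: np.ndarray
    source: dict[str, np.ndarray] | None = field(default=None)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ConfigurationError("flags must be one-dimensional")
        if self.source is not None:
            self.source = {k: np.asarray(v, dtype=bool) for k, v in self.source.items()}
            for name, sub in self.source.items():
                if len(sub) != len(self.flags):
                    raise ConfigurationError(
                        f"source mask {name!r} length {len(sub)} != {len(self.flags)}"
                    )

    def __len__(self) -> int:
        return len(self.flags)

    def slice(self, start: int, stop: int) -> "LabelMask":
        src = None
        if self.source is not None:
            src = {k: v[start:stop] for k, v in self.source.items()}
        return LabelMask(self.flags[start:stop], src)

    def n_anomalies(self) -> int:
        return int(self.flags.sum())

    def segments(self) -> list[tuple[int, int]]:
        """Maximal contiguous runs of flagged points as ``(start, stop)`` pairs."""
        return _runs(self.flags)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.concatenate([[False], flags, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), stops.tolist()))
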