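"""Seeded synthetic generator for nocturnal heart-rate nights.

The study data these models target — sleep-time mean heart rate from a wrist
wearable, sampled every 30 s or every minute — are private, so this module
emulates them with a transparent generative model whose ground truth is known:

* a smooth overnight drift (slow sinusoid, a few BPM),
* piecewise-constant level shifts standing in for sleep-stage changes,
* AR(1) noise for short-range autocorrelation,

plus injected anomalies of the two kinds the detectors must find: *global*
outliers pushed outside the night's overall range, and *contextual* outliers
that stay inside the global range but sit several local standard deviations
away from their neighbourhood mean.

Every function is a pure function of its arguments including seeds, so any
downstream result is exactly reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .datatypes import HRSeries, LabelMask, _runs
from .errors import CapacityError, ConfigurationError

__all__ = [
    "NightProfile",
    "AnomalySpec",
    "simulate_night",
    "inject_anomalies",
    "simulate_participant",
]

#: samples inside this many minutes of either edge never host injected anomalies,
#: so that edge trimming cannot remove ground-truth segments
EDGE_GUARD_MINUTES = 30

#: uniform range (BPM) for the magnitude of one sleep-stage level shift
STAGE_SHIFT_RANGE = (1.0, 2.5)


@dataclass(frozen=True)
class NightProfile:
    """Generative parameters for one clean (anomaly-free) night.

    Defaults describe a typical adult nocturnal recording: a 7-hour night at
    1-min sampling, resting level ~62 BPM, a ~4 BPM slow drift, three
    sleep-stage level shifts and mildly autocorrelated noise.
    """

    duration_minutes: int = 420
    interval_seconds: int = 60
    baseline_bpm: float = 62.0
    drift_amplitude_bpm: float = 4.0
    n_stage_shifts: int = 3
    noise_sd_bpm: float = 1.2
    ar_coefficient: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if self.duration_minutes <= 0:
            raise ConfigurationError("duration_minutes must be positive")
        if self.interval_seconds not in (30, 60):
            raise ConfigurationError("interval_seconds must be 30 or 60")
        n = self.duration_minutes * 60 / self.interval_seconds
        if n != int(n) or int(n) < 2:
            raise ConfigurationError(
                "duration_minutes*60/interval_seconds must be an integer >= 2"
            )
        if self.baseline_bpm <= 0:
            raise ConfigurationError("baseline_bpm must be positive")
        if self.drift_amplitude_bpm < 0:
            raise ConfigurationError("drift_amplitude_bpm must be >= 0")
        if self.n_stage_shifts < 0:
            raise ConfigurationError("n_stage_shifts must be >= 0")
        if self.noise_sd_bpm < 0:
            raise ConfigurationError("noise_sd_bpm must be >= 0")
        if not abs(self.ar_coefficient) < 1:
            raise ConfigurationError("ar_coefficient must satisfy |ar| < 1")

    @property
    def n_samples(self) -> int:
        return int(self.duration_minutes * 60 // self.interval_seconds)


@dataclass(frozen=True)
class AnomalySpec:
    """Counts and magnitudes of injected anomalous segments.

    ``n_global`` segments are offset by ``global_magnitude_sd`` times the
    night's overall SD, pushed away from the mean so they leave the clean
    night's [min, max] range. ``n_contextual`` segments are moved to
    ``contextual_magnitude_sd`` local (windowed) SDs from the local mean,
    on whichever side keeps them inside the global range. Segment lengths are
    drawn uniformly from ``segment_length_range``; with the defaults
    (3 + 3 segments of 1-4 points) a night carries ~15 anomalous points,
    matching the anomaly densities the detectors are meant to face.
    """

    n_global: int = 3
    n_contextual: int = 3
    global_magnitude_sd: float = 6.0
    contextual_magnitude_sd: float = 3.5
    segment_length_range: tuple[int, int] = (1, 4)
    seed: int = 0

    def validate(self) -> None:
        if self.n_global < 0 or self.n_contextual < 0:
            raise ConfigurationError("anomaly counts must be >= 0")
        if self.global_magnitude_sd <= 0:
            raise ConfigurationError("global_magnitude_sd must be > 0")
        if self.contextual_magnitude_sd <= 0:
            raise ConfigurationError("contextual_magnitude_sd must be > 0")
        lo, hi = self.segment_length_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("segment_length_range must satisfy 1 <= lo <= hi")


def _night_rng(seed) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed))


def simulate_night(
    profile: NightProfile,
    participant_id: str = "sim",
    night_index: int = 0,
) -> HRSeries:
    """Simulate one clean night of heart-rate samples.

    The clean signal is ``baseline + drift + stage_shifts + AR(1) noise``.
    Deterministic given ``profile.seed``.
    """
    profile.validate()
    n = profile.n_samples
    rng = _night_rng(profile.seed)
    t = np.arange(n, dtype=float) * profile.interval_seconds

    # slow sinusoidal drift: ~one cycle per night with a random phase
    cycles = rng.uniform(0.75, 1.25)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    drift = profile.drift_amplitude_bpm * np.sin(
        2.0 * np.pi * cycles * np.arange(n) / max(n, 1) + phase
    )

    # piecewise-constant sleep-stage level shifts, centred so they do not move
    # the night's mean level
    shifts = np.zeros(n)
    if profile.n_stage_shifts > 0 and n > profile.n_stage_shifts + 1:
        points = rng.choice(
            np.arange(1, n), size=profile.n_stage_shifts, replace=False
        )
        steps = rng.uniform(*STAGE_SHIFT_RANGE, size=profile.n_stage_shifts)
        steps *= rng.choice([-1.0, 1.0], size=profile.n_stage_shifts)
        for p, s in zip(np.sort(points), steps):
            shifts[p:] += s
        shifts -= shifts.mean()

    # stationary AR(1) noise
    noise = np.zeros(n)
    if profile.noise_sd_bpm > 0:
        innov = rng.normal(0.0, profile.noise_sd_bpm, size=n)
        marginal_sd = profile.noise_sd_bpm / np.sqrt(1.0 - profile.ar_coefficient**2)
        noise[0] = rng.normal(0.0, marginal_sd)
        for i in range(1, n):
            noise[i] = profile.ar_coefficient * noise[i - 1] + innov[i]

    bpm = profile.baseline_bpm + drift + shifts + noise
    return HRSeries(participant_id=participant_id, night_index=night_index, t=t, bpm=bpm)


def _place_segments(
    rng: np.random.Generator, n: int, guard: int, lengths: list[int]
) -> list[int]:
    """Choose non-overlapping segment starts, >=1 sample apart, outside the guards."""
    starts: list[int] = []
    placed: list[tuple[int, int]] = []
    lo, hi = guard, n - guard
    for length in lengths:
        if hi - lo < length:
            raise CapacityError(
                f"series of length {n} cannot host a segment of length {length} "
                f"outside the {guard}-sample edge guards"
            )
        for _ in range(10_000):
            s = int(rng.integers(lo, hi - length + 1))
            # require a 1-sample gap so distinct segments never merge
            if all(s + length + 1 <= a or s >= b + 1 for a, b in placed):
                starts.append(s)
                placed.append((s, s + length))
                break
        else:
            raise CapacityError(
                f"could not place {len(lengths)} non-overlapping anomalous segments "
                f"in a series of length {n}"
            )
    return starts


def inject_anomalies(
    series: HRSeries, spec: AnomalySpec
) -> tuple[HRSeries, LabelMask]:
    """Inject global and contextual anomalous segments into a clean night.

    Returns the perturbed series and a truth mask marking exactly the
    perturbed points, with sub-masks ``global``/``contextual`` in
    ``mask.source``. Segments avoid the first/last 30 minutes so edge
    trimming never removes ground truth.
    """
    spec.validate()
    n = len(series)
    guard = int(EDGE_GUARD_MINUTES * 60 // max(series.interval_seconds, 1))
    rng = _night_rng(spec.seed)

    n_seg = spec.n_global + spec.n_contextual
    flags = np.zeros(n, dtype=bool)
    g_mask = np.zeros(n, dtype=bool)
    c_mask = np.zeros(n, dtype=bool)
    if n_seg == 0:
        return series.with_bpm(series.bpm.copy()), LabelMask(
            flags, {"global": g_mask, "contextual": c_mask}
        )

    lo, hi = spec.segment_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(n_seg)]
    kinds = ["global"] * spec.n_global + ["contextual"] * spec.n_contextual
    order = rng.permutation(n_seg)
    starts = _place_segments(rng, n, guard, [lengths[i] for i in order])

    clean = series.bpm
    c_mean = float(clean.mean())
    c_sd = float(clean.std())
    c_min, c_max = float(clean.min()), float(clean.max())
    bpm = clean.copy()

    for start, idx in zip(starts, order):
        length, kind = lengths[idx], kinds[idx]
        sl = slice(start, start + length)
        if kind == "global":
            # push outward from the night mean so the point leaves [min, max]
            sign = 1.0 if clean[start] >= c_mean else -1.0
            bpm[sl] = clean[sl] + sign * spec.global_magnitude_sd * c_sd
            g_mask[sl] = True
        else:
            w = 15  # local neighbourhood half-width (samples)
            a, b = max(0, start - w), min(n, start + length + w)
            local = np.concatenate([clean[a:start], clean[start + length : b]])
            l_mean = float(local.mean())
            l_sd = float(local.std()) if local.std() > 0 else c_sd
            off = spec.contextual_magnitude_sd * l_sd
            up, down = l_mean + off, l_mean - off
            if up <= c_max and (down < c_min or rng.random() < 0.5):
                val = up
            elif down >= c_min:
                val = down
            else:  # no side fits fully: clamp inside the global range
                val = min(max(up, c_min), c_max)
            bpm[sl] = val
            c_mask[sl] = True
        flags[sl] = True

    # ensure positivity of BPM (baseline levels keep this far from binding)
    bpm = np.maximum(bpm, 1.0)
    return series.with_bpm(bpm), LabelMask(
        flags, {"global": g_mask, "contextual": c_mask}
    )


def night_seed(master_seed: int, night_index: int, stream: int = 0) -> int:
    """Stable per-night seed: adding nights never reshuffles earlier ones."""
    ss = np.random.SeedSequence([int(master_seed), int(night_index), int(stream)])
    return int(ss.generate_state(1)[0])


def simulate_participant(
    profile: NightProfile,
    spec: AnomalySpec,
    n_nights: int = 7,
    participant_id: str = "P1",
) -> list[tuple[HRSeries, LabelMask]]:
    """Simulate ``n_nights`` nights sharing a profile but with derived seeds.

    The master seeds are ``profile.seed`` (signal) and ``spec.seed``
    (anomalies); night ``i`` uses counter-derived sub-seeds so each night is
    distinct yet fully reproducible.
    """
    if n_nights < 3:
        raise ConfigurationError(
            "n_nights must be >= 3 to allow a train/validation/test split"
        )
    profile.validate()
    spec.validate()
    out = []
    for i in range(n_nights):
        p = dataclasses.replace(profile, seed=night_seed(profile.seed, i, stream=0))
        s = dataclasses.replace(spec, seed=night_seed(spec.seed, i, stream=1))
        clean = simulate_night(p, participant_id=participant_id, night_index=i)
        out.append(inject_anomalies(clean, s))
    return out


def anomaly_segment_count(mask: LabelMask) -> int:
    """Number of maximal contiguous anomalous runs in a mask."""
    return len(_runs(mask.flags))
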