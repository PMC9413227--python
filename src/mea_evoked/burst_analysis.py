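"""String-method burst detection and spontaneous-activity metrics.

A burst is a maximal run of consecutive spikes on one electrode whose
inter-spike intervals (ISIs) are all at most ``max_isi`` (100 ms) and
which contains at least ``min_spikes`` (5) spikes — the "string" method.
Spontaneous activity is summarised per electrode by the mean firing rate
(MFR, spikes/s), the mean bursting rate (MBR, bursts/min), and the burst
durations (BD, ms, first spike to last spike).  Electrodes with
MFR < 0.1 spikes/s are flagged inactive and excluded from downstream
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import SpikeTrain, ValidationError

__all__ = [
    "Burst",
    "ActivityMetrics",
    "detect_bursts",
    "mean_firing_rate",
    "burst_rate_and_durations",
    "activity_metrics",
    "filter_active",
    "ACTIVE_MFR_THRESHOLD",
]

#: electrodes below this MFR (spikes/s) are considered inactive
ACTIVE_MFR_THRESHOLD = 0.1


@dataclass(frozen=True)
class Burst:
    electrode_id: str
    start: float  # s
    end: float  # s
    n_spikes: int

    @property
    def duration_ms(self) -> float:
        return (self.end - self.start) * 1e3


@dataclass(frozen=True)
class ActivityMetrics:
    electrode_id: str
    mfr: float  # spikes/s
    mbr: float  # bursts/min
    burst_durations: tuple[float, ...] = field(default=())  # ms
    is_active: bool = False


def detect_bursts(
    train: SpikeTrain, min_spikes: int = 5, max_isi: float = 100.0
) -> list[Burst]:
    """Find maximal runs of spikes with all ISIs <= ``max_isi`` ms.

    Runs shorter than ``min_spikes`` are discarded.  Bursts are
    non-overlapping and ordered; every spike belongs to at most one burst.
    """
    t = train.times
    if t.size < min_spikes:
        return []
    max_isi_s = max_isi * 1e-3
    # split at ISIs exceeding the threshold; each segment is a maximal run
    gaps = np.flatnonzero(np.diff(t) > max_isi_s)
    starts = np.concatenate(([0], gaps + 1))
    ends = np.concatenate((gaps, [t.size - 1]))
    bursts = []
    for s, e in zip(starts, ends):
        n = e - s + 1
        if n >= min_spikes:
            bursts.append(Burst(train.electrode_id, float(t[s]), float(t[e]), int(n)))
    return bursts


def mean_firing_rate(train: SpikeTrain) -> float:
    """Spike count divided by the observation window, in spikes/s."""
    if not np.isfinite(train.duration) or train.duration <= 0:
        raise ValidationError("mean_firing_rate requires a finite positive window")
    return len(train) / train.duration


def burst_rate_and_durations(
    bursts: list[Burst], window: float
) -> tuple[float, list[float]]:
    """MBR in bursts/min and burst durations in ms over a window in seconds."""
    if window <= 0:
        raise ValidationError("window must be positive")
    mbr = 60.0 * len(bursts) / window
    durations = [b.duration_ms for b in bursts]
    return mbr, durations


def activity_metrics(
    train: SpikeTrain,
    min_spikes: int = 5,
    max_isi: float = 100.0,
    active_threshold: float = ACTIVE_MFR_THRESHOLD,
) -> ActivityMetrics:
    """Compute MFR, MBR, BD and the activity flag for one electrode."""
    mfr = mean_firing_rate(train)
    bursts = detect_bursts(train, min_spikes=min_spikes, max_isi=max_isi)
    mbr, durations = burst_rate_and_durations(bursts, train.duration)
    return ActivityMetrics(
        electrode_id=train.electrode_id,
        mfr=mfr,
        mbr=mbr,
        burst_durations=tuple(durations),
        is_active=mfr >= active_threshold,
    )


def filter_active(
    metrics: list[ActivityMetrics], threshold: float = ACTIVE_MFR_THRESHOLD
) -> tuple[list[ActivityMetrics], list[ActivityMetrics]]:
    """Partition metrics into (active, inactive) by the MFR cut.

    The rule is strict: an electrode is discarded only when its MFR is
    *lower than* the threshold, so MFR == 0.1 exactly is active.
    """
    active = [m for m in metrics if m.mfr >= threshold]
    inactive = [m for m in metrics if m.mfr < threshold]
    return active, inactive
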