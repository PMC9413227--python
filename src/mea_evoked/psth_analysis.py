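"""Post-Stimulus Time Histogram (PSTH) computation and area filtering.

The PSTH is the impulsive response of one electrode to repeated
stimulation: spike times are referenced to each stimulus, counted in
4 ms bins over a 600 ms window, and divided by the number of stimuli, so
each bin holds mean spikes per stimulus.  The PSTH *area* (sum over
bins, i.e. mean evoked spikes per stimulus in the window) measures how
strongly an electrode responds; electrodes with area < 1 are considered
unresponsive and removed from evoked statistics.  For cross-network
comparison, areas are normalised by the maximum area in scope.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core_model import (
    ElectrodeLayout,
    SpikeTrain,
    StimulationSession,
    ValidationError,
)

__all__ = [
    "Psth",
    "compute_psth",
    "filter_responsive",
    "normalize_areas",
    "area_map",
    "RESPONSIVE_AREA_THRESHOLD",
    "PSTH_WINDOW_MS",
    "PSTH_BIN_MS",
]

PSTH_WINDOW_MS = 600.0
PSTH_BIN_MS = 4.0
#: electrodes whose PSTH area (spikes/stimulus summed over the window)
#: falls below this are unresponsive
RESPONSIVE_AREA_THRESHOLD = 1.0


@dataclass(frozen=True)
class Psth:
    """Per-electrode PSTH: ``values[b]`` is mean spikes/stimulus in bin b."""

    electrode_id: str
    bin_edges: np.ndarray  # ms, length n_bins + 1
    values: np.ndarray  # spikes per stimulus per bin
    n_stimuli: int
    normalized_area: float | None = None
    is_stimulated_electrode: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.size != self.bin_edges.size - 1:
            raise ValidationError("values length must equal len(bin_edges) - 1")
        if np.any(self.values < 0):
            raise ValidationError("PSTH values must be non-negative")

    @property
    def area(self) -> float:
        """Sum of bin values: mean evoked spikes per stimulus in-window."""
        return float(self.values.sum())

    @property
    def raw_count_area(self) -> float:
        """Total evoked spike count (area x n_stimuli)."""
        return self.area * self.n_stimuli

    @property
    def is_responsive(self) -> bool:
        return self.area >= RESPONSIVE_AREA_THRESHOLD

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def compute_psth(
    train: SpikeTrain,
    session: StimulationSession,
    window: float = PSTH_WINDOW_MS,
    bin: float = PSTH_BIN_MS,
) -> Psth:
    """Bin post-stimulus spikes into a PSTH.

    Windows are half-open ``[t_stim, t_stim + window)`` with half-open
    bins, so a spike exactly at a stimulus time lands in bin 0.  Windows
    of distinct stimuli must not overlap (impossible for the 0.2 Hz
    protocol but checked for nonconforming sessions).
    """
    if session.n_stimuli < 1:
        raise ValidationError("session has no stimuli")
    n_bins, rem = divmod(window, bin)
    if rem:
        raise ValidationError(f"window {window} ms not divisible by bin {bin} ms")
    n_bins = int(n_bins)
    stim = session.stimulus_times
    if stim.size > 1 and np.any(np.diff(stim) < window * 1e-3):
        raise ValidationError("post-stimulus windows overlap")
    counts = np.zeros(n_bins)
    w_s = window * 1e-3
    for ts in stim:
        # spike offsets within [0, window), binned at `bin` ms
        lo, hi = np.searchsorted(train.times, [ts, ts + w_s])
        offs_ms = (train.times[lo:hi] - ts) * 1e3
        idx = np.floor(offs_ms / bin).astype(int)
        idx = idx[idx < n_bins]  # guard float edge at exactly `window`
        np.add.at(counts, idx, 1)
    edges = np.arange(n_bins + 1) * bin
    return Psth(
        electrode_id=train.electrode_id,
        bin_edges=edges,
        values=counts / session.n_stimuli,
        n_stimuli=int(session.n_stimuli),
        is_stimulated_electrode=(train.electrode_id == session.stimulated_electrode),
    )


def filter_responsive(
    psths: list[Psth], min_area: float = RESPONSIVE_AREA_THRESHOLD
) -> tuple[list[Psth], list[Psth]]:
    """Partition PSTHs into (responsive, unresponsive) by the area cut.

    Strict rule: removed only when area is *lower than* ``min_area``, so
    an area of exactly 1 is kept.
    """
    kept = [p for p in psths if p.area >= min_area]
    removed = [p for p in psths if p.area < min_area]
    return kept, removed


def normalize_areas(psths: list[Psth], scope_max: float | None = None) -> list[Psth]:
    """Set ``normalized_area = area / max(area)`` over the given scope.

    By default the scope is the supplied list (per recording-session);
    pass ``scope_max`` to normalise against a wider scope, e.g. the
    maximum over a whole dataset.
    """
    if not psths:
        return []
    m = max(p.area for p in psths) if scope_max is None else float(scope_max)
    if m <= 0:
        raise ValidationError("cannot normalise: all PSTH areas are zero")
    return [replace(p, normalized_area=p.area / m) for p in psths]


def area_map(
    psths: list[Psth], layout: ElectrodeLayout
) -> tuple[np.ndarray, np.ndarray]:
    """Spatial matrices of PSTH area and responsiveness.

    Returns ``(areas, responsive)`` of shape ``(n_rows, n_cols)``; grid
    cells without an electrode or without a PSTH hold NaN (areas) and
    False (responsive), which keeps absent electrodes distinct from true
    zero responses.
    """
    known = set(layout.electrode_ids)
    for p in psths:
        if p.electrode_id not in known:
            raise ValidationError(f"unknown electrode {p.electrode_id!r}")
    pitch = layout.pitch
    areas = np.full((layout.n_rows, layout.n_cols), np.nan)
    responsive = np.zeros((layout.n_rows, layout.n_cols), dtype=bool)
    pos = {e: xy for e, xy in zip(layout.electrode_ids, layout.positions)}
    for p in psths:
        x, y = pos[p.electrode_id]
        c, r = int(round(x / pitch)), int(round(y / pitch))
        areas[r, c] = p.area
        responsive[r, c] = p.is_responsive
    return areas, responsive
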