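"""Early/late evoked-response classification of PSTH profiles.

Electrical stimulation of a cultured network evokes up to two response
components on each electrode: an *early* one (first tens of ms,
AMPA-mediated in the pharmacological nomenclature) and a *late* one
(tens to hundreds of ms, NMDA-mediated nomenclature).  This module
separates them per recording-session:

1. k-means clusters the per-electrode PSTHs (150-bin vectors); the
   number of classes is chosen by maximising the mean silhouette score.
2. Each class mean is smoothed with a 50 ms moving average
   (``psth_smooth``).
3. Local maxima of the smoothed profile are scanned: an early peak x1 is
   sought within the first 52 ms; a late peak x2 within (52, 600] ms,
   gated at >= 10% of the early peak's prominence.
4. When both peaks exist, the local minimum x_min between them and a
   separation statistic ``s`` decide whether the class genuinely has a
   late component (``s`` > 0.3).  ``x_min`` then splits each member
   electrode's own smoothed PSTH into early/late latency estimates.
5. Electrodes of early-only classes get the 650 ms sentinel as late
   latency (beyond the 600 ms observation window).

The default ``dip_depth`` separation form is
``s = 1 - v / sqrt(p1 * p2)`` with ``v = psth_smooth(x_min)`` and
``p1, p2`` the smoothed values at the two peaks: 1 for a valley reaching
zero, 0 when the valley equals the geometric mean of the peaks, so s
grows with separation.  A ``literal_ratio`` form
``s = v / (p1 * p2)`` is provided as an alternative reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, peak_prominences
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .core_model import ValidationError
from .psth_analysis import Psth

__all__ = [
    "ClassificationConfig",
    "ResponseClass",
    "LatencyMap",
    "classify_psths",
    "class_mean_and_smooth",
    "moving_average",
    "find_early_late_peaks",
    "separation_statistic",
    "assign_latencies",
    "classify_session",
    "LATE_SENTINEL_MS",
]

#: late latency assigned when no late component exists (beyond the window)
LATE_SENTINEL_MS = 650.0


@dataclass(frozen=True)
class ClassificationConfig:
    """Knobs of the early/late classifier.

    k_range : candidate class counts for k-means (silhouette-selected).
    smoothing_window : ms; moving-average width, realised as a centred
        13-bin (52 ms) window so peak positions are preserved.
    early_limit : ms; the early peak must lie within (0, early_limit].
    prominence_fraction : late-peak prominence gate, as a fraction of the
        early peak's prominence.
    separation_threshold : classes with separation s above this have a
        genuine late component.
    separation_form : "dip_depth" (default) or "literal_ratio".
    normalize_features : cluster on max-normalised profiles instead of raw.
    """

    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    smoothing_window: float = 50.0
    early_limit: float = 52.0
    prominence_fraction: float = 0.10
    separation_threshold: float = 0.3
    separation_form: str = "dip_depth"
    normalize_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.separation_form not in ("dip_depth", "literal_ratio"):
            raise ValueError(f"unknown separation form {self.separation_form!r}")
        if min(self.k_range) < 1:
            raise ValueError("k_range entries must be >= 1")
        if self.early_limit <= 0 or self.smoothing_window <= 0:
            raise ValueError("early_limit and smoothing_window must be > 0")


@dataclass(frozen=True)
class ResponseClass:
    """One k-means class of PSTHs with its early/late characterisation."""

    class_id: int
    member_electrodes: tuple[str, ...]
    mean_psth: np.ndarray
    psth_smooth: np.ndarray
    bin_centers: np.ndarray  # ms
    x1: float | None  # early peak, ms
    x2: float | None  # late peak, ms
    x_min: float | None  # inter-peak local minimum, ms
    s: float | None  # separation statistic
    has_late: bool
    separation_form: str = "dip_depth"

    @property
    def time_threshold(self) -> float | None:
        """Early/late split time for member electrodes (= x_min)."""
        return self.x_min if self.has_late else None

    @property
    def is_responding(self) -> bool:
        """Whether the class shows an early peak at all."""
        return self.x1 is not None


@dataclass(frozen=True)
class LatencyMap:
    """Per-electrode early and late latencies in ms.

    ``late`` holds the 650 ms sentinel for electrodes whose class has no
    late component.
    """

    early: dict[str, float] = field(default_factory=dict)
    late: dict[str, float] = field(default_factory=dict)

    def __getitem__(self, electrode_id: str) -> tuple[float, float]:
        return self.early[electrode_id], self.late[electrode_id]

    @property
    def electrode_ids(self) -> list[str]:
        return sorted(self.early)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def classify_psths(
    psths: list[Psth], config: ClassificationConfig | None = None
) -> tuple[np.ndarray, int]:
    """Cluster PSTH profiles with k-means; silhouette picks k.

    Returns ``(labels, k)`` with labels aligned to the input order and
    relabelled deterministically by order of first appearance.  When all
    profiles are identical (silhouette undefined) a single class is
    returned.
    """
    if config is None:
        config = ClassificationConfig()
    if not psths:
        raise ValidationError("no PSTHs to classify")
    X = np.stack([p.values for p in psths])
    if config.normalize_features:
        m = X.max(axis=1, keepdims=True)
        X = np.divide(X, m, out=np.zeros_like(X), where=m > 0)
    n = X.shape[0]
    n_distinct = len(np.unique(X, axis=0))
    ks = [k for k in config.k_range if 2 <= k <= min(n - 1, n_distinct)]
    if not ks:
        return np.zeros(n, dtype=int), 1
    best_k, best_score, best_labels = 1, -np.inf, np.zeros(n, dtype=int)
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=config.seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score, best_labels = k, score, labels
    if best_k == 1:
        return np.zeros(n, dtype=int), 1
    return _canonical_labels(best_labels), best_k


def _canonical_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..k-1 in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


# ---------------------------------------------------------------------------
# smoothing and peak analysis
# ---------------------------------------------------------------------------


def moving_average(x: np.ndarray, window_bins: int) -> np.ndarray:
    """Centred moving average; edge bins use a shrunken window."""
    if window_bins < 1 or window_bins % 2 == 0:
        raise ValueError("window_bins must be a positive odd integer")
    half = window_bins // 2
    kernel = np.ones(window_bins)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def _window_bins(smoothing_window_ms: float, bin_ms: float) -> int:
    w = int(round(smoothing_window_ms / bin_ms))
    return w + 1 if w % 2 == 0 else w  # force odd length, centred


def class_mean_and_smooth(
    psths: list[Psth], smoothing_window: float = 50.0
) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise mean over class members, then moving-average smoothing."""
    if not psths:
        raise ValidationError("class has no members")
    mean = np.mean([p.values for p in psths], axis=0)
    bin_ms = float(psths[0].bin_edges[1] - psths[0].bin_edges[0])
    smooth = moving_average(mean, _window_bins(smoothing_window, bin_ms))
    return mean, smooth


def _local_maxima(profile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima with endpoint peaks allowed; returns (indices, prominences).

    The profile is padded with a zero on each side (PSTH baseline) so a
    maximum at the first or last bin is detectable and has a finite
    prominence.
    """
    padded = np.concatenate(([0.0], profile, [0.0]))
    idx, _ = find_peaks(padded)
    prom = peak_prominences(padded, idx)[0]
    return idx - 1, prom


def find_early_late_peaks(
    psth_smooth: np.ndarray,
    bin_centers: np.ndarray,
    config: ClassificationConfig | None = None,
) -> tuple[float | None, float | None]:
    """Locate the early peak x1 and, if any, a qualifying late peak x2.

    x1 is the highest local maximum with bin centre in (0, early_limit]
    ms; x2 is the highest local maximum beyond early_limit whose
    prominence reaches ``prominence_fraction`` of x1's.  Either may be
    absent (``None``): no x1 means the class is non-responding.
    """
    if config is None:
        config = ClassificationConfig()
    idx, prom = _local_maxima(np.asarray(psth_smooth, dtype=float))
    if idx.size == 0:
        return None, None
    centers = np.asarray(bin_centers, dtype=float)
    early_mask = centers[idx] <= config.early_limit
    if not np.any(early_mask):
        return None, None
    e_idx = idx[early_mask]
    e_prom = prom[early_mask]
    best_e = np.argmax(psth_smooth[e_idx])
    x1_bin, x1_prom = e_idx[best_e], e_prom[best_e]
    late_mask = (centers[idx] > config.early_limit) & (
        prom >= config.prominence_fraction * x1_prom
    )
    if not np.any(late_mask):
        return float(centers[x1_bin]), None
    l_idx = idx[late_mask]
    x2_bin = l_idx[np.argmax(psth_smooth[l_idx])]
    return float(centers[x1_bin]), float(centers[x2_bin])


def separation_statistic(
    psth_smooth: np.ndarray,
    bin_centers: np.ndarray,
    x1: float,
    x2: float,
    form: str = "dip_depth",
) -> tuple[float, float]:
    """Separation ``s`` between two peaks and the valley location x_min.

    x_min is the argmin of the smoothed profile strictly between x1 and
    x2.  ``dip_depth``: ``s = 1 - v / sqrt(p1 p2)``; ``literal_ratio``:
    ``s = v / (p1 p2)``.
    """
    if not x1 < x2:
        raise ValidationError("separation requires x1 < x2")
    centers = np.asarray(bin_centers, dtype=float)
    profile = np.asarray(psth_smooth, dtype=float)
    p1 = float(profile[np.argmin(np.abs(centers - x1))])
    p2 = float(profile[np.argmin(np.abs(centers - x2))])
    if p1 <= 0 or p2 <= 0:
        raise ValidationError("profile must be positive at both peaks")
    between = np.flatnonzero((centers > x1) & (centers < x2))
    if between.size == 0:
        raise ValidationError("no bins strictly between the peaks")
    v_idx = between[np.argmin(profile[between])]
    v = float(profile[v_idx])
    if form == "dip_depth":
        s = 1.0 - v / float(np.sqrt(p1 * p2))
    elif form == "literal_ratio":
        s = v / (p1 * p2)
    else:
        raise ValueError(f"unknown separation form {form!r}")
    return s, float(centers[v_idx])


# ---------------------------------------------------------------------------
# session-level orchestration
# ---------------------------------------------------------------------------


def characterize_class(
    class_id: int,
    members: list[Psth],
    config: ClassificationConfig,
) -> ResponseClass:
    """Mean + smooth a class and run the early/late peak analysis."""
    mean, smooth = class_mean_and_smooth(members, config.smoothing_window)
    centers = members[0].bin_centers
    x1, x2 = find_early_late_peaks(smooth, centers, config)
    s: float | None = None
    x_min: float | None = None
    has_late = False
    if x1 is not None and x2 is not None:
        s, x_min = separation_statistic(
            smooth, centers, x1, x2, config.separation_form
        )
        has_late = s > config.separation_threshold
        if not has_late:
            x_min = None
    return ResponseClass(
        class_id=class_id,
        member_electrodes=tuple(p.electrode_id for p in members),
        mean_psth=mean,
        psth_smooth=smooth,
        bin_centers=np.asarray(centers, dtype=float),
        x1=x1,
        x2=x2 if has_late else x2,
        x_min=x_min,
        s=s,
        has_late=has_late,
        separation_form=config.separation_form,
    )


def assign_latencies(
    psths: list[Psth],
    classes: list[ResponseClass],
    labels: np.ndarray,
    config: ClassificationConfig | None = None,
) -> LatencyMap:
    """Per-electrode latencies from each electrode's own PSTH.

    The class provides the split point (x_min for has_late classes).
    The early latency is the argmax of the electrode's *raw* PSTH on
    (0, min(early_limit, time_threshold)]: the early component is
    temporally sharp (of the order of one 4 ms bin), so the 50 ms moving
    average would flatten it into a plateau and destroy latency
    precision.  The late component is broad (tens to hundreds of ms),
    so the late latency is the argmax of the *smoothed* PSTH beyond the
    threshold, where smoothing suppresses single-spike noise.  Members
    of non-responding classes (no early class peak) are excluded;
    early-only classes map to the 650 ms sentinel.
    """
    if config is None:
        config = ClassificationConfig()
    if len(labels) != len(psths):
        raise ValidationError("labels do not align with PSTHs")
    by_id = {c.class_id: c for c in classes}
    early: dict[str, float] = {}
    late: dict[str, float] = {}
    for p, lab in zip(psths, labels):
        cls = by_id.get(int(lab))
        if cls is None:
            raise ValidationError(f"electrode {p.electrode_id!r} has no class")
        if not cls.is_responding:
            continue
        centers = p.bin_centers
        early_limit = config.early_limit
        if cls.has_late and cls.time_threshold is not None:
            early_limit = min(early_limit, cls.time_threshold)
        e_idx = np.flatnonzero(centers <= early_limit)
        early[p.electrode_id] = float(centers[e_idx[np.argmax(p.values[e_idx])]])
        if cls.has_late and cls.time_threshold is not None:
            bin_ms = float(p.bin_edges[1] - p.bin_edges[0])
            smooth = moving_average(
                p.values, _window_bins(config.smoothing_window, bin_ms)
            )
            l_idx = np.flatnonzero(centers > cls.time_threshold)
            late[p.electrode_id] = float(centers[l_idx[np.argmax(smooth[l_idx])]])
        else:
            late[p.electrode_id] = LATE_SENTINEL_MS
    return LatencyMap(early=early, late=late)


def classify_session(
    psths: list[Psth], config: ClassificationConfig | None = None
) -> tuple[list[ResponseClass], np.ndarray, LatencyMap]:
    """Full classifier for one session's responsive PSTHs.

    Returns the characterised classes, the per-PSTH labels, and the
    per-electrode latency map.
    """
    if config is None:
        config = ClassificationConfig()
    labels, k = classify_psths(psths, config)
    classes = []
    for j in range(k):
        members = [p for p, lab in zip(psths, labels) if lab == j]
        classes.append(characterize_class(j, members, config))
    latencies = assign_latencies(psths, classes, labels, config)
    return classes, labels, latencies
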