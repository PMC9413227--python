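"""Precise Timing Spike Detection (PTSD) on raw extracellular traces.

Extracellular spikes are brief biphasic voltage excursions riding on
thermal and biological noise.  PTSD detects them with a *differential*
threshold: a spike is a pair of opposite-polarity extrema, occurring
within a short "peak lifetime period" (PLP), whose peak-to-peak amplitude
exceeds a multiple of the noise standard deviation.  The event timestamp
is placed at the extremum of larger absolute amplitude, and a refractory
period suppresses multiple detections of one waveform.

Default parameters: PLP 2 ms, refractory period 1 ms, threshold 8x the
noise SD.  The noise SD is estimated robustly from the median absolute
deviation by default, since spikes inflate an ordinary sample SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.signal import argrelextrema

from .core_model import RawTrace, SpikeTrain, ValidationError

__all__ = ["PtsdParams", "estimate_noise_sd", "detect_spikes_ptsd"]

#: Phi^{-1}(0.75): scales the MAD of a Gaussian to its SD
_MAD_SCALE = 0.6744897501960817


@dataclass(frozen=True)
class PtsdParams:
    """Detector parameters.

    peak_lifetime_period : ms
        Maximum separation between the two opposite-polarity extrema of
        one spike (default 2 ms).
    refractory_period : ms
        Minimum separation between detected spikes (default 1 ms).
    threshold_multiplier : float
        Differential threshold as a multiple of the noise SD (default 8).
    noise_estimator : {"robust_mad", "global_sd"}
        How the per-electrode noise SD is estimated.
    blanking_ms : float
        Optional window after each stimulus during which detections are
        discarded (stimulus-artifact blanking); 0 disables it.
    """

    peak_lifetime_period: float = 2.0
    refractory_period: float = 1.0
    threshold_multiplier: float = 8.0
    noise_estimator: str = "robust_mad"
    blanking_ms: float = 0.0

    def __post_init__(self) -> None:
        if self.peak_lifetime_period <= 0 or self.refractory_period <= 0:
            raise ValueError("peak_lifetime_period and refractory_period must be > 0")
        if self.threshold_multiplier <= 0:
            raise ValueError("threshold_multiplier must be > 0")
        if self.noise_estimator not in ("robust_mad", "global_sd"):
            raise ValueError(f"unknown noise estimator {self.noise_estimator!r}")


def estimate_noise_sd(trace: RawTrace, estimator: str = "robust_mad") -> float:
    """Estimate the noise SD of a trace, in uV.

    ``robust_mad`` returns ``median(|x - median(x)|) / 0.6745``, which is
    insensitive to sparse large-amplitude spikes; ``global_sd`` returns
    the ordinary sample standard deviation.
    """
    x = trace.samples
    if x.size == 0:
        raise ValidationError("cannot estimate noise on an empty trace")
    if estimator == "robust_mad":
        return float(np.median(np.abs(x - np.median(x))) / _MAD_SCALE)
    if estimator == "global_sd":
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0
    raise ValueError(f"unknown noise estimator {estimator!r}")


def _local_extrema(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of local maxima and minima (order-1 neighbourhoods).

    Plateaus keep only their first index, so runs of equal samples do
    not produce duplicate extrema.
    """

    def _dedupe(idx: np.ndarray) -> np.ndarray:
        if idx.size == 0:
            return idx
        # drop indices that directly continue an equal-valued neighbour
        keep = np.ones(idx.size, dtype=bool)
        keep[1:] = ~((np.diff(idx) == 1) & (x[idx[1:]] == x[idx[:-1]]))
        return idx[keep]

    maxima = argrelextrema(x, np.greater_equal, order=1)[0]
    minima = argrelextrema(x, np.less_equal, order=1)[0]
    return _dedupe(maxima), _dedupe(minima)


def detect_spikes_ptsd(
    trace: RawTrace,
    params: PtsdParams | None = None,
    noise_sd: float | None = None,
    stimulus_times: np.ndarray | None = None,
) -> SpikeTrain:
    """Run PTSD on one raw trace and return the detected spike train.

    Each threshold-crossing local extremum is paired with the
    largest-excursion opposite-polarity extremum within the peak lifetime
    period (searched both forward and backward); the pair is accepted when
    its peak-to-peak amplitude exceeds
    ``threshold_multiplier x noise_sd``, and the spike time is the sample
    of the larger-|amplitude| extremum.  Conflicts within the refractory
    period are resolved in favour of the larger peak-to-peak amplitude,
    ties toward the earlier event.

    Parameters
    ----------
    noise_sd
        Override the noise estimate (uV); estimated from the trace when
        omitted.
    stimulus_times
        Stimulus times in seconds; only used when ``params.blanking_ms``
        is positive, to discard detections inside the blanking window.
    """
    if params is None:
        params = PtsdParams()
    x = trace.samples
    fs = trace.sampling_rate
    plp = max(1, int(round(params.peak_lifetime_period * 1e-3 * fs)))
    refr = params.refractory_period * 1e-3
    if x.size < plp:
        raise ValidationError("trace shorter than the peak lifetime period")
    if noise_sd is None:
        noise_sd = estimate_noise_sd(trace, params.noise_estimator)
    thr = params.threshold_multiplier * noise_sd

    all_max, all_min = _local_extrema(x)
    if all_max.size == 0 or all_min.size == 0:
        return SpikeTrain(trace.electrode_id, np.empty(0), 0.0, trace.duration)

    # cheap prefilter: an extremum can only anchor a supra-threshold pair
    # if the peak-to-peak excursion within +-plp around it exceeds thr
    win = 2 * plp + 1
    p2p = maximum_filter1d(x, win) - minimum_filter1d(x, win)
    maxima = all_max[p2p[all_max] > thr]
    minima = all_min[p2p[all_min] > thr]

    # candidate events: (index of larger extremum, peak-to-peak amplitude)
    candidates: list[tuple[int, float]] = []
    for idx_a, partner_pool, sign in ((maxima, all_min, 1.0), (minima, all_max, -1.0)):
        pp = partner_pool
        for i in idx_a:
            lo = np.searchsorted(pp, i - plp)
            hi = np.searchsorted(pp, i + plp + 1)
            if lo == hi:
                continue
            window = pp[lo:hi]
            # opposite extremum with largest excursion from x[i]
            j = window[np.argmin(sign * x[window])]
            amp = abs(x[i] - x[j])
            if amp > thr:
                t_idx = i if abs(x[i]) >= abs(x[j]) else j
                candidates.append((int(t_idx), float(amp)))

    if not candidates:
        return SpikeTrain(trace.electrode_id, np.empty(0), 0.0, trace.duration)

    # dedupe identical timestamps keeping the largest amplitude, then
    # enforce refractoriness keeping the larger-amplitude event
    by_idx: dict[int, float] = {}
    for i, a in candidates:
        if a > by_idx.get(i, -1.0):
            by_idx[i] = a
    events = sorted(by_idx.items())
    accepted: list[tuple[int, float]] = []
    for i, a in events:
        if accepted and (i - accepted[-1][0]) / fs < refr:
            if a > accepted[-1][1]:
                accepted[-1] = (i, a)
        else:
            accepted.append((i, a))
    # a replacement can re-violate refractoriness with its new predecessor;
    # sweep until stable (rare, bounded by event count)
    changed = True
    while changed and len(accepted) > 1:
        changed = False
        out: list[tuple[int, float]] = [accepted[0]]
        for i, a in accepted[1:]:
            if (i - out[-1][0]) / fs < refr:
                changed = True
                if a > out[-1][1]:
                    out[-1] = (i, a)
            else:
                out.append((i, a))
        accepted = out

    times = np.array([i / fs for i, _ in accepted])
    if params.blanking_ms > 0 and stimulus_times is not None and times.size:
        keep = np.ones(times.size, dtype=bool)
        for ts in np.asarray(stimulus_times, dtype=float):
            keep &= ~((times >= ts) & (times < ts + params.blanking_ms * 1e-3))
        times = times[keep]
    return SpikeTrain(trace.electrode_id, times, 0.0, trace.duration)
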