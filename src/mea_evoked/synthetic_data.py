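"""Ground-truthed synthetic MEA recordings for pipeline verification.

The generator is a *statistical emulator*, not a biophysical simulation:
it reproduces the statistical structure the analysis stages assume so
that every stage can be verified against known ground truth.

A synthetic recording follows the experimental protocol: a spontaneous
phase (default 600 s) of homogeneous Poisson background firing plus
injected burst combs, followed by stimulation sessions (default three,
300 s each, one stimulated electrode per compartment) with pulses at
0.2 Hz — 60 stimuli per session.  Per stimulus and electrode, evoked
spikes are drawn from Poisson counts whose rate decays with distance
from the stimulated electrode (on top of a spatially uniform floor), at
latencies that grow linearly with distance plus Gaussian jitter.

Two population profiles mirror the phenomenology of cortical-like and
hippocampal-like cultures: Cx-like networks fire and burst more, respond
almost uniformly across the array, and show a *late* evoked component
(~200 ms); Hp-like networks respond with shorter early latencies, their
response amplitude is concentrated near the stimulation site, and they
have no late component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .core_model import (
    CompartmentMap,
    ElectrodeLayout,
    RawTrace,
    Recording,
    SpikeTrain,
    StimulationSession,
    ValidationError,
    assign_compartments,
    standard_120_layout,
    three_compartment_geometry,
    TIME_DECIMALS,
)

__all__ = [
    "PopulationProfile",
    "SyntheticGroundTruth",
    "cortical_like_profile",
    "hippocampal_like_profile",
    "generate_recording",
    "generate_raw_traces",
    "generate_profile_dataset",
    "make_benchmark_suite",
    "biphasic_template",
]

REFRACTORY_S = 1e-3  # generated trains respect the 1 ms refractory period


@dataclass(frozen=True)
class PopulationProfile:
    """Generative parameters of one population.

    Evoked rates follow
    ``rate(d) = prob * (baseline_fraction + (1 - baseline_fraction) *
    exp(-d / spatial_decay))`` with ``d`` the distance from the
    stimulated electrode in electrode pitches: ``spatial_decay`` sets how
    localised the response is, ``baseline_fraction`` the spatially
    uniform floor that keeps distant electrodes minimally responsive.

    Units: rates in spikes/s, burst_rate in bursts/min, latencies and
    spreads in ms, latency_slope in ms per pitch, probs in expected
    spikes per stimulus.
    """

    label: str
    background_rate: float
    burst_rate: float
    burst_len: int
    burst_isi: float
    early_prob: float
    early_latency0: float
    latency_slope: float
    early_jitter: float
    late_prob: float
    late_latency: float
    late_spread: float
    spatial_decay: float
    baseline_fraction: float

    def __post_init__(self) -> None:
        if min(self.early_prob, self.late_prob, self.background_rate) < 0:
            raise ValidationError("rates and probabilities must be >= 0")
        if not (0 <= self.early_latency0 <= 600 and 0 <= self.late_latency <= 600):
            raise ValidationError("latencies must lie in [0, 600] ms")
        if not 0 <= self.baseline_fraction <= 1:
            raise ValidationError("baseline_fraction must be in [0, 1]")
        if self.spatial_decay <= 0:
            raise ValidationError("spatial_decay must be > 0")

    def evoked_rate(self, prob: float, d: float) -> float:
        return prob * (
            self.baseline_fraction
            + (1.0 - self.baseline_fraction) * np.exp(-d / self.spatial_decay)
        )

    def early_latency(self, d: float) -> float:
        return self.early_latency0 + self.latency_slope * d


def cortical_like_profile() -> PopulationProfile:
    """Cx-like defaults: strong, spatially uniform, with a late component."""
    return PopulationProfile(
        label="Cx-like",
        background_rate=0.5,
        burst_rate=6.0,
        burst_len=10,
        burst_isi=15.0,
        early_prob=1.5,
        early_latency0=10.0,
        latency_slope=1.2,
        early_jitter=2.0,
        late_prob=1.0,
        late_latency=200.0,
        late_spread=40.0,
        spatial_decay=40.0,
        baseline_fraction=0.55,
    )


def hippocampal_like_profile() -> PopulationProfile:
    """Hp-like defaults: faster, localised early response, no late one."""
    return PopulationProfile(
        label="Hp-like",
        background_rate=0.3,
        burst_rate=4.0,
        burst_len=6,
        burst_isi=10.0,
        early_prob=2.5,
        early_latency0=6.0,
        latency_slope=0.8,
        early_jitter=1.5,
        late_prob=0.0,
        late_latency=0.0,
        late_spread=0.0,
        spatial_decay=2.5,
        baseline_fraction=0.4,
    )


@dataclass
class SyntheticGroundTruth:
    """Everything the generator knows, for use as a test oracle."""

    profile: PopulationProfile
    seed: int
    stimulated_electrodes: tuple[str, ...]  # one per session
    #: session index -> electrode -> true early latency centre (ms)
    early_latency: dict[int, dict[str, float]] = field(default_factory=dict)
    #: session index -> electrode -> expected early spikes/stimulus
    early_rate: dict[int, dict[str, float]] = field(default_factory=dict)
    #: session index -> electrode -> expected late spikes/stimulus (0 if none)
    late_rate: dict[int, dict[str, float]] = field(default_factory=dict)
    #: true late latency centre (ms) or None when the profile has no late
    late_latency: float | None = None
    #: electrodes forced sub-threshold (MFR < 0.1 spikes/s, no evoked spikes)
    inactive_electrodes: tuple[str, ...] = ()
    #: electrode -> all injected spike times (s), for raw-trace oracles
    spike_times: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def has_late(self) -> bool:
        return self.profile.late_prob > 0


def _pick_stimulated(
    layout: ElectrodeLayout, compartments: CompartmentMap
) -> dict[str, str]:
    """One stimulated electrode per compartment: nearest to its centroid."""
    chosen = {}
    for label in compartments.labels:
        members = compartments.electrodes_in(label)
        pos = np.array([layout.position_of(e) for e in members])
        centroid = pos.mean(axis=0)
        chosen[label] = members[
            int(np.argmin(np.linalg.norm(pos - centroid, axis=1)))
        ]
    return chosen


def _dedupe_refractory(times: np.ndarray) -> np.ndarray:
    """Sort and drop spikes within 1 ms of their predecessor."""
    t = np.sort(np.round(times, TIME_DECIMALS))
    if t.size == 0:
        return t
    keep = [0]
    for i in range(1, t.size):
        if t[i] - t[keep[-1]] >= REFRACTORY_S:
            keep.append(i)
    return t[keep]


def generate_recording(
    profile: PopulationProfile,
    layout: ElectrodeLayout | None = None,
    compartments: CompartmentMap | None = None,
    n_sessions: int = 3,
    stim_freq: float = 0.2,
    session_len: float = 300.0,
    spont_len: float = 600.0,
    seed: int = 0,
    inactive_electrodes: tuple[str, ...] = (),
) -> tuple[Recording, SyntheticGroundTruth]:
    """Generate one protocol-conformant recording with ground truth.

    ``inactive_electrodes`` are forced sub-threshold (0.02 spikes/s
    background, no bursts, no evoked response) so that the MFR and PSTH
    area filters have known targets.
    """
    if stim_freq <= 0 or session_len <= 0 or spont_len < 0:
        raise ValidationError("stim_freq and session_len must be positive")
    if layout is None:
        layout = standard_120_layout()
    if compartments is None:
        compartments = assign_compartments(layout, three_compartment_geometry(layout))
    rng = np.random.default_rng(seed)
    duration = spont_len + n_sessions * session_len
    n_stim = int(round(session_len * stim_freq))
    period = 1.0 / stim_freq

    stim_by_label = _pick_stimulated(layout, compartments)
    labels_order = sorted(stim_by_label)
    sessions = []
    session_stims: list[np.ndarray] = []
    stimulated: list[str] = []
    for i in range(n_sessions):
        start = spont_len + i * session_len
        times = start + period / 2 + period * np.arange(n_stim)
        electrode = stim_by_label[labels_order[i % len(labels_order)]]
        sessions.append(StimulationSession(electrode, times))
        session_stims.append(times)
        stimulated.append(electrode)

    truth = SyntheticGroundTruth(
        profile=profile,
        seed=seed,
        stimulated_electrodes=tuple(stimulated),
        late_latency=profile.late_latency if profile.late_prob > 0 else None,
        inactive_electrodes=tuple(inactive_electrodes),
    )
    for i in range(n_sessions):
        truth.early_latency[i] = {}
        truth.early_rate[i] = {}
        truth.late_rate[i] = {}

    inactive = set(inactive_electrodes)
    trains: dict[str, SpikeTrain] = {}
    for eid, pos in zip(layout.electrode_ids, layout.positions):
        parts: list[np.ndarray] = []
        if eid in inactive:
            bkg_rate = 0.02
        else:
            bkg_rate = profile.background_rate
        n_bkg = rng.poisson(bkg_rate * duration)
        parts.append(rng.uniform(0, duration, n_bkg))
        if eid not in inactive and profile.burst_rate > 0 and spont_len > 0:
            n_bursts = rng.poisson(profile.burst_rate / 60.0 * spont_len)
            comb = np.arange(profile.burst_len) * profile.burst_isi * 1e-3
            burst_span = comb[-1] if comb.size else 0.0
            onsets = rng.uniform(0, max(spont_len - burst_span, 1e-6), n_bursts)
            for onset in onsets:
                parts.append(onset + comb)
        for i, (sess, stims) in enumerate(zip(sessions, session_stims)):
            stim_pos = layout.position_of(sess.stimulated_electrode)
            d = float(np.linalg.norm(pos - stim_pos) / layout.pitch)
            if eid in inactive:
                lam_e, lam_l = 0.0, 0.0
            else:
                lam_e = profile.evoked_rate(profile.early_prob, d)
                lam_l = profile.evoked_rate(profile.late_prob, d)
            centre = profile.early_latency(d)
            truth.early_latency[i][eid] = centre
            truth.early_rate[i][eid] = lam_e
            truth.late_rate[i][eid] = lam_l
            if lam_e > 0:
                counts = rng.poisson(lam_e, stims.size)
                tot = int(counts.sum())
                if tot:
                    lat = centre + profile.early_jitter * rng.standard_normal(tot)
                    lat = np.clip(lat, 0.5, 51.0)
                    parts.append(np.repeat(stims, counts) + lat * 1e-3)
            if lam_l > 0:
                counts = rng.poisson(lam_l, stims.size)
                tot = int(counts.sum())
                if tot:
                    lat = profile.late_latency + profile.late_spread * (
                        rng.standard_normal(tot)
                    )
                    lat = np.clip(lat, 60.0, 590.0)
                    parts.append(np.repeat(stims, counts) + lat * 1e-3)
        times = _dedupe_refractory(np.concatenate(parts))
        times = times[(times >= 0) & (times <= duration)]
        trains[eid] = SpikeTrain(eid, times, 0.0, duration)
        truth.spike_times[eid] = times

    rec = Recording(
        layout=layout,
        compartments=compartments,
        trains=trains,
        sessions=tuple(sessions),
        population_label="Cx" if profile.late_prob > 0 else "Hp",
        duration=duration,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# raw traces
# ---------------------------------------------------------------------------


def biphasic_template(
    sampling_rate: float = 10_000.0,
    duration_ms: float = 1.2,
    positive_fraction: float = 0.35,
) -> np.ndarray:
    """Unit biphasic spike waveform (positive lobe then larger negative).

    Scaled so the peak-to-peak amplitude is 1; multiply by the desired
    amplitude in uV.
    """
    n = max(4, int(round(duration_ms * 1e-3 * sampling_rate)))
    n_pos = max(1, int(round(n * 0.4)))
    n_neg = n - n_pos
    pos = positive_fraction * np.sin(np.linspace(0, np.pi, n_pos))
    neg = -(1 - positive_fraction) * np.sin(np.linspace(0, np.pi, n_neg))
    w = np.concatenate([pos, neg])
    return w / (w.max() - w.min())


def generate_raw_traces(
    spike_times: dict[str, np.ndarray],
    duration: float,
    amplitude: float = 50.0,
    noise_sd: float = 3.0,
    sampling_rate: float = 10_000.0,
    seed: int = 0,
    waveform: np.ndarray | None = None,
) -> dict[str, RawTrace]:
    """Gaussian noise plus a spike waveform at each ground-truth time.

    Overlapping waveforms superpose.  The waveform's larger (negative)
    peak is aligned to the spike time.
    """
    if amplitude < 0 or noise_sd < 0:
        raise ValidationError("amplitude and noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if waveform is None:
        waveform = biphasic_template(sampling_rate)
    w = amplitude * waveform
    peak_off = int(np.argmax(np.abs(w)))
    n = int(round(duration * sampling_rate))
    traces = {}
    for eid, times in spike_times.items():
        x = noise_sd * rng.standard_normal(n) if noise_sd > 0 else np.zeros(n)
        for t in np.asarray(times, dtype=float):
            i0 = int(round(t * sampling_rate)) - peak_off
            a, b = max(i0, 0), min(i0 + w.size, n)
            if a < b:
                x[a:b] += w[a - i0 : b - i0]
        traces[eid] = RawTrace(eid, x, sampling_rate)
    return traces


# ---------------------------------------------------------------------------
# direct PSTH profile datasets (for the classifier)
# ---------------------------------------------------------------------------


def _gauss_profile(centers: np.ndarray, mu: float, sigma: float, mass: float):
    g = np.exp(-0.5 * ((centers - mu) / sigma) ** 2)
    return mass * g / g.sum()


def generate_profile_dataset(
    seed: int = 0,
    n_per_class: int = 20,
    n_stimuli: int = 60,
    bin_ms: float = 4.0,
    window_ms: float = 600.0,
):
    """Two well-separated PSTH classes: early-only vs early + late.

    Both classes share an early component (1.2 spikes/stimulus at 15 ms,
    sigma 5 ms); the second class adds a late component (1.8
    spikes/stimulus at 220 ms, sigma 35 ms).  Per-electrode amplitudes
    vary by +-15% and bin counts are Poisson at ``n_stimuli`` trials.

    Returns ``(psths, labels)`` with label 1 for the late-bearing class.
    """
    from .psth_analysis import Psth

    rng = np.random.default_rng(seed)
    n_bins = int(round(window_ms / bin_ms))
    edges = np.arange(n_bins + 1) * bin_ms
    centers = 0.5 * (edges[:-1] + edges[1:])
    early = _gauss_profile(centers, 15.0, 5.0, 1.2)
    late = _gauss_profile(centers, 220.0, 35.0, 1.8)
    psths, labels = [], []
    for i in range(2 * n_per_class):
        lab = int(i >= n_per_class)
        amp_e = rng.uniform(0.85, 1.15)
        expected = amp_e * early
        if lab:
            expected = expected + rng.uniform(0.85, 1.15) * late
        values = rng.poisson(n_stimuli * expected) / n_stimuli
        psths.append(
            Psth(
                electrode_id=f"e{i:03d}",
                bin_edges=edges,
                values=values,
                n_stimuli=n_stimuli,
            )
        )
        labels.append(lab)
    return psths, np.asarray(labels)


# ---------------------------------------------------------------------------
# benchmark suite
# ---------------------------------------------------------------------------


def make_benchmark_suite(
    seed: int = 0,
    n_per_population: int = 4,
    n_sessions: int = 3,
    session_len: float = 300.0,
    spont_len: float = 600.0,
) -> tuple[list[tuple[Recording, SyntheticGroundTruth]], dict]:
    """Paired Cx-like and Hp-like recordings with a ground-truth manifest.

    Defaults mirror the experimental design: 4 cortical-like and 4
    hippocampal-like networks, each with one stimulation session per
    compartment.  Deterministic given ``seed``.
    """
    datasets = []
    manifest: dict = {"seed": seed, "recordings": []}
    for p_idx, make_profile in enumerate(
        (cortical_like_profile, hippocampal_like_profile)
    ):
        profile = make_profile()
        for i in range(n_per_population):
            child_seed = seed * 1000 + p_idx * 100 + i
            rec, truth = generate_recording(
                profile,
                n_sessions=n_sessions,
                session_len=session_len,
                spont_len=spont_len,
                seed=child_seed,
            )
            datasets.append((rec, truth))
            manifest["recordings"].append(
                {
                    "label": profile.label,
                    "index": i,
                    "seed": child_seed,
                    "population": rec.population_label,
                    "stimulated_electrodes": list(truth.stimulated_electrodes),
                    "late_latency_ms": truth.late_latency,
                    "profile": asdict(profile),
                }
            )
    return datasets, manifest
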