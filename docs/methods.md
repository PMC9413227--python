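# Methods

This note documents the models, parameter choices, numerical decisions,
and limitations of the package. All defaults are set at module level
and echoed into every pipeline report, so any number in an output table
can be traced to the configuration that produced it.

## Data model

A *recording* is a set of per-electrode spike trains (seconds from
recording start, strictly increasing) on a 120-electrode MEA — a 12×12
grid at 200 µm pitch with the six corner positions per corner absent
(144 − 24 = 120, the standard commercial 120-electrode layout) — plus a
compartment map and zero or more stimulation sessions. Compartments are
assigned geometrically: each electrode belongs to the (rectangular or
circular) region containing its position, electrodes under microchannel
strips stay unassigned, and overlapping regions are a configuration
error. Because published datasets do not enumerate which electrodes
fall under the mask, the geometry is always an explicit input; the
bundled default splits the 12 columns into left chamber (0–3), central
band (5–6), right chamber (8–11), with columns 4 and 7 unassigned.

Spike times are serialized at 0.1 ms resolution — the sampling period
of the 10 kHz acquisition clock — which makes save/load round-trips
exact and file output byte-deterministic. Native formats: a JSON
schema, an HDF5 mirror, and a CSV-per-electrode directory.

## Spike detection

The detector implements differential-threshold detection with precise
timing: every local extremum is paired with the largest
opposite-polarity extremum within the *peak lifetime period* (2 ms);
the pair is a spike when its peak-to-peak amplitude exceeds
`k·σ_noise` (k = 8), timestamped at the extremum of larger absolute
amplitude. Conflicts within the refractory period (1 ms) keep the
larger-amplitude event, ties resolve toward the earlier one, so output
is deterministic and inter-spike intervals never violate
refractoriness.

σ_noise defaults to the MAD estimator `median(|x − median(x)|)/0.6745`,
because occasional large spikes inflate an ordinary sample SD (the
sample-SD estimator is available as `global_sd` for comparison). The
threshold is polarity-agnostic and differential, so detection commutes
with amplitude scaling. An optional post-stimulus blanking window
(default 0 ms: off) can discard detections inside stimulus artifacts.

A performance note: extrema are prefiltered by a rolling peak-to-peak
bound (max-filter minus min-filter over ±PLP), so the pairing loop only
visits extrema that could possibly cross threshold; this makes minute-
long 10 kHz traces take a fraction of a second.

## Bursts and spontaneous metrics

A burst is a maximal run of consecutive spikes whose ISIs are all
≤ 100 ms, kept when it has ≥ 5 spikes ("string" method). Burst duration
is measured first spike to last spike. MFR is count/window, MBR is
60·bursts/window; both are computed on the spontaneous phase only
(window an explicit parameter, default the first 600 s). The activity
filter discards electrodes with MFR strictly below 0.1 spikes/s —
exactly 0.1 is active — and MBR is normalized over the full window, not
only active time.

## PSTH

Post-stimulus windows are half-open `[t_stim, t_stim + 600 ms)` with
half-open 4 ms bins, so a spike coincident with a stimulus lands in bin
0; bin values are mean spikes per stimulus. Windows cannot overlap at
0.2 Hz stimulation, but overlap is still detected and rejected for
nonconforming sessions. The PSTH *area* (sum over bins) is the mean
evoked spike count per stimulus; `raw_count_area = area × n_stimuli`
recovers the total spike count. Electrodes with area strictly below 1
are unresponsive (exactly 1 is kept). Normalized areas divide by the
maximum area in scope — per session by default, per recording
optionally, the scope being recorded in the report. The stimulated
electrode's own PSTH is computed and flagged (artifact-prone);
inclusion is configurable and defaults to included.

## Early/late classification

Responsive PSTHs of one session are clustered by k-means (Euclidean
distance on the raw 150-bin vectors, 10 restarts, fixed seed) for every
k in 2…8 (bounded by n − 1 and the number of distinct profiles); the k
maximizing the mean silhouette score wins. If fewer than two distinct
profiles exist, silhouette is undefined and a single class is returned.
Labels are relabelled by order of first appearance, making the output
deterministic given the seed.

Each class mean is smoothed by a centred moving average of 13 bins
(52 ms ≈ the nominal 50 ms; odd length preserves interior peak
positions), edge bins averaging over the shrunken in-range window.
Local maxima are found with the profile zero-padded at both ends (the
PSTH baseline), so a maximum in the first or last bin is detectable and
has finite prominence. The early peak `x1` is the highest local maximum
with bin centre ≤ 52 ms; candidate late peaks beyond 52 ms must have
prominence ≥ 10% of `x1`'s, and the highest qualifying one is `x2`.
Classes without an early peak are non-responding and excluded from
latency statistics.

The separation statistic between the peaks is, with
`v = PSTH_smooth(x_min)` at the inter-peak minimum and `p1, p2` the
smoothed peak values,

    s = 1 − v / sqrt(p1 · p2)        (dip_depth, default)
    s = v / (p1 · p2)                (literal_ratio, alternative)

`dip_depth` measures relative valley depth below the geometric mean of
the peaks: 1 for a valley reaching zero, 0 for no dip, growing with
separation, which matches the decision rule "s above 0.3 ⇒ the peaks
are separable". The product-ratio form is provided because the
defining expression admits that reading too; the form used is recorded
in every output. `has_late` requires `s > 0.3`, and then `x_min` is the
time threshold splitting early from late.

**Per-electrode latencies.** The class provides the split point; each
electrode's latencies come from its own PSTH. The early latency is the
argmax of the electrode's *raw* PSTH on `(0, min(52 ms, x_min)]`: the
early component is temporally sharp — of the order of one 4 ms bin — so
a 50 ms moving average flattens it into a near-plateau whose argmax is
decided by noise and edge effects rather than by the response (on
synthetic data this destroys latency precision entirely, < 1% of
electrodes recovered within one bin, versus 100% with the raw argmax).
The late latency is the argmax of the *smoothed* PSTH beyond `x_min`:
the late component is tens-to-hundreds of ms wide and per-bin counts
are low, so there smoothing suppresses single-spike noise instead of
destroying structure. Electrodes of early-only classes receive the
650 ms sentinel, a value beyond the 600 ms observation window.

## Group statistics

Comparisons use the Kruskal–Wallis test on midranks with tie correction
(always on — latencies quantized to 4 ms bins are heavily tied), with
p-values from the χ² approximation with g − 1 degrees of freedom;
identical constant groups return H = 0, p = 1. A KS screen against a
fitted normal is advisory only: analysis always proceeds
nonparametrically. Significance is declared at p < 0.05 with no
multiple-testing correction; the number of comparisons is attached to
the output table so users can correct as they prefer. Descriptors
report mean ± SD alongside median and quartiles. The site-comparison
table contrasts populations per (stimulation site, compartment) cell
and compartments within a population per site; the grouping unit is the
electrode by default, compartment means being available through the
summary tables.

## Synthetic generator

The generator is a statistical emulator of the protocol, not a
biophysical simulation: no membrane or synapse models, and nothing it
produces is a claim about real tissue — it defines the ground truth
that the pipeline is tested against.

*Spontaneous phase* (600 s): homogeneous Poisson background per
electrode plus bursts injected as deterministic spike combs
(`burst_len` spikes at `burst_isi`) at Poisson onset times.
*Sessions* (3 × 300 s at 0.2 Hz = 60 stimuli each, one stimulated
electrode per compartment, chosen nearest the compartment centroid for
determinism): per stimulus and electrode, evoked spike counts are
Poisson with rate

    rate(d) = prob · (f + (1 − f)·exp(−d / λ))

where `d` is the distance from the stimulated electrode in pitches,
`λ = spatial_decay` and `f = baseline_fraction`, a spatially uniform
floor. The floor is needed because a pure exponential cannot make the
response both detectable on all electrodes (early components appear
array-wide in both populations) and strongly localized in the
hippocampal-like case; localization is expressed as amplitude contrast.
Early latencies are `early_latency0 + latency_slope·d` plus Gaussian
jitter; late spikes (if any) fall at `late_latency ± late_spread`.
Trains are cleaned to respect a 1 ms refractory period, so generated
recordings satisfy the same invariants as detector output.

Default profiles (chosen once to mirror the qualitative contrast
between cortical and hippocampal cultures at realistic magnitudes —
PSTH areas of order 1–3 spikes/stimulus, MFR of order 1 spike/s):

| parameter | Cx-like | Hp-like | unit |
|---|---|---|---|
| background_rate | 0.5 | 0.3 | spikes/s |
| burst_rate / len / isi | 6 / 10 / 15 | 4 / 6 / 10 | min⁻¹ / spikes / ms |
| early_prob | 1.5 | 2.5 | spikes/stimulus |
| early_latency0 / slope / jitter | 10 / 1.2 / 2 | 6 / 0.8 / 1.5 | ms / ms·pitch⁻¹ / ms |
| late_prob / latency / spread | 1.0 / 200 / 40 | 0 / – / – | spikes/stimulus, ms |
| spatial_decay / baseline_fraction | 40 / 0.55 | 2.5 / 0.4 | pitches / – |

Cortical-like networks thus fire and burst more, burst longer, respond
almost uniformly, and carry a late component; hippocampal-like networks
are faster in the early phase, localized, and early-only. Raw traces
for detector testing superpose a unit biphasic template (positive lobe
then larger negative lobe, 1.2 ms) scaled to the requested amplitude on
Gaussian noise, aligned at the larger peak.

The two-class profile dataset used for classifier verification builds
PSTHs directly: a shared early Gaussian component (1.2 spikes/stimulus
at 15 ms, σ 5 ms) and, for the second class, a late component (1.8
spikes/stimulus at 220 ms, σ 35 ms), with ±15% per-electrode amplitude
scatter and Poisson bin noise at 60 stimuli — well-separated shapes in
the sense that the silhouette optimum is k = 2 by construction.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: network-wide synchronized bursting
(bursts are independent across electrodes), stimulus artifacts,
electrode-to-electrode noise heterogeneity, non-stationarity over the
session, polysynaptic reverberation structure inside the late window,
and any receptor-level mechanism. Tests against the generator verify
the *algorithms*, not biological claims.

## Benchmark suite and problem sizes

`make_benchmark_suite` produces 4 cortical-like + 4 hippocampal-like
recordings (mirroring a 4 + 4 culture design), each with three
300 s sessions, one per compartment — 36 compartment–session pairs per
population. The verification script and acceptance tests run the full
pipeline on this suite and additionally use 1000 random trains for the
burst oracle, 50 seeded two-class datasets for the classifier, and 15
thirty-second traces for the detector; these sizes keep the whole
verification in the tens of seconds while leaving estimator noise well
below the tested margins.

## Known limitations

- No reader for proprietary acquisition formats; data must be converted
  to the documented JSON/HDF5/CSV schemas.
- No spike sorting (deliberate: overlapping waveforms during bursts
  make sorting unreliable at this electrode density) and no
  network-burst (population-level) detection.
- The early/late nomenclature follows the AMPA/NMDA convention of the
  stimulation literature but the package makes no receptor-identity
  claims.
- Silhouette-based k selection cannot choose k = 1; the degenerate
  single-class path triggers only when profiles are exactly identical.
- Kruskal–Wallis p-values rely on the χ² approximation; very small
  groups (total n < 5) should be interpreted with care.
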