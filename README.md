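# mea-evoked

Analysis of spontaneous and electrically evoked activity of neuronal
cultures on 120-electrode micro-electrode arrays (MEAs), aimed at
experiments where a culture is partitioned into interconnected
compartments (e.g. one large and two small chambers joined by
neurite-permissive microchannels) and probed with low-frequency
(0.2 Hz) biphasic stimulation.

The package is for electrophysiologists and methods developers who need
a tested, scriptable version of the standard MEA analysis chain plus an
early/late evoked-response classifier:

1. **Spike detection** — differential-threshold detection on raw
   traces: a spike is a pair of opposite-polarity extrema within a
   2 ms peak lifetime period whose peak-to-peak amplitude exceeds
   8·σ_noise (σ estimated robustly via MAD), with a 1 ms refractory
   period.
2. **Spontaneous metrics** — string-method burst detection (≥ 5 spikes,
   inter-spike intervals ≤ 100 ms) and per-electrode MFR (spikes/s),
   MBR (bursts/min), and burst duration (ms); electrodes with
   MFR < 0.1 spikes/s are discarded.
3. **PSTH** — post-stimulus time histograms over 600 ms windows in
   4 ms bins, normalized per stimulus; electrodes with PSTH area < 1
   are treated as unresponsive; areas are max-normalized for
   cross-network comparison.
4. **Early/late classification** — k-means over PSTH profiles with the
   class count chosen by silhouette analysis; each class mean is
   smoothed with a 50 ms moving average, an early peak `x1` is sought
   within 52 ms and a late peak `x2` in (52, 600] ms (≥ 10% of the
   early peak's prominence). The separation statistic

   `s_j = 1 − PSTH_smooth,j(x_min) / sqrt(PSTH_smooth,j(x1) · PSTH_smooth,j(x2))`

   with `x_min` the inter-peak local minimum decides (s_j > 0.3)
   whether the class genuinely carries a late component; `x_min` then
   splits each member electrode's PSTH into early and late latencies,
   and electrodes of early-only classes receive the 650 ms sentinel
   (beyond the observation window).
5. **Group statistics** — Kruskal–Wallis comparisons (with a
   Kolmogorov–Smirnov normality screen) across populations,
   compartments, and stimulation sites.

A fully ground-truthed **synthetic generator** emulates cortical-like
(strong, spatially uniform response with a late component) and
hippocampal-like (fast, localized, early-only) networks under the
experimental protocol (10 min spontaneous phase, then 5-min sessions of
0.2 Hz stimulation — 60 stimuli per session, one stimulated electrode
per compartment), so every stage is testable without any recordings.

## Worked example

```python
from mea_evoked import (
    cortical_like_profile, generate_recording, run_pipeline, PipelineConfig,
)

recording, truth = generate_recording(cortical_like_profile(), seed=7)
report = run_pipeline(recording, PipelineConfig(seed=7))

print(f"active electrodes: {report.metrics['is_active'].sum()}/120")
print(f"mean MFR: {report.metrics['mfr'].mean():.2f} spikes/s")
print(report.classes.head(2))
late = report.latencies[report.latencies["has_late"]]
print(f"late responses: {len(late)}/{len(report.latencies)} electrodes, "
      f"mean late latency {late['late_latency_ms'].mean():.0f} ms "
      f"(truth: {truth.late_latency:.0f} ms)")
```

prints

```
active electrodes: 120/120
mean MFR: 1.51 spikes/s
 session  class_id  n_members  x1    x2  x_min        s  has_late
       0         0         66 2.0 198.0   50.0 0.980504      True
       0         1         54 2.0 190.0   50.0 0.975846      True
late responses: 360/360 electrodes, mean late latency 199 ms (truth: 200 ms)
```

All 120 electrodes pass the activity filter (the cortical-like profile
fires well above 0.1 spikes/s); every session's PSTHs split into
classes whose smoothed profiles show both an early peak (`x1`, within
52 ms) and a late peak (`x2` ≈ 200 ms) separated by a deep valley
(`s` ≈ 0.98 > 0.3), so every responsive electrode is assigned a late
latency, which recovers the generator's 200 ms ground truth. Running
the same pipeline on `hippocampal_like_profile()` instead yields
early-only classes and 650 ms sentinels throughout.

The same stages are scriptable from the shell:

```sh
mea-evoked synth --profile cx --seed 7 --out rec.json
mea-evoked run --in rec.json --out report/ --seed 7
mea-evoked summarize --reports report/ --out tables/
```

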