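"""End-to-end orchestration: metrics -> PSTH -> classification -> stats.

``run_pipeline`` executes the full analysis of one recording and returns
a :class:`Report` of tidy tables; ``summarize`` pools reports across
recordings into cross-population tables (spontaneous metrics, normalised
PSTH areas, compartment-mean latencies, evoked-response counts).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .burst_analysis import ACTIVE_MFR_THRESHOLD, activity_metrics, filter_active
from .core_model import Recording, ValidationError, load_recording
from .psth_analysis import (
    PSTH_BIN_MS,
    PSTH_WINDOW_MS,
    RESPONSIVE_AREA_THRESHOLD,
    compute_psth,
    filter_responsive,
    normalize_areas,
)
from .response_classification import (
    LATE_SENTINEL_MS,
    ClassificationConfig,
    classify_session,
)

__all__ = ["PipelineConfig", "Report", "run_pipeline", "summarize"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters, defaulting to the protocol values."""

    spontaneous_window: tuple[float, float] = (0.0, 600.0)
    burst_min_spikes: int = 5
    burst_max_isi: float = 100.0  # ms
    mfr_threshold: float = ACTIVE_MFR_THRESHOLD  # spikes/s
    psth_window: float = PSTH_WINDOW_MS  # ms
    psth_bin: float = PSTH_BIN_MS  # ms
    area_threshold: float = RESPONSIVE_AREA_THRESHOLD
    smoothing_window: float = 50.0  # ms
    early_limit: float = 52.0  # ms
    prominence_fraction: float = 0.10
    separation_threshold: float = 0.3
    separation_form: str = "dip_depth"
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    normalization_scope: str = "per-session"  # or "per-recording"
    include_stimulated_electrode: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psth_window % self.psth_bin:
            raise ValidationError(
                f"PSTH window {self.psth_window} ms not divisible by "
                f"bin {self.psth_bin} ms"
            )
        if self.normalization_scope not in ("per-session", "per-recording"):
            raise ValidationError(
                f"unknown normalization scope {self.normalization_scope!r}"
            )

    def classification_config(self) -> ClassificationConfig:
        return ClassificationConfig(
            k_range=self.k_range,
            smoothing_window=self.smoothing_window,
            early_limit=self.early_limit,
            prominence_fraction=self.prominence_fraction,
            separation_threshold=self.separation_threshold,
            separation_form=self.separation_form,
            seed=self.seed,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class Report:
    """Per-stage tables of one recording's analysis."""

    population_label: str
    config: PipelineConfig
    metrics: pd.DataFrame  # electrode_id, mfr, mbr, mean_bd_ms, is_active
    psth: pd.DataFrame  # session, electrode_id, area, normalized_area, ...
    classes: pd.DataFrame  # session, class_id, x1, x2, x_min, s, has_late, ...
    latencies: pd.DataFrame  # session, electrode_id, compartment, early, late
    log: list[str] = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        return self.config.config_hash()

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("metrics", "psth", "classes", "latencies"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        manifest = {
            "population_label": self.population_label,
            "config": asdict(self.config),
            "config_hash": self.config_hash,
            "log": self.log,
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )


def run_pipeline(recording: Recording, config: PipelineConfig | None = None) -> Report:
    """Run metrics, PSTH, and classification on one recording."""
    if config is None:
        config = PipelineConfig()
    log: list[str] = [f"config_hash={config.config_hash()}"]

    # --- spontaneous-phase metrics ------------------------------------
    t0, t1 = config.spontaneous_window
    rows = []
    for eid in sorted(recording.trains):
        train = recording.trains[eid].slice(t0, t1)
        m = activity_metrics(
            train,
            min_spikes=config.burst_min_spikes,
            max_isi=config.burst_max_isi,
            active_threshold=config.mfr_threshold,
        )
        rows.append(
            {
                "electrode_id": eid,
                "compartment": recording.compartments.label(eid),
                "mfr": m.mfr,
                "mbr": m.mbr,
                "mean_bd_ms": float(np.mean(m.burst_durations))
                if m.burst_durations
                else np.nan,
                "n_bursts": len(m.burst_durations),
                "is_active": m.is_active,
            }
        )
    metrics = pd.DataFrame(rows)
    log.append(
        f"spontaneous window [{t0}, {t1}] s: "
        f"{int(metrics['is_active'].sum())}/{len(metrics)} active electrodes"
    )

    # --- PSTH per session ---------------------------------------------
    psth_rows = []
    class_rows = []
    lat_rows = []
    all_session_psths = []
    for si, session in enumerate(recording.sessions):
        psths = []
        for eid in sorted(recording.trains):
            p = compute_psth(
                recording.trains[eid], session, config.psth_window, config.psth_bin
            )
            if p.is_stimulated_electrode and not config.include_stimulated_electrode:
                continue
            psths.append(p)
        responsive, removed = filter_responsive(psths, config.area_threshold)
        all_session_psths.append((si, session, psths, responsive))
        log.append(
            f"session {si} (stim {session.stimulated_electrode}): "
            f"{len(responsive)} responsive, {len(removed)} below area threshold"
        )

    recording_max = max(
        (p.area for _, _, psths, _ in all_session_psths for p in psths),
        default=0.0,
    )

    for si, session, psths, responsive in all_session_psths:
        scope_max = None if config.normalization_scope == "per-session" else (
            recording_max
        )
        normalized = (
            normalize_areas(responsive, scope_max=scope_max) if responsive else []
        )
        norm_by_id = {p.electrode_id: p.normalized_area for p in normalized}
        for p in psths:
            psth_rows.append(
                {
                    "session": si,
                    "stimulated_electrode": session.stimulated_electrode,
                    "electrode_id": p.electrode_id,
                    "compartment": recording.compartments.label(p.electrode_id),
                    "area": p.area,
                    "raw_count_area": p.raw_count_area,
                    "normalized_area": norm_by_id.get(p.electrode_id, np.nan),
                    "is_responsive": p.is_responsive,
                    "is_stimulated_electrode": p.is_stimulated_electrode,
                }
            )
        if not responsive:
            continue
        classes, labels, latencies = classify_session(
            responsive, config.classification_config()
        )
        stim_comp = recording.compartments.label(session.stimulated_electrode)
        for c in classes:
            class_rows.append(
                {
                    "session": si,
                    "class_id": c.class_id,
                    "n_members": len(c.member_electrodes),
                    "x1": c.x1,
                    "x2": c.x2,
                    "x_min": c.x_min,
                    "s": c.s,
                    "has_late": c.has_late,
                    "is_responding": c.is_responding,
                    "separation_form": c.separation_form,
                }
            )
        label_by_id = {
            p.electrode_id: int(lab) for p, lab in zip(responsive, labels)
        }
        for eid in latencies.electrode_ids:
            e, l = latencies[eid]
            lat_rows.append(
                {
                    "session": si,
                    "stimulated_compartment": stim_comp,
                    "electrode_id": eid,
                    "compartment": recording.compartments.label(eid),
                    "class_id": label_by_id[eid],
                    "early_latency_ms": e,
                    "late_latency_ms": l,
                    "has_late": l < LATE_SENTINEL_MS,
                }
            )

    psth_df = pd.DataFrame(psth_rows)
    classes_df = pd.DataFrame(
        class_rows,
        columns=[
            "session", "class_id", "n_members", "x1", "x2", "x_min", "s",
            "has_late", "is_responding", "separation_form",
        ],
    )
    lat_df = pd.DataFrame(
        lat_rows,
        columns=[
            "session", "stimulated_compartment", "electrode_id", "compartment",
            "class_id", "early_latency_ms", "late_latency_ms", "has_late",
        ],
    )
    return Report(
        population_label=recording.population_label,
        config=config,
        metrics=metrics,
        psth=psth_df,
        classes=classes_df,
        latencies=lat_df,
        log=log,
    )


def summarize(
    reports: list[Report], labels: list[str] | None = None
) -> dict[str, pd.DataFrame]:
    """Pool reports into cross-recording tables.

    Returns a dict of tidy frames:

    - ``spontaneous``: per-recording pooled MFR/MBR/BD over active
      electrodes (compartments condensed);
    - ``areas``: per-electrode normalised areas with population labels;
    - ``latencies``: compartment-mean early/late latencies per session;
    - ``counts``: evoked-response counts (compartment-session pairs with
      an early / late response) per population.
    """
    if not reports:
        raise ValidationError("no reports to summarize")
    if labels is None:
        labels = [r.population_label for r in reports]

    spont_rows, area_rows, lat_rows, count_rows = [], [], [], []
    for idx, (rep, pop) in enumerate(zip(reports, labels)):
        active = rep.metrics[rep.metrics["is_active"]]
        spont_rows.append(
            {
                "recording": idx,
                "population": pop,
                "n_active": len(active),
                "mfr": active["mfr"].mean(),
                "mbr": active["mbr"].mean(),
                "mean_bd_ms": active["mean_bd_ms"].mean(),
            }
        )
        resp = rep.psth[rep.psth["is_responsive"]]
        for _, row in resp.iterrows():
            area_rows.append(
                {
                    "recording": idx,
                    "population": pop,
                    "session": row["session"],
                    "electrode_id": row["electrode_id"],
                    "compartment": row["compartment"],
                    "normalized_area": row["normalized_area"],
                }
            )
        if len(rep.latencies):
            grouped = rep.latencies.groupby(["session", "compartment"])
            for (si, comp), g in grouped:
                stim_comp = g["stimulated_compartment"].iloc[0]
                late_vals = g.loc[g["has_late"], "late_latency_ms"]
                lat_rows.append(
                    {
                        "recording": idx,
                        "population": pop,
                        "session": si,
                        "compartment": comp,
                        "stimulated_compartment": stim_comp,
                        "early_latency_ms": g["early_latency_ms"].mean(),
                        "late_latency_ms": late_vals.mean()
                        if len(late_vals)
                        else LATE_SENTINEL_MS,
                        "n_electrodes": len(g),
                        "has_early": len(g) > 0,
                        "has_late": bool(g["has_late"].any()),
                    }
                )
    lat_df = pd.DataFrame(
        lat_rows,
        columns=[
            "recording", "population", "session", "compartment",
            "stimulated_compartment", "early_latency_ms", "late_latency_ms",
            "n_electrodes", "has_early", "has_late",
        ],
    )
    for pop in sorted(set(labels)):
        sub = lat_df[lat_df["population"] == pop]
        count_rows.append(
            {
                "population": pop,
                "n_early": int(sub["has_early"].sum()),
                "n_late": int(sub["has_late"].sum()),
                "n_compartment_sessions": len(sub),
            }
        )
    return {
        "spontaneous": pd.DataFrame(spont_rows),
        "areas": pd.DataFrame(area_rows),
        "latencies": lat_df,
        "counts": pd.DataFrame(count_rows),
    }
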