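"""Domain types and I/O for MEA spike-train recordings.

The experimental object is a planar micro-electrode array (MEA) with 120
electrodes on a 12x12 grid (200 um pitch, corner positions absent), over
which a neuronal culture is physically partitioned into three compartments
(one large central chamber flanked by two smaller ones) by a PDMS mask.
A recording holds per-electrode spike trains, the electrode layout, the
compartment assignment, and zero or more stimulation sessions (each a list
of stimulus times delivered to one electrode).

Spike times are stored in seconds from recording start.  On disk they are
serialized at 0.1 ms resolution — the period of the 10 kHz acquisition
clock — so that save/load round-trips are exact.

Supported on-disk formats: a documented JSON schema (native), an HDF5
mirror of the same schema, and a CSV directory dialect (one file of spike
times per electrode).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "CompartmentMap",
    "SpikeTrain",
    "RawTrace",
    "StimulationSession",
    "Recording",
    "SchemaError",
    "ValidationError",
    "standard_120_layout",
    "assign_compartments",
    "load_recording",
    "save_recording",
    "TIME_DECIMALS",
]

#: serialized time resolution: 1e-4 s = 0.1 ms, the 10 kHz sampling period
TIME_DECIMALS = 4

COMPARTMENT_LABELS = ("big", "small_left", "small_right")


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar electrode positions, in micrometres.

    Parameters
    ----------
    electrode_ids
        Unique string identifiers, one per electrode.
    positions
        ``(n, 2)`` array of (x, y) coordinates in um.
    pitch
        Inter-electrode spacing in um (default 200).
    n_rows, n_cols
        Nominal grid dimensions.
    """

    electrode_ids: tuple[str, ...]
    positions: np.ndarray
    pitch: float = 200.0
    n_rows: int = 12
    n_cols: int = 12

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(self.electrode_ids)) != len(self.electrode_ids):
            raise ValidationError("electrode_ids must be unique")
        if pos.shape != (len(self.electrode_ids), 2):
            raise ValidationError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.electrode_ids)} electrodes"
            )
        if len(np.unique(pos, axis=0)) != len(pos):
            raise ValidationError("electrode positions must be pairwise distinct")

    def __len__(self) -> int:
        return len(self.electrode_ids)

    def position_of(self, electrode_id: str) -> np.ndarray:
        return self.positions[self.electrode_ids.index(electrode_id)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ElectrodeLayout):
            return NotImplemented
        return (
            self.electrode_ids == other.electrode_ids
            and np.array_equal(self.positions, other.positions)
            and self.pitch == other.pitch
        )


@dataclass(frozen=True)
class CompartmentMap:
    """Assignment of electrodes to culture compartments.

    Electrodes lying under the microchannels or outside the chambers are
    simply absent from ``assignment``.
    """

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment", dict(self.assignment))

    def label(self, electrode_id: str) -> str | None:
        return self.assignment.get(electrode_id)

    def electrodes_in(self, label: str) -> list[str]:
        return [e for e, c in self.assignment.items() if c == label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignment.values())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompartmentMap):
            return NotImplemented
        return dict(self.assignment) == dict(other.assignment)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one electrode, in seconds, strictly increasing."""

    electrode_id: str
    times: np.ndarray
    t_start: float = 0.0
    t_stop: float = math.inf

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.ndim != 1:
            raise ValidationError("spike times must be a 1-d array")
        if t.size:
            if not np.all(np.diff(t) > 0):
                raise ValidationError(
                    f"spike times of {self.electrode_id} not strictly increasing"
                )
            if t[0] < self.t_start or t[-1] > self.t_stop:
                raise ValidationError(
                    f"spike times of {self.electrode_id} outside "
                    f"[{self.t_start}, {self.t_stop}]"
                )

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def slice(self, t0: float, t1: float) -> "SpikeTrain":
        """Spikes in [t0, t1), re-windowed to that interval."""
        lo, hi = np.searchsorted(self.times, [t0, t1])
        return SpikeTrain(self.electrode_id, self.times[lo:hi], t0, t1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (
            self.electrode_id == other.electrode_id
            and np.array_equal(self.times, other.times)
            and self.t_start == other.t_start
            and self.t_stop == other.t_stop
        )


@dataclass(frozen=True)
class RawTrace:
    """Raw extracellular voltage trace of one electrode, in uV."""

    electrode_id: str
    samples: np.ndarray
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", x)
        if self.sampling_rate <= 0:
            raise ValidationError("sampling_rate must be positive")
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"non-finite samples in trace {self.electrode_id}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


#: stimulation pulse used throughout: biphasic, positive phase first,
#: 400 us total with 50% duty cycle, 1.5 V peak-to-peak, delivered at 0.2 Hz
DEFAULT_PULSE = {
    "shape": "biphasic",
    "polarity": "positive-first",
    "duration_us": 400.0,
    "duty_cycle": 0.5,
    "amplitude_vpp": 1.5,
    "frequency_hz": 0.2,
}


@dataclass(frozen=True)
class StimulationSession:
    """One stimulation session: pulses delivered to a single electrode."""

    stimulated_electrode: str
    stimulus_times: np.ndarray
    pulse_descriptor: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_PULSE)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.stimulus_times, dtype=float)
        object.__setattr__(self, "stimulus_times", t)
        object.__setattr__(self, "pulse_descriptor", dict(self.pulse_descriptor))
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError("stimulus_times must be strictly increasing")

    @property
    def n_stimuli(self) -> int:
        return self.stimulus_times.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StimulationSession):
            return NotImplemented
        return (
            self.stimulated_electrode == other.stimulated_electrode
            and np.array_equal(self.stimulus_times, other.stimulus_times)
            and dict(self.pulse_descriptor) == dict(other.pulse_descriptor)
        )


@dataclass(frozen=True)
class Recording:
    """A full experimental recording.

    ``population_label`` identifies the plated cell type: ``"Cx"``
    (cortical), ``"Hp"`` (hippocampal), or ``"other"``.
    """

    layout: ElectrodeLayout
    compartments: CompartmentMap
    trains: Mapping[str, SpikeTrain]
    sessions: tuple[StimulationSession, ...] = ()
    population_label: str = "other"
    duration: float = 0.0
    sampling_rate: float = 10_000.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "trains", dict(self.trains))
        object.__setattr__(self, "sessions", tuple(self.sessions))
        ids = set(self.layout.electrode_ids)
        for eid in self.trains:
            if eid not in ids:
                raise ValidationError(f"train electrode {eid!r} not in layout")
        for eid in self.compartments.assignment:
            if eid not in ids:
                raise ValidationError(f"compartment electrode {eid!r} not in layout")
        for s in self.sessions:
            if s.stimulated_electrode not in ids:
                raise ValidationError(
                    f"stimulated electrode {s.stimulated_electrode!r} not in layout"
                )
            if s.n_stimuli and (
                s.stimulus_times[0] < 0 or s.stimulus_times[-1] > self.duration
            ):
                raise ValidationError("stimulus times outside [0, duration]")
        for eid, tr in self.trains.items():
            if tr.times.size and tr.times[-1] > self.duration:
                raise ValidationError(
                    f"spike time {tr.times[-1]} of {eid} exceeds duration "
                    f"{self.duration}"
                )

    def train(self, electrode_id: str) -> SpikeTrain:
        return self.trains[electrode_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.layout == other.layout
            and self.compartments == other.compartments
            and dict(self.trains) == dict(other.trains)
            and self.sessions == other.sessions
            and self.population_label == other.population_label
            and self.duration == other.duration
            and self.sampling_rate == other.sampling_rate
        )


# ---------------------------------------------------------------------------
# layout / compartment construction
# ---------------------------------------------------------------------------


def standard_120_layout(pitch: float = 200.0) -> ElectrodeLayout:
    """The standard 120-electrode MEA layout.

    A 12x12 grid with the six positions in each corner (the triangle
    ``dr + dc <= 2`` measured from the corner) absent: 144 - 24 = 120
    electrodes.  Ids are ``"r<row>c<col>"`` with row 0 at the bottom.
    """
    ids: list[str] = []
    pos: list[tuple[float, float]] = []
    for r in range(12):
        for c in range(12):
            dr = min(r, 11 - r)
            dc = min(c, 11 - c)
            if dr + dc <= 2:
                continue
            ids.append(f"r{r:02d}c{c:02d}")
            pos.append((c * pitch, r * pitch))
    return ElectrodeLayout(tuple(ids), np.array(pos), pitch=pitch)


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned rectangle [x0, x1] x [y0, y1] in um."""

    label: str
    x0: float
    y0: float
    x1: float
    y1: float

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x <= self.x1 and self.y0 <= y <= self.y1


@dataclass(frozen=True)
class CircleRegion:
    """Disc of radius r centred at (cx, cy), in um."""

    label: str
    cx: float
    cy: float
    r: float

    def contains(self, x: float, y: float) -> bool:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.r**2


def assign_compartments(
    layout: ElectrodeLayout, geometry: Sequence[RectRegion | CircleRegion]
) -> CompartmentMap:
    """Assign each electrode to the region containing its position.

    Electrodes contained in no region stay unassigned (microchannel or
    outside-chamber sites).  Overlapping regions — any electrode contained
    in two — are a configuration error.
    """
    assignment: dict[str, str] = {}
    for eid, (x, y) in zip(layout.electrode_ids, layout.positions):
        hits = [g.label for g in geometry if g.contains(x, y)]
        if len(hits) > 1:
            raise ValidationError(
                f"electrode {eid} falls in overlapping regions {hits}"
            )
        if hits:
            assignment[eid] = hits[0]
    return CompartmentMap(assignment)


def three_compartment_geometry(
    layout: ElectrodeLayout,
) -> list[RectRegion]:
    """Default three-compartment geometry over a 12x12 grid.

    Columns 0-3 form the left small chamber, columns 8-11 the right one,
    and columns 5-6 the central band of the big chamber; columns 4 and 7
    model the microchannel strips and stay unassigned.  This is a
    convention of this package (real masks vary); supply explicit
    geometry to override.
    """
    p = layout.pitch
    lo, hi = -0.5 * p, 11.5 * p
    return [
        RectRegion("small_left", lo, lo, 3.5 * p, hi),
        RectRegion("big", 4.5 * p, lo, 6.5 * p, hi),
        RectRegion("small_right", 7.5 * p, lo, hi, hi),
    ]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def _round_times(t: np.ndarray) -> list[float]:
    return [round(float(x), TIME_DECIMALS) for x in t]


def _recording_to_dict(rec: Recording) -> dict:
    return {
        "meta": {
            "sampling_rate": rec.sampling_rate,
            "duration": rec.duration,
            "population_label": rec.population_label,
            "pitch": rec.layout.pitch,
        },
        "layout": [
            {"id": eid, "x": float(x), "y": float(y)}
            for eid, (x, y) in zip(rec.layout.electrode_ids, rec.layout.positions)
        ],
        "compartments": dict(sorted(rec.compartments.assignment.items())),
        "trains": {
            eid: _round_times(rec.trains[eid].times) for eid in sorted(rec.trains)
        },
        "sessions": [
            {
                "stimulated_electrode": s.stimulated_electrode,
                "stimulus_times_s": _round_times(s.stimulus_times),
                "pulse_descriptor": dict(s.pulse_descriptor),
            }
            for s in rec.sessions
        ],
    }


def _require(d: Mapping, key: str, ctx: str):
    if key not in d:
        raise SchemaError(f"missing field {key!r} in {ctx}")
    return d[key]


def _recording_from_dict(d: Mapping) -> Recording:
    meta = _require(d, "meta", "recording")
    duration = float(_require(meta, "duration", "meta"))
    sampling_rate = float(_require(meta, "sampling_rate", "meta"))
    layout_spec = _require(d, "layout", "recording")
    ids = tuple(str(e["id"]) for e in layout_spec)
    pos = np.array([[float(e["x"]), float(e["y"])] for e in layout_spec])
    layout = ElectrodeLayout(ids, pos, pitch=float(meta.get("pitch", 200.0)))
    comp = CompartmentMap(dict(d.get("compartments", {})))
    trains = {}
    for eid, times in _require(d, "trains", "recording").items():
        if eid not in set(ids):
            raise SchemaError(f"train references unknown electrode {eid!r}")
        trains[eid] = SpikeTrain(eid, np.asarray(times, dtype=float), 0.0, duration)
    sessions = []
    for s in d.get("sessions", []):
        sessions.append(
            StimulationSession(
                str(_require(s, "stimulated_electrode", "session")),
                np.asarray(_require(s, "stimulus_times_s", "session"), dtype=float),
                dict(s.get("pulse_descriptor", DEFAULT_PULSE)),
            )
        )
    return Recording(
        layout=layout,
        compartments=comp,
        trains=trains,
        sessions=tuple(sessions),
        population_label=str(meta.get("population_label", "other")),
        duration=duration,
        sampling_rate=sampling_rate,
    )


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    if path.suffix == ".json":
        return "json"
    if path.suffix in (".h5", ".hdf5"):
        return "hdf5"
    if path.is_dir() or path.suffix == "":
        return "csv-dir"
    raise SchemaError(f"cannot infer format of {path}")


def save_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Write a recording to ``path`` as json, hdf5, or a csv directory.

    Serialization is deterministic: two saves of the same recording are
    byte-identical, and times round-trip exactly at 0.1 ms resolution.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    d = _recording_to_dict(rec)
    if fmt == "json":
        path.write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")
    elif fmt == "hdf5":
        _save_hdf5(d, path)
    elif fmt == "csv-dir":
        _save_csv_dir(d, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def load_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording previously written by :func:`save_recording`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        d = json.loads(path.read_text())
    elif fmt == "hdf5":
        d = _load_hdf5(path)
    elif fmt == "csv-dir":
        d = _load_csv_dir(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return _recording_from_dict(d)


def _save_hdf5(d: Mapping, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        for k, v in d["meta"].items():
            meta.attrs[k] = v
        lay = f.create_group("layout")
        ids = [e["id"] for e in d["layout"]]
        lay.create_dataset("ids", data=np.array(ids, dtype="S"))
        lay.create_dataset(
            "xy", data=np.array([[e["x"], e["y"]] for e in d["layout"]])
        )
        comp = f.create_group("compartments")
        for eid, label in d["compartments"].items():
            comp.attrs[eid] = label
        tr = f.create_group("trains")
        for eid in sorted(d["trains"]):
            tr.create_dataset(eid, data=np.asarray(d["trains"][eid], dtype=float))
        sess = f.create_group("sessions")
        for i, s in enumerate(d["sessions"]):
            g = sess.create_group(f"{i:03d}")
            g.attrs["stimulated_electrode"] = s["stimulated_electrode"]
            g.attrs["pulse_descriptor"] = json.dumps(
                s["pulse_descriptor"], sort_keys=True
            )
            g.create_dataset(
                "stimulus_times_s", data=np.asarray(s["stimulus_times_s"], dtype=float)
            )


def _load_hdf5(path: Path) -> dict:
    import h5py

    with h5py.File(path, "r") as f:
        meta = {k: v for k, v in f["meta"].attrs.items()}
        meta["duration"] = float(meta["duration"])
        meta["sampling_rate"] = float(meta["sampling_rate"])
        ids = [x.decode() for x in f["layout/ids"][...]]
        xy = f["layout/xy"][...]
        layout = [
            {"id": i, "x": float(x), "y": float(y)} for i, (x, y) in zip(ids, xy)
        ]
        compartments = {k: str(v) for k, v in f["compartments"].attrs.items()}
        trains = {eid: f["trains"][eid][...].tolist() for eid in f["trains"]}
        sessions = []
        for key in sorted(f["sessions"]):
            g = f["sessions"][key]
            sessions.append(
                {
                    "stimulated_electrode": str(g.attrs["stimulated_electrode"]),
                    "stimulus_times_s": g["stimulus_times_s"][...].tolist(),
                    "pulse_descriptor": json.loads(g.attrs["pulse_descriptor"]),
                }
            )
    return {
        "meta": meta,
        "layout": layout,
        "compartments": compartments,
        "trains": trains,
        "sessions": sessions,
    }


def _save_csv_dir(d: Mapping, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    manifest = {k: d[k] for k in ("meta", "layout", "compartments", "sessions")}
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    for eid in sorted(d["trains"]):
        lines = ["time_s"] + [f"{t:.4f}" for t in d["trains"][eid]]
        (path / f"{eid}.csv").write_text("\n".join(lines) + "\n")


def _load_csv_dir(path: Path) -> dict:
    manifest = json.loads((path / "manifest.json").read_text())
    trains = {}
    for csv_path in sorted(path.glob("*.csv")):
        eid = csv_path.stem
        lines = csv_path.read_text().strip().splitlines()
        if not lines or lines[0] != "time_s":
            raise SchemaError(f"{csv_path} missing 'time_s' header")
        trains[eid] = [float(x) for x in lines[1:]]
    manifest["trains"] = trains
    return manifest
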