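"""Domain types and on-disk serialization for chronic-array experiments.

The data model mirrors a longitudinal recording study: daily sessions,
each containing a passive-fixation block followed (after pre-training)
by an active match/nonmatch block, with multi-unit or single-unit spike
trains and LFP traces recorded from a fixed 8x8 microelectrode grid.

Conventions
-----------
* All times are in seconds, relative to trial start; the event table
  stores absolute trial-relative times and analyses align to cue onset.
* Electrodes are indexed 0-based, row-major over the grid.
* Stimulus locations are indexed 0-8 row-major over the 3x3 grid;
  index 4 is the central (foveal) location.
* Spike times are ragged per-trial lists; binned counts are always
  computed on demand with half-open bins [t, t + dt).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PHASES",
    "TASKS",
    "CENTER_LOCATION",
    "PERIPHERAL_LOCATIONS",
    "GridGeometry",
    "TaskTiming",
    "TrialRecord",
    "UnitSpikeTrain",
    "LfpTrace",
    "SessionRecording",
    "ExperimentDataset",
    "DatasetValidationError",
    "SchemaError",
    "electrode_distance",
    "location_angle",
    "diametric_location",
    "write_dataset",
    "read_dataset",
]

PHASES: Tuple[str, ...] = ("pre", "I", "II", "III", "IV")
TASKS: Tuple[str, ...] = ("passive", "active")

#: index of the central (foveal) location on the 3x3 stimulus grid
CENTER_LOCATION = 4
PERIPHERAL_LOCATIONS: Tuple[int, ...] = (0, 1, 2, 3, 5, 6, 7, 8)

SCHEMA_VERSION = 1


class DatasetValidationError(ValueError):
    """An in-memory dataset violates one of its structural invariants."""


class SchemaError(ValueError):
    """An on-disk dataset does not conform to the documented schema."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridGeometry:
    """Physical layout of the chronic electrode array.

    The default is an 8x8 grid with adjacent electrodes 0.75 mm apart,
    covering 5.25 x 5.25 mm of cortex.
    """

    n_rows: int = 8
    n_cols: int = 8
    pitch_mm: float = 0.75

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pitch_mm <= 0:
            raise ValueError("pitch_mm must be positive")

    @property
    def n_electrodes(self) -> int:
        return self.n_rows * self.n_cols

    def position_mm(self, electrode: int) -> Tuple[float, float]:
        """(x, y) position of an electrode, row-major indexing."""
        if not 0 <= electrode < self.n_electrodes:
            raise IndexError(
                f"electrode {electrode} out of range [0, {self.n_electrodes})"
            )
        row, col = divmod(int(electrode), self.n_cols)
        return (col * self.pitch_mm, row * self.pitch_mm)

    def all_positions_mm(self) -> np.ndarray:
        """(n_electrodes, 2) array of (x, y) positions."""
        idx = np.arange(self.n_electrodes)
        rows, cols = np.divmod(idx, self.n_cols)
        return np.column_stack([cols * self.pitch_mm, rows * self.pitch_mm])


def electrode_distance(grid: GridGeometry, e1: int, e2: int) -> float:
    """Euclidean distance in mm between two electrodes on the physical grid."""
    x1, y1 = grid.position_mm(e1)
    x2, y2 = grid.position_mm(e2)
    return math.hypot(x1 - x2, y1 - y2)


def location_angle(location: int) -> float:
    """Polar angle (radians) of a peripheral 3x3-grid location.

    Angles are measured counterclockwise from the rightward horizontal,
    around the central fixation location. The center has no angle.
    """
    if location == CENTER_LOCATION:
        raise ValueError("the central location has no polar angle")
    if not 0 <= location <= 8:
        raise IndexError(f"location {location} out of range [0, 9)")
    row, col = divmod(int(location), 3)
    return math.atan2(1 - row, col - 1)


def diametric_location(location: int) -> int:
    """Location diametrically opposite on the 3x3 grid (center maps to itself)."""
    if not 0 <= location <= 8:
        raise IndexError(f"location {location} out of range [0, 9)")
    row, col = divmod(int(location), 3)
    return (2 - row) * 3 + (2 - col)


# ---------------------------------------------------------------------------
# task timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskTiming:
    """Durations of the trial epochs.

    The passive task and active phases I-III use fixed delays; in active
    phase IV the two delays vary per trial between ``phase4_delay_min_s``
    and ``phase4_delay_max_s`` (increased in tandem, so delay1 == delay2).
    """

    fixation_s: float = 1.0
    cue_s: float = 0.5
    sample_s: float = 0.5
    passive_delay_s: float = 1.5
    early_active_delay_s: float = 0.25
    phase4_delay_min_s: float = 0.25
    phase4_delay_max_s: float = 1.5
    post_sample_s: float = 0.5  # recorded tail after the last delay

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if not (self.phase4_delay_min_s <= self.phase4_delay_max_s):
            raise ValueError("phase-IV delay range inverted")
        if self.phase4_delay_min_s < 0.25 or self.phase4_delay_max_s > 1.5:
            raise ValueError("phase-IV delays must lie in [0.25, 1.5] s")

    def active_delay_s(self, phase: str) -> float:
        """Fixed delay for active phases I-III (phase IV is per-trial)."""
        if phase == "IV":
            raise ValueError("phase IV delays are drawn per trial")
        return self.early_active_delay_s


# ---------------------------------------------------------------------------
# trial / unit / LFP records
# ---------------------------------------------------------------------------


@dataclass
class TrialRecord:
    """Event times and condition labels for one trial.

    Event times are seconds from trial start. Passive trials have no
    choice-target onset (``targets_on`` is NaN).
    """

    trial_id: int
    task: str
    phase: str
    cue_location: int
    sample_location: int
    is_match: bool
    correct: bool
    fixation_on: float
    cue_on: float
    cue_off: float
    sample_on: float
    sample_off: float
    targets_on: float  # NaN for passive trials
    end: float

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise DatasetValidationError(f"unknown task {self.task!r}")
        if self.phase not in PHASES:
            raise DatasetValidationError(f"unknown phase {self.phase!r}")
        for loc in (self.cue_location, self.sample_location):
            if not 0 <= loc <= 8:
                raise DatasetValidationError(f"location {loc} out of range")
        if self.is_match != (self.cue_location == self.sample_location):
            raise DatasetValidationError(
                f"trial {self.trial_id}: is_match inconsistent with locations "
                f"({self.cue_location} vs {self.sample_location})"
            )
        times = [self.fixation_on, self.cue_on, self.cue_off,
                 self.sample_on, self.sample_off]
        if self.task == "active":
            if math.isnan(self.targets_on):
                raise DatasetValidationError(
                    f"trial {self.trial_id}: active trial missing targets_on"
                )
            times.append(self.targets_on)
        elif not math.isnan(self.targets_on):
            raise DatasetValidationError(
                f"trial {self.trial_id}: passive trial has a targets-on event"
            )
        times.append(self.end)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DatasetValidationError(
                f"trial {self.trial_id}: event times not strictly increasing"
            )

    @property
    def duration(self) -> float:
        return self.end - self.fixation_on

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialRecord):
            return NotImplemented
        for f in dc_fields(self):
            a, b = getattr(self, f.name), getattr(other, f.name)
            if isinstance(a, float) and isinstance(b, float):
                if not (a == b or (math.isnan(a) and math.isnan(b))):
                    return False
            elif a != b:
                return False
        return True


@dataclass
class UnitSpikeTrain:
    """Spike times of one MUA or single unit across the trials of a session."""

    unit_id: str
    kind: str  # "MUA" | "SUA"
    electrode: int
    spikes: Dict[int, np.ndarray] = field(default_factory=dict)  # trial_id -> times

    def __post_init__(self) -> None:
        if self.kind not in ("MUA", "SUA"):
            raise DatasetValidationError(f"unit {self.unit_id}: kind {self.kind!r}")
        self.spikes = {
            int(k): np.asarray(v, dtype=np.float64) for k, v in self.spikes.items()
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UnitSpikeTrain):
            return NotImplemented
        if (self.unit_id, self.kind, self.electrode) != (
            other.unit_id, other.kind, other.electrode
        ):
            return False
        if self.spikes.keys() != other.spikes.keys():
            return False
        return all(np.array_equal(self.spikes[k], other.spikes[k])
                   for k in self.spikes)


@dataclass
class LfpTrace:
    """LFP samples for one electrode across the trials of a session."""

    electrode: int
    fs: float
    samples: Dict[int, np.ndarray] = field(default_factory=dict)  # trial_id -> float32

    def __post_init__(self) -> None:
        if self.fs < 500:
            raise DatasetValidationError(
                f"electrode {self.electrode}: LFP sampling rate {self.fs} < 500 Hz"
            )
        self.samples = {
            int(k): np.asarray(v, dtype=np.float32) for k, v in self.samples.items()
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LfpTrace):
            return NotImplemented
        if (self.electrode, self.fs) != (other.electrode, other.fs):
            return False
        if self.samples.keys() != other.samples.keys():
            return False
        return all(np.array_equal(self.samples[k], other.samples[k])
                   for k in self.samples)


@dataclass
class SessionRecording:
    """One day's recording: trials, units and LFP for both task blocks."""

    session_index: int
    phase: str
    trials: List[TrialRecord]
    units: List[UnitSpikeTrain]
    lfp: List[LfpTrace]
    grid: GridGeometry = field(default_factory=GridGeometry)

    def validate(self) -> None:
        errors: List[str] = []
        trial_ids = {t.trial_id for t in self.trials}
        if len(trial_ids) != len(self.trials):
            errors.append(f"session {self.session_index}: duplicate trial ids")
        tr_by_id = {t.trial_id: t for t in self.trials}
        for u in self.units:
            if not 0 <= u.electrode < self.grid.n_electrodes:
                errors.append(f"unit {u.unit_id}: electrode {u.electrode} invalid")
            for tid, st in u.spikes.items():
                if tid not in trial_ids:
                    errors.append(f"unit {u.unit_id}: unknown trial {tid}")
                elif st.size and (st.min() < 0 or st.max() > tr_by_id[tid].duration):
                    errors.append(
                        f"unit {u.unit_id}, trial {tid}: spike outside trial bounds"
                    )
        for tr in self.lfp:
            if not 0 <= tr.electrode < self.grid.n_electrodes:
                errors.append(f"lfp electrode {tr.electrode} invalid")
            for tid, x in tr.samples.items():
                if tid not in trial_ids:
                    errors.append(f"lfp electrode {tr.electrode}: unknown trial {tid}")
                else:
                    expected = int(round(tr_by_id[tid].duration * tr.fs))
                    if abs(len(x) - expected) > 1:
                        errors.append(
                            f"lfp electrode {tr.electrode}, trial {tid}: "
                            f"length {len(x)} != expected {expected}"
                        )
        if errors:
            raise DatasetValidationError("; ".join(errors))

    def trials_for_task(self, task: str, correct_only: bool = False
                        ) -> List[TrialRecord]:
        out = [t for t in self.trials if t.task == task]
        if correct_only:
            out = [t for t in out if t.correct]
        return out


@dataclass
class ExperimentDataset:
    """Ordered list of sessions plus generation provenance."""

    sessions: List[SessionRecording]
    seed: Optional[int] = None
    config_hash: str = ""

    def validate(self) -> None:
        order = [s.session_index for s in self.sessions]
        if order != sorted(order):
            raise DatasetValidationError("sessions not ordered by date index")
        ranks = [PHASES.index(s.phase) for s in self.sessions]
        if any(b < a for a, b in zip(ranks, ranks[1:])):
            raise DatasetValidationError("phase labels decrease over sessions")
        for s in self.sessions:
            s.validate()

    def sessions_in_phase(self, phase: str) -> List[SessionRecording]:
        return [s for s in self.sessions if s.phase == phase]

    @property
    def phases_present(self) -> List[str]:
        return [p for p in PHASES if any(s.phase == p for s in self.sessions)]


def config_digest(obj) -> str:
    """Stable hash of a JSON-serializable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

_TRIAL_COLUMNS = [f.name for f in dc_fields(TrialRecord)]


def write_dataset(ds: ExperimentDataset, path) -> dict:
    """Write a dataset to ``path`` (a directory) and return the manifest.

    Layout: ``manifest.json``; per session a trial table CSV and one HDF5
    file with groups ``/units/<unit_id>/trial_<k>`` (float64 spike times)
    and ``/lfp/<electrode>/trial_<k>`` (float32 samples); grid geometry,
    phase and sampling rate stored as root attributes.
    """
    ds.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema_version": SCHEMA_VERSION,
        "seed": ds.seed,
        "config_hash": ds.config_hash,
        "sessions": [],
    }
    for s in ds.sessions:
        stem = f"session_{s.session_index:03d}"
        rows = [{c: getattr(t, c) for c in _TRIAL_COLUMNS} for t in s.trials]
        pd.DataFrame(rows, columns=_TRIAL_COLUMNS).to_csv(
            root / f"{stem}_trials.csv", index=False
        )
        h5path = root / f"{stem}.h5"
        with h5py.File(h5path, "w") as h5:
            h5.attrs["phase"] = s.phase
            h5.attrs["session_index"] = s.session_index
            h5.attrs["grid_n_rows"] = s.grid.n_rows
            h5.attrs["grid_n_cols"] = s.grid.n_cols
            h5.attrs["grid_pitch_mm"] = s.grid.pitch_mm
            if s.lfp:
                h5.attrs["lfp_fs"] = s.lfp[0].fs
            ug = h5.create_group("units")
            for u in s.units:
                g = ug.create_group(u.unit_id)
                g.attrs["kind"] = u.kind
                g.attrs["electrode"] = u.electrode
                for tid in sorted(u.spikes):
                    g.create_dataset(
                        f"trial_{tid}", data=u.spikes[tid].astype(np.float64)
                    )
            lg = h5.create_group("lfp")
            for tr in s.lfp:
                g = lg.create_group(str(tr.electrode))
                g.attrs["fs"] = tr.fs
                for tid in sorted(tr.samples):
                    g.create_dataset(
                        f"trial_{tid}", data=tr.samples[tid].astype(np.float32)
                    )
        manifest["sessions"].append(
            {
                "session_index": s.session_index,
                "phase": s.phase,
                "n_trials": len(s.trials),
                "n_units": len(s.units),
                "n_lfp_electrodes": len(s.lfp),
                "trials_csv": f"{stem}_trials.csv",
                "h5": f"{stem}.h5",
            }
        )
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _read_trials(csv_path: Path) -> List[TrialRecord]:
    df = pd.read_csv(csv_path)
    missing = set(_TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{csv_path}: missing required fields {sorted(missing)}")
    trials = []
    for row in df.itertuples(index=False):
        kw = {c: getattr(row, c) for c in _TRIAL_COLUMNS}
        kw["trial_id"] = int(kw["trial_id"])
        kw["cue_location"] = int(kw["cue_location"])
        kw["sample_location"] = int(kw["sample_location"])
        kw["is_match"] = bool(kw["is_match"])
        kw["correct"] = bool(kw["correct"])
        try:
            trials.append(TrialRecord(**kw))
        except DatasetValidationError as exc:
            raise SchemaError(f"{csv_path}: {exc}") from exc
    return trials


def read_dataset(path) -> ExperimentDataset:
    """Read and fully validate a dataset written by :func:`write_dataset`."""
    root = Path(path)
    mpath = root / "manifest.json"
    if not mpath.exists():
        raise SchemaError(f"{mpath}: manifest not found")
    with open(mpath) as fh:
        manifest = json.load(fh)
    for key in ("schema_version", "sessions"):
        if key not in manifest:
            raise SchemaError(f"{mpath}: missing required field {key!r}")
    sessions: List[SessionRecording] = []
    for entry in manifest["sessions"]:
        trials = _read_trials(root / entry["trials_csv"])
        h5path = root / entry["h5"]
        units: List[UnitSpikeTrain] = []
        lfp: List[LfpTrace] = []
        with h5py.File(h5path, "r") as h5:
            grid = GridGeometry(
                n_rows=int(h5.attrs["grid_n_rows"]),
                n_cols=int(h5.attrs["grid_n_cols"]),
                pitch_mm=float(h5.attrs["grid_pitch_mm"]),
            )
            phase = str(h5.attrs["phase"])
            for uid in sorted(h5["units"]):
                g = h5["units"][uid]
                spikes = {
                    int(name.split("_", 1)[1]): g[name][()]
                    for name in g
                }
                units.append(
                    UnitSpikeTrain(
                        unit_id=uid,
                        kind=str(g.attrs["kind"]),
                        electrode=int(g.attrs["electrode"]),
                        spikes=spikes,
                    )
                )
            for el in sorted(h5["lfp"], key=int):
                g = h5["lfp"][el]
                samples = {
                    int(name.split("_", 1)[1]): g[name][()]
                    for name in g
                }
                lfp.append(
                    LfpTrace(electrode=int(el), fs=float(g.attrs["fs"]),
                             samples=samples)
                )
        sessions.append(
            SessionRecording(
                session_index=int(entry["session_index"]),
                phase=phase,
                trials=trials,
                units=units,
                lfp=lfp,
                grid=grid,
            )
        )
    ds = ExperimentDataset(
        sessions=sessions,
        seed=manifest.get("seed"),
        config_hash=manifest.get("config_hash", ""),
    )
    try:
        ds.validate()
    except DatasetValidationError as exc:
        raise SchemaError(f"{root}: {exc}") from exc
    return ds
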