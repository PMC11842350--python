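"""Trial records and on-disk dataset layout.

A dataset directory holds, per trial, two CSV files (motion-rate channels
and EMG-rate channels, since the two streams are sampled at different
rates) plus a JSON sidecar with sampling metadata, the condition, the load
mass and the iMVC peaks; dataset-level files are ``subjects.json``,
``tasks.json`` and ``manifest.json``.  Time series can additionally be
exported as motion-storage tabular text (tab-separated, named-column
header) for interoperability with musculoskeletal tools.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rnle import Coupling, DurationClass, LiftingTask
from .trunk_model import Subject

__all__ = [
    "Trial",
    "write_trial",
    "read_trial",
    "write_subjects",
    "read_subjects",
    "write_tasks",
    "read_tasks",
    "export_storage_text",
    "list_trials",
]

EMG_CHANNELS = (
    "erector_spinae_longissimus_left",
    "erector_spinae_longissimus_right",
    "erector_spinae_iliocostalis_left",
    "erector_spinae_iliocostalis_right",
    "rectus_abdominis_middle_left",
    "rectus_abdominis_middle_right",
)


@dataclass
class Trial:
    """One lift repetition: kinematics, hand force, raw EMG and metadata."""

    subject_id: str
    risk_level: int            # designed LI level: 1, 2 or 3
    repetition: int
    load_mass: float           # kg
    fs_motion: float           # Hz
    fs_emg: float              # Hz
    box_height: np.ndarray     # m, vertical box position
    box_velocity: np.ndarray   # m/s, vertical box velocity
    angle: np.ndarray          # rad, lumbosacral flexion angle
    load_force: np.ndarray     # N, vertical hand force from the load
    emg: dict[str, np.ndarray] = field(default_factory=dict)       # V-like units
    imvc_peaks: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}_LI{self.risk_level}_rep{self.repetition}"


def _motion_frame(trial: Trial) -> pd.DataFrame:
    t = np.arange(trial.box_height.size) / trial.fs_motion
    return pd.DataFrame(
        {
            "time": t,
            "box_height": trial.box_height,
            "box_velocity": trial.box_velocity,
            "lumbosacral_angle": trial.angle,
            "load_force": trial.load_force,
        }
    )


def _emg_frame(trial: Trial) -> pd.DataFrame:
    n = next(iter(trial.emg.values())).size
    frame = {"time": np.arange(n) / trial.fs_emg}
    frame.update(trial.emg)
    return pd.DataFrame(frame)


def write_trial(directory: str | Path, trial: Trial) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _motion_frame(trial).to_csv(directory / f"{trial.trial_id}_motion.csv", index=False)
    _emg_frame(trial).to_csv(directory / f"{trial.trial_id}_emg.csv", index=False)
    sidecar = {
        "subject_id": trial.subject_id,
        "risk_level": trial.risk_level,
        "repetition": trial.repetition,
        "load_mass": trial.load_mass,
        "fs_motion": trial.fs_motion,
        "fs_emg": trial.fs_emg,
        "imvc_peaks": {k: list(v) for k, v in trial.imvc_peaks.items()},
        "emg_channels": list(trial.emg),
    }
    (directory / f"{trial.trial_id}.json").write_text(json.dumps(sidecar, indent=1))


def read_trial(directory: str | Path, trial_id: str) -> Trial:
    directory = Path(directory)
    sidecar = json.loads((directory / f"{trial_id}.json").read_text())
    motion = pd.read_csv(directory / f"{trial_id}_motion.csv")
    emg = pd.read_csv(directory / f"{trial_id}_emg.csv")
    return Trial(
        subject_id=sidecar["subject_id"],
        risk_level=int(sidecar["risk_level"]),
        repetition=int(sidecar["repetition"]),
        load_mass=float(sidecar["load_mass"]),
        fs_motion=float(sidecar["fs_motion"]),
        fs_emg=float(sidecar["fs_emg"]),
        box_height=motion["box_height"].to_numpy(),
        box_velocity=motion["box_velocity"].to_numpy(),
        angle=motion["lumbosacral_angle"].to_numpy(),
        load_force=motion["load_force"].to_numpy(),
        emg={c: emg[c].to_numpy() for c in sidecar["emg_channels"]},
        imvc_peaks={k: tuple(v) for k, v in sidecar["imvc_peaks"].items()},
    )


def list_trials(directory: str | Path) -> list[str]:
    """Trial ids found in a dataset directory (sorted)."""
    directory = Path(directory)
    ids = []
    for sidecar in directory.glob("*_rep*.json"):
        ids.append(sidecar.stem)
    return sorted(ids)


def write_subjects(directory: str | Path, subjects: list[Subject]) -> None:
    payload = [dataclasses.asdict(s) for s in subjects]
    Path(directory, "subjects.json").write_text(json.dumps(payload, indent=1))


def read_subjects(directory: str | Path) -> list[Subject]:
    payload = json.loads(Path(directory, "subjects.json").read_text())
    return [Subject(**p) for p in payload]


def write_tasks(directory: str | Path, tasks: dict[int, LiftingTask]) -> None:
    payload = {
        str(level): dataclasses.asdict(task) | {
            "duration_class": task.duration_class.value,
            "coupling": task.coupling.value,
        }
        for level, task in tasks.items()
    }
    Path(directory, "tasks.json").write_text(json.dumps(payload, indent=1))


def read_tasks(directory: str | Path) -> dict[int, LiftingTask]:
    payload = json.loads(Path(directory, "tasks.json").read_text())
    out: dict[int, LiftingTask] = {}
    for level, fields in payload.items():
        fields["duration_class"] = DurationClass(fields["duration_class"])
        fields["coupling"] = Coupling(fields["coupling"])
        out[int(level)] = LiftingTask(**fields)
    return out


def export_storage_text(path: str | Path, t: np.ndarray, columns: dict[str, np.ndarray], name: str = "series") -> None:
    """Write a motion-storage style tabular text file (tab-separated)."""
    path = Path(path)
    n = t.size
    header = [
        name,
        f"nRows={n}",
        f"nColumns={len(columns) + 1}",
        "endheader",
        "\t".join(["time", *columns]),
    ]
    body = np.column_stack([t, *[np.asarray(v) for v in columns.values()]])
    lines = ["\t".join(f"{x:.8f}" for x in row) for row in body]
    path.write_text("\n".join(header + lines) + "\n")
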