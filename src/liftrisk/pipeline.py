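"""End-to-end analysis pipeline.

Orchestrates generate -> segment -> process -> calibrate -> estimate loads
-> lifting-equation risk -> statistics/clustering as a seeded, logged,
re-runnable sequence.  Each stage's products are written to disk
(CSV/JSON) so any stage can be inspected or re-run independently, and a
manifest records the configuration, per-stage timings and output
checksums.

Per-trial processing chain
--------------------------
1. 6 Hz zero-phase low-pass of box kinematics, joint angle and hand force;
2. lift-cycle segmentation from the vertical box velocity (0.025 m/s);
3. EMG envelopes (20-400 Hz band-pass, rectify, 5 Hz low-pass), iMVC
   normalisation, and resampling onto the motion time base as excitations;
4. inverse-dynamics moment from the filtered angle and hand force.

Calibration uses only the low- and high-risk trials of each subject; the
calibrated model then produces EMG-driven moments and L5-S1 loads for all
trials, which feed the risk statistics and the cluster analysis.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import trunk_model as tm
from .calibration import CalibrationConfig, CalibrationResult, CalTrial, calibrate, validate
from .io import Trial, list_trials, read_subjects, read_tasks, read_trial
from .rnle import compute_li
from .risk_analysis import (
    TrialSummary,
    cluster_loads,
    normality_test,
    summaries_to_frame,
    summarize_trial,
    wilcoxon_pairwise,
)
from .signals import (
    EnvelopeConfig,
    LiftCycle,
    SegmentationConfig,
    TimeSeries,
    emg_envelope,
    lowpass_motion,
    normalize_envelope,
    segment_lift,
)
from .synthetic_data import Dataset, GeneratorConfig, generate_dataset
from .trunk_model import MtuGroup, Subject, default_groups

logger = logging.getLogger("liftrisk")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "StageError",
    "ProcessedTrial",
    "process_trial",
    "run_all",
    "validate_dataset",
]

_CHANNEL_TO_GROUP = {
    "erector_spinae_longissimus_left": "longissimus_left",
    "erector_spinae_longissimus_right": "longissimus_right",
    "erector_spinae_iliocostalis_left": "iliocostalis_left",
    "erector_spinae_iliocostalis_right": "iliocostalis_right",
    "rectus_abdominis_middle_left": "rectus_abdominis_left",
    "rectus_abdominis_middle_right": "rectus_abdominis_right",
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str | Path = "results/pipeline"
    seed: int = 0
    generator: GeneratorConfig | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    envelope: EnvelopeConfig = field(default_factory=EnvelopeConfig)
    calibration: CalibrationConfig | None = None
    k_clusters: int = 6
    write_dataset: bool = False


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    stage_seconds: dict[str, float] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started: float = 0.0
    finished: float = 0.0


@dataclass
class ProcessedTrial:
    """Stage products for one trial, before and after load estimation."""

    trial: Trial
    cycle: LiftCycle
    angle_filtered: TimeSeries
    load_force_filtered: TimeSeries
    envelopes: dict[str, TimeSeries]       # iMVC-normalized, EMG rate
    excitations: dict[str, np.ndarray]     # per group, motion rate
    m_id: np.ndarray
    loads: tm.JointLoadSeries | None = None
    summary: TrialSummary | None = None

    @property
    def cal_trial(self) -> CalTrial:
        return CalTrial(
            name=self.trial.trial_id,
            condition=self.trial.risk_level,
            angle=self.angle_filtered,
            m_id=self.m_id,
            excitations=self.excitations,
        )


def process_trial(
    trial: Trial,
    subject: Subject,
    seg_cfg: SegmentationConfig | None = None,
    env_cfg: EnvelopeConfig | None = None,
) -> ProcessedTrial:
    """Run the per-trial conditioning chain (no model parameters needed)."""
    seg_cfg = seg_cfg or SegmentationConfig()
    env_cfg = env_cfg or EnvelopeConfig()
    fs = trial.fs_motion
    height = lowpass_motion(TimeSeries(values=trial.box_height, fs=fs))
    velocity = lowpass_motion(TimeSeries(values=trial.box_velocity, fs=fs))
    angle = lowpass_motion(TimeSeries(values=trial.angle, fs=fs))
    load_force = lowpass_motion(TimeSeries(values=trial.load_force, fs=fs))
    cycle = segment_lift(height, velocity, seg_cfg)

    t_motion = np.arange(trial.angle.size) / fs
    envelopes: dict[str, TimeSeries] = {}
    excitations: dict[str, np.ndarray] = {}
    for channel, raw in trial.emg.items():
        env = emg_envelope(TimeSeries(values=raw, fs=trial.fs_emg), env_cfg)
        env = normalize_envelope(env, trial.imvc_peaks[channel])
        envelopes[channel] = env
        u = np.interp(t_motion, env.t, np.squeeze(env.values))
        excitations[_CHANNEL_TO_GROUP[channel]] = np.clip(u, 0.0, 1.0)

    m_id = np.squeeze(
        tm.inverse_dynamics_moment(angle, subject, load_force).values
    )
    return ProcessedTrial(
        trial=trial,
        cycle=cycle,
        angle_filtered=angle,
        load_force_filtered=load_force,
        envelopes=envelopes,
        excitations=excitations,
        m_id=m_id,
    )


def estimate_loads(
    processed: ProcessedTrial,
    subject: Subject,
    groups: list[MtuGroup],
) -> ProcessedTrial:
    """EMG-driven moment + joint reaction + body normalization + summary."""
    m_emg, forces = tm.emg_driven_moment(
        groups, processed.excitations, processed.angle_filtered, return_forces=True
    )
    loads = tm.joint_reaction(
        processed.angle_filtered,
        subject,
        np.squeeze(m_emg.values),
        forces,
        processed.load_force_filtered,
    )
    loads = tm.normalize_loads(loads, subject)
    processed.loads = loads
    processed.summary = summarize_trial(
        processed.trial, loads, processed.envelopes, processed.cycle
    )
    return processed


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_dict(cfg: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return enc(cfg)


def run_all(cfg: PipelineConfig | None = None, dataset: Dataset | None = None) -> RunManifest:
    """Execute every stage in order and write stage outputs + manifest.

    ``dataset`` may be supplied (e.g. pre-generated or loaded from disk);
    otherwise it is generated from ``cfg.generator`` / ``cfg.seed``.
    """
    cfg = cfg or PipelineConfig()
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_dict = _config_dict(cfg)
    manifest = RunManifest(
        config=config_dict,
        config_hash=hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        started=time.time(),
    )

    def stage(name):
        class _Timer:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is None:
                    manifest.stage_seconds[name] = time.perf_counter() - self.t0
                    logger.info(
                        "stage %s: done in %.2fs", name, manifest.stage_seconds[name]
                    )
                else:
                    # leave the failing stage out of stage_seconds so the
                    # error can be tagged with it; keep a partial manifest
                    _write_manifest(out_dir, manifest)
                return False

        return _Timer()

    try:
        with stage("generate"):
            if dataset is None:
                gen_cfg = cfg.generator or GeneratorConfig(seed=cfg.seed)
                dataset = generate_dataset(
                    gen_cfg, out_dir / "dataset" if cfg.write_dataset else None
                )
        with stage("rnle"):
            rnle_rows = []
            for level, task in sorted(dataset.tasks.items()):
                res = compute_li(task)
                rnle_rows.append(
                    {"risk_level": level, "load_mass": task.load_mass,
                     "H": task.H, "V": task.V, "D": task.D,
                     **res.multipliers, "RWL": res.RWL, "LI": res.LI,
                     "risk_band": res.risk_level.value}
                )
            pd.DataFrame(rnle_rows).to_csv(out_dir / "rnle_conditions.csv", index=False)
        with stage("process"):
            subjects = {s.subject_id: s for s in dataset.subjects}
            processed = [
                process_trial(t, subjects[t.subject_id], cfg.segmentation, cfg.envelope)
                for t in dataset.trials
            ]
        with stage("calibrate"):
            cal_cfg = cfg.calibration or CalibrationConfig(seed=cfg.seed)
            calibrations: dict[str, CalibrationResult] = {}
            validations: dict[str, dict] = {}
            for sid in subjects:
                own = [p.cal_trial for p in processed if p.trial.subject_id == sid]
                result = calibrate(own, cal_cfg)
                calibrations[sid] = result
                held_out = [
                    c for c in own if c.condition not in cal_cfg.calibration_conditions
                ]
                if held_out:
                    validations[sid] = validate(result, held_out)
            cal_report = {
                sid: {
                    "params": r.params,
                    "objective": r.objective,
                    "per_trial_rmse_norm": r.per_trial_rmse_norm,
                    "converged": r.converged,
                    "n_evaluations": r.n_evaluations,
                    "held_out": validations.get(sid, {}),
                }
                for sid, r in calibrations.items()
            }
            (out_dir / "calibration.json").write_text(json.dumps(cal_report, indent=1))
        with stage("loads"):
            for p in processed:
                estimate_loads(p, subjects[p.trial.subject_id],
                               calibrations[p.trial.subject_id].groups)
            summaries = summaries_to_frame([p.summary for p in processed])
            summaries.to_csv(out_dir / "summaries.csv", index=False)
        with stage("analyze"):
            stats_report: dict = {"normality": {}, "wilcoxon": {}}
            metrics = ["rom_deg", "peak_moment_norm", "peak_compression_bw",
                       "peak_shear_bw", "peak_emg_longissimus",
                       "peak_emg_iliocostalis", "peak_emg_rectus_abdominis"]
            for metric in metrics:
                stats_report["normality"][metric] = {
                    str(level): dict(
                        zip(("W", "p"),
                            normality_test(
                                summaries.loc[summaries.risk_level == level, metric]
                            ))
                    )
                    for level in sorted(summaries.risk_level.unique())
                }
                stats_report["wilcoxon"][metric] = wilcoxon_pairwise(
                    summaries, metric
                ).to_dict(orient="records")
            report = cluster_loads(summaries, k=cfg.k_clusters, seed=cfg.seed)
            clusters = {
                "k": report.k,
                "assignments": report.assignments.tolist(),
                "centroids": report.centroids.to_dict(orient="records"),
                "ttests": report.ttests.to_dict(orient="records"),
                "crosstab": {
                    str(level): row.to_dict()
                    for level, row in report.crosstab.iterrows()
                },
                "silhouette": report.silhouette,
            }
            (out_dir / "stats.json").write_text(json.dumps(stats_report, indent=1))
            (out_dir / "clusters.json").write_text(json.dumps(clusters, indent=1))
    except StageError:
        raise
    except Exception as exc:  # tag the failing stage for the caller
        failed = next(
            (n for n in ("generate", "rnle", "process", "calibrate", "loads", "analyze")
             if n not in manifest.stage_seconds),
            "unknown",
        )
        raise StageError(failed, str(exc)) from exc

    manifest.finished = time.time()
    for name in ("rnle_conditions.csv", "calibration.json", "summaries.csv",
                 "stats.json", "clusters.json"):
        path = out_dir / name
        if path.exists():
            manifest.outputs[name] = _sha256(path)
    _write_manifest(out_dir, manifest)
    return manifest


def _write_manifest(out_dir: Path, manifest: RunManifest) -> None:
    (out_dir / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=1, default=str)
    )


def validate_dataset(path: str | Path) -> dict:
    """Schema check of a dataset directory (report-only, never raises)."""
    path = Path(path)
    report = {"path": str(path), "trials": 0, "issues": []}
    if not path.exists():
        report["issues"].append("dataset directory does not exist")
        return report
    ids = list_trials(path)
    if not ids:
        report["issues"].append("empty dataset: no trial sidecars found")
    try:
        read_subjects(path)
    except Exception as exc:
        report["issues"].append(f"subjects.json unreadable: {exc}")
    try:
        read_tasks(path)
    except Exception as exc:
        report["issues"].append(f"tasks.json unreadable: {exc}")
    for trial_id in ids:
        try:
            trial = read_trial(path, trial_id)
            missing = [c for c in _CHANNEL_TO_GROUP if c not in trial.emg]
            if missing:
                report["issues"].append(f"{trial_id}: missing EMG channels {missing}")
            report["trials"] += 1
        except Exception as exc:
            report["issues"].append(f"{trial_id}: unreadable ({exc})")
    return report
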