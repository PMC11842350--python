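"""Seeded synthetic lifting datasets.

Generates data with the statistical structure the analysis pipeline
assumes, so every stage is testable without any experimental recordings:

* three lifting conditions designed to LI = 1, 2, 3 (loads 21/21/20 kg)
  with identical asymmetry, frequency and coupling multipliers;
* 7 subjects x 3 conditions x 3 repetitions = 63 trials by default;
* minimum-jerk box trajectories with a clean 0.025 m/s velocity crossing;
* lumbosacral flexion arcs whose range of motion increases with risk level;
* per-subject ground-truth strength scales, and raw-like surface EMG
  synthesised as amplitude-modulated 20-400 Hz noise whose envelope tracks
  the excitation required to reproduce the inverse-dynamics moment through
  the trunk model (with risk-scaled antagonist co-activation, which makes
  compression grow faster than moment across levels).

Every trial stores its ground truth (excitations, moments, loads) so that
parameter-recovery and self-consistency tests can close the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import trunk_model as tm
from .io import EMG_CHANNELS, Trial, write_subjects, write_tasks, write_trial
from .rnle import LiftingTask, compute_li, design_task_for_li
from .signals import TimeSeries
from .trunk_model import G, MtuGroup, Role, Subject, default_groups

__all__ = [
    "GeneratorConfig",
    "TrialTruth",
    "Dataset",
    "CapacityError",
    "DegenerateLiftError",
    "make_subject",
    "make_strength_scales",
    "make_conditions",
    "make_trajectory",
    "make_angle_profile",
    "forward_simulate",
    "generate_dataset",
    "apply_scales",
    "min_jerk_position",
    "min_jerk_velocity",
]


class CapacityError(RuntimeError):
    """Required moment exceeds total muscle capacity; raise f_max."""


class DegenerateLiftError(ValueError):
    """The task has no vertical travel; no lift can be synthesised."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the study protocol: 7 subjects, three conditions at
    LI = 1/2/3 with 21/21/20 kg loads, 3 repetitions each, motion sampled
    at 340 Hz and EMG at 1000 Hz.  Trunk flexion peaks of 45/65/85 degrees
    encode the increasing range of motion across risk levels, and the
    antagonist co-activation 0.05 + 0.03 * level makes compression grow
    faster than the net moment.
    """

    n_subjects: int = 7
    li_targets: tuple[float, ...] = (1.0, 2.0, 3.0)
    load_masses: tuple[float, ...] = (21.0, 21.0, 20.0)
    repetitions: int = 3
    fs_motion: float = 340.0
    fs_emg: float = 1000.0
    lift_duration: float = 2.0   # s, box in motion
    lead_in: float = 0.5         # s before lift onset
    tail: float = 0.7            # s settling after the lift
    theta_peaks_deg: tuple[float, ...] = (45.0, 65.0, 85.0)
    theta_jitter_sd_deg: float = 3.0
    coactivation_base: float = 0.05
    coactivation_per_level: float = 0.03
    emg_gain_mvc: float = 0.5    # raw-EMG amplitude at maximal effort, mV
    tail_velocity_noise: float = 0.004  # m/s, below the 0.025 m/s threshold
    imvc_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects, self.repetitions) <= 0:
            raise ValueError("counts must be positive")
        if any(m <= 0 for m in self.load_masses):
            raise ValueError("load masses must be positive")


@dataclass
class TrialTruth:
    """Ground truth stored alongside one generated trial."""

    excitations: dict[str, np.ndarray]   # per group, motion-rate
    m_id: np.ndarray                     # inverse-dynamics moment, N m
    m_true: np.ndarray                   # EMG-driven moment at true params
    compression: np.ndarray              # N
    shear: np.ndarray                    # N
    f_max_scales: dict[str, float]       # per group type


@dataclass
class Dataset:
    """In-memory synthetic dataset with aligned trials and ground truth."""

    config: GeneratorConfig
    subjects: list[Subject]
    tasks: dict[int, LiftingTask]
    trials: list[Trial]
    truths: list[TrialTruth]
    subject_scales: dict[str, dict[str, float]]

    def trials_for(self, subject_id: str, risk_level: int | None = None) -> list[Trial]:
        out = [t for t in self.trials if t.subject_id == subject_id]
        if risk_level is not None:
            out = [t for t in out if t.risk_level == risk_level]
        return out

    def truth_for(self, trial: Trial) -> TrialTruth:
        return self.truths[self.trials.index(trial)]


# --------------------------------------------------------------------------
# minimum-jerk primitives


def min_jerk_position(tau):
    """Normalized minimum-jerk displacement, 0 -> 1 over tau in [0, 1]."""
    tau = np.clip(np.asarray(tau, dtype=float), 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_velocity(tau):
    """d/dtau of :func:`min_jerk_position`; peak 1.875 at tau = 0.5."""
    tau = np.asarray(tau, dtype=float)
    v = 30 * tau**2 - 60 * tau**3 + 30 * tau**4
    return np.where((tau < 0) | (tau > 1), 0.0, v)


# --------------------------------------------------------------------------
# subjects and conditions

_GROUP_TYPES = ("longissimus", "iliocostalis", "rectus_abdominis")


def make_subject(seed: int | np.random.Generator, subject_id: str = "S1") -> Subject:
    """Draw one subject: mass ~ N(75, 8) kg truncated to [55, 100],
    BMI ~ N(24.70, 1.80), stature derived; fixed segment fractions."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    mass = float(np.clip(rng.normal(75.0, 8.0), 55.0, 100.0))
    bmi = float(np.clip(rng.normal(24.70, 1.80), 19.0, 31.0))
    height = float(np.sqrt(mass / bmi))
    trunk_length = 0.30 * height
    trunk_mass = 0.43 * mass
    return Subject(
        subject_id=subject_id,
        body_mass=mass,
        height=height,
        trunk_mass=trunk_mass,
        trunk_com_distance=0.45 * trunk_length,
        trunk_inertia=trunk_mass * (0.60 * trunk_length) ** 2,
        arms_head_mass=0.15 * mass,
        arms_head_lever=0.55 * trunk_length,
        load_lever=1.0 * trunk_length,
    )


def make_strength_scales(rng: np.random.Generator) -> dict[str, float]:
    """Per-subject ground-truth f_max scales, one per group type."""
    return {g: float(rng.uniform(0.8, 1.2)) for g in _GROUP_TYPES}


def apply_scales(groups: list[MtuGroup], scales: dict[str, float]) -> list[MtuGroup]:
    """Return groups with f_max multiplied by the matching type scale."""
    out = []
    for g in groups:
        scale = next((s for t, s in scales.items() if g.name.startswith(t)), 1.0)
        out.append(replace(g, params=replace(g.params, f_max=g.params.f_max * scale)))
    return out


def make_conditions(cfg: GeneratorConfig | None = None) -> dict[int, LiftingTask]:
    """The three study conditions, designed so computed LI hits the targets
    while AM, FM and CM stay identical across conditions."""
    cfg = cfg or GeneratorConfig()
    template = LiftingTask(load_mass=cfg.load_masses[0], A=0.0, F=1.0)
    tasks: dict[int, LiftingTask] = {}
    for level, (li, load) in enumerate(zip(cfg.li_targets, cfg.load_masses), start=1):
        tasks[level] = design_task_for_li(li, load, ("H", "V", "D"), fixed=template)
    return tasks


# --------------------------------------------------------------------------
# per-trial kinematics


def make_trajectory(
    task: LiftingTask,
    duration: float,
    fs: float,
    lead_in: float = 0.5,
    tail: float = 0.7,
    rng: np.random.Generator | None = None,
    tail_velocity_noise: float = 0.004,
) -> tuple[TimeSeries, TimeSeries]:
    """Minimum-jerk vertical box trajectory from V to V + D (cm -> m).

    Returns (height, velocity) series covering lead-in + lift + settling
    tail; the tail carries sub-threshold velocity noise so segmentation
    sees a realistic (but clean) end crossing.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if task.D <= 0:
        raise DegenerateLiftError("task has zero vertical travel distance")
    rng = rng or np.random.default_rng(0)
    v0 = task.V / 100.0
    d = task.D / 100.0
    n_lead = round(lead_in * fs)
    n_lift = round(duration * fs)
    n_tail = round(tail * fs)
    t_lift = np.arange(n_lift) / fs
    tau = t_lift / duration
    height = np.concatenate(
        [
            np.full(n_lead, v0),
            v0 + d * min_jerk_position(tau),
            np.full(n_tail, v0 + d),
        ]
    )
    velocity = np.concatenate(
        [
            np.zeros(n_lead),
            (d / duration) * min_jerk_velocity(tau),
            rng.normal(0.0, tail_velocity_noise, n_tail),
        ]
    )
    return (
        TimeSeries(values=height, fs=fs),
        TimeSeries(values=velocity, fs=fs),
    )


def make_angle_profile(
    task: LiftingTask,
    duration_total: float,
    fs: float,
    risk_level: int,
    theta_peaks_deg: tuple[float, ...] = (45.0, 65.0, 85.0),
    jitter_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> TimeSeries:
    """Smooth flexion-extension arc; range of motion increases with risk.

    theta(t) = theta_peak * sin^2(pi t / T): the trunk flexes to grab the
    box and extends back to upright, peaking mid-trial.
    """
    if risk_level not in (1, 2, 3):
        raise ValueError("risk_level must be 1, 2 or 3")
    rng = rng or np.random.default_rng(0)
    peak = theta_peaks_deg[risk_level - 1] + (rng.normal(0.0, jitter_deg) if jitter_deg else 0.0)
    n = round(duration_total * fs)
    t = np.arange(n) / fs
    theta = np.deg2rad(peak) * np.sin(np.pi * t / (duration_total)) ** 2
    return TimeSeries(values=theta, fs=fs)


# --------------------------------------------------------------------------
# forward simulation


# Extensor recruitment weighting: activation_g = c(t) * w_g(theta).  The
# iliocostalis is recruited relatively more at deeper flexion, which gives
# the two extensor groups distinguishable activation profiles (and makes
# their strength scales separately identifiable from moment tracking).
def _recruitment_weight(name: str, theta: np.ndarray) -> np.ndarray:
    if name.startswith("iliocostalis"):
        return 0.7 + 0.3 * np.clip(theta, 0.0, None)
    return np.ones_like(theta)


def _required_excitations(
    groups: list[MtuGroup],
    angle: TimeSeries,
    m_id: np.ndarray,
    coactivation: float,
) -> dict[str, np.ndarray]:
    """Distribute the inverse-dynamics moment over the extensor groups.

    Flexors receive the constant antagonist excitation; the passive pool
    its fixed drive; extensor activations are c(t) * w_g(theta) with a
    single common scaling c(t) solving the (linear) sagittal moment
    balance sample-by-sample.
    """
    theta = np.squeeze(angle.values)
    omega, _ = tm._derivatives(theta, angle.fs)
    fixed_moment = np.zeros_like(theta)
    gains = np.zeros_like(theta)
    weights: dict[str, np.ndarray] = {}
    for g in groups:
        l_mt, r = tm.mtu_geometry(theta, g)
        v_mt = int(g.role) * r * omega
        l_norm = (l_mt - g.params.l_ts) / g.params.l_opt
        fl = tm.force_length_active(l_norm)
        fv = tm.force_velocity(v_mt / (tm.VMAX_LOPT_PER_S * g.params.l_opt))
        fp = tm.force_length_passive(l_norm)
        fixed_moment += int(g.role) * r * g.params.f_max * fp
        if g.role == Role.FLEXOR:
            a_f = tm.activation(coactivation, g.params.shape_A)
            fixed_moment += int(g.role) * r * g.params.f_max * a_f * fl * fv
        elif g.emg_channel is None:
            a_p = tm.activation(g.passive_excitation, g.params.shape_A)
            fixed_moment += int(g.role) * r * g.params.f_max * a_p * fl * fv
        else:
            w = _recruitment_weight(g.name, theta)
            weights[g.name] = w
            gains += w * r * g.params.f_max * fl * fv
    needed = m_id - fixed_moment
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(gains > 0, needed / gains, 0.0)
    w_max = np.max([w for w in weights.values()], axis=0)
    if np.any(c * w_max > 1.0 + 1e-9):
        raise CapacityError(
            f"required extensor activation {np.max(c * w_max):.2f} exceeds 1; "
            "raise f_max or reduce the task demand"
        )
    c = np.clip(c, 0.0, None)
    excitations: dict[str, np.ndarray] = {}
    for g in groups:
        if g.emg_channel is None:
            excitations[g.name] = np.full_like(theta, g.passive_excitation)
        elif g.role == Role.FLEXOR:
            excitations[g.name] = np.full_like(theta, coactivation)
        else:
            a_g = np.clip(c * weights[g.name], 0.0, 1.0)
            excitations[g.name] = tm.excitation_for_activation(a_g, g.params.shape_A)
    return excitations


def _synth_emg_channel(
    u_motion: np.ndarray,
    fs_motion: float,
    fs_emg: float,
    gain: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Amplitude-modulated band-limited noise whose linear envelope tracks
    ``u_motion`` (in units of the maximal-effort gain)."""
    duration = u_motion.size / fs_motion
    n = round(duration * fs_emg)
    t_emg = np.arange(n) / fs_emg
    t_mot = np.arange(u_motion.size) / fs_motion
    u = np.interp(t_emg, t_mot, u_motion)
    carrier = rng.standard_normal(n)
    sos = sps.butter(4, (20.0, 400.0), btype="band", fs=fs_emg, output="sos")
    carrier = sps.sosfiltfilt(sos, carrier)
    # scale so the rectified-and-smoothed envelope of the carrier is ~1
    carrier /= np.std(carrier) * np.sqrt(2.0 / np.pi)
    return gain * u * carrier


def forward_simulate(
    subject: Subject,
    task: LiftingTask,
    risk_level: int,
    repetition: int,
    scales: dict[str, float],
    cfg: GeneratorConfig,
    seed: int | np.random.SeedSequence,
) -> tuple[Trial, TrialTruth]:
    """Synthesise one trial consistent with the trunk-model equations.

    Pipeline inversion: kinematics -> inverse-dynamics moment -> extensor
    excitations (plus risk-scaled co-activation) -> raw-like EMG whose
    processed envelope reproduces those excitations.
    """
    rng = np.random.default_rng(seed)
    groups = apply_scales(default_groups(), scales)
    duration_total = cfg.lead_in + cfg.lift_duration + cfg.tail
    height, velocity = make_trajectory(
        task,
        cfg.lift_duration,
        cfg.fs_motion,
        lead_in=cfg.lead_in,
        tail=cfg.tail,
        rng=rng,
        tail_velocity_noise=cfg.tail_velocity_noise,
    )
    angle = make_angle_profile(
        task,
        duration_total,
        cfg.fs_motion,
        risk_level,
        cfg.theta_peaks_deg,
        jitter_deg=cfg.theta_jitter_sd_deg,
        rng=rng,
    )
    n = min(angle.n_samples, height.n_samples)
    angle = TimeSeries(values=angle.values[:n], fs=cfg.fs_motion)
    height = TimeSeries(values=height.values[:n], fs=cfg.fs_motion)
    velocity = TimeSeries(values=velocity.values[:n], fs=cfg.fs_motion)

    # vertical hand force: load weight plus the box's inertial force
    accel = np.gradient(np.squeeze(velocity.values), 1.0 / cfg.fs_motion)
    load_force = task.load_mass * (G + accel)
    load_series = TimeSeries(values=load_force, fs=cfg.fs_motion)

    m_id = np.squeeze(
        tm.inverse_dynamics_moment(angle, subject, load_series).values
    )
    coact = cfg.coactivation_base + cfg.coactivation_per_level * risk_level
    excitations = _required_excitations(groups, angle, m_id, coact)
    m_true_series, forces = tm.emg_driven_moment(
        groups, excitations, angle, return_forces=True
    )
    loads = tm.joint_reaction(
        angle, subject, np.squeeze(m_true_series.values), forces, load_series
    )

    emg: dict[str, np.ndarray] = {}
    imvc: dict[str, tuple[float, float, float]] = {}
    for g in groups:
        if g.emg_channel is None:
            continue
        emg[g.emg_channel] = _synth_emg_channel(
            excitations[g.name], cfg.fs_motion, cfg.fs_emg, cfg.emg_gain_mvc, rng
        )
        peaks = cfg.emg_gain_mvc * (1.0 + rng.normal(0.0, cfg.imvc_jitter_sd, 3))
        imvc[g.emg_channel] = tuple(float(p) for p in peaks)

    trial = Trial(
        subject_id=subject.subject_id,
        risk_level=risk_level,
        repetition=repetition,
        load_mass=task.load_mass,
        fs_motion=cfg.fs_motion,
        fs_emg=cfg.fs_emg,
        box_height=np.squeeze(height.values),
        box_velocity=np.squeeze(velocity.values),
        angle=np.squeeze(angle.values),
        load_force=load_force,
        emg=emg,
        imvc_peaks=imvc,
    )
    truth = TrialTruth(
        excitations=excitations,
        m_id=m_id,
        m_true=np.squeeze(m_true_series.values),
        compression=loads.compression,
        shear=loads.shear,
        f_max_scales=dict(scales),
    )
    return trial, truth


def generate_dataset(
    cfg: GeneratorConfig | None = None,
    out_dir: str | Path | None = None,
) -> Dataset:
    """Generate the full dataset (and optionally write it to ``out_dir``).

    A single seed fans out deterministically to per-subject and per-trial
    seeds through :class:`numpy.random.SeedSequence`.
    """
    cfg = cfg or GeneratorConfig()
    root = np.random.SeedSequence(cfg.seed)
    subject_seeds = root.spawn(cfg.n_subjects)
    tasks = make_conditions(cfg)
    subjects: list[Subject] = []
    trials: list[Trial] = []
    truths: list[TrialTruth] = []
    subject_scales: dict[str, dict[str, float]] = {}
    for i, sseq in enumerate(subject_seeds, start=1):
        srng = np.random.default_rng(sseq)
        subject = make_subject(srng, subject_id=f"S{i}")
        scales = make_strength_scales(srng)
        subjects.append(subject)
        subject_scales[subject.subject_id] = scales
        trial_seeds = sseq.spawn(len(tasks) * cfg.repetitions)
        k = 0
        for level, task in sorted(tasks.items()):
            for rep in range(1, cfg.repetitions + 1):
                trial, truth = forward_simulate(
                    subject, task, level, rep, scales, cfg, trial_seeds[k]
                )
                trials.append(trial)
                truths.append(truth)
                k += 1
    dataset = Dataset(
        config=cfg,
        subjects=subjects,
        tasks=tasks,
        trials=trials,
        truths=truths,
        subject_scales=subject_scales,
    )
    if out_dir is not None:
        _write_dataset(dataset, Path(out_dir))
    return dataset


def _write_dataset(dataset: Dataset, out_dir: Path) -> None:
    import json

    out_dir.mkdir(parents=True, exist_ok=True)
    write_subjects(out_dir, dataset.subjects)
    write_tasks(out_dir, dataset.tasks)
    for trial in dataset.trials:
        write_trial(out_dir, trial)
    manifest = {
        "seed": dataset.config.seed,
        "n_subjects": dataset.config.n_subjects,
        "repetitions": dataset.config.repetitions,
        "li_targets": list(dataset.config.li_targets),
        "load_masses": list(dataset.config.load_masses),
        "n_trials": len(dataset.trials),
        "subject_scales": dataset.subject_scales,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
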