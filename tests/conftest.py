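import numpy as np
import pytest

from liftrisk.calibration import CalibrationConfig, CalTrial, calibrate
from liftrisk.pipeline import PipelineConfig, run_all
from liftrisk.signals import TimeSeries
from liftrisk.synthetic_data import GeneratorConfig, generate_dataset


def truth_cal_trials(dataset, subject_id):
    """CalTrials built from a subject's ground-truth excitations and ID
    moments (the noiseless route, bypassing EMG synthesis)."""
    out = []
    for trial, truth in zip(dataset.trials, dataset.truths):
        if trial.subject_id != subject_id:
            continue
        out.append(
            CalTrial(
                name=trial.trial_id,
                condition=trial.risk_level,
                angle=TimeSeries(values=trial.angle, fs=trial.fs_motion),
                m_id=truth.m_id,
                excitations=truth.excitations,
            )
        )
    return out


@pytest.fixture(scope="session")
def small_dataset():
    """Two subjects, three repetitions: enough for per-trial machinery."""
    return generate_dataset(GeneratorConfig(n_subjects=2, repetitions=3, seed=42))


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-sized dataset: 7 subjects x 3 conditions x 3 reps."""
    return generate_dataset(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def recovery_result(small_dataset):
    """Strength-scale calibration of subject S1 on its LI1+LI3 trials,
    driven by ground-truth (noiseless) excitations."""
    trials = truth_cal_trials(small_dataset, "S1")
    cfg = CalibrationConfig(
        adjustable=(
            ("f_max_scale", "longissimus"),
            ("f_max_scale", "iliocostalis"),
            ("f_max_scale", "rectus_abdominis"),
        ),
        seed=1,
        restarts=3,
        max_evaluations=1500,
    )
    return calibrate(trials, cfg), trials


@pytest.fixture(scope="session")
def pipeline_run(default_dataset, tmp_path_factory):
    """One end-to-end pipeline run on the study-sized dataset with a
    reduced optimiser budget (sufficient: the objective is near its floor
    well before the full budget)."""
    out = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(
        out_dir=out,
        seed=0,
        calibration=CalibrationConfig(seed=0, restarts=2, max_evaluations=600),
        k_clusters=6,
    )
    manifest = run_all(cfg, dataset=default_dataset)
    return cfg, manifest, out


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
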