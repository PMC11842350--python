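"""Personalize the trunk model per subject on the low/high-risk trials.

Calibrates the lumped MTU parameters (strength scales, activation shape
factors, shared optimal-length scale) by moment tracking on the LI1 and
LI3 trials, then validates on the held-out LI2 trials.  Writes
results/calibration.json including the raw parameter vector so the next
step can rebuild the calibrated model without re-optimizing.
"""

import json
from pathlib import Path

from liftrisk.calibration import CalibrationConfig, calibrate, validate
from liftrisk.io import list_trials, read_subjects, read_trial
from liftrisk.pipeline import process_trial

DATASET_DIR = Path("scratch/dataset")
RESULTS = Path("results")
SEED = 0


def main() -> None:
    subjects = {s.subject_id: s for s in read_subjects(DATASET_DIR)}
    processed = {sid: [] for sid in subjects}
    for trial_id in list_trials(DATASET_DIR):
        trial = read_trial(DATASET_DIR, trial_id)
        processed[trial.subject_id].append(
            process_trial(trial, subjects[trial.subject_id]).cal_trial
        )
    cfg = CalibrationConfig(seed=SEED, restarts=3, max_evaluations=1500)
    report = {}
    for sid, own in processed.items():
        result = calibrate(own, cfg)
        held = [c for c in own if c.condition not in cfg.calibration_conditions]
        held_report = validate(result, held)
        report[sid] = {
            "params": {k: round(v, 4) for k, v in result.params.items()},
            "x": list(result.x),
            "adjustable": [list(a) for a in cfg.adjustable],
            "objective": result.objective,
            "held_out_li2_rmse_norm": {
                k: round(v["rmse_norm"], 4) for k, v in held_report.items()
            },
        }
        worst = max(v["rmse_norm"] for v in held_report.values())
        print(f"{sid}: calibration objective {result.objective:.4f}, "
              f"worst held-out LI2 moment RMSE {100 * worst:.1f}% of peak")
    RESULTS.mkdir(exist_ok=True)
    (RESULTS / "calibration.json").write_text(json.dumps(report, indent=1))
    print(f"\nwrote {RESULTS / 'calibration.json'}")


if __name__ == "__main__":
    main()
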