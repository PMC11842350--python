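"""Score the three lifting conditions with the revised lifting equation.

Recomputes the six multipliers, the recommended weight limit and the
lifting index for each designed condition and confirms that the asymmetry,
frequency and coupling multipliers are identical across conditions (only
load and geometry differ).  Writes results/rnle_conditions.csv.
"""

from pathlib import Path

import pandas as pd

from liftrisk.io import read_tasks
from liftrisk.rnle import compute_li

DATASET_DIR = Path("scratch/dataset")
RESULTS = Path("results")


def main() -> None:
    tasks = read_tasks(DATASET_DIR)
    rows = []
    for level, task in sorted(tasks.items()):
        res = compute_li(task)
        rows.append({"risk_level": level, "load_kg": task.load_mass,
                     **{k: round(v, 3) for k, v in res.multipliers.items()},
                     "RWL_kg": round(res.RWL, 2), "LI": round(res.LI, 3),
                     "band": res.risk_level.value})
    frame = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    frame.to_csv(RESULTS / "rnle_conditions.csv", index=False)
    print(frame.to_string(index=False))
    same = frame[["AM", "FM", "CM"]].nunique().eq(1).all()
    print(f"\nAM/FM/CM identical across conditions: {bool(same)}")


if __name__ == "__main__":
    main()
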