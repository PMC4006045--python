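"""Generate the synthetic study cohort.

Four skill groups (6 uninitiated, 6 novice, 3 intermediate, 4 expert — 19
participants) each perform three flake attempts in the analyzed condition
(small-flake production, 600 g hammer), up to three strikes per attempt.
Sensor streams, stylus calibrations and outcome records are written in the
package's plain-text formats under scratch/study/; the ground-truth energy
ledger goes to results/.

Run from the repository root:  python analysis/01_simulate_cohort.py [--seed N]
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from knapkin.rig import default_cohort_spec, simulate_cohort  # noqa: E402


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    spec = default_cohort_spec()
    study = simulate_cohort(spec, seed=args.seed)
    study_dir = ROOT / "scratch" / "study"
    study.write(study_dir)

    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    truth = pd.DataFrame(study.truth_energy_table())
    truth.to_csv(results / "truth_energies.csv", index=False)

    n_strikes = len(truth)
    print(f"simulated {spec.n_subjects} subjects, {n_strikes} strikes -> {study_dir}")
    print(truth.groupby("group")[["ek_max", "ep", "ratio"]].mean().round(2))


if __name__ == "__main__":
    main()
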