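"""Calibrate, reconstruct and segment the study.

Runs the full pipeline on the study directory written by 01: per subject a
CAST calibration (sphere-fit shoulder center, landmark offsets), per trial
the 9-DOF joint-angle reconstruction with segment-length enforcement,
strike segmentation by the apex/lowest-point rules, per-strike energies and
per-strike PCA. Writes every result table under results/pipeline/.

Run:  python analysis/02_reconstruct_and_segment.py
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from knapkin.io import RunConfig  # noqa: E402
from knapkin.pipeline import run_pipeline  # noqa: E402


def main() -> None:
    study_dir = ROOT / "scratch" / "study"
    if not study_dir.exists():
        raise SystemExit("no study found; run analysis/01_simulate_cohort.py first")
    results = run_pipeline(study_dir, RunConfig())
    outdir = ROOT / "results" / "pipeline"
    results.write(outdir)
    m = results.manifest
    print(
        f"{m['n_subjects']} subjects, {m['n_trials']} trials: "
        f"{m['strikes_detected']} strikes detected, {m['flakes_analyzed']} flakes -> {outdir}"
    )


if __name__ == "__main__":
    main()
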