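"""Coordinative structure: per-strike PCA summaries and loading regularity.

Reports the PC1/PC2 explained-variance summaries (overall and per group)
and, per subject, whether the PC1 loadings of the successful strikes
correlate above |r| = 0.7 in ALL pairwise comparisons — the criterion for a
consistent joint-angle coordination pattern across successful strikes.

Run after 02:  python analysis/05_coordination_synergy.py
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))


def main() -> None:
    pipedir = ROOT / "results" / "pipeline"
    pc = json.loads((pipedir / "pc_summary.json").read_text())
    ov = pc["overall"]
    print("PC1: mean %.0f%% (median %.0f%%, SD %.0f%%, range %.0f-%.0f%%)" % (
        ov["pc1"]["mean"], ov["pc1"]["median"], ov["pc1"]["sd"], ov["pc1"]["min"], ov["pc1"]["max"]))
    print("PC2: mean %.0f%% (median %.0f%%, SD %.0f%%, range %.0f-%.0f%%)" % (
        ov["pc2"]["mean"], ov["pc2"]["median"], ov["pc2"]["sd"], ov["pc2"]["min"], ov["pc2"]["max"]))
    rows = [
        {"group": g, "pc1_mean": v["pc1"]["mean"], "pc2_mean": v["pc2"]["mean"]}
        for g, v in pc["groups"].items()
    ]
    table = pd.DataFrame(rows).round(1)
    table.to_csv(ROOT / "results" / "pc_variance_by_group.csv", index=False)
    print(table.to_string(index=False))
    if pc["flagged"]:
        print("groups below the 90% PC1+PC2 adequacy line:", pc["flagged"])

    comps = pd.read_csv(pipedir / "loading_comparisons.csv")
    manifest = json.loads((pipedir / "manifest.json").read_text())
    consistent = manifest["consistent_coordination_subjects"]
    n_subj = comps["subject"].nunique()
    print(f"\nloading comparisons: {len(comps)} pairs over {n_subj} subjects; "
          f"median |r| = {comps['abs_r'].median():.2f}")
    print(f"subjects with |r| > 0.7 in ALL successful-strike pairs: "
          f"{len(consistent)} ({consistent if consistent else 'none'})")


if __name__ == "__main__":
    main()
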