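"""Regulation of functional parameters by skill group.

Summarizes per-strike maximal kinetic energy (Ek = m v^2 / 2 at the hammer
working point), potential energy at movement start (Ep = m g h above the
striking surface) and their ratio, by group, and reports the pairwise Welch
t-tests at the Bonferroni-adjusted level 0.05/6. A high Ek/Ep ratio means
energy added by muscular work beyond gravity.

Run after 02:  python analysis/03_functional_parameters.py
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))


def main() -> None:
    pipedir = ROOT / "results" / "pipeline"
    strikes = pd.read_csv(pipedir / "strikes.csv")
    tests = pd.read_csv(pipedir / "group_tests.csv")
    summary = (
        strikes.groupby("group")[["ek_max", "ep", "ratio"]]
        .agg(["mean", "std"])
        .round(2)
    )
    order = ["uninitiated", "novice", "intermediate", "expert"]
    summary = summary.reindex([g for g in order if g in summary.index])
    summary.to_csv(ROOT / "results" / "functional_parameters.csv")
    print(summary)
    energy_tests = tests[tests["measure"].isin(["ek_max", "ep", "ratio"])]
    sig = energy_tests[energy_tests["significant"]]
    print(f"\n{len(sig)}/{len(energy_tests)} pairwise energy comparisons significant "
          f"at alpha/6:")
    print(sig[["measure", "group_a", "group_b", "p_value"]].to_string(index=False))


if __name__ == "__main__":
    main()
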