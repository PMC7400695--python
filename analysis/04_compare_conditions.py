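#!/usr/bin/env python
"""Print the study-style before/after comparison from a completed run.

Reads the study output directory of 03_run_study.py and prints the
shear-rate and WSS tables (mean ± SD per condition, gated paired test,
significance stars) plus the percent-difference report.

Usage: python analysis/04_compare_conditions.py [--dir results/study]
"""

import argparse
from pathlib import Path

import pandas as pd


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--dir", type=Path, default=Path("results/study"))
    args = ap.parse_args()

    comparison = pd.read_csv(args.dir / "comparison.csv")
    for quantity, label in (("shear_rate", "Shear rate [1/s]"),
                            ("wss", "Wall shear stress [Pa]")):
        sub = comparison[comparison.quantity == quantity]
        print(f"\n=== {label} ===")
        for _, r in sub.iterrows():
            star = " *" if r.significant else ""
            print(f"  {r.region:>6} {r.side:>5} {r.statistic:>13}: "
                  f"{r.before_mean:8.3f} ± {r.before_sd:6.3f}  ->  "
                  f"{r.after_mean:8.3f} ± {r.after_sd:6.3f}   "
                  f"p={r.p_value:.3f}{star}")
    print("\n* indicates p < 0.05")

    pct = pd.read_csv(args.dir / "percent_differences.csv")
    print("\n=== Percent differences (positive = lower after saline) ===")
    print(pct.to_string(index=False))

    recirc = pd.read_csv(args.dir / "recirculation.csv")
    print("\n=== Bulb recirculation fraction ===")
    print(recirc.groupby("condition")["recirc_ica_bulb"].mean().to_string())


if __name__ == "__main__":
    main()
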