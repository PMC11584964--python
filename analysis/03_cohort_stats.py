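"""Cohort statistics: descriptive tables, clustered CIs, bleeding transitions.

Joins the digital measurements with the clinical chart and reproduces the
study's reporting layout: probing-depth variation (baseline, re-evaluation,
difference), digital height/width loss with cluster-robust 95% CIs, and the
paired bleeding transition table with the exact McNemar test.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from periomesh import summarize_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    chart = pd.read_csv(args.results / "chart.csv")
    meas = pd.read_csv(args.results / "measurements.csv")
    summary = summarize_cohort(chart, meas)

    frame = summary.to_frame()
    depth = frame[frame.label.isin(["pst0", "pst1", "diff"])]
    losses = frame[frame.label.isin(["height_loss", "width_loss"])]
    depth.to_csv(args.results / "table1_probing_depth.csv", index=False)
    losses.to_csv(args.results / "table2_digital_losses.csv", index=False)

    b = summary.bleeding
    (args.results / "bleeding_transitions.json").write_text(
        json.dumps(b.to_dict(), indent=1))

    print("probing depth (mm):")
    for _, row in depth.iterrows():
        print(f"  {row.label:12s} mean {row['mean']:+.2f} sd {row.sd:.2f} "
              f"CI95 [{row.ci95_low:+.2f}, {row.ci95_high:+.2f}]")
    print("digital losses (mm):")
    for _, row in losses.iterrows():
        print(f"  {row.label:12s} mean {row['mean']:.3f} sd {row.sd:.3f} "
              f"CI95 [{row.ci95_low:.3f}, {row.ci95_high:.3f}]")
    print(f"bleeding: {b.prevalence0_pct}% -> {b.prevalence1_pct}% "
          f"(resolved {b.resolved_pct}%, appeared {b.appeared_pct}%, "
          f"exact McNemar p = {b.mcnemar_p:.2e})")


if __name__ == "__main__":
    main()
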