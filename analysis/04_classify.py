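#!/usr/bin/env python
"""Apply the fixed diagnostic thresholds to each simulated subject.

Integral 73 separates patients (below) from non-patients; centroid 54 s
separates psychosis-spectrum (later) from MDD-like (earlier) activation
timing.  Writes results/classification.csv and
results/classification_summary.json and prints the per-group percentages,
plus a markdown digest of all stages in results/report.md.
"""

from pathlib import Path

from nirsvft.config import CENTROID_THRESHOLD_S, INTEGRAL_THRESHOLD
from nirsvft.pipeline import stage_classify, stage_report

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"
OUT = ROOT / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    summary = stage_classify(OUT / "features.csv", SIM / "cohort.csv", OUT,
                             INTEGRAL_THRESHOLD, CENTROID_THRESHOLD_S)
    print(f"thresholds: integral {INTEGRAL_THRESHOLD}, "
          f"centroid {CENTROID_THRESHOLD_S} s")
    for g in summary["groups"]:
        print(f"  {g['group']:>4}: n={g['n']:3d}  "
              f"{g['pct_classified_patient']:5.1f}% patient  "
              f"{g['pct_classified_psychosis_spectrum']:5.1f}% "
              "psychosis-spectrum")
    report = stage_report(OUT)
    print(f"wrote {report}")


if __name__ == "__main__":
    main()
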