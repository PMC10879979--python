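#!/usr/bin/env python
"""Simulate the study cohorts and write the survey-export CSVs.

Generates a pandemic-period cross-sectional cohort (713 pwMS, 1,250
controls, the complete-case analysis cell sizes) and a paired
prepandemic/pandemic longitudinal cohort (230 pwMS, 136 controls), with
the published principal association (negative health influence → MSRS-R in
pwMS, → PROMIS in controls) built into the cross-sectional generator and a
null longitudinal generator. Outputs go to results/sim_cross/ and
results/sim_long/ as participants/alters/ties CSVs plus ground-truth
effect tables.
"""

from pathlib import Path

from persnet.pipeline import simulate_to_csv
from persnet.synthetic import GeneratorConfig

SEED = 17
ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cross = simulate_to_csv(GeneratorConfig.cross_sectional(), ROOT / "sim_cross", seed=SEED)
    print("cross-sectional cohort (713 pwMS + 1250 controls):")
    for name, path in cross.items():
        print(f"  {name}: {path}")
    long = simulate_to_csv(GeneratorConfig.longitudinal(), ROOT / "sim_long", seed=SEED + 1)
    print("longitudinal cohort (230 pwMS + 136 controls, two timepoints):")
    for name, path in long.items():
        print(f"  {name}: {path}")


if __name__ == "__main__":
    main()
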