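#!/usr/bin/env python
"""Cross-tabulate CPAP response by community and label response classes.

For every detected community: the severity-class mix before and after
the one-night treatment (table2.csv), the percentage of severe
patients reclassified to norm/mild (AHI improvement, table3.csv, with
best/good labels at the 85% threshold), and which parameter classes
are representative per community (table4.csv).
"""

import argparse
from pathlib import Path

import pandas as pd

from cpapnet.cli import _read_partition
from cpapnet.cohort import discretize_patient
from cpapnet.io import read_patients
from cpapnet.pipeline import response_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_patients(args.outdir / "d1_patients.csv")
    partition = _read_partition(args.outdir / "partition.csv")
    profiles = {r.id: discretize_patient(r) for r in records}
    labeling = response_stage(records, profiles, partition, args.outdir)
    t4 = pd.read_csv(args.outdir / "table4.csv")
    for c in sorted(labeling.improvement):
        thick = t4[(t4.community == c) & (t4.parameter == "thick_neck")].iloc[0]
        print(f"community {c}: improvement {labeling.improvement[c]:5.1f}% -> "
              f"{labeling.labels[c]:4s}; thick-neck class {thick.display} "
              f"({100 * thick.prevalence:.0f}%)")
    best = sorted(labeling.communities("best"))
    thick_best = sorted(
        int(c) for c in t4[(t4.parameter == "thick_neck") & (t4.display == "1")].community
    )
    print(f"best response class: communities {best}; "
          f"thick-neck-representative communities: {thick_best}")


if __name__ == "__main__":
    main()
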