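#!/usr/bin/env python
"""Evaluate NC thresholds as classifiers of the network response classes.

Closes the loop of the two-stage design: patients with NC at or below
a cutoff are predicted to belong to the good response class and the
rest to the best class; predictions are scored against the
community-derived labels at cutoffs 39–43 cm (table7.csv).
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from cpapnet.cli import _read_partition
from cpapnet.io import read_patients
from cpapnet.pipeline import cutoff_stage
from cpapnet.response import label_response_classes


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    records = read_patients(args.outdir / "d1_patients.csv")
    partition = _read_partition(args.outdir / "partition.csv")
    t3 = pd.read_csv(args.outdir / "table3.csv")
    labeling = label_response_classes(
        dict(zip(t3["community"], t3["ahi_improvement"]))
    )
    df = cutoff_stage(records, labeling, partition, args.outdir)
    roc = json.loads((args.outdir / "roc.json").read_text())
    star = roc["youden_cutoff"]
    sel = df[(df.cutoff == star)]
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    for _, row in sel.iterrows():
        print(f"at the Youden cutoff {star:g} cm, {row.orientation}-class: "
              f"TPR {row.tpr:.3f}, TNR {row.tnr:.3f}, PPV {row.ppv:.3f}")


if __name__ == "__main__":
    main()
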