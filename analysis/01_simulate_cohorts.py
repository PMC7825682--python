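#!/usr/bin/env python
"""Simulate the study cohorts.

Generates (a) a 145-patient CPAP-titration cohort with four planted
risk-profile communities and one-night treatment response, and (b)
labeled screening cohorts: 836 OSA-diagnosed and 65 control male
subjects whose neck-circumference marginals follow the published
summary moments. Writes the patient CSVs and ground-truth community
labels under results/.
"""

import argparse
from pathlib import Path

from cpapnet.pipeline import simulate_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort, screening = simulate_stage(args.outdir, seed=args.seed)
    n_osa = sum(bool(r.osa_label) for r in screening)
    print(f"titration cohort: {len(cohort.records)} patients, "
          f"{len(set(cohort.labels.values()))} planted communities")
    print(f"screening cohorts: {n_osa} OSA vs {len(screening) - n_osa} controls")
    print(f"written to {args.outdir}/d1_patients.csv, "
          f"{args.outdir}/screening_patients.csv")


if __name__ == "__main__":
    main()
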