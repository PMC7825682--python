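#!/usr/bin/env python
"""ROC analysis of neck circumference on the screening cohorts.

Computes the ROC curve and AUC (with Hanley–McNeil 95% CI) of NC for
discriminating OSA-diagnosed from control subjects, the cutoff metric
table at whole-centimetre cutoffs 39–46 (table5.csv), the
Youden-optimal cutoff, the Spearman NC–AHI correlation within the OSA
group, and a Mann–Whitney comparison of AHI across the chosen NC
threshold (table6.csv). Writes roc.json.
"""

import argparse
from pathlib import Path

from cpapnet.io import read_patients
from cpapnet.pipeline import roc_stage


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    screening = read_patients(args.outdir / "screening_patients.csv")
    res = roc_stage(screening, args.outdir)
    print(f"AUC {res['auc']:.3f} (95% CI {res['ci_low']:.3f}-{res['ci_high']:.3f}) "
          f"over {res['n_positive']} OSA vs {res['n_negative']} controls")
    print(f"Youden-optimal NC cutoff: {res['youden_cutoff']:g} cm")
    print(f"Spearman NC-AHI in the OSA group: rho={res['spearman_nc_ahi']:.3f} "
          f"(p={res['spearman_p']:.2g})")
    print(f"AHI above vs below the cutoff: U={res['mann_whitney_u']:.0f} "
          f"(p={res['mann_whitney_p']:.2g})")


if __name__ == "__main__":
    main()
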