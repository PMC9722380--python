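#!/usr/bin/env python
"""Tabulate antipsychotic prescription patterns from the cohort table.

Produces the per-class prevalence report (overall and by treatment
setting, with chi-square comparisons) and the mutually exclusive
FGA / SGA / FGA+SGA regimen-by-comedication breakdown with Wald 95% CIs.
"""

import argparse
from pathlib import Path

from acticohort import class_prevalence, combination_table
from acticohort.io import read_cohort_csv


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cohort = read_cohort_csv(args.cohort)
    prevalence = class_prevalence(cohort)
    prevalence.to_csv(args.outdir / "class_prevalence.csv", index=False)
    print("drug-class prevalence (patients):")
    for _, row in prevalence.iterrows():
        print(f"  {row['drug_class']:<18} {row['n_users']:>5} "
              f"({row['pct_users']:.1f}%)  outpatient {row['pct_outpatient']:.1f}% "
              f"vs residential {row['pct_residential']:.1f}%  p={row['p_value']:.3g}")

    comb = combination_table(cohort)
    comb.to_csv(args.outdir / "combination_table.csv", index=False)
    print(f"\nregimen x comedication cells (denominator "
          f"{comb.attrs['denominator']} patients):")
    for _, row in comb.iterrows():
        print(f"  {row['ap_regimen']:<9} {row['comedication']:<30} "
              f"{row['n']:>4} ({row['pct']:.1f}%, "
              f"CI {row['ci_low']:.1f}-{row['ci_high']:.1f}%)")
    print(f"  excluded: {comb.attrs['clozapine_only']} clozapine-only, "
          f"{comb.attrs['no_antipsychotic']} without antipsychotics")


if __name__ == "__main__":
    main()
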