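#!/usr/bin/env python
"""Validate the contingency layer against the published summary tables.

Recomputes uncorrected Pearson chi-squares and chi-square-based effect
sizes from the published categorical count tables of the modelled cohort,
and the Wald 95% CIs of the published regimen-combination cells, printing
each next to its published value.
"""

import argparse
from pathlib import Path

import pandas as pd

from acticohort import wald_ci
from acticohort import reference_counts as rc
from acticohort.stats import chi_square_test


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rows = []
    for (family, var), published in rc.PUBLISHED_CHI2.items():
        tables = rc.MONO_VS_POLY_TABLES if family == "mono_vs_poly" else rc.SETTING_TABLES
        res = chi_square_test(tables[var])
        rows.append({"comparison": family, "variable": var, "n": res.n,
                     "chi2": round(res.chi2, 3), "chi2_published": published,
                     "df": res.df, "p_value": res.p_value,
                     "effect_size": round(res.effect_size, 3),
                     "effect_size_published": rc.PUBLISHED_EFFECT_SIZE.get((family, var))})
        print(f"  {family:<13} {var:<16} chi2 {res.chi2:8.3f} "
              f"(published {published})  V {res.effect_size:.3f}")
    pd.DataFrame(rows).to_csv(args.outdir / "contingency_checks.csv", index=False)

    rows = []
    for (regimen, comed), (count, den, pct, lo, hi) in rc.PUBLISHED_COMBINATION_CIS.items():
        ci = wald_ci(count, den)
        rows.append({"ap_regimen": regimen, "comedication": comed,
                     "count": count, "denominator": den,
                     "pct": round(ci.percent, 1), "ci_low": round(ci.ci_low, 1),
                     "ci_high": round(ci.ci_high, 1),
                     "published": f"{pct}% ({lo}-{hi})"})
        print(f"  {regimen}/{comed}: {ci.percent:.1f}% "
              f"CI {ci.ci_low:.1f}-{ci.ci_high:.1f} (published {pct}% {lo}-{hi})")
    pd.DataFrame(rows).to_csv(args.outdir / "wald_ci_checks.csv", index=False)


if __name__ == "__main__":
    main()
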