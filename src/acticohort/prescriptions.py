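"""Antipsychotic regimen classification and prescription-pattern tables.

A subject's antipsychotic load is ``n_fga + n_sga + clozapine`` (clozapine
counts as one antipsychotic): zero drugs means no antipsychotic, one means
monopharmacy (APM), two or more concurrent antipsychotics mean polypharmacy
(APP). The tabulations reproduce the standard cross-sectional reports:
per-class prevalence overall and by treatment setting, and the mutually
exclusive FGA / SGA / FGA+SGA regimen-by-comedication breakdown with Wald
95% confidence intervals on proportions of the full patient cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import chi_square_test

DRUG_CLASSES = ("fga", "sga", "clozapine", "mood_stabilizer",
                "antidepressant", "benzodiazepine")

AP_REGIMENS = ("fga_only", "sga_only", "fga_sga")
COMEDICATIONS = ("alone", "mood_stabilizer", "antidepressant",
                 "antidepressant_mood_stabilizer")


@dataclass(frozen=True)
class ProportionWithCI:
    """A count/denominator proportion with a Wald 95% CI, in percent."""

    count: int
    denominator: int
    percent: float
    ci_low: float
    ci_high: float


def wald_ci(count: int, denominator: int, z: float = 1.96) -> ProportionWithCI:
    """Normal-approximation CI on the unrounded proportion, truncated to [0, 100]."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError("count must lie in [0, denominator]")
    p = count / denominator
    half = z * np.sqrt(p * (1 - p) / denominator)
    return ProportionWithCI(
        count=int(count),
        denominator=int(denominator),
        percent=100.0 * p,
        ci_low=max(0.0, 100.0 * (p - half)),
        ci_high=min(100.0, 100.0 * (p + half)),
    )


def antipsychotic_count(rec) -> int:
    """Total concurrent antipsychotics in a record (row or mapping)."""
    n = int(rec["n_fga"]) + int(rec["n_sga"]) + int(bool(rec["clozapine"]))
    if int(rec["n_fga"]) < 0 or int(rec["n_sga"]) < 0:
        raise ValueError("drug counts must be non-negative")
    return n


def classify_regimen(rec) -> str:
    """``no_antipsychotic`` / ``APM`` / ``APP`` from the antipsychotic count."""
    n = antipsychotic_count(rec)
    return "no_antipsychotic" if n == 0 else ("APM" if n == 1 else "APP")


def _patients(cohort: pd.DataFrame) -> pd.DataFrame:
    return cohort[cohort["group"] != "HC"]


def class_prevalence(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-class users and mean drug counts, overall and by setting.

    One row per drug class (plus an ``antipsychotic_any`` row): N and % of
    users in the whole patient sample and per setting, the chi-square
    comparison of prevalence between settings, and mean (SD) drugs from the
    class among users only (missing when the class has no users, and for
    clozapine which is recorded as a flag).
    """
    pats = _patients(cohort)
    if len(pats) == 0:
        raise ValueError("cohort contains no patients")
    out_ = pats[pats["setting"] == "outpatient"]
    res_ = pats[pats["setting"] == "residential"]

    def row(name: str, user_mask: pd.Series, counts: pd.Series | None) -> dict:
        n_all, n_out, n_res = (
            int(user_mask.sum()),
            int(user_mask[out_.index].sum()),
            int(user_mask[res_.index].sum()),
        )
        r = {
            "drug_class": name,
            "n_users": n_all, "pct_users": 100.0 * n_all / len(pats),
            "n_outpatient": n_out,
            "pct_outpatient": 100.0 * n_out / len(out_) if len(out_) else np.nan,
            "n_residential": n_res,
            "pct_residential": 100.0 * n_res / len(res_) if len(res_) else np.nan,
        }
        table = np.array(
            [[n_out, len(out_) - n_out], [n_res, len(res_) - n_res]]
        )
        try:
            ct = chi_square_test(table)
            r["chi2"], r["p_value"] = ct.chi2, ct.p_value
        except ValueError:  # zero margin (all or no users in both settings)
            r["chi2"], r["p_value"] = np.nan, np.nan
        if counts is not None and n_all > 0:
            used = counts[user_mask]
            r["mean_n_users"] = float(used.mean())
            r["sd_n_users"] = float(used.std(ddof=1)) if n_all > 1 else 0.0
        else:
            r["mean_n_users"] = np.nan
            r["sd_n_users"] = np.nan
        return r

    ap_n = pats["n_fga"] + pats["n_sga"] + pats["clozapine"].astype(bool).astype(int)
    rows = [row("antipsychotic_any", ap_n > 0, ap_n)]
    for cls in DRUG_CLASSES:
        if cls == "clozapine":
            rows.append(row(cls, pats["clozapine"].astype(bool), None))
        else:
            rows.append(row(cls, pats[f"n_{cls}"] > 0, pats[f"n_{cls}"]))
    return pd.DataFrame(rows)


def combination_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mutually exclusive FGA/SGA regimen x comedication breakdown.

    Rows are {FGA only, SGA only, FGA+SGA} x {alone, +mood stabilizer,
    +antidepressant(s), +antidepressant+mood stabilizer}; every cell is
    reported for all such patients and for the subset also taking any
    benzodiazepine, each with a Wald 95% CI over the full patient cohort.
    Patients on clozapine without FGA or SGA are excluded from the rows and
    returned in ``DataFrame.attrs["clozapine_only"]``; patients with no
    antipsychotic at all in ``attrs["no_antipsychotic"]``. Rows plus the two
    excluded counts partition the patient cohort.
    """
    pats = _patients(cohort)
    denom = len(pats)
    has_fga, has_sga = pats["n_fga"] > 0, pats["n_sga"] > 0
    has_mood = pats["n_mood_stabilizer"] > 0
    has_ad = pats["n_antidepressant"] > 0
    has_bzd = pats["n_benzodiazepine"] > 0

    regimen = pd.Series("none", index=pats.index)
    regimen[has_fga & ~has_sga] = "fga_only"
    regimen[~has_fga & has_sga] = "sga_only"
    regimen[has_fga & has_sga] = "fga_sga"
    comed = pd.Series("alone", index=pats.index)
    comed[has_mood & ~has_ad] = "mood_stabilizer"
    comed[~has_mood & has_ad] = "antidepressant"
    comed[has_mood & has_ad] = "antidepressant_mood_stabilizer"

    rows = []
    for reg in AP_REGIMENS:
        for com in COMEDICATIONS:
            cell = (regimen == reg) & (comed == com)
            all_ci = wald_ci(int(cell.sum()), denom)
            bzd_ci = wald_ci(int((cell & has_bzd).sum()), denom)
            rows.append(
                {"ap_regimen": reg, "comedication": com,
                 "n": all_ci.count, "pct": all_ci.percent,
                 "ci_low": all_ci.ci_low, "ci_high": all_ci.ci_high,
                 "n_benzodiazepine": bzd_ci.count, "pct_benzodiazepine": bzd_ci.percent,
                 "ci_low_benzodiazepine": bzd_ci.ci_low,
                 "ci_high_benzodiazepine": bzd_ci.ci_high}
            )
    out = pd.DataFrame(rows)
    none_ap = regimen == "none"
    cloz_only = none_ap & pats["clozapine"].astype(bool)
    out.attrs["denominator"] = denom
    out.attrs["clozapine_only"] = int(cloz_only.sum())
    out.attrs["no_antipsychotic"] = int((none_ap & ~pats["clozapine"].astype(bool)).sum())
    return out
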