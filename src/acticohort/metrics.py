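"""Epoch ENMO -> VO2 -> MET -> intensity category, and activity summaries.

Energy expenditure is estimated per epoch from the epoch-mean ENMO by the
wrist power law VO2 = 0.901 * ENMO^0.534 (ENMO in milli-g, VO2 in
ml.kg-1.min-1), floored at 3.0 before conversion to metabolic equivalents
(MET = VO2 / 3.5). Epochs are classified sedentary (MET <= 1.5), light
(1.5 < MET < 3), moderate (3 <= MET < 6) or vigorous (MET >= 6).

Summaries follow the wear-time convention: category minutes are counts of
wear epochs, percentages are relative to daily wear time (not 24 h), and
subject-level values are unweighted means over valid days only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize

from .config import PipelineConfig, DEFAULT_CONFIG, CATEGORIES
from .accelerometry import mark_valid_days, is_valid_subject


def estimate_vo2(enmo_mg, config: PipelineConfig = DEFAULT_CONFIG):
    """VO2 (ml.kg-1.min-1) from epoch ENMO (milli-g), floored at 3.0."""
    enmo = np.asarray(enmo_mg, dtype=float)
    if np.any(enmo < 0):
        raise ValueError("ENMO must be non-negative")
    vo2 = np.maximum(config.vo2_coef * enmo ** config.vo2_exp, config.vo2_floor)
    return vo2 if vo2.ndim else float(vo2)


def vo2_to_met(vo2, config: PipelineConfig = DEFAULT_CONFIG):
    """MET = VO2 / 3.5; with the VO2 floor the minimum is 3.0/3.5 ~ 0.857."""
    met = np.asarray(vo2, dtype=float) / config.met_denominator
    return met if met.ndim else float(met)


def classify_intensity(met, config: PipelineConfig = DEFAULT_CONFIG):
    """Intensity category from MET with inclusive boundaries as defined.

    1.5 -> sedentary, 3.0 -> moderate, 6.0 -> vigorous.
    """
    met_arr = np.asarray(met, dtype=float)
    c1, c2, c3 = config.cutpoints
    out = np.select(
        [met_arr <= c1, met_arr < c2, met_arr < c3],
        [CATEGORIES[0], CATEGORIES[1], CATEGORIES[2]],
        default=CATEGORIES[3],
    )
    return out if met_arr.ndim else str(out)


def met_cutpoints_in_enmo(config: PipelineConfig = DEFAULT_CONFIG) -> tuple[float, float, float]:
    """ENMO (milli-g) preimages of the MET cut-points under the power law.

    Solved numerically; with the default constants the sedentary/light
    boundary sits near 27.1 mg, light/moderate near 99.3 mg and
    moderate/vigorous near 363.8 mg.
    """
    def root(met: float) -> float:
        target = met * config.met_denominator
        return optimize.brentq(
            lambda e: config.vo2_coef * e ** config.vo2_exp - target, 1e-6, 1e6
        )

    return tuple(root(m) for m in config.cutpoints)


def annotate_epochs(
    epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """Add ``vo2``, ``met`` and ``category`` columns to an epoch series."""
    out = epochs.copy()
    out["vo2"] = estimate_vo2(out["enmo_mg"].to_numpy(), config)
    out["met"] = vo2_to_met(out["vo2"].to_numpy(), config)
    out["category"] = classify_intensity(out["met"].to_numpy(), config)
    return out


def summarize_days(
    epochs: pd.DataFrame, config: PipelineConfig = DEFAULT_CONFIG
) -> pd.DataFrame:
    """One row per calendar day: wear minutes, category minutes/percents,
    mean MET over wear epochs, weekday index and validity flag.

    Percentages are relative to wear minutes; a day with zero wear minutes
    keeps NaN percents and NaN mean MET (flagged missing, never imputed).
    """
    if "category" not in epochs:
        epochs = annotate_epochs(epochs, config)
    mpe = config.epoch_length_s / 60.0
    dates = epochs["epoch_start"].dt.date
    rows = []
    for date, day in epochs.groupby(dates):
        worn = day[day["wear"]]
        wear_min = len(worn) * mpe
        row = {"date": date, "weekday": pd.Timestamp(date).weekday(), "wear_min": wear_min}
        counts = worn["category"].value_counts()
        for cat in CATEGORIES:
            mins = counts.get(cat, 0) * mpe
            row[f"{cat}_min"] = mins
            row[f"{cat}_pct"] = 100.0 * mins / wear_min if wear_min > 0 else np.nan
        row["mean_met"] = worn["met"].mean() if wear_min > 0 else np.nan
        row["valid"] = wear_min >= config.min_wear_min_per_day
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_subject(
    day_summaries: pd.DataFrame,
    subject_id: str | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict | None:
    """Unweighted mean over valid days; ``None`` for an invalid subject.

    Wearing time is reported in hours/day to match the conventional report
    scale; all other fields keep the day-summary units.
    """
    valid = day_summaries[day_summaries["valid"]]
    if len(valid) < config.min_valid_days:
        return None
    out = {"subject_id": subject_id, "n_valid_days": int(len(valid))}
    out["wearing_time_h"] = valid["wear_min"].mean() / 60.0
    out["mean_met"] = valid["mean_met"].mean()
    for cat in CATEGORIES:
        out[f"{cat}_min"] = valid[f"{cat}_min"].mean()
        out[f"{cat}_pct"] = valid[f"{cat}_pct"].mean()
    return out


def weekly_group_curves(day_summaries: pd.DataFrame) -> pd.DataFrame:
    """Mean daily percent and normal 95% CI per group x weekday x category.

    ``day_summaries`` must carry a ``group`` column and only valid days
    should be passed in. Every valid day contributes equally (a subject with
    two Mondays contributes both). Cells with a single contributing day get
    NaN CI bounds (a zero-width interval would be misleading); empty cells
    are simply absent.
    """
    rows = []
    for (group, weekday), chunk in day_summaries.groupby(["group", "weekday"]):
        for cat in CATEGORIES:
            vals = chunk[f"{cat}_pct"].dropna()
            if len(vals) == 0:
                continue
            mean = vals.mean()
            if len(vals) > 1:
                se = vals.std(ddof=1) / np.sqrt(len(vals))
                lo, hi = mean - 1.96 * se, mean + 1.96 * se
            else:
                lo = hi = np.nan
            rows.append(
                {"group": group, "weekday": int(weekday), "category": cat,
                 "n_days": int(len(vals)), "mean_pct": mean, "ci_lo": lo, "ci_hi": hi}
            )
    return pd.DataFrame(rows)


def epochs_to_subject_summary(
    epochs: pd.DataFrame,
    subject_id: str | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, dict | None]:
    """Convenience: annotated epochs -> (day summaries, subject summary)."""
    days = summarize_days(epochs, config)
    valid_map = mark_valid_days(epochs, config)
    if not is_valid_subject(valid_map, config):
        return days, None
    return days, summarize_subject(days, subject_id, config)
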