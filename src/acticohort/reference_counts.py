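"""Published summary counts from the cross-sectional cohort this pipeline
models (620 patients with schizophrenia spectrum disorders -- 316 on
antipsychotic monopharmacy, 291 on polypharmacy, plus 114 healthy controls;
307 outpatients vs 313 residential patients).

These printed tables are inputs: the raw per-subject data are deposited
under restricted access, but the categorical rows let the contingency layer
be validated against the published statistics exactly. Row variables with
missing values use pairwise deletion, which is why totals vary (607
patients for patient-group rows, 619 or 620 for setting rows).
"""

from __future__ import annotations

import numpy as np

# Patient-group comparisons (monopharmacy vs polypharmacy), counts per level.
MONO_VS_POLY_TABLES = {
    # males / females
    "sex": np.array([[215, 101], [202, 89]]),
    # single / married-cohabiting / divorced-widowed
    "marital_status": np.array([[259, 34, 23], [266, 8, 17]]),
    # lifetime hospitalisation duration: <1 y / 1-5 y / >5 y
    "hospitalizations": np.array([[176, 84, 56], [108, 77, 106]]),
}

# Outpatient vs residential comparisons.
SETTING_TABLES = {
    "sex": np.array([[202, 105], [220, 93]]),
    "marital_status": np.array([[263, 30, 14], [271, 13, 28]]),
    # working / studying / neither
    "working_status": np.array([[90, 21, 196], [38, 14, 260]]),
    "hospitalizations": np.array([[240, 42, 25], [53, 122, 137]]),
}

# Published statistics for the same rows (chi-square to 3 decimals and the
# chi-square-based effect size where published to 3 decimals).
PUBLISHED_CHI2 = {
    ("mono_vs_poly", "sex"): 0.134,
    ("mono_vs_poly", "marital_status"): 16.086,
    ("mono_vs_poly", "hospitalizations"): 31.041,
    ("setting", "sex"): 1.437,
    ("setting", "marital_status"): 11.468,
    ("setting", "working_status"): 31.469,
    ("setting", "hospitalizations"): 235.780,
}

PUBLISHED_EFFECT_SIZE = {
    ("mono_vs_poly", "marital_status"): 0.163,
    ("setting", "marital_status"): 0.136,
    ("setting", "hospitalizations"): 0.617,
}

# Regimen-by-comedication cells published with Wald 95% CIs over the full
# patient cohort (count, denominator, percent, ci_low, ci_high).
PUBLISHED_COMBINATION_CIS = {
    ("sga_only", "alone"): (177, 620, 28.6, 25.0, 32.1),
    ("sga_only", "mood_stabilizer"): (47, 620, 7.6, 5.5, 9.7),
    ("fga_sga", "alone"): (64, 620, 10.3, 7.9, 12.7),
}

N_PATIENTS = 620
N_OUTPATIENT = 307
N_RESIDENTIAL = 313
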