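"""Published demographic/clinical summary of a four-group maltreatment cohort.

These are the printed group summaries (mean, SD per group; sex counts) of a
first-episode drug-naive MDD / healthy-control cohort stratified by
childhood-maltreatment exposure. They serve two purposes: as input to the
summary-statistics reconstructions (ANOVA, Tukey HSD, two-sample t,
chi-squared), and as the target distributions the synthetic cohort generator
emulates. Group sizes follow from the per-group female/male counts
(84, 46, 32, 90).
"""

from __future__ import annotations

import pandas as pd

GROUPS = ("MDD-CM", "MDD-nCM", "HC-CM", "HC-nCM")

#: female/male counts per group, in GROUPS order
SEX_COUNTS = {
    "MDD-CM": (67, 17),
    "MDD-nCM": (28, 18),
    "HC-CM": (21, 11),
    "HC-nCM": (58, 32),
}

GROUP_SIZES = {g: sum(SEX_COUNTS[g]) for g in GROUPS}

#: per-variable (mean, sd) per group; HAMD/HAMA assessed in patients only
SUMMARY = {
    "age": {"MDD-CM": (25.45, 5.61), "MDD-nCM": (26.76, 8.00),
            "HC-CM": (26.59, 7.26), "HC-nCM": (27.12, 7.65)},
    "education": {"MDD-CM": (14.83, 2.24), "MDD-nCM": (15.00, 2.70),
                  "HC-CM": (15.47, 2.59), "HC-nCM": (15.31, 2.26)},
    "HAMD": {"MDD-CM": (31.92, 9.41), "MDD-nCM": (27.67, 9.87)},
    "HAMA": {"MDD-CM": (21.45, 7.77), "MDD-nCM": (18.11, 7.43)},
    "CTQ": {"MDD-CM": (55.25, 13.46), "MDD-nCM": (36.98, 6.61),
            "HC-CM": (41.81, 8.84), "HC-nCM": (30.38, 4.06)},
    "EA": {"MDD-CM": (11.57, 4.69), "MDD-nCM": (7.65, 1.99),
           "HC-CM": (8.25, 3.20), "HC-nCM": (5.92, 1.40)},
    "PA": {"MDD-CM": (7.81, 3.68), "MDD-nCM": (5.54, 0.81),
           "HC-CM": (6.78, 2.94), "HC-nCM": (5.29, 0.55)},
    "SA": {"MDD-CM": (6.68, 3.20), "MDD-nCM": (5.09, 0.35),
           "HC-CM": (5.94, 2.42), "HC-nCM": (5.10, 0.37)},
    "EN": {"MDD-CM": (16.69, 4.19), "MDD-nCM": (10.41, 2.48),
           "HC-CM": (11.41, 4.83), "HC-nCM": (8.06, 2.55)},
    "PN": {"MDD-CM": (11.45, 3.64), "MDD-nCM": (7.11, 1.62),
           "HC-CM": (9.44, 2.64), "HC-nCM": (6.01, 1.26)},
}


def summary_table() -> pd.DataFrame:
    """Long-form summary: one row per (variable, group) with mean, sd, n."""
    rows = []
    for var, per_group in SUMMARY.items():
        for g, (m, s) in per_group.items():
            rows.append({"variable": var, "group": g, "mean": m, "sd": s,
                         "n": GROUP_SIZES[g]})
    return pd.DataFrame(rows)


def sex_contingency() -> pd.DataFrame:
    """2 x 4 female/male contingency table in GROUPS order."""
    return pd.DataFrame(
        {g: SEX_COUNTS[g] for g in GROUPS}, index=["F", "M"]
    )
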