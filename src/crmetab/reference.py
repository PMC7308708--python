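"""Reference cohort parameters for the synthetic-experiment generator.

Group-level summary statistics (mean, SD per sex x diet condition) of a
12-animal gray mouse lemur experiment -- six females and six males, each
measured under an ad-libitum control diet (CTL) and again after a two-week
60% caloric restriction (CR) at the end of the long-day season.  These
published summary values parameterize the synthetic cohort so that every
downstream stage can be exercised, and its statistical behaviour checked,
without access to the underlying animal data.

Value entries are ``{sex: {condition: (mean, sd)}}``; clock-time entries
are in minutes since midnight with SDs in minutes.  Right-skewed hormone
panels (cortisol, testosterone, estradiol) are drawn log-normally
(moment-matched), everything else normally.
"""

from __future__ import annotations

# incurrent-stream composition and flow used when synthesizing gas traces
FI_O2 = 0.2095
FI_CO2 = 0.0004
FLOW_ML_PER_H = 30_000.0

#: daily ration energy content, kcal/day, control vs restricted
RATION_KCAL = {"CTL": 24.48, "CR": 9.79}

# ---------------------------------------------------------------------------
# Scalar endpoint variables: {var: {"dist": ..., sex: {cond: (mean, sd)}}}

GROUP_STATS = {
    # urinary panel (per mg creatinine)
    "cortisol": {
        "dist": "lognormal",
        "family": "urinary",
        "F": {"CTL": (603.4, 317.8), "CR": (992.3, 604.3)},
        "M": {"CTL": (403.2, 111.5), "CR": (596.4, 245.3)},
    },
    "ohdg8": {
        "dist": "normal",
        "family": "urinary",
        "F": {"CTL": (387.4, 93.0), "CR": (214.1, 36.3)},
        "M": {"CTL": (591.0, 262.4), "CR": (324.6, 110.8)},
    },
    "estradiol": {
        "dist": "lognormal",
        "family": "urinary",
        "F": {"CTL": (33558.8, 15819.7), "CR": (60086.8, 13681.9)},
        "M": {"CTL": (23364.4, 8297.4), "CR": (40180.7, 14563.2)},
    },
    "testosterone": {
        "dist": "lognormal",
        "family": "urinary",
        "F": {"CTL": (2.8, 1.9), "CR": (12.9, 16.7)},
        "M": {"CTL": (64.1, 31.1), "CR": (94.4, 78.0)},
    },
    # blood panel
    "thiols": {
        "dist": "normal",
        "family": "blood",
        "F": {"CTL": (1.8, 0.5), "CR": (1.8, 0.6)},
        "M": {"CTL": (2.2, 0.3), "CR": (1.4, 0.2)},
    },
    "gpx": {
        "dist": "normal",
        "family": "blood",
        "F": {"CTL": (0.28, 0.10), "CR": (0.34, 0.06)},
        "M": {"CTL": (0.25, 0.17), "CR": (0.14, 0.04)},
    },
    "t4": {
        "dist": "normal",
        "family": "blood",
        "F": {"CTL": (30.6, 8.5), "CR": (25.8, 8.8)},
        "M": {"CTL": (32.4, 3.2), "CR": (21.3, 10.0)},
    },
    "glycaemia": {
        "dist": "normal",
        "family": "blood",
        "F": {"CTL": (95.0, 32.0), "CR": (84.0, 18.0)},
        "M": {"CTL": (65.0, 9.0), "CR": (72.0, 11.0)},
    },
    "body_mass": {
        "dist": "normal",
        "family": "blood",  # reported alongside the panel
        "F": {"CTL": (99.7, 3.8), "CR": (83.0, 5.1)},
        "M": {"CTL": (90.0, 6.6), "CR": (77.2, 5.4)},
    },
    # extracellular-flux metrics (% of own baseline)
    "oxcr": {
        "dist": "normal",
        "family": "flux",
        "F": {"CTL": (60.96, 6.6), "CR": (69.49, 2.3)},
        "M": {"CTL": (72.59, 8.3), "CR": (67.54, 2.1)},
    },
    "mtrc": {
        "dist": "normal",
        "family": "flux",
        "F": {"CTL": (202.4, 45.9), "CR": (148.9, 33.0)},
        "M": {"CTL": (152.0, 21.8), "CR": (134.8, 41.8)},
    },
    "glcp": {
        "dist": "normal",
        "family": "flux",
        "F": {"CTL": (325.28, 27.37), "CR": (407.43, 128.65)},
        "M": {"CTL": (363.92, 203.20), "CR": (439.77, 35.41)},
    },
    # relative mitochondrial genome copy number
    "mtnu_ratio": {
        "dist": "lognormal",
        "family": "qpcr",
        "F": {"CTL": (1.78, 0.43), "CR": (2.56, 1.16)},
        "M": {"CTL": (3.01, 0.44), "CR": (3.30, 1.43)},
    },
    # calorimetry phase means
    "vo2_night_mean": {
        "dist": "normal",
        "family": "gas",
        "F": {"CTL": (2147.0, 403.0), "CR": (2260.0, 432.0)},
        "M": {"CTL": (2192.0, 510.0), "CR": (1882.0, 473.0)},
    },
    "vo2_day_mean": {
        "dist": "normal",
        "family": "gas",
        "F": {"CTL": (1226.0, 406.0), "CR": (1328.0, 598.0)},
        "M": {"CTL": (1296.0, 425.0), "CR": (1001.0, 382.0)},
    },
    "rer_night_mean": {
        "dist": "normal",
        "family": "gas",
        "F": {"CTL": (0.99, 0.077), "CR": (0.85, 0.076)},
        "M": {"CTL": (0.96, 0.099), "CR": (0.90, 0.085)},
    },
    "rer_day_mean": {
        "dist": "normal",
        "family": "gas",
        "F": {"CTL": (0.77, 0.07), "CR": (0.76, 0.06)},
        "M": {"CTL": (0.78, 0.07), "CR": (0.75, 0.07)},
    },
}

# ---------------------------------------------------------------------------
# Clock times of the programmed circadian features (minutes since midnight,
# SD in minutes): start of the nocturnal peak and of the diurnal trough of
# the VO2 and RER daily profiles.

CLOCK_STATS = {
    "vo2_hmax": {
        "F": {"CTL": (19 * 60 + 36, 184), "CR": (18 * 60 + 55, 236)},
        "M": {"CTL": (19 * 60 + 1, 187), "CR": (17 * 60 + 39, 133)},
    },
    "vo2_hmin": {
        "F": {"CTL": (7 * 60 + 59, 129), "CR": (5 * 60 + 50, 214)},
        "M": {"CTL": (6 * 60 + 58, 272), "CR": (4 * 60 + 5, 68)},
    },
    "rer_hmax": {
        "F": {"CTL": (18 * 60 + 23, 99), "CR": (17 * 60 + 30, 41)},
        "M": {"CTL": (17 * 60 + 44, 94), "CR": (17 * 60 + 17, 41)},
    },
    "rer_hmin": {
        "F": {"CTL": (7 * 60 + 0, 225), "CR": (3 * 60 + 53, 275)},
        "M": {"CTL": (10 * 60 + 43, 192), "CR": (4 * 60 + 58, 238)},
    },
}

#: variables whose group-mean recovery is checked in parameter-recovery
#: suites (scalar endpoints; clock times are checked by direction only)
RECOVERY_VARIABLES = [v for v in GROUP_STATS]
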