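"""Published summary tables from the ENGAGE telomere-cognition effort.

These are the printed consortium results: the per-cohort descriptive table
(12 European-ancestry studies, N = 17 052) and the pooled observational,
instrumental-variable and CHARGE two-sample estimates per cognitive trait.
They serve as worked-example inputs — the package's arithmetic (CI-to-SE
recovery, Wald ratios, difference Z-tests, weighted means) can be replayed
on them and compared with the printed columns.

Betas are s.d.-change in trait per s.d.-change in telomere length (TL);
the pooled GRS-TL effect is s.d.-change of TL per counted allele.
"""

from __future__ import annotations

import pandas as pd

TRAITS = ("MMSE", "DSST", "BLOCK", "MEMORY", "STROOP", "GENERAL")

# cohort, n, age mean, age sd, raw T/S mean, T/S sd, % women, GRS mean, GRS sd,
# traits contributed, APOE genotype available
_COHORT_ROWS = [
    ("BETULA1", 163, 50.9, 7.8, 1.01, 0.17, 58.3, 8.50, 1.57,
     ("MMSE", "DSST", "BLOCK", "MEMORY", "GENERAL"), True),
    ("BETULA2", 396, 62.4, 14.5, 0.93, 0.15, 54.8, 8.87, 1.56,
     ("MMSE", "DSST", "BLOCK", "MEMORY", "GENERAL"), True),
    ("BETULA3", 315, 60.0, 15.0, 0.97, 0.17, 54.0, 8.65, 1.51,
     ("MMSE", "DSST", "BLOCK", "MEMORY", "GENERAL"), True),
    ("ERF", 2502, 51.6, 15.8, 1.76, 0.36, 55.6, 8.65, 1.57,
     ("MEMORY", "STROOP", "GENERAL"), True),
    ("FITSA", 429, 68.6, 3.4, 0.90, 0.19, 100.0, 8.52, 1.46,
     ("MMSE", "DSST"), True),
    ("GENDER", 466, 74.5, 2.6, 0.68, 0.15, 49.0, 8.43, 1.34,
     ("DSST", "BLOCK", "MEMORY", "GENERAL"), True),
    ("HRS", 4117, 70.4, 9.4, 1.30, 0.30, 58.0, 8.60, 1.52,
     ("MMSE", "MEMORY", "GENERAL"), False),
    ("LBC1936", 999, 69.6, 0.8, 1.30, 0.50, 49.0, 8.36, 1.56,
     ("MMSE", "DSST", "BLOCK", "MEMORY", "GENERAL"), True),
    ("LLS1", 2305, 59.2, 6.8, 1.46, 0.26, 54.8, 8.47, 1.52,
     ("DSST", "MEMORY", "STROOP"), True),
    ("LLS2", 868, 93.3, 2.6, 1.28, 0.22, 61.6, 8.44, 1.57,
     ("MMSE",), True),
    ("NSHD", 2425, 53.0, 0.0, 1.54, 0.91, 50.0, 8.55, 1.40,
     ("MEMORY", "GENERAL"), True),
    ("NTR", 200, 40.3, 16.4, 2.72, 0.56, 66.5, 8.50, 1.56,
     ("GENERAL",), False),
    ("QIMR", 1280, 14.1, 2.4, 3.70, 0.60, 52.6, 8.50, 1.50,
     ("GENERAL",), False),
    ("SATSA", 587, 68.8, 9.6, 0.76, 0.27, 58.0, 8.45, 1.45,
     ("DSST", "BLOCK", "MEMORY", "GENERAL"), True),
]


def cohort_table() -> pd.DataFrame:
    """Per-cohort descriptive statistics of the 12 contributing studies."""
    return pd.DataFrame(
        _COHORT_ROWS,
        columns=["cohort", "n", "age_mean", "age_sd", "tl_mean", "tl_sd",
                 "pct_women", "grs_mean", "grs_sd", "traits", "has_apoe"],
    )


# Pooled observational TL-trait effects: beta (95% CI) and printed P.
OBSERVED = {
    "MMSE":    {"beta": 0.025, "ci": (0.002, 0.047), "p": 0.030},
    "DSST":    {"beta": 0.051, "ci": (0.024, 0.077), "p": 0.0002},
    "BLOCK":   {"beta": 0.004, "ci": (-0.024, 0.032), "p": 0.781},
    "MEMORY":  {"beta": 0.011, "ci": (-0.005, 0.028), "p": 0.187},
    "STROOP":  {"beta": -0.053, "ci": (-0.087, -0.018), "p": 0.003},
    "GENERAL": {"beta": 0.020, "ci": (-0.008, 0.047), "p": 0.156},
}

# One-sample Wald IV estimates (predicted TL effect) with analysis n.
IV_ONE_SAMPLE = {
    "MMSE":    {"n": 7066, "beta": 0.291, "ci": (-0.05, 0.631), "p": 0.095},
    "DSST":    {"n": 4419, "beta": -0.016, "ci": (-0.437, 0.405), "p": 0.941},
    "BLOCK":   {"n": 5001, "beta": -0.192, "ci": (-0.594, 0.21), "p": 0.349},
    "MEMORY":  {"n": 13060, "beta": -0.022, "ci": (-0.264, 0.22), "p": 0.860},
    "STROOP":  {"n": 2940, "beta": -0.598, "ci": (-1.125, -0.072), "p": 0.026},
    "GENERAL": {"n": 12283, "beta": 0.039, "ci": (-0.229, 0.306), "p": 0.778},
}

# Printed observed-vs-causal difference P-values per trait.
DIFF_P = {
    "MMSE": 0.13, "DSST": 0.76, "BLOCK": 0.34,
    "MEMORY": 0.79, "STROOP": 0.04, "GENERAL": 0.89,
}

# CHARGE two-sample replication. DSST and STROOP outcome GWAS lacked effect
# sizes, so only Z-scores are printed for them.
CHARGE = {
    "GENERAL": {"n": 53949, "beta": 0.086, "ci": (0.016, 0.156), "p": 0.016},
    "DSST":    {"n": 32088, "z": 2.021, "p": 0.043},
    "STROOP":  {"n": 7726, "z": -0.780, "p": 0.435},
}

# Pooled genetic-instrument strength: GRS on TL, random-effects pooled,
# with the consortium's printed first-stage F.
GRS_TL_POOLED = {"beta": -0.048, "ci": (-0.064, -0.032), "p": 4.0e-9, "f": 36}
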