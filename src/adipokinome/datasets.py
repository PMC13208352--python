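"""Built-in worked-example datasets.

``diet_study_weights`` holds the published group summaries (mean ± SD, n)
of the diet-induced-obesity mouse study behind the adipose kinome atlas:
normal-chow (NCD, n = 6) versus 60% high-fat diet (HFD, n = 7) animal and
tissue weights, plus the body-weight-normalized block.  Ratio variables
(e.g. BAT/BW) are treated as their own summarized variables, since
per-animal ratios are not reconstructible from the printed table.
"""

from __future__ import annotations

import pandas as pd

from .summary_stats import GroupSummary

N_NCD = 6
N_HFD = 7

# variable, NCD mean, NCD sd, HFD mean, HFD sd, block
_ROWS = [
    ("Body Weight (g)",      25.45,  1.66,   46.80,  3.41,   "raw"),
    ("Fat Mass (g)",          1.00,  0.31,   14.34,  2.88,   "raw"),
    ("Lean Mass (g)",        23.43,  2.05,   30.48,  1.49,   "raw"),
    ("Blood Glucose (mg/dL)", 123.50, 16.85, 159.00, 13.53,  "raw"),
    ("iWAT (g)",              0.15,  0.03,    1.61,  0.52,   "raw"),
    ("eWAT (g)",              0.25,  0.06,    1.22,  0.37,   "raw"),
    ("mWAT (g)",              0.14,  0.07,    0.71,  0.27,   "raw"),
    ("rWAT (g)",              0.07,  0.01,    1.11,  0.27,   "raw"),
    ("BAT (g)",               0.08,  0.01,    0.19,  0.02,   "raw"),
    ("Liver (g)",             0.95,  0.08,    1.63,  0.30,   "raw"),
    ("Heart (g)",             0.13,  0.02,    0.19,  0.03,   "raw"),
    ("Pancreas (g)",          0.12,  0.05,    0.40,  0.18,   "raw"),
    ("Spleen (g)",            0.06,  0.01,    0.11,  0.04,   "raw"),
    ("Kidney (g)",            0.31,  0.03,    0.45,  0.04,   "raw"),
    ("Fat Mass/BW",           0.0399, 0.0127, 0.3042, 0.0375, "normalized"),
    ("Lean Mass/BW",          0.9194, 0.0262, 0.6539, 0.0516, "normalized"),
    ("iWAT/BW",               0.0058, 0.0012, 0.0339, 0.0088, "normalized"),
    ("eWAT/BW",               0.0096, 0.0019, 0.0263, 0.0080, "normalized"),
    ("mWAT/BW",               0.0055, 0.0024, 0.0149, 0.0050, "normalized"),
    ("rWAT/BW",               0.0027, 0.0005, 0.0234, 0.0040, "normalized"),
    ("BAT/BW",                0.0030, 0.0003, 0.0041, 0.0005, "normalized"),
    ("Liver/BW",              0.0371, 0.0013, 0.0348, 0.0051, "normalized"),
    ("Heart/BW",              0.0050, 0.0003, 0.0040, 0.0006, "normalized"),
    ("Pancreas/BW",           0.0046, 0.0019, 0.0084, 0.0034, "normalized"),
    ("Spleen/BW",             0.0022, 0.0003, 0.0023, 0.0006, "normalized"),
    ("Kidney/BW",             0.0121, 0.0003, 0.0096, 0.0008, "normalized"),
]


def diet_study_weights(block: str | None = None) -> pd.DataFrame:
    """Published NCD-vs-HFD weight summaries as a tidy DataFrame.

    ``block`` may be "raw", "normalized" (per body weight) or None for both.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=["variable", "ncd_mean", "ncd_sd", "hfd_mean", "hfd_sd", "block"],
    )
    df["ncd_n"] = N_NCD
    df["hfd_n"] = N_HFD
    if block is not None:
        df = df[df["block"] == block].reset_index(drop=True)
    return df


def diet_study_comparisons(block: str | None = None):
    """The same table as (variable, GroupSummary, GroupSummary) triples."""
    df = diet_study_weights(block)
    return [
        (
            r.variable,
            GroupSummary("NCD", r.ncd_mean, r.ncd_sd, r.ncd_n),
            GroupSummary("HFD", r.hfd_mean, r.hfd_sd, r.hfd_n),
        )
        for r in df.itertuples()
    ]
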