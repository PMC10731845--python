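"""Bundled example data for the cross-study meta-analysis.

``example_two_study_comparison`` returns a published-style comparison of 20
serum metabolites measured in two independent case-control studies (an
external hospital-based study, n=460, and a community-based study, n=919):
per-study two-sided p-values and linear-scale fold changes, plus the
reported multiplicity-adjusted combined p-value for each metabolite.  Useful
as a worked example for :mod:`metamwas.crossstudy` and in tests.
"""

from __future__ import annotations

import pandas as pd

EXTERNAL_N = 460
INTERNAL_N = 919

# metabolite, p_external, fc_external, p_internal, fc_internal, adj_combined_p
_ROWS = [
    ("p-Cresol glucuronide", 0.0021, 2.15, 1e-05, 3.80, 7.5e-06),
    ("p-Cresol sulfate", 0.0278, 1.08, 8e-05, 1.55, 2.3e-04),
    ("FFA 20:3", 0.0000, 0.63, 0.000, 1.23, 1.8e-06),
    ("FFA 20:4", 0.0004, 0.65, 0.002, 1.18, 1.4e-04),
    ("Uridine", 0.0300, 0.91, 0.003, 1.18, 3.0e-03),
    ("Phenylacetyl-L-glutamine", 0.0023, 1.57, 0.008, 1.27, 1.5e-03),
    ("FFA 18:2", 0.0106, 0.73, 0.01, 1.17, 3.3e-03),
    ("Trigonelline", 0.0119, 0.53, 0.03, 0.73, 9.5e-03),
    ("Ubiquinone 1", 0.0030, 0.73, 0.03, 1.16, 3.3e-03),
    ("FFA 14:1", 0.0100, 0.77, 0.04, 1.25, 9.5e-03),
    ("Kynurenine", 0.0113, 0.86, 0.05, 0.93, 1.3e-02),
    ("Biliverdin", 0.0003, 0.70, 0.08, 0.74, 1.8e-03),
    ("Pantothenic acid", 0.0174, 0.85, 0.09, 0.79, 2.2e-02),
    ("FFA 20:2", 0.0090, 0.76, 0.09, 1.12, 1.6e-02),
    ("Indolelactic acid", 0.0109, 0.81, 0.09, 0.91, 1.7e-02),
    ("FFA 22:5", 0.0002, 0.63, 0.17, 1.09, 2.3e-03),
    ("FFA 19:1", 0.0179, 0.78, 0.18, 1.15, 3.3e-02),
    ("Cortisol", 0.0165, 1.21, 0.19, 1.12, 3.3e-02),
    ("FFA 20:0", 0.0307, 0.87, 0.19, 0.88, 5.1e-02),
    ("cis-Aconitic acid", 0.0078, 0.83, 0.25, 0.90, 2.9e-02),
]


def example_two_study_comparison() -> pd.DataFrame:
    """Per-metabolite two-study summaries (see module docstring)."""
    df = pd.DataFrame(_ROWS, columns=[
        "metabolite", "p_external", "fc_external", "p_internal", "fc_internal",
        "adj_combined_p",
    ])
    df["n_external"] = EXTERNAL_N
    df["n_internal"] = INTERNAL_N
    return df


def example_external_summary() -> pd.DataFrame:
    """The external study's rows in the standard summary format."""
    df = example_two_study_comparison()
    return pd.DataFrame({
        "metabolite": df["metabolite"],
        "fold_change": df["fc_external"],
        "p_value": df["p_external"],
        "n": df["n_external"],
    })


def example_internal_summary() -> pd.DataFrame:
    """The internal study's rows in the standard summary format."""
    df = example_two_study_comparison()
    return pd.DataFrame({
        "metabolite": df["metabolite"],
        "fold_change": df["fc_internal"],
        "p_value": df["p_internal"],
        "n": df["n_internal"],
    })
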