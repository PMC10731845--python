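"""Adduct-based matching of features to a reference metabolite library.

Tier 1 requires mass accuracy within the tight ppm tolerance AND a library
retention time within the RT tolerance; tier 2 is mass-only at the looser
ppm tolerance.  One-to-many matches are preserved; downstream pathway
weighting handles the ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PROTON_MASS = 1.007276
NA_MASS = 22.989218
CL_MASS = 34.969402
H2O_MASS = 18.010565


@dataclass(frozen=True)
class AdductRule:
    name: str
    mode: str  # "pos" | "neg"
    mass_shift: float
    charge: int = 1

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        if self.mode not in ("pos", "neg"):
            raise ValueError("mode must be 'pos' or 'neg'")


POSITIVE_ADDUCTS = (
    AdductRule("[M+H]+", "pos", PROTON_MASS),
    AdductRule("[M+Na]+", "pos", NA_MASS),
    AdductRule("[M+H-H2O]+", "pos", PROTON_MASS - H2O_MASS),
)
NEGATIVE_ADDUCTS = (
    AdductRule("[M-H]-", "neg", -PROTON_MASS),
    AdductRule("[M+Cl]-", "neg", CL_MASS),
    AdductRule("[M-H2O-H]-", "neg", -PROTON_MASS - H2O_MASS),
)
DEFAULT_ADDUCTS = POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS

COLUMN_MODE = {"hilicpos": "pos", "c18neg": "neg"}
COLUMN_RT_FIELD = {"hilicpos": "rt_hilic", "c18neg": "rt_c18"}


def expected_mz(monoisotopic_mass: float, rule: AdductRule) -> float:
    """m/z of the adduct ion: (mass + shift) / charge."""
    return (monoisotopic_mass + rule.mass_shift) / rule.charge


def match_features(features: pd.DataFrame, library: pd.DataFrame,
                   rules=DEFAULT_ADDUCTS,
                   ppm_tol_tier1: float = 5.0,
                   ppm_tol_tier2: float = 10.0,
                   rt_tol: float = 30.0) -> pd.DataFrame:
    """Match feature m/z (and optionally RT) against the library via adducts.

    Parameters
    ----------
    features : frame indexed by feature_id with ``column``, ``mz``, ``rt``.
    library : frame indexed by metabolite_id with ``monoisotopic_mass`` and
        optional ``rt_c18`` / ``rt_hilic``.

    Returns hits sorted by |ppm_error| with columns feature_id,
    metabolite_id, adduct, ppm_error, rt_error, tier.
    """
    if (library["monoisotopic_mass"] <= 0).any():
        raise ValueError("library masses must be positive")
    masses = library["monoisotopic_mass"].to_numpy(dtype=float)
    met_ids = np.asarray(library.index)
    rows = []
    for fid, frow in features.iterrows():
        mode = COLUMN_MODE.get(frow["column"])
        rt_field = COLUMN_RT_FIELD.get(frow["column"])
        lib_rt = (library[rt_field].to_numpy(dtype=float)
                  if rt_field in library.columns else np.full(len(library), np.nan))
        for rule in rules:
            if mode is not None and rule.mode != mode:
                continue
            exp = (masses + rule.mass_shift) / rule.charge
            ppm = 1e6 * (frow["mz"] - exp) / exp
            hit = np.abs(ppm) <= ppm_tol_tier2
            for j in np.flatnonzero(hit):
                rt_err = frow["rt"] - lib_rt[j] if np.isfinite(lib_rt[j]) else np.nan
                tier = 2
                if abs(ppm[j]) <= ppm_tol_tier1 and np.isfinite(rt_err) and abs(rt_err) <= rt_tol:
                    tier = 1
                rows.append(dict(feature_id=fid, metabolite_id=met_ids[j],
                                 adduct=rule.name, ppm_error=float(ppm[j]),
                                 rt_error=float(rt_err) if np.isfinite(rt_err) else np.nan,
                                 tier=tier))
    hits = pd.DataFrame(rows, columns=["feature_id", "metabolite_id", "adduct",
                                       "ppm_error", "rt_error", "tier"])
    if len(hits):
        hits = hits.iloc[np.argsort(np.abs(hits["ppm_error"].to_numpy()), kind="stable")]
        hits = hits.reset_index(drop=True)
    return hits
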