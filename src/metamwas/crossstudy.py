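"""Cross-study meta-analysis of per-metabolite (fold change, p, n) summaries.

Combines an internal study's results with an external study's published
summary statistics: size-weighted log fold-change averaging, a
Lancaster-style weighted p-value combination, a pseudo t-score measuring
cross-study consistency, and a three-criteria validation rubric
(significance, direction, magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from metamwas.mwas import bh_fdr


@dataclass
class ValidationThresholds:
    study_p_max: float = 0.25          # inclusive
    adj_combined_p_max: float = 0.05   # strict
    min_direction_fc: float = 1.05     # each study's FC at least +-5%
    magnitude_log2fc: float = 0.25     # strict on |log2 combined FC|


def combined_fc(fcs, ns) -> float:
    """Size-weighted geometric combination: 2^(sum n_i log2 FC_i / sum n_i)."""
    fcs = np.asarray(fcs, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (fcs <= 0).any():
        raise ValueError("fold changes must be positive")
    return float(2.0 ** (np.sum(ns * np.log2(fcs)) / ns.sum()))


def pseudo_t_stats(fcs) -> tuple[float, float, float]:
    """Cross-study consistency statistic.

    For log2 fold changes L_i over k studies: pseudo_t = mean(L) / (sd(L)/sqrt(k))
    with the sample SD (k-1 denominator).  Returns (mean_fc, sd_fc, pseudo_t)
    with mean and SD back-transformed to the linear scale.  Zero SD yields a
    signed infinity (NaN when the mean is also zero).
    """
    fcs = np.asarray(fcs, dtype=float)
    if len(fcs) < 2:
        raise ValueError("pseudo t requires at least 2 studies")
    if (fcs <= 0).any():
        raise ValueError("fold changes must be positive")
    L = np.log2(fcs)
    mean_l = float(L.mean())
    sd_l = float(L.std(ddof=1))
    if sd_l == 0:
        t = math.copysign(math.inf, mean_l) if mean_l != 0 else math.nan
    else:
        t = mean_l / (sd_l / math.sqrt(len(L)))
    return float(2.0 ** mean_l), float(2.0 ** sd_l), float(t)


def combined_p_weighted(ps, ns) -> float:
    """Lancaster-style weighted p-value combination.

    Each p maps to the upper-tail quantile of Gamma(w_i/2, scale=2) with
    weights w_i = 4 n_i / sum(n); the summed statistic is referred to
    Gamma(sum(w_i)/2, scale=2).  With equal weights this is exactly Fisher's
    method on two studies.
    """
    ps = np.asarray(ps, dtype=float)
    ns = np.asarray(ns, dtype=float)
    if (ps > 1).any() or (ps < 0).any():
        raise ValueError("p-values must be in (0, 1]")
    tiny = np.finfo(float).tiny
    if (ps == 0).any():
        import warnings

        warnings.warn("p = 0 clipped to smallest positive float")
        ps = np.clip(ps, tiny, 1.0)
    w = 4.0 * ns / ns.sum()
    x = stats.gamma.isf(ps, a=w / 2.0, scale=2.0)
    T = float(np.sum(x))
    return float(stats.gamma.sf(T, a=w.sum() / 2.0, scale=2.0))


def classify_validation(p_internal: float, p_external: float,
                        fc_internal: float, fc_external: float,
                        comb_fc: float, adj_combined_p: float,
                        thresholds: ValidationThresholds | None = None) -> tuple[dict, str]:
    """Apply the three-criteria rubric; returns (flags, label).

    significance: both study p <= 0.25 and adjusted combined p < 0.05;
    direction: both |log2 FC| >= log2(1.05) with matching sign;
    magnitude: |log2 combined FC| > 0.25.
    The label concatenates satisfied criteria ("none" if empty).
    """
    th = thresholds or ValidationThresholds()
    l_int, l_ext = math.log2(fc_internal), math.log2(fc_external)
    min_l = math.log2(th.min_direction_fc)
    flags = {
        "significance": (p_internal <= th.study_p_max and p_external <= th.study_p_max
                         and adj_combined_p < th.adj_combined_p_max),
        "direction": (abs(l_int) >= min_l and abs(l_ext) >= min_l
                      and l_int * l_ext > 0),
        "magnitude": abs(math.log2(comb_fc)) > th.magnitude_log2fc,
    }
    parts = [name.capitalize() for name in ("direction", "significance", "magnitude")
             if flags[name]]
    if not parts:
        label = "none"
    elif len(parts) == 1:
        label = parts[0]
    elif len(parts) == 2:
        label = f"{parts[0]} & {parts[1]}"
    else:
        label = f"{parts[0]}, {parts[1]}, & {parts[2]}"
    return flags, label


def validate_external(internal: pd.DataFrame, external: pd.DataFrame,
                      thresholds: ValidationThresholds | None = None,
                      adj_p_override: pd.Series | None = None) -> pd.DataFrame:
    """Cross-study meta-analysis over metabolites present in both studies.

    Both inputs need columns ``metabolite``, ``fold_change``, ``p_value``,
    ``n``.  Matching is exact, case-insensitive, after trimming.  BH adjusts
    the combined p over the tested metabolites unless ``adj_p_override``
    supplies pre-computed adjusted values (indexed like the matched rows).
    """
    def keyed(df):
        out = df.copy()
        out["_key"] = out["metabolite"].astype(str).str.strip().str.lower()
        return out.set_index("_key")

    a = keyed(internal)
    b = keyed(external)
    common = [k for k in a.index if k in b.index]
    rows = []
    for k in common:
        ra, rb = a.loc[k], b.loc[k]
        fcs = [float(rb["fold_change"]), float(ra["fold_change"])]
        ns = [float(rb["n"]), float(ra["n"])]
        ps = [float(rb["p_value"]), float(ra["p_value"])]
        cfc = combined_fc(fcs, ns)
        mean_fc, sd_fc, pseudo_t = pseudo_t_stats(fcs)
        rows.append(dict(
            metabolite=ra["metabolite"],
            fc_external=fcs[0], fc_internal=fcs[1],
            p_external=ps[0], p_internal=ps[1],
            combined_fc=cfc,
            combined_p=combined_p_weighted(ps, ns),
            mean_fc=mean_fc, sd_fc=sd_fc, pseudo_t=pseudo_t,
        ))
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    if adj_p_override is not None:
        res["adj_combined_p"] = np.asarray(adj_p_override, dtype=float)
    else:
        res["adj_combined_p"] = bh_fdr(res["combined_p"].to_numpy())
    flags_labels = [
        classify_validation(r["p_internal"], r["p_external"], r["fc_internal"],
                            r["fc_external"], r["combined_fc"], r["adj_combined_p"],
                            thresholds)
        for _, r in res.iterrows()
    ]
    res["significance"] = [f[0]["significance"] for f in flags_labels]
    res["direction"] = [f[0]["direction"] for f in flags_labels]
    res["magnitude"] = [f[0]["magnitude"] for f in flags_labels]
    res["validation"] = [f[1] for f in flags_labels]
    return res
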