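"""Permutation-based weighted pathway enrichment over annotated features.

Ambiguous matches are down-weighted: a feature matching k distinct
metabolites contributes weight 1/k to each, and a metabolite's contribution
is capped at 1 regardless of how many features (from either ion mode) match
it, so the joint dual-mode analysis never double counts.  Significance of a
pathway's weighted hit count is assessed by permuting the significant /
non-significant labels over all mapped features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metamwas.mwas import bh_fdr

log = logging.getLogger(__name__)


@dataclass
class WeightMap:
    """Match weights: ``pair_weight[(feature, metabolite)] = 1/k`` where k is
    the number of distinct metabolites the feature matches; ``u[met]`` is the
    metabolite's capped total contribution."""

    pair_weight: dict = field(default_factory=dict)
    u: dict = field(default_factory=dict)
    feature_mets: dict = field(default_factory=dict)
    met_features: dict = field(default_factory=dict)

    @property
    def mapped_features(self) -> list:
        return sorted(self.feature_mets)

    @property
    def mapped_metabolites(self) -> list:
        return sorted(self.u)


def build_weight_map(hits: pd.DataFrame) -> WeightMap:
    """Derive match weights from an annotation hit table (feature_id,
    metabolite_id columns; duplicate feature-metabolite pairs from multiple
    adducts count once)."""
    wm = WeightMap()
    pairs = hits[["feature_id", "metabolite_id"]].drop_duplicates()
    for fid, group in pairs.groupby("feature_id"):
        mets = sorted(group["metabolite_id"])
        wm.feature_mets[fid] = mets
        w = 1.0 / len(mets)
        for m in mets:
            wm.pair_weight[(fid, m)] = w
            wm.met_features.setdefault(m, []).append(fid)
    for m, feats in wm.met_features.items():
        wm.u[m] = min(1.0, sum(wm.pair_weight[(f, m)] for f in feats))
    return wm


def pathway_score(wm: WeightMap, significant_features: set, pathway: set) -> float:
    """Observed statistic: sum of u_m over pathway metabolites matched by at
    least one significant feature."""
    s = 0.0
    for m in pathway:
        feats = wm.met_features.get(m)
        if feats and any(f in significant_features for f in feats):
            s += wm.u[m]
    return s


def pathway_permutation_test(wm: WeightMap, significant_features,
                             pathways: dict, B: int = 9999,
                             seed: int = 0) -> pd.DataFrame:
    """Permutation test of the weighted significant-metabolite count per pathway.

    The null redistributes the significant labels uniformly over all mapped
    features; p = (1 + #{S* >= S_obs}) / (B + 1); BH FDR across pathways.
    """
    if B < 99:
        raise ValueError("B must be >= 99")
    rng = np.random.default_rng(seed)
    mapped = wm.mapped_features
    feat_pos = {f: i for i, f in enumerate(mapped)}
    sig = set(significant_features) & set(mapped)
    k = len(sig)

    mets = wm.mapped_metabolites
    met_pos = {m: i for i, m in enumerate(mets)}
    u = np.array([wm.u[m] for m in mets])
    incidence = np.zeros((len(mets), len(mapped)), dtype=bool)
    for m, feats in wm.met_features.items():
        for f in feats:
            incidence[met_pos[m], feat_pos[f]] = True

    clean_pathways = {}
    for name, members in pathways.items():
        present = sorted(set(members) & set(mets))
        dropped = len(members) - len(present)
        if dropped:
            log.info("pathway %s: %d member(s) absent from the weight map", name, dropped)
        clean_pathways[name] = present
    path_masks = {
        name: np.array([m in set(members) for m in mets])
        for name, members in clean_pathways.items()
    }

    sig_vec = np.zeros(len(mapped), dtype=bool)
    if k:
        sig_vec[[feat_pos[f] for f in sig]] = True
    hit_obs = incidence[:, sig_vec].any(axis=1) if len(mapped) else np.zeros(0, dtype=bool)
    obs = {name: float(u[mask & hit_obs].sum()) for name, mask in path_masks.items()}

    names = list(pathways)
    if k == 0:
        res = pd.DataFrame({
            "pathway": names,
            "n_metabolites_mapped": [len(clean_pathways[n]) for n in names],
            "S": [obs[n] for n in names],
            "p": 1.0,
        })
        res["fdr"] = bh_fdr(res["p"].to_numpy())
        return res.set_index("pathway")

    exceed = {name: 0 for name in names}
    for _ in range(B):
        perm = np.zeros(len(mapped), dtype=bool)
        perm[rng.choice(len(mapped), size=k, replace=False)] = True
        hit_met = incidence[:, perm].any(axis=1)
        for name, mask in path_masks.items():
            s_star = float(u[mask & hit_met].sum())
            if s_star >= obs[name] - 1e-12:
                exceed[name] += 1

    res = pd.DataFrame({
        "pathway": names,
        "n_metabolites_mapped": [len(clean_pathways[n]) for n in names],
        "S": [obs[n] for n in names],
        "p": [(1 + exceed[n]) / (B + 1) for n in names],
    })
    res["fdr"] = bh_fdr(res["p"].to_numpy())
    return res.set_index("pathway")
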