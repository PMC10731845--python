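"""Per-feature case-control testing, meta-analysis, replication, and networks.

The differential-abundance model is a per-feature linear fit of log2
intensity on case status plus covariates, with empirical-Bayes variance
moderation pooled across features.  Per-wave logistic fits feed a
fixed-effects inverse-variance meta-analysis; Benjamini-Hochberg controls
the FDR within each analysis family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

COVARIATE_NOTE = "age, gender, ethnicity, draw year, wave"


@dataclass
class ModerationParams:
    """Empirical-Bayes variance prior: d0 may be infinite when the per-feature
    variances are homogeneous."""

    d0: float
    s0_sq: float
    s_g_sq: np.ndarray
    d_g: float
    s_post_sq: np.ndarray


@dataclass
class ReplicationConfig:
    meta_fdr_max: float = 0.05
    per_wave_p_max: float = 0.05
    log2fc_tier1: float = 0.25
    log2fc_tier2: float = 0.50

    def validate(self) -> None:
        if min(self.meta_fdr_max, self.per_wave_p_max, self.log2fc_tier1, self.log2fc_tier2) <= 0:
            raise ValueError("thresholds must be positive")
        if self.log2fc_tier2 <= self.log2fc_tier1:
            raise ValueError("tier-2 threshold must exceed tier 1")


def trigamma_inverse(y: float, max_iter: int = 100) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = (tri - y) / special.polygamma(2, x)
        x_new = x - dif
        if x_new <= 0:
            x_new = x / 2.0
        if abs(x_new - x) < 1e-10 * max(1.0, abs(x)):
            x = x_new
            break
        x = x_new
    return float(x)


def squeeze_variances(s_sq: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on per-feature variances.

    Matches the log-variance mean and excess variance against digamma /
    trigamma moments; returns (d0, s0_sq), with d0 = inf when the observed
    log-variance spread does not exceed the chi-square sampling spread.
    """
    s_sq = np.maximum(np.asarray(s_sq, dtype=float), 1e-300)
    z = np.log(s_sq)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    if len(e) < 2:
        return np.inf, float(np.exp(e_mean))
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * trigamma_inverse(e_var)
    s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_sq


def fit_moderated_linear(values: pd.DataFrame, design: pd.DataFrame,
                         coef: str = "case",
                         prior_df: float | None = None) -> tuple[pd.DataFrame, ModerationParams]:
    """Moderated per-feature linear model.

    Parameters
    ----------
    values : features x subjects log2 matrix.
    design : subjects x parameters model matrix (must include an intercept
        column and the ``coef`` column of interest, e.g. a case indicator).
    prior_df : override for the prior degrees of freedom; ``0`` reproduces
        ordinary least-squares t-tests, ``None`` estimates d0 from the data.

    Returns a per-feature frame (log2fc, se, moderated_t, p, ci_low, ci_high,
    df_total) and the moderation parameters.
    """
    if list(design.index) != list(values.columns):
        design = design.loc[values.columns]
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design is not full rank")
    if n <= p + 1:
        raise ValueError("not enough subjects for the design")
    c_idx = list(design.columns).index(coef)

    Y = values.to_numpy(dtype=float)
    beta_all, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    resid = Y.T - X @ beta_all
    df = n - p
    if df < 1:
        raise ValueError("zero residual degrees of freedom")
    s_sq = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    se_unit = float(np.sqrt(xtx_inv[c_idx, c_idx]))
    log2fc = beta_all[c_idx]

    if prior_df is None:
        d0, s0_sq = squeeze_variances(s_sq, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.median(s_sq))
    elif np.isinf(prior_df):
        _, s0_sq = squeeze_variances(s_sq, df)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_sq = squeeze_variances(s_sq, df)

    if np.isinf(d0):
        s_post = np.full_like(s_sq, s0_sq)
        df_total = np.inf
    elif d0 == 0:
        s_post = s_sq.copy()
        df_total = float(df)
    else:
        s_post = (d0 * s0_sq + df * s_sq) / (d0 + df)
        df_total = float(d0 + df)

    se_mod = se_unit * np.sqrt(s_post)
    t_stat = log2fc / se_mod
    p_val = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    t_crit = stats.t.ppf(0.975, df_total)
    out = pd.DataFrame({
        "log2fc": log2fc,
        "se": se_mod,
        "moderated_t": t_stat,
        "p": p_val,
        "ci_low": log2fc - t_crit * se_mod,
        "ci_high": log2fc + t_crit * se_mod,
        "df_total": df_total,
    }, index=values.index)
    params = ModerationParams(d0=d0, s0_sq=s0_sq, s_g_sq=s_sq, d_g=float(df),
                              s_post_sq=s_post)
    return out, params


def mwas_design(subjects: pd.DataFrame, include_wave: bool = True) -> pd.DataFrame:
    """Model matrix: intercept, case indicator, and the adjustment covariates."""
    df = pd.DataFrame(index=subjects.index)
    df["intercept"] = 1.0
    df["case"] = (subjects["status"] == "case").astype(float)
    df["age"] = subjects["age"] - subjects["age"].mean()
    df["gender_M"] = (subjects["gender"] == "M").astype(float)
    for lev in sorted(subjects["ethnicity"].unique())[1:]:
        df[f"eth_{lev}"] = (subjects["ethnicity"] == lev).astype(float)
    df["draw_year"] = subjects["draw_year"] - subjects["draw_year"].mean()
    if include_wave and subjects["wave"].nunique() > 1:
        df["wave_2"] = (subjects["wave"] == 2).astype(float)
    # drop constant columns other than the intercept
    keep = ["intercept"] + [c for c in df.columns[1:] if df[c].nunique() > 1]
    df = df[keep]
    while np.linalg.matrix_rank(df.to_numpy()) < df.shape[1]:
        df = df.iloc[:, :-1]
    return df


def _fit_logistic_one(y: np.ndarray, X: np.ndarray) -> tuple[float, float, float]:
    """Logistic ML fit returning (coef, se, p) for the LAST column of X;
    NaNs when the fit does not converge or separates."""
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200, method="newton")
    except (PerfectSeparationError, np.linalg.LinAlgError, Exception):
        return np.nan, np.nan, np.nan
    if not res.mle_retvals.get("converged", False):
        return np.nan, np.nan, np.nan
    b = res.params[-1]
    se = res.bse[-1]
    if not (np.isfinite(b) and np.isfinite(se)) or se > 50 or abs(b) > 50:
        return np.nan, np.nan, np.nan
    p = 2.0 * stats.norm.sf(abs(b) / se)
    return float(b), float(se), float(p)


def fit_logistic_per_wave(values: pd.DataFrame, subjects: pd.DataFrame) -> dict:
    """Per-wave logistic fits of case status on each feature plus covariates.

    Returns ``{wave: DataFrame(b, se, p)}``; features with separation or
    non-convergence carry NaN rows (excluded from meta-analysis downstream).
    """
    out = {}
    for wave in sorted(subjects["wave"].unique()):
        sub = subjects[subjects["wave"] == wave]
        if sub["status"].nunique() < 2:
            raise ValueError(f"wave {wave} lacks both outcome classes")
        design = mwas_design(sub, include_wave=False).drop(columns=["case"], errors="ignore")
        X0 = design.to_numpy(dtype=float)
        y = (sub["status"] == "case").to_numpy(dtype=float)
        vals = values[sub.index].to_numpy(dtype=float)
        rows = np.empty((vals.shape[0], 3))
        for g in range(vals.shape[0]):
            X = np.column_stack([X0, vals[g]])
            rows[g] = _fit_logistic_one(y, X)
        out[wave] = pd.DataFrame(rows, columns=["b", "se", "p"], index=values.index)
    return out


def meta_fixed(b1, se1, b2, se2):
    """Fixed-effects inverse-variance pooling of two estimates.

    Any missing wave (NaN) returns the available wave's estimate with the
    ``single_wave`` flag set.  Returns (b_meta, se_meta, p_meta, single_wave).
    """
    have1 = np.isfinite(b1) and np.isfinite(se1) and se1 > 0
    have2 = np.isfinite(b2) and np.isfinite(se2) and se2 > 0
    if not have1 and not have2:
        return np.nan, np.nan, np.nan, True
    if have1 and not have2:
        return b1, se1, 2.0 * stats.norm.sf(abs(b1 / se1)), True
    if have2 and not have1:
        return b2, se2, 2.0 * stats.norm.sf(abs(b2 / se2)), True
    w1, w2 = 1.0 / se1 ** 2, 1.0 / se2 ** 2
    b = (w1 * b1 + w2 * b2) / (w1 + w2)
    se = (w1 + w2) ** -0.5
    return b, se, 2.0 * stats.norm.sf(abs(b / se)), False


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return out
    order = np.argsort(ps, kind="stable")
    ranked = ps[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def classify_replication(p_disc: float, p_rep: float, b_disc: float, b_rep: float,
                         log2fc: float, cfg: ReplicationConfig | None = None) -> str:
    """Replication tier from per-wave p-values and the adjusted fold change.

    Requires same-direction per-wave estimates; tiers by |log2FC| >= 0.25
    (``replicated_fc25``) and >= 0.5 (``replicated_fc50``).
    """
    cfg = cfg or ReplicationConfig()
    cfg.validate()
    if not (np.isfinite(p_disc) and np.isfinite(p_rep)):
        return "not_replicated"
    if p_disc >= cfg.per_wave_p_max or p_rep >= cfg.per_wave_p_max:
        return "not_replicated"
    if not (np.isfinite(b_disc) and np.isfinite(b_rep)) or b_disc * b_rep <= 0:
        return "not_replicated"
    if abs(log2fc) >= cfg.log2fc_tier2:
        return "replicated_fc50"
    if abs(log2fc) >= cfg.log2fc_tier1:
        return "replicated_fc25"
    return "not_replicated"


def phenotype_assoc(values: pd.DataFrame, subjects: pd.DataFrame,
                    phenotype: str) -> pd.DataFrame:
    """Linear regression of a patient phenotype on each feature, cases only.

    Covariates: age, gender, ethnicity, draw year, wave.  Returns per-feature
    (beta, se, p, fdr); the FDR family is this phenotype.
    """
    cases = subjects[subjects["status"] == "case"]
    y = cases[phenotype].to_numpy(dtype=float)
    if np.nanstd(y) == 0 or np.all(np.isnan(y)):
        raise ValueError(f"phenotype {phenotype} is constant among cases")
    keep = np.isfinite(y)
    cases = cases[keep]
    y = y[keep]
    design = mwas_design(cases).drop(columns=["case"], errors="ignore")
    X0 = design.to_numpy(dtype=float)
    vals = values[cases.index].to_numpy(dtype=float)

    # Frisch-Waugh: residualize outcome and features on the covariates
    Q, _ = np.linalg.qr(X0)
    ry = y - Q @ (Q.T @ y)
    rv = vals - (vals @ Q) @ Q.T
    sxx = (rv ** 2).sum(axis=1)
    beta = np.where(sxx > 0, (rv @ ry) / np.maximum(sxx, 1e-300), np.nan)
    df = len(y) - X0.shape[1] - 1
    if df < 1:
        raise ValueError("not enough cases for phenotype regression")
    rss = (ry ** 2).sum() - beta ** 2 * sxx
    se = np.sqrt(np.maximum(rss / df, 0.0) / np.maximum(sxx, 1e-300))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"beta": beta, "se": se, "p": p, "fdr": bh_fdr(p)},
                        index=values.index)


def correlation_network(values: pd.DataFrame, feature_ids,
                        min_abs_r: float = 0.2) -> pd.DataFrame:
    """Pearson correlation edges between selected features across subjects.

    Undirected, no self-edges; signed r reported; |r| >= ``min_abs_r``.
    """
    ids = [f for f in feature_ids if f in values.index]
    if len(ids) < 2:
        return pd.DataFrame(columns=["feature_a", "feature_b", "r"])
    sub = values.loc[ids].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(sub)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.isfinite(r[i, j]) and abs(r[i, j]) >= min_abs_r:
                rows.append((ids[i], ids[j], float(r[i, j])))
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "r"])


def network_to_graphml(edges: pd.DataFrame, path: str) -> None:
    import networkx as nx

    g = nx.Graph()
    for _, row in edges.iterrows():
        g.add_edge(row["feature_a"], row["feature_b"], r=float(row["r"]))
    nx.write_graphml(g, path)


def age_matched_subset(subjects: pd.DataFrame, max_age_diff: float = 2.0,
                       ratio: int = 1) -> list:
    """Greedy nearest-age case-control matching within gender/ethnicity strata.

    Deterministic: cases processed in subject-id order, each matched to the
    ``ratio`` nearest unused controls within ``max_age_diff`` years.  Returns
    the matched subject ids (cases with at least one match plus their controls).
    """
    matched: list = []
    used: set = set()
    cases = subjects[subjects["status"] == "case"].sort_index()
    controls = subjects[subjects["status"] == "control"]
    for sid, row in cases.iterrows():
        pool = controls[(controls["gender"] == row["gender"])
                        & (controls["ethnicity"] == row["ethnicity"])
                        & (~controls.index.isin(used))]
        pool = pool[(pool["age"] - row["age"]).abs() <= max_age_diff]
        if pool.empty:
            continue
        picks = (pool["age"] - row["age"]).abs().sort_values(kind="stable").index[:ratio]
        matched.append(sid)
        for c in picks:
            used.add(c)
            matched.append(c)
    return matched


def run_mwas(values: pd.DataFrame, subjects: pd.DataFrame,
             replication_cfg: ReplicationConfig | None = None,
             fit_logistic: bool = True,
             phenotypes: tuple = ("ledd", "hy", "updrs3")) -> pd.DataFrame:
    """Full per-feature MWAS: moderated linear model, per-wave logistic fits,
    fixed-effects meta-analysis, FDR, replication tiers, and phenotype
    associations among cases.  One row per feature."""
    replication_cfg = replication_cfg or ReplicationConfig()
    design = mwas_design(subjects)
    linear, _ = fit_moderated_linear(values, design)
    res = linear.rename(columns={"p": "p_limma", "se": "se_limma"})
    res["fdr_limma"] = bh_fdr(res["p_limma"].to_numpy())

    if fit_logistic and subjects["wave"].nunique() >= 2:
        per_wave = fit_logistic_per_wave(values, subjects)
        waves = sorted(per_wave)
        disc, rep = per_wave[waves[0]], per_wave[waves[1]]
        res["b_disc"], res["se_disc"], res["p_disc"] = disc["b"], disc["se"], disc["p"]
        res["b_rep"], res["se_rep"], res["p_rep"] = rep["b"], rep["se"], rep["p"]
        meta = np.array([
            meta_fixed(res["b_disc"].iloc[g], res["se_disc"].iloc[g],
                       res["b_rep"].iloc[g], res["se_rep"].iloc[g])[:3]
            for g in range(len(res))
        ])
        res["b_meta"], res["se_meta"], res["p_meta"] = meta[:, 0], meta[:, 1], meta[:, 2]
        res["or_meta"] = np.exp(res["b_meta"])
        res["or_ci_low"] = np.exp(res["b_meta"] - 1.959963984540054 * res["se_meta"])
        res["or_ci_high"] = np.exp(res["b_meta"] + 1.959963984540054 * res["se_meta"])
        res["fdr_meta"] = bh_fdr(res["p_meta"].to_numpy())
        res["replication_tier"] = [
            classify_replication(res["p_disc"].iloc[g], res["p_rep"].iloc[g],
                                 res["b_disc"].iloc[g], res["b_rep"].iloc[g],
                                 res["log2fc"].iloc[g], replication_cfg)
            for g in range(len(res))
        ]

    for pheno in phenotypes:
        if pheno not in subjects.columns:
            continue
        cases = subjects[subjects["status"] == "case"]
        vals = cases[pheno].dropna()
        if len(vals) < 10 or vals.std() == 0:
            continue
        assoc = phenotype_assoc(values, subjects, pheno)
        res[f"{pheno}_beta"] = assoc["beta"]
        res[f"{pheno}_p"] = assoc["p"]
        res[f"{pheno}_fdr"] = assoc["fdr"]
    return res
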