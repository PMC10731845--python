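"""Feature-table preprocessing: alignment, QC filters, normalization, batch correction.

The preprocessing chain is: replicate-quality filtering -> replicate collapse
(median) -> zero replacement with the per-feature minimum detected value ->
log2 -> column quantile normalization -> empirical-Bayes location/scale batch
correction -> optional detection and re-correction of a technical PC cluster.
QC (pooled standard) columns travel through every step so before/after
coefficients of variation are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metamwas.tables import FeatureTable, ProcessedMatrix


@dataclass
class AlignmentConfig:
    mz_rel_tol: float = 1e-05
    rt_tol_c18: float = 37.016
    rt_tol_hilic: float = 38.246

    def rt_tol(self, column: str) -> float:
        return self.rt_tol_c18 if column == "c18neg" else self.rt_tol_hilic

    def validate(self) -> None:
        if min(self.mz_rel_tol, self.rt_tol_c18, self.rt_tol_hilic) <= 0:
            raise ValueError("alignment tolerances must be positive")


@dataclass
class FilterConfig:
    max_median_cv: float = 0.30
    min_replicate_pearson: float = 0.90
    min_detection_frac: float = 0.50

    def validate(self) -> None:
        if not (0 < self.max_median_cv <= 1 and 0 < self.min_detection_frac <= 1):
            raise ValueError("filter fractions must be in (0, 1]")
        if not -1 <= self.min_replicate_pearson <= 1:
            raise ValueError("min_replicate_pearson must be in [-1, 1]")


@dataclass
class FilterReport:
    """Per-rule casualties; each dropped feature is attributed to the first
    rule (cv -> correlation -> detection) it fails, so counts partition."""

    n_input: int = 0
    kept: list = field(default_factory=list)
    dropped_cv: list = field(default_factory=list)
    dropped_correlation: list = field(default_factory=list)
    dropped_detection: list = field(default_factory=list)
    replicate_rules_skipped: bool = False
    median_cv: dict = field(default_factory=dict)
    mean_replicate_r: dict = field(default_factory=dict)
    detection_frac: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_kept": len(self.kept),
            "n_dropped_cv": len(self.dropped_cv),
            "n_dropped_correlation": len(self.dropped_correlation),
            "n_dropped_detection": len(self.dropped_detection),
            "replicate_rules_skipped": self.replicate_rules_skipped,
        }


@dataclass
class CvReport:
    """Per-feature CV across pooled-QC columns, linear scale, before vs after."""

    before: pd.Series
    after: pd.Series

    def summary(self) -> dict:
        out = {}
        for label, series in (("before", self.before), ("after", self.after)):
            s = series.dropna()
            out[label] = {
                "mean": float(s.mean()) if len(s) else float("nan"),
                "median": float(s.median()) if len(s) else float("nan"),
                "iqr": float(s.quantile(0.75) - s.quantile(0.25)) if len(s) else float("nan"),
            }
        return out


def align_runs(a: FeatureTable, b: FeatureTable, cfg: AlignmentConfig | None = None) -> FeatureTable:
    """Greedy one-to-one alignment of two same-column feature tables.

    Candidate pairs satisfy the inclusive m/z relative tolerance and RT
    tolerance; they are resolved in ascending order of the combined
    normalized distance, ties broken by lowest feature id.  Matched features
    merge (mean m/z, mean RT, concatenated injections); unmatched features
    carry zeros for the other run's injections.
    """
    cfg = cfg or AlignmentConfig()
    cfg.validate()
    cols_a = set(a.features["column"].unique())
    cols_b = set(b.features["column"].unique())
    if len(cols_a | cols_b) != 1:
        raise ValueError(f"mixed column types: {sorted(cols_a)} vs {sorted(cols_b)}")
    column = next(iter(cols_a))
    rt_tol = cfg.rt_tol(column)

    mz_a = a.features["mz"].to_numpy()
    mz_b = b.features["mz"].to_numpy()
    rt_a = a.features["rt"].to_numpy()
    rt_b = b.features["rt"].to_numpy()

    cand = []
    for i in range(len(mz_a)):
        dmz = np.abs(mz_b - mz_a[i])
        rel = dmz / (0.5 * (mz_b + mz_a[i]))
        drt = np.abs(rt_b - rt_a[i])
        ok = (rel <= cfg.mz_rel_tol) & (drt <= rt_tol)
        for j in np.flatnonzero(ok):
            dist = float(np.hypot(rel[j] / cfg.mz_rel_tol, drt[j] / rt_tol))
            cand.append((dist, a.features.index[i], b.features.index[j], i, j))
    cand.sort(key=lambda c: (c[0], c[1], c[2]))

    used_a: set = set()
    used_b: set = set()
    matches: list = []
    for _, fa, fb, i, j in cand:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((fa, fb, i, j))

    injections = pd.concat([a.injections, b.injections])
    if not injections.index.is_unique:
        raise ValueError("injection ids must not collide between runs")

    feat_rows, int_rows, ids = [], [], []
    zeros_b = np.zeros(a.intensity.shape[1])
    zeros_a = np.zeros(b.intensity.shape[1])
    for fa, fb, i, j in matches:
        ids.append(fa)
        feat_rows.append(dict(column=column,
                              mz=0.5 * (mz_a[i] + mz_b[j]),
                              rt=0.5 * (rt_a[i] + rt_b[j])))
        int_rows.append(np.concatenate([a.intensity.iloc[i].to_numpy(),
                                        b.intensity.iloc[j].to_numpy()]))
    for i in range(len(mz_a)):
        if i in used_a:
            continue
        ids.append(a.features.index[i])
        feat_rows.append(dict(column=column, mz=mz_a[i], rt=rt_a[i]))
        int_rows.append(np.concatenate([a.intensity.iloc[i].to_numpy(), zeros_a[:b.intensity.shape[1]]]))
    taken = set(ids)
    for j in range(len(mz_b)):
        if j in used_b:
            continue
        fid = b.features.index[j]
        if fid in taken:
            fid = f"{fid}_b"
        taken.add(fid)
        ids.append(fid)
        feat_rows.append(dict(column=column, mz=mz_b[j], rt=rt_b[j]))
        int_rows.append(np.concatenate([zeros_b, b.intensity.iloc[j].to_numpy()]))

    features = pd.DataFrame(feat_rows, index=pd.Index(ids, name="feature_id"))
    intensity = pd.DataFrame(np.vstack(int_rows), index=features.index,
                             columns=injections.index)
    return FeatureTable(features=features, injections=injections, intensity=intensity)


def _replicate_array(t: FeatureTable) -> tuple[np.ndarray, list, list]:
    """Stack study intensities into (features, subjects, replicates), NaN-padded."""
    study = t.study_injections()
    subjects = sorted(study["subject_id"].unique())
    reps = sorted(study["replicate_index"].unique())
    s_pos = {s: i for i, s in enumerate(subjects)}
    r_pos = {r: i for i, r in enumerate(reps)}
    arr = np.full((t.n_features, len(subjects), len(reps)), np.nan)
    vals = t.intensity[study.index].to_numpy()
    for k, (inj, row) in enumerate(study.iterrows()):
        arr[:, s_pos[row["subject_id"]], r_pos[row["replicate_index"]]] = vals[:, k]
    return arr, subjects, reps


def filter_features(t: FeatureTable, cfg: FilterConfig | None = None) -> tuple[FeatureTable, FilterReport]:
    """Apply the replicate-CV, replicate-correlation, and detection-frequency filters."""
    cfg = cfg or FilterConfig()
    cfg.validate()
    report = FilterReport(n_input=t.n_features)
    arr, subjects, reps = _replicate_array(t)
    n_feat = t.n_features

    with np.errstate(invalid="ignore", divide="ignore"):
        detected = np.nansum(arr > 0, axis=2) > 0  # features x subjects
        det_frac = detected.mean(axis=1) if len(subjects) else np.zeros(n_feat)

        have_reps = len(reps) >= 2
        if have_reps:
            counts = np.sum(~np.isnan(arr), axis=2)
            means = np.nanmean(arr, axis=2)
            sds = np.nanstd(arr, axis=2, ddof=1)
            cv = sds / means
            cv[(counts < 2) | (means <= 0)] = np.nan  # all-zero / singleton subjects excluded
            median_cv = np.nanmedian(cv, axis=1)

            r_sum = np.zeros(n_feat)
            r_cnt = np.zeros(n_feat)
            for i in range(len(reps)):
                for j in range(i + 1, len(reps)):
                    x, y = arr[:, :, i], arr[:, :, j]
                    ok = ~(np.isnan(x) | np.isnan(y))
                    xm = np.where(ok, x, 0.0)
                    ym = np.where(ok, y, 0.0)
                    n = ok.sum(axis=1)
                    mx = xm.sum(axis=1) / np.maximum(n, 1)
                    my = ym.sum(axis=1) / np.maximum(n, 1)
                    dx = np.where(ok, x - mx[:, None], 0.0)
                    dy = np.where(ok, y - my[:, None], 0.0)
                    cov = (dx * dy).sum(axis=1)
                    denom = np.sqrt((dx * dx).sum(axis=1) * (dy * dy).sum(axis=1))
                    r = np.where(denom > 0, cov / np.maximum(denom, 1e-300), np.nan)
                    valid = (n >= 3) & ~np.isnan(r)
                    r_sum[valid] += r[valid]
                    r_cnt[valid] += 1
            mean_r = np.where(r_cnt > 0, r_sum / np.maximum(r_cnt, 1), np.nan)
        else:
            report.replicate_rules_skipped = True
            median_cv = np.full(n_feat, np.nan)
            mean_r = np.full(n_feat, np.nan)

    ids = list(t.features.index)
    report.median_cv = dict(zip(ids, median_cv))
    report.mean_replicate_r = dict(zip(ids, mean_r))
    report.detection_frac = dict(zip(ids, det_frac))

    for k, fid in enumerate(ids):
        if have_reps and np.isfinite(median_cv[k]) and median_cv[k] >= cfg.max_median_cv:
            report.dropped_cv.append(fid)
        elif have_reps and np.isfinite(mean_r[k]) and mean_r[k] <= cfg.min_replicate_pearson:
            report.dropped_correlation.append(fid)
        elif det_frac[k] <= cfg.min_detection_frac:
            report.dropped_detection.append(fid)
        else:
            report.kept.append(fid)

    return t.subset_features(report.kept), report


def collapse_replicates(t: FeatureTable) -> FeatureTable:
    """Collapse replicate injections to their median, one column per subject.

    QC injections collapse per (batch, slot position) so within-batch QC slots
    remain distinct columns for CV reporting.
    """
    groups: dict = {}
    meta: dict = {}
    for inj, row in t.injections.iterrows():
        if row["role"] == "study":
            key = row["subject_id"]
        else:
            key = f"{row['subject_id']}:b{row['batch']}:p{row['replicate_index']}"
        groups.setdefault(key, []).append(inj)
        if key not in meta:
            meta[key] = dict(subject_id=row["subject_id"], role=row["role"],
                             replicate_index=0, batch=row["batch"], run=row["run"],
                             order=row["order"])
    keys = list(groups)
    vals = np.column_stack([
        np.median(t.intensity[groups[k]].to_numpy(), axis=1) for k in keys
    ])
    injections = pd.DataFrame([meta[k] for k in keys],
                              index=pd.Index(keys, name="injection_id"))
    intensity = pd.DataFrame(vals, index=t.features.index, columns=injections.index)
    return FeatureTable(features=t.features.copy(), injections=injections,
                        intensity=intensity)


def replace_zeros(m: pd.DataFrame) -> pd.DataFrame:
    """Replace zeros (not detected) with the feature's lowest detected value.

    Features with no detected value at all fall back to 1 (log2 -> 0).
    """
    vals = m.to_numpy(dtype=float).copy()
    masked = np.where(vals > 0, vals, np.inf)
    min_nonzero = masked.min(axis=1)
    min_nonzero[~np.isfinite(min_nonzero)] = 1.0
    vals = np.where(vals > 0, vals, min_nonzero[:, None])
    return pd.DataFrame(vals, index=m.index, columns=m.columns)


def quantile_normalize(m: pd.DataFrame) -> pd.DataFrame:
    """Classical column quantile normalization.

    Each column's sorted values are replaced by the across-column mean of
    sorted values; tied values receive the mean of their would-be quantile
    values, so rank orders are preserved and the map is idempotent.
    """
    vals = m.to_numpy(dtype=float)
    n = vals.shape[0]
    if n == 0 or vals.shape[1] == 0:
        return m.copy()
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    positions = np.arange(n, dtype=float)
    for j in range(vals.shape[1]):
        ranks = pd.Series(vals[:, j]).rank(method="average").to_numpy() - 1.0
        out[:, j] = np.interp(ranks, positions, ref)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def combat_adjust(m: pd.DataFrame, batch, protected=None, tol: float = 1e-8,
                  max_iter: int = 500) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment.

    Per feature: fit a model with batch indicators and protected covariates,
    standardize residual variation, estimate per-batch additive (gamma) and
    multiplicative (delta^2) effects, shrink them toward batch-level priors
    (normal for gamma, inverse-gamma for delta^2, hyperparameters by method
    of moments), then adjust and back-transform.  Protected-covariate effects
    are restored unchanged.

    Parameters
    ----------
    m : DataFrame, features x samples.
    batch : array-like of batch labels per sample.
    protected : optional DataFrame/array (samples x p) of covariates whose
        effects must survive correction; must be full rank.
    """
    batch = np.asarray(pd.Series(list(batch)).astype(str))
    if len(batch) != m.shape[1]:
        raise ValueError("batch labels must match number of columns")
    levels, batch_idx = np.unique(batch, return_inverse=True)
    n_batch = len(levels)
    counts = np.bincount(batch_idx)
    for lev, c in zip(levels, counts):
        if c < 2:
            raise ValueError(f"batch '{lev}' has fewer than 2 columns")
    if n_batch == 1:
        return m.copy()

    Y = m.to_numpy(dtype=float)  # G x N
    N = Y.shape[1]
    B = np.zeros((N, n_batch))
    B[np.arange(N), batch_idx] = 1.0
    if protected is not None:
        C = np.asarray(protected, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("protected design is not full rank")
    else:
        C = np.zeros((N, 0))
    X = np.hstack([B, C])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("combined batch + protected design is not full rank")

    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (n_batch+p) x G
    grand = (counts / N) @ beta[:n_batch]  # G
    stand_mean = grand[None, :] + C @ beta[n_batch:]  # N x G
    resid = Y.T - X @ beta
    var_pooled = (resid ** 2).mean(axis=0)  # G
    scale = np.sqrt(np.maximum(var_pooled, 1e-300))
    constant = var_pooled <= 0

    Z = (Y - stand_mean.T) / scale[:, None]  # G x N

    gamma_hat = np.stack([Z[:, batch_idx == i].mean(axis=1) for i in range(n_batch)])
    delta_hat = np.stack([Z[:, batch_idx == i].var(axis=1, ddof=1) for i in range(n_batch)])

    gamma_star = np.empty_like(gamma_hat)
    delta_star = np.empty_like(delta_hat)
    for i in range(n_batch):
        g_hat, d_hat = gamma_hat[i], delta_hat[i]
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        dm, dv = d_hat.mean(), d_hat.var(ddof=1)
        a = (2 * dv + dm ** 2) / dv if dv > 0 else np.inf
        b = (dm * dv + dm ** 3) / dv if dv > 0 else 0.0
        n_i = counts[i]
        Zi = Z[:, batch_idx == i]
        g_old, d_old = g_hat.copy(), d_hat.copy()
        if not np.isfinite(a):  # degenerate prior: no scale shrinkage
            g_new = _postmean(g_hat, g_bar, n_i, d_old, t2) if t2 > 0 else np.full_like(g_hat, g_bar)
            gamma_star[i], delta_star[i] = g_new, d_old
            continue
        for _ in range(max_iter):
            g_new = _postmean(g_hat, g_bar, n_i, d_old, t2) if t2 > 0 else np.full_like(g_hat, g_bar)
            sum2 = ((Zi - g_new[:, None]) ** 2).sum(axis=1)
            d_new = _postvar(sum2, n_i, a, b)
            change = max(np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                         np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)))
            g_old, d_old = g_new, d_new
            if change < tol:
                break
        gamma_star[i], delta_star[i] = g_old, d_old

    Z_adj = np.empty_like(Z)
    for i in range(n_batch):
        sel = batch_idx == i
        Z_adj[:, sel] = (Z[:, sel] - gamma_star[i][:, None]) / np.sqrt(
            np.maximum(delta_star[i][:, None], 1e-300))
    out = Z_adj * scale[:, None] + stand_mean.T
    out[constant] = Y[constant]
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def detect_technical_clusters(m: pd.DataFrame, k_pcs: int = 2,
                              silhouette_min: float = 0.4,
                              min_cluster_frac: float = 0.05) -> np.ndarray:
    """Flag a technical sample cluster from PCA scores.

    PCA on feature-centered data, deterministic 2-means (farthest-pair
    seeding) on the top ``k_pcs`` sample scores.  A split is reported only if
    the silhouette reaches ``silhouette_min`` and the minor cluster holds at
    least ``min_cluster_frac`` of the columns; otherwise the indicator is all
    zeros.  Returns an int array (1 = member of the minor cluster).
    """
    from sklearn.metrics import silhouette_score

    n = m.shape[1]
    indicator = np.zeros(n, dtype=int)
    if n < 4 or m.shape[0] < 2:
        return indicator
    X = m.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    # sample scores from SVD of samples x features
    U, S, _ = np.linalg.svd(X.T, full_matrices=False)
    k = min(k_pcs, len(S))
    scores = U[:, :k] * S[:k]

    d2 = ((scores[:, None, :] - scores[None, :, :]) ** 2).sum(axis=2)
    i0, j0 = np.unravel_index(np.argmax(d2), d2.shape)
    centers = scores[[i0, j0]].copy()
    labels = np.zeros(n, dtype=int)
    for _ in range(100):
        dist = ((scores[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        if (new_labels == labels).all() and _ > 0:
            break
        labels = new_labels
        for c in (0, 1):
            if (labels == c).any():
                centers[c] = scores[labels == c].mean(axis=0)

    n1 = int(labels.sum())
    if n1 == 0 or n1 == n:
        return indicator
    sil = silhouette_score(scores, labels)
    minor = 1 if n1 <= n - n1 else 0
    minor_frac = min(n1, n - n1) / n
    if sil >= silhouette_min and minor_frac >= min_cluster_frac:
        indicator = (labels == minor).astype(int)
    return indicator


def _protected_design(subjects: pd.DataFrame, column_meta: pd.DataFrame) -> np.ndarray:
    """Protected covariate matrix for batch correction: case status, age,
    gender, ethnicity, wave, draw year, plus a QC-role indicator.  Study-level
    covariates are centered on study means and zeroed for QC columns."""
    rows = []
    study_subj = subjects
    age_mean = study_subj["age"].mean()
    year_mean = study_subj["draw_year"].mean()
    eth_levels = sorted(study_subj["ethnicity"].unique())[1:]
    for _, meta in column_meta.iterrows():
        if meta["role"] == "qc":
            rows.append([0.0, 0.0, 0.0] + [0.0] * len(eth_levels) + [0.0, 0.0, 1.0])
            continue
        s = study_subj.loc[meta["subject_id"]]
        rows.append([
            1.0 if s["status"] == "case" else 0.0,
            s["age"] - age_mean,
            1.0 if s["gender"] == "M" else 0.0,
            *[1.0 if s["ethnicity"] == lev else 0.0 for lev in eth_levels],
            1.0 if s["wave"] == 2 else 0.0,
            s["draw_year"] - year_mean,
            0.0,
        ])
    X = np.asarray(rows, dtype=float)
    # drop constant / collinear columns (e.g. single-wave data)
    keep = [j for j in range(X.shape[1]) if np.ptp(X[:, j]) > 0]
    X = X[:, keep]
    while X.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        X = X[:, :-1]
    return X


def preprocess(t: FeatureTable, subjects: pd.DataFrame,
               filter_cfg: FilterConfig | None = None,
               detect_clusters: bool = True,
               k_pcs: int = 2,
               silhouette_min: float = 0.4,
               min_cluster_frac: float = 0.05) -> tuple[ProcessedMatrix, CvReport, FilterReport]:
    """Run the full preprocessing chain on one feature table.

    Returns the processed features x subjects matrix (log2 scale), a CV
    report computed on the pooled-QC columns before vs after processing, and
    the filter report.
    """
    filtered, filter_report = filter_features(t, filter_cfg)
    collapsed = collapse_replicates(filtered)

    vals = collapsed.intensity.to_numpy(dtype=float).copy()
    qc_mask = (collapsed.injections["role"] == "qc").to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        cv_before = pd.Series(
            np.nanstd(np.where(vals[:, qc_mask] > 0, vals[:, qc_mask], np.nan), axis=1, ddof=1)
            / np.nanmean(np.where(vals[:, qc_mask] > 0, vals[:, qc_mask], np.nan), axis=1),
            index=collapsed.features.index,
        ) if qc_mask.any() else pd.Series(dtype=float)

    filled = replace_zeros(pd.DataFrame(vals, index=collapsed.features.index,
                                        columns=collapsed.intensity.columns))
    logged = pd.DataFrame(np.log2(filled.to_numpy()), index=collapsed.features.index,
                          columns=collapsed.intensity.columns)
    normed = quantile_normalize(logged)

    protected = _protected_design(subjects, collapsed.injections)
    corrected = combat_adjust(normed, collapsed.injections["batch"], protected)

    provenance = [
        {"step": "filter_features", **(filter_cfg or FilterConfig()).__dict__},
        {"step": "collapse_replicates", "rule": "median"},
        {"step": "zero_replacement", "rule": "per-feature min nonzero"},
        {"step": "log2"},
        {"step": "quantile_normalize"},
        {"step": "combat_adjust", "batch": "acquisition batch"},
    ]

    cluster_indicator = np.zeros(corrected.shape[1], dtype=int)
    if detect_clusters:
        # QC columns sit apart from study samples by construction; the cluster
        # search must not rediscover that split, so it runs on study columns.
        study_sel = ~qc_mask
        study_ind = detect_technical_clusters(
            corrected.loc[:, study_sel], k_pcs=k_pcs,
            silhouette_min=silhouette_min, min_cluster_frac=min_cluster_frac)
        if study_ind.any():
            # a split explained by case status is biology, not a technical
            # artifact; leave it alone
            study_cols_meta = collapsed.injections[study_sel]
            case = (subjects.loc[study_cols_meta["subject_id"], "status"] == "case")
            phi = abs(np.corrcoef(study_ind, case.to_numpy(dtype=float))[0, 1])
            if np.isfinite(phi) and phi > 0.5:
                study_ind = np.zeros_like(study_ind)
        cluster_indicator[study_sel] = study_ind
        if cluster_indicator.any():
            n_minor = int(cluster_indicator.sum())
            if n_minor >= 2 and corrected.shape[1] - n_minor >= 2:
                corrected = combat_adjust(corrected, cluster_indicator, protected)
                provenance.append({"step": "combat_adjust",
                                   "batch": "technical PC cluster indicator",
                                   "n_minor": n_minor})

    qc_cols = collapsed.injections.index[qc_mask]
    study_cols = collapsed.injections.index[~qc_mask]
    values = corrected[study_cols]
    values.columns = [collapsed.injections.loc[c, "subject_id"] for c in study_cols]
    qc = corrected[qc_cols]

    with np.errstate(invalid="ignore", divide="ignore"):
        lin_after = np.exp2(qc.to_numpy())
        cv_after = pd.Series(
            lin_after.std(axis=1, ddof=1) / lin_after.mean(axis=1),
            index=qc.index,
        ) if qc.shape[1] > 1 else pd.Series(dtype=float)

    matrix = ProcessedMatrix(values=values, qc=qc, provenance=provenance)
    cv_report = CvReport(before=cv_before, after=cv_after)
    return matrix, cv_report, filter_report
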