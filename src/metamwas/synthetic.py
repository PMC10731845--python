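"""Synthetic two-wave case-control cohort generator for pipeline testing.

Emulates a dual-column LC-HRMS study design: two recruitment waves, two
instrument runs, batches of ``batch_size`` subjects, triplicate injections,
periodic pooled-QC injections, per-feature batch/run/drift effects, planted
case-control effects, medication-dose-linked features, age-correlated
features, and deliberately noisy ("junk") features.  Every planted parameter
is returned in a truth table so downstream recovery can be tested.

The generative model for the log2 intensity of feature ``g``, subject ``i``,
injection ``j`` is::

    mu_g + beta_g*case_i + alpha_g*(age_i - mean age) + lambda_g*ledd_i*case_i
         + b_{g,batch(j)} + r_{g,run(j)} + slope_g*order(j)
         + eps_{g,i} + eta_{g,i,j}

Intensities below the feature's LOD quantile are censored to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from metamwas.tables import FeatureTable

PROTON_MASS = 1.007276

COLUMNS = ("c18neg", "hilicpos")


@dataclass
class CohortConfig:
    """Parameters of the synthetic study; defaults mirror the full-scale design."""

    n_cases_wave1: int = 282
    n_controls_wave1: int = 185
    n_cases_wave2: int = 360
    n_controls_wave2: int = 90
    batch_size: int = 40
    n_batches: int | None = None  # derived from subject count when None
    n_runs: int = 2
    n_replicate_injections: int = 3
    qc_per_batch: int = 3
    n_features_per_column: int = 2000
    frac_true_effects: float = 0.05
    effect_log2fc_min: float = 0.25
    effect_log2fc_max: float = 2.0
    n_medication_features: int = 10
    n_age_features: int = 10
    n_junk_cv_features: int = 10
    batch_sd: float = 0.4
    run_sd: float = 0.6
    drift_slope: float = 2e-4
    residual_sd: float = 0.5
    replicate_cv: float = 0.08
    junk_replicate_cv: float = 0.8
    lod_quantile: float = 0.02
    frac_mapped: float = 0.4
    age_case_shift: float = 3.0
    male_frac_cases: float = 0.62
    male_frac_controls: float = 0.50
    external_rho: float = 0.8
    external_noise_sd: float = 0.4
    external_n: int = 460
    seed: int = 0

    def validate(self) -> None:
        counts = [
            self.n_cases_wave1, self.n_controls_wave1, self.n_cases_wave2,
            self.n_controls_wave2, self.qc_per_batch, self.n_features_per_column,
            self.n_medication_features, self.n_age_features, self.n_junk_cv_features,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("counts must be nonnegative")
        if self.batch_size < 1 or self.n_runs < 1 or self.n_replicate_injections < 1:
            raise ValueError("batch_size, n_runs, n_replicate_injections must be >= 1")
        for name in ("frac_true_effects", "lod_quantile", "frac_mapped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.replicate_cv <= 0:
            raise ValueError("replicate_cv must be positive")
        n_subjects = self.n_subjects
        if self.n_batches is not None and self.n_batches * self.batch_size < n_subjects:
            raise ValueError(
                f"{self.n_batches} batches of {self.batch_size} cannot hold "
                f"{n_subjects} subjects"
            )

    @property
    def n_subjects(self) -> int:
        return (self.n_cases_wave1 + self.n_controls_wave1
                + self.n_cases_wave2 + self.n_controls_wave2)

    @classmethod
    def test_scale(cls, **overrides) -> "CohortConfig":
        """Small configuration that generates in well under a minute."""
        defaults = dict(
            n_cases_wave1=40, n_controls_wave1=30, n_cases_wave2=35,
            n_controls_wave2=15, batch_size=20, n_features_per_column=100,
            n_medication_features=5, n_age_features=5, n_junk_cv_features=5,
        )
        defaults.update(overrides)
        return cls(**defaults)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted per-feature parameters for recovery testing.

    ``per_feature`` columns: ``true_log2fc``, ``is_medication_linked``,
    ``ledd_slope``, ``age_slope``, ``is_junk``, ``mapped_metabolite_id``.
    ``batch_offsets`` holds the per-feature additive batch effects.
    """

    per_feature: pd.DataFrame
    batch_offsets: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, path: str) -> None:
        self.per_feature.to_csv(path, sep="\t", index_label="feature_id")

    @classmethod
    def read(cls, path: str) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", index_col="feature_id")
        return cls(per_feature=df)


def _log2_replicate_sd(cv: float) -> float:
    # lognormal: CV on the linear scale maps to this sd on the log2 scale
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


def _generate_subjects(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    spec = [
        (1, "case", cfg.n_cases_wave1), (1, "control", cfg.n_controls_wave1),
        (2, "case", cfg.n_cases_wave2), (2, "control", cfg.n_controls_wave2),
    ]
    idx = 0
    for wave, status, n in spec:
        for _ in range(n):
            idx += 1
            case = status == "case"
            age = float(np.clip(rng.normal(65.0 + (cfg.age_case_shift if case else 0.0), 8.0), 35, 95))
            male_p = cfg.male_frac_cases if case else cfg.male_frac_controls
            gender = "M" if rng.random() < male_p else "F"
            eth_p = (0.55, 0.35, 0.10) if case else (0.65, 0.25, 0.10)
            ethnicity = rng.choice(["white", "hispanic", "other"], p=eth_p)
            smoke_p = (0.65, 0.30, 0.05) if case else (0.50, 0.40, 0.10)
            smoking = rng.choice(["never", "former", "current"], p=smoke_p)
            draw_year = int(rng.integers(2001, 2008) if wave == 1 else rng.integers(2012, 2018))
            if case:
                z = rng.normal()
                ledd = float(max(0.0, 300.0 + 150.0 * z + rng.normal(0, 80)))
                hy = float(np.clip(round(2.0 + 0.7 * z + rng.normal(0, 0.5)), 1, 5))
                updrs3 = float(np.clip(20.0 + 8.0 * z + rng.normal(0, 5), 0, 80))
            else:
                ledd, hy, updrs3 = 0.0, np.nan, np.nan
            rows.append(dict(
                subject_id=f"S{idx:05d}", wave=wave, status=status, age=age,
                gender=gender, ethnicity=ethnicity, smoking=smoking,
                draw_year=draw_year, ledd=ledd, hy=hy, updrs3=updrs3,
            ))
    return pd.DataFrame(rows).set_index("subject_id")


def _injection_layout(cfg: CohortConfig, subjects: pd.DataFrame,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Randomly sort subjects into batches, split batches across runs, insert QC slots."""
    ids = list(subjects.index)
    perm = rng.permutation(len(ids))
    shuffled = [ids[i] for i in perm]
    batches = [shuffled[i:i + cfg.batch_size] for i in range(0, len(shuffled), cfg.batch_size)]
    per_run = int(math.ceil(len(batches) / cfg.n_runs))
    rows, order = [], 0
    for b_idx, members in enumerate(batches):
        run = min(b_idx // per_run, cfg.n_runs - 1) + 1
        # QC slots spread evenly: before, between chunks, after
        n_qc = cfg.qc_per_batch
        chunk = max(1, int(math.ceil(len(members) / max(1, n_qc - 1)))) if n_qc > 1 else len(members)
        chunks = [members[i:i + chunk] for i in range(0, len(members), chunk)] or [[]]
        qc_pos = 0

        def qc_row(pos, order):
            return dict(
                injection_id=f"R{run}B{b_idx:03d}QC{pos}",
                subject_id=f"QC_run{run}", role="qc", replicate_index=pos,
                batch=b_idx, run=run, order=order,
            )

        if n_qc > 0:
            rows.append(qc_row(qc_pos, order)); qc_pos += 1; order += 1
        for c_idx, members_chunk in enumerate(chunks):
            for sid in members_chunk:
                for rep in range(cfg.n_replicate_injections):
                    rows.append(dict(
                        injection_id=f"{sid}_r{rep}", subject_id=sid, role="study",
                        replicate_index=rep, batch=b_idx, run=run, order=order,
                    ))
                    order += 1
            if qc_pos < n_qc:
                rows.append(qc_row(qc_pos, order)); qc_pos += 1; order += 1
        while qc_pos < n_qc:
            rows.append(qc_row(qc_pos, order)); qc_pos += 1; order += 1
    return pd.DataFrame(rows).set_index("injection_id")


def _assign_feature_roles(cfg: CohortConfig, n_total: int,
                          rng: np.random.Generator) -> pd.DataFrame:
    n_true = int(round(cfg.frac_true_effects * n_total))
    roles = pd.DataFrame(index=range(n_total))
    roles["true_log2fc"] = 0.0
    roles["is_medication_linked"] = False
    roles["ledd_slope"] = 0.0
    roles["age_slope"] = 0.0
    roles["is_junk"] = False

    n_special = n_true + cfg.n_medication_features + cfg.n_age_features + cfg.n_junk_cv_features
    if n_special > n_total:
        raise ValueError("special feature counts exceed total features")
    picks = rng.choice(n_total, size=n_special, replace=False)
    true_idx = picks[:n_true]
    med_idx = picks[n_true:n_true + cfg.n_medication_features]
    age_idx = picks[n_true + cfg.n_medication_features:
                    n_true + cfg.n_medication_features + cfg.n_age_features]
    junk_idx = picks[n_true + cfg.n_medication_features + cfg.n_age_features:]

    mags = rng.uniform(cfg.effect_log2fc_min, cfg.effect_log2fc_max, size=n_true)
    signs = rng.choice([-1.0, 1.0], size=n_true)
    roles.loc[true_idx, "true_log2fc"] = mags * signs
    roles.loc[med_idx, "is_medication_linked"] = True
    roles.loc[med_idx, "ledd_slope"] = (rng.uniform(8e-4, 2e-3, size=len(med_idx))
                                        * rng.choice([-1.0, 1.0], size=len(med_idx)))
    roles.loc[age_idx, "age_slope"] = (rng.uniform(0.01, 0.03, size=len(age_idx))
                                       * rng.choice([-1.0, 1.0], size=len(age_idx)))
    roles.loc[junk_idx, "is_junk"] = True
    return roles


def generate_cohort(cfg: CohortConfig) -> tuple[FeatureTable, pd.DataFrame, TruthTable]:
    """Generate the feature table, subject metadata, and ground-truth table."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    subjects = _generate_subjects(cfg, rng)
    injections = _injection_layout(cfg, subjects, rng)
    n_total = cfg.n_features_per_column * len(COLUMNS)
    roles = _assign_feature_roles(cfg, n_total, rng)

    feat_rows = []
    for c_i, col in enumerate(COLUMNS):
        for k in range(cfg.n_features_per_column):
            g = c_i * cfg.n_features_per_column + k
            feat_rows.append(dict(
                feature_id=f"F{g:05d}", column=col,
                mz=float(rng.uniform(80, 850)), rt=float(rng.uniform(10, 300)),
            ))
    features = pd.DataFrame(feat_rows).set_index("feature_id")
    roles.index = features.index

    batch_labels = sorted(injections["batch"].unique())
    run_labels = sorted(injections["run"].unique())
    n_feat, n_inj = len(features), len(injections)

    mu = rng.uniform(10, 20, size=n_feat)
    batch_off = rng.normal(0, cfg.batch_sd, size=(n_feat, len(batch_labels)))
    run_off = rng.normal(0, cfg.run_sd, size=(n_feat, len(run_labels)))
    slope = rng.normal(0, cfg.drift_slope, size=n_feat)

    subj_ids = list(subjects.index)
    subj_pos = {s: i for i, s in enumerate(subj_ids)}
    age_c = subjects["age"].to_numpy() - subjects["age"].mean()
    case = (subjects["status"] == "case").to_numpy(dtype=float)
    ledd = subjects["ledd"].to_numpy()

    beta = roles["true_log2fc"].to_numpy()
    lam = roles["ledd_slope"].to_numpy()
    alpha = roles["age_slope"].to_numpy()

    # subject-level biological signal (features x subjects)
    subj_signal = (mu[:, None]
                   + beta[:, None] * case[None, :]
                   + alpha[:, None] * age_c[None, :]
                   + lam[:, None] * (ledd * case)[None, :]
                   + rng.normal(0, cfg.residual_sd, size=(n_feat, len(subj_ids))))
    # one pooled QC profile per run
    qc_signal = mu[:, None] + rng.normal(0, cfg.residual_sd,
                                         size=(n_feat, len(run_labels)))

    rep_sd = np.full(n_feat, _log2_replicate_sd(cfg.replicate_cv))
    rep_sd[roles["is_junk"].to_numpy()] = _log2_replicate_sd(cfg.junk_replicate_cv)

    batch_idx = np.searchsorted(batch_labels, injections["batch"].to_numpy())
    run_idx = np.searchsorted(run_labels, injections["run"].to_numpy())
    order = injections["order"].to_numpy(dtype=float)
    is_study = (injections["role"] == "study").to_numpy()
    col_subject = np.array([subj_pos.get(s, -1) for s in injections["subject_id"]])

    log2_int = np.empty((n_feat, n_inj))
    log2_int[:, is_study] = subj_signal[:, col_subject[is_study]]
    log2_int[:, ~is_study] = qc_signal[:, run_idx[~is_study]]
    log2_int += batch_off[:, batch_idx] + run_off[:, run_idx] + slope[:, None] * order[None, :]
    log2_int += rng.normal(0, 1, size=(n_feat, n_inj)) * rep_sd[:, None]

    intensity = np.exp2(log2_int)
    if cfg.lod_quantile > 0:
        lod = np.quantile(intensity, cfg.lod_quantile, axis=1, keepdims=True)
        intensity = np.where(intensity < lod, 0.0, intensity)

    # metabolite mapping: all true-effect features plus random fill up to frac_mapped
    mapped = np.zeros(n_feat, dtype=bool)
    mapped |= beta != 0
    n_target = int(round(cfg.frac_mapped * n_feat))
    pool = np.flatnonzero(~mapped)
    extra = max(0, n_target - mapped.sum())
    if extra and len(pool):
        mapped[rng.choice(pool, size=min(extra, len(pool)), replace=False)] = True
    met_ids = np.array([f"M{g:05d}" if m else "" for g, m in enumerate(mapped)], dtype=object)
    roles["mapped_metabolite_id"] = met_ids

    table = FeatureTable(
        features=features,
        injections=injections,
        intensity=pd.DataFrame(intensity, index=features.index, columns=injections.index),
    )
    truth = TruthTable(
        per_feature=roles,
        batch_offsets=pd.DataFrame(batch_off, index=features.index, columns=batch_labels),
    )
    return table, subjects, truth


def generate_reference_and_pathways(
    truth: TruthTable,
    features: pd.DataFrame,
    cfg: CohortConfig,
    n_null_pathways: int = 4,
    null_pathway_size: int = 8,
) -> tuple[pd.DataFrame, dict]:
    """Build a reference library and GMT-style pathway sets from the truth table.

    Each mapped metabolite's monoisotopic mass is back-computed from its
    feature's m/z through the default adduct for that chromatography column
    ([M+H]+ for hilicpos, [M-H]- for c18neg), so mass matching reproduces the
    m/z at 0 ppm.  One pathway is enriched for true-effect metabolites by
    construction; the remainder draw from null metabolites.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    tf = truth.per_feature
    mapped = tf[tf["mapped_metabolite_id"] != ""]
    rows = []
    for fid, row in mapped.iterrows():
        col = features.loc[fid, "column"]
        mz = features.loc[fid, "mz"]
        rt = features.loc[fid, "rt"]
        mass = mz - PROTON_MASS if col == "hilicpos" else mz + PROTON_MASS
        rows.append(dict(
            metabolite_id=row["mapped_metabolite_id"],
            name=f"metabolite {row['mapped_metabolite_id']}",
            monoisotopic_mass=mass,
            rt_c18=rt if col == "c18neg" else np.nan,
            rt_hilic=rt if col == "hilicpos" else np.nan,
        ))
    library = pd.DataFrame(rows).set_index("metabolite_id").sort_index()

    effect_mets = sorted(mapped.loc[mapped["true_log2fc"] != 0, "mapped_metabolite_id"])
    null_mets = sorted(mapped.loc[mapped["true_log2fc"] == 0, "mapped_metabolite_id"])
    pathways: dict = {}
    n_eff = min(len(effect_mets), 10)
    if n_eff:
        eff_pick = list(rng.choice(effect_mets, size=n_eff, replace=False))
        n_pad = min(len(null_mets), max(0, min(n_eff, 4)))
        pad = list(rng.choice(null_mets, size=n_pad, replace=False)) if n_pad else []
        pathways["pathway_enriched"] = set(eff_pick) | set(pad)
    remaining = [m for m in null_mets if m not in pathways.get("pathway_enriched", set())]
    for i in range(n_null_pathways):
        if not remaining:
            break
        size = min(null_pathway_size, len(remaining))
        pick = list(rng.choice(remaining, size=size, replace=False))
        pathways[f"pathway_null_{i + 1}"] = set(pick)
        remaining = [m for m in remaining if m not in pathways[f"pathway_null_{i + 1}"]]
    return library, pathways


def generate_external_summary(truth: TruthTable, cfg: CohortConfig) -> pd.DataFrame:
    """Simulate an external study's (fold change, p, n) summary per mapped metabolite.

    External log2 fold changes correlate with the planted internal effects at
    ``cfg.external_rho``; p-values derive from a normal test of the external
    effect at the external sample size.
    """
    from scipy import stats

    rng = np.random.default_rng(cfg.seed + 2)
    tf = truth.per_feature
    mapped = tf[tf["mapped_metabolite_id"] != ""]
    rho = cfg.external_rho
    rows = []
    for _, row in mapped.iterrows():
        l_true = row["true_log2fc"]
        noise = math.sqrt(max(0.0, 1.0 - rho * rho)) * cfg.external_noise_sd * rng.normal()
        l_ext = rho * l_true + noise
        se = 2.0 / math.sqrt(cfg.external_n)
        p = float(np.clip(2.0 * stats.norm.sf(abs(l_ext) / se), 1e-300, 1.0))
        rows.append(dict(
            metabolite=f"metabolite {row['mapped_metabolite_id']}",
            fold_change=float(2.0 ** l_ext),
            p_value=p,
            n=cfg.external_n,
        ))
    return pd.DataFrame(rows)
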