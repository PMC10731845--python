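"""End-to-end orchestration: simulate -> preprocess -> MWAS -> annotate ->
pathways -> network -> external validation -> report.

Every stage writes plain-text outputs under the configured output directory
and appends to a JSON run manifest (seed, parameters, step timings), so a
rerun with the same configuration and seed reproduces all numeric outputs
exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from metamwas import io as mio
from metamwas import __version__
from metamwas.annotation import match_features
from metamwas.crossstudy import ValidationThresholds, validate_external
from metamwas.mwas import (ReplicationConfig, correlation_network,
                           network_to_graphml, run_mwas)
from metamwas.pathways import build_weight_map, pathway_permutation_test
from metamwas.processing import FilterConfig, preprocess
from metamwas.synthetic import (COLUMNS, CohortConfig, generate_cohort,
                                generate_external_summary,
                                generate_reference_and_pathways)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    out_dir: str = "results"
    seed: int = 0
    scale: str = "test"  # "test" or "full"
    simulate: bool = True
    cohort: CohortConfig | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    replication: ReplicationConfig = field(default_factory=ReplicationConfig)
    fdr_max: float = 0.05
    network_min_abs_r: float = 0.2
    ppm_tol_tier1: float = 5.0
    ppm_tol_tier2: float = 10.0
    rt_tol: float = 30.0
    permutation_b: int = 999
    detect_clusters: bool = True
    fit_logistic: bool = True
    # optional externally supplied inputs (used when simulate is False)
    feature_table_path: str | None = None
    injections_path: str | None = None
    subjects_path: str | None = None
    library_path: str | None = None
    pathway_gmt_path: str | None = None
    external_summary_path: str | None = None

    def resolved_cohort(self) -> CohortConfig:
        if self.cohort is not None:
            return self.cohort
        cfg = CohortConfig(seed=self.seed) if self.scale == "full" else \
            CohortConfig.test_scale(seed=self.seed)
        return cfg

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        cohort_raw = raw.pop("cohort", None)
        filt_raw = raw.pop("filter", None)
        rep_raw = raw.pop("replication", None)
        cfg = cls(**raw)
        if cohort_raw:
            cfg.cohort = CohortConfig(**cohort_raw)
        if filt_raw:
            cfg.filter = FilterConfig(**filt_raw)
        if rep_raw:
            cfg.replication = ReplicationConfig(**rep_raw)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is None:
            d["cohort"] = dataclasses.asdict(self.resolved_cohort())
        return d


def _path(cfg: PipelineConfig, name: str) -> str:
    mio.ensure_dir(cfg.out_dir)
    return os.path.join(cfg.out_dir, name)


def run_full(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the in-memory result bundle."""
    manifest = {"version": __version__, "seed": cfg.seed,
                "config": cfg.to_dict(), "timings": {}}
    bundle: dict = {"manifest": manifest}
    t_start = time.time()

    def tic(stage):
        manifest["timings"][stage] = round(time.time() - t_start, 3)

    try:
        # ---- simulate or load ---------------------------------------------
        if cfg.simulate:
            cohort_cfg = cfg.resolved_cohort()
            table, subjects, truth = generate_cohort(cohort_cfg)
            library, pathways = generate_reference_and_pathways(
                truth, table.features, cohort_cfg)
            external = generate_external_summary(truth, cohort_cfg)
            mio.write_feature_table(table, _path(cfg, "feature_table.tsv"),
                                    _path(cfg, "injections.tsv"))
            mio.write_subjects(subjects, _path(cfg, "subjects.tsv"))
            mio.write_library(library, _path(cfg, "library.tsv"))
            mio.write_gmt(pathways, _path(cfg, "pathways.gmt"))
            external.to_csv(_path(cfg, "external_summary.csv"), index=False)
            truth.write(_path(cfg, "truth.tsv"))
        else:
            table = mio.read_feature_table(cfg.feature_table_path, cfg.injections_path)
            subjects = mio.read_subjects(cfg.subjects_path)
            library = mio.read_library(cfg.library_path) if cfg.library_path else None
            pathways = (mio.read_gmt(cfg.pathway_gmt_path)
                        if cfg.pathway_gmt_path and os.path.exists(cfg.pathway_gmt_path)
                        else None)
            external = (pd.read_csv(cfg.external_summary_path)
                        if cfg.external_summary_path else None)
        bundle.update(table=table, subjects=subjects, library=library,
                      pathways=pathways, external=external)
        tic("simulate")

        # ---- preprocess per chromatography column -------------------------
        matrices, cv_reports, filter_reports = [], {}, {}
        for col in COLUMNS:
            sub = table.subset_column(col)
            if sub.n_features == 0:
                continue
            matrix, cv_rep, filt_rep = preprocess(
                sub, subjects, filter_cfg=cfg.filter,
                detect_clusters=cfg.detect_clusters)
            matrices.append(matrix)
            cv_reports[col] = cv_rep
            filter_reports[col] = filt_rep
        values = pd.concat([m.values for m in matrices])
        bundle["values"] = values
        bundle["cv_reports"] = cv_reports
        bundle["filter_reports"] = filter_reports
        mio.write_matrix(values, _path(cfg, "processed_matrix.tsv"))
        with open(_path(cfg, "qc_report.json"), "w") as fh:
            json.dump({
                "seed": cfg.seed,
                "cv": {c: r.summary() for c, r in cv_reports.items()},
                "filters": {c: r.to_dict() for c, r in filter_reports.items()},
            }, fh, indent=2)
        tic("preprocess")

        # ---- MWAS ----------------------------------------------------------
        results = run_mwas(values, subjects, replication_cfg=cfg.replication,
                           fit_logistic=cfg.fit_logistic)
        bundle["mwas"] = results
        results.to_csv(_path(cfg, "mwas_results.tsv"), sep="\t",
                       index_label="feature_id")
        tic("mwas")

        # ---- annotation ----------------------------------------------------
        hits = pd.DataFrame(columns=["feature_id", "metabolite_id", "adduct",
                                     "ppm_error", "rt_error", "tier"])
        if library is not None and len(library):
            feats = table.features.loc[[f for f in values.index
                                        if f in table.features.index]]
            hits = match_features(feats, library,
                                  ppm_tol_tier1=cfg.ppm_tol_tier1,
                                  ppm_tol_tier2=cfg.ppm_tol_tier2,
                                  rt_tol=cfg.rt_tol)
        bundle["hits"] = hits
        hits.to_csv(_path(cfg, "annotation_hits.tsv"), sep="\t", index=False)
        tic("annotate")

        # ---- pathways ------------------------------------------------------
        significant = set(results.index[results["fdr_limma"] < cfg.fdr_max])
        if pathways and len(hits):
            wm = build_weight_map(hits)
            path_res = pathway_permutation_test(wm, significant, pathways,
                                                B=cfg.permutation_b,
                                                seed=cfg.seed)
            bundle["pathways_result"] = path_res
            path_res.to_csv(_path(cfg, "pathway_results.tsv"), sep="\t")
        else:
            log.warning("pathway stage skipped: no pathway sets or no annotation hits")
            bundle["pathways_result"] = None
        tic("pathways")

        # ---- correlation network ------------------------------------------
        edges = correlation_network(values, sorted(significant),
                                    min_abs_r=cfg.network_min_abs_r)
        bundle["network"] = edges
        edges.to_csv(_path(cfg, "network_edges.tsv"), sep="\t", index=False)
        network_to_graphml(edges, _path(cfg, "network.graphml"))
        tic("network")

        # ---- external validation ------------------------------------------
        bundle["validation"] = None
        if external is not None and library is not None and len(hits):
            internal = internal_summary(results, hits, library,
                                        n_subjects=len(subjects))
            if len(internal):
                val = validate_external(internal, external)
                bundle["validation"] = val
                val.to_csv(_path(cfg, "external_validation.tsv"), sep="\t",
                           index=False)
        tic("validate_external")

        report = export_report(cfg)
        bundle["report"] = report
        with open(_path(cfg, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2)
        tic("report")
    except Exception as exc:  # partial outputs stay on disk for inspection
        stage = max(manifest["timings"], default="simulate")
        raise RuntimeError(f"pipeline failed after stage '{stage}': {exc}") from exc
    finally:
        with open(_path(cfg, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
    return bundle


def internal_summary(results: pd.DataFrame, hits: pd.DataFrame,
                     library: pd.DataFrame, n_subjects: int) -> pd.DataFrame:
    """Per-metabolite internal study summary: each metabolite takes its
    best-matching feature (smallest |ppm error|, tier 1 preferred)."""
    rows = []
    usable = hits[hits["feature_id"].isin(results.index)]
    for met, group in usable.groupby("metabolite_id"):
        group = group.sort_values(["tier", "ppm_error"],
                                  key=lambda s: np.abs(s) if s.name == "ppm_error" else s,
                                  kind="stable")
        fid = group["feature_id"].iloc[0]
        row = results.loc[fid]
        name = library.loc[met, "name"] if met in library.index else str(met)
        rows.append(dict(metabolite=name,
                         fold_change=float(2.0 ** row["log2fc"]),
                         p_value=float(row["p_limma"]),
                         n=n_subjects))
    return pd.DataFrame(rows)


def export_report(cfg: PipelineConfig) -> dict:
    """Summary counts recomputed from the written result TSVs (never cached)."""
    report: dict = {"seed": cfg.seed}
    mwas_path = _path(cfg, "mwas_results.tsv")
    if os.path.exists(mwas_path):
        res = pd.read_csv(mwas_path, sep="\t", index_col="feature_id")
        hits = res[res["fdr_limma"] < cfg.fdr_max]
        report["n_features_tested"] = int(len(res))
        report["n_fdr_hits"] = int(len(hits))
        report["n_fc_beyond_0.5"] = int((hits["log2fc"].abs() > 0.5).sum())
        report["n_fc_beyond_0.25"] = int((hits["log2fc"].abs() > 0.25).sum())
        if "replication_tier" in res.columns:
            tiers = res["replication_tier"].value_counts().to_dict()
            report["n_replicated"] = int(sum(v for k, v in tiers.items()
                                             if k.startswith("replicated")))
            report["replication_tiers"] = {k: int(v) for k, v in tiers.items()}
        if "ledd_fdr" in res.columns:
            report["n_ledd_fdr_hits"] = int((res["ledd_fdr"] < cfg.fdr_max).sum())
    path_path = _path(cfg, "pathway_results.tsv")
    if os.path.exists(path_path):
        pr = pd.read_csv(path_path, sep="\t")
        report["n_pathways_tested"] = int(len(pr))
        report["n_pathways_p05"] = int((pr["p"] < 0.05).sum())
        report["n_pathways_fdr05"] = int((pr["fdr"] < 0.05).sum())
    net_path = _path(cfg, "network_edges.tsv")
    if os.path.exists(net_path):
        report["n_network_edges"] = int(len(pd.read_csv(net_path, sep="\t")))
    val_path = _path(cfg, "external_validation.tsv")
    if os.path.exists(val_path):
        val = pd.read_csv(val_path, sep="\t")
        report["n_externally_tested"] = int(len(val))
        report["validation_labels"] = dict(zip(val["metabolite"],
                                               val["validation"]))
        report["n_all_three_criteria"] = int(
            (val["significance"] & val["direction"] & val["magnitude"]).sum())
    return report
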