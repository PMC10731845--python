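"""Plain-text readers and writers for the pipeline's tabular formats.

All tables are tab-separated; pathway sets use the GMT convention
(name <tab> description <tab> member ids...).
"""

from __future__ import annotations

import os

import pandas as pd

from metamwas.tables import FeatureTable


def write_feature_table(table: FeatureTable, intensity_path: str, injections_path: str) -> None:
    """Write intensities (feature metadata + one column per injection) and injection metadata."""
    out = table.features.copy()
    out = out.rename(columns={"rt": "rt_seconds"})
    out = pd.concat([out, table.intensity], axis=1)
    out.to_csv(intensity_path, sep="\t", index_label="feature_id")
    table.injections.to_csv(injections_path, sep="\t", index_label="injection_id")


def read_feature_table(intensity_path: str, injections_path: str) -> FeatureTable:
    raw = pd.read_csv(intensity_path, sep="\t", index_col="feature_id")
    injections = pd.read_csv(injections_path, sep="\t", index_col="injection_id")
    injections.index = injections.index.astype(str)
    features = raw[["column", "mz", "rt_seconds"]].rename(columns={"rt_seconds": "rt"})
    intensity = raw.drop(columns=["column", "mz", "rt_seconds"])
    intensity.columns = intensity.columns.astype(str)
    intensity = intensity[list(injections.index)]
    return FeatureTable(features=features, injections=injections, intensity=intensity)


def write_subjects(subjects: pd.DataFrame, path: str) -> None:
    subjects.to_csv(path, sep="\t", index_label="subject_id")


def read_subjects(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    df.index = df.index.astype(str)
    return df


def write_library(library: pd.DataFrame, path: str) -> None:
    library.to_csv(path, sep="\t", index_label="metabolite_id")


def read_library(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="metabolite_id")


def write_matrix(matrix: pd.DataFrame, path: str, index_label: str = "feature_id") -> None:
    matrix.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path: str, index_label: str = "feature_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = index_label
    df.columns = df.columns.astype(str)
    return df


def write_gmt(pathways: dict, path: str) -> None:
    """Write pathway sets: ``{name: iterable of metabolite ids}``."""
    with open(path, "w") as fh:
        for name, members in pathways.items():
            fh.write("\t".join([name, name] + sorted(map(str, members))) + "\n")


def read_gmt(path: str) -> dict:
    pathways: dict = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(parts[2:])
    return pathways


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
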