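"""Core tabular containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FEATURE_COLUMNS = ["column", "mz", "rt"]
INJECTION_COLUMNS = ["subject_id", "role", "replicate_index", "batch", "run", "order"]


@dataclass
class FeatureTable:
    """A features x injections intensity table with feature and injection metadata.

    Attributes
    ----------
    features : pd.DataFrame
        Indexed by ``feature_id``; columns ``column`` (chromatography column,
        ``c18neg`` or ``hilicpos``), ``mz`` (Da) and ``rt`` (seconds).
    injections : pd.DataFrame
        Indexed by ``injection_id``; columns ``subject_id``, ``role``
        (``study`` or ``qc``), ``replicate_index``, ``batch``, ``run``,
        ``order`` (global acquisition order).
    intensity : pd.DataFrame
        Nonnegative intensities, rows aligned with ``features``, columns with
        ``injections``.  Zero means not detected.
    """

    features: pd.DataFrame
    injections: pd.DataFrame
    intensity: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.features.index.is_unique:
            raise ValueError("feature ids must be unique")
        if not self.injections.index.is_unique:
            raise ValueError("injection ids must be unique")
        if list(self.intensity.index) != list(self.features.index):
            raise ValueError("intensity rows must match features index")
        if list(self.intensity.columns) != list(self.injections.index):
            raise ValueError("intensity columns must match injections index")
        vals = self.intensity.to_numpy()
        if vals.size:
            if np.isnan(vals).any():
                raise ValueError("intensity contains NaN")
            if (vals < 0).any():
                raise ValueError("intensity contains negative values")
        if (self.features["mz"] <= 0).any():
            raise ValueError("mz must be positive")
        if (self.features["rt"] < 0).any():
            raise ValueError("rt must be nonnegative")

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_injections(self) -> int:
        return len(self.injections)

    def study_injections(self) -> pd.DataFrame:
        return self.injections[self.injections["role"] == "study"]

    def qc_injections(self) -> pd.DataFrame:
        return self.injections[self.injections["role"] == "qc"]

    def subset_features(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            features=self.features.loc[ids].copy(),
            injections=self.injections.copy(),
            intensity=self.intensity.loc[ids].copy(),
        )

    def subset_column(self, column: str) -> "FeatureTable":
        ids = self.features.index[self.features["column"] == column]
        return self.subset_features(ids)

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(), self.injections.copy(), self.intensity.copy()
        )


@dataclass
class ProcessedMatrix:
    """Log2-scale, normalized, batch-corrected features x subjects matrix.

    ``values`` holds study subjects only; ``qc`` holds the collapsed pooled-QC
    columns processed identically, kept aside for CV reporting.  ``provenance``
    records each applied step with its parameters, in execution order.
    """

    values: pd.DataFrame
    qc: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.size and not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("processed values must be finite")

    def log_step(self, step: str, **params) -> None:
        self.provenance.append({"step": step, **params})

    @property
    def feature_ids(self) -> list:
        return list(self.values.index)

    @property
    def subject_ids(self) -> list:
        return list(self.values.columns)
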