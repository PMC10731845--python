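import numpy as np
import pandas as pd
import pytest

from metamwas.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def tiny_cfg():
    return CohortConfig.test_scale(seed=11)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def tiny_processed(tiny_cohort):
    from metamwas.processing import preprocess

    table, subjects, truth = tiny_cohort
    matrix, cv_report, filter_report = preprocess(table.subset_column("c18neg"), subjects)
    return matrix, cv_report, filter_report


def make_feature_table(intensity, mz=None, rt=None, column="c18neg",
                       subject_of=None, role_of=None, replicate_of=None,
                       batch_of=None, run_of=None):
    """Build a small FeatureTable from an intensity array and simple metadata."""
    from metamwas.tables import FeatureTable

    intensity = np.asarray(intensity, dtype=float)
    n_feat, n_inj = intensity.shape
    fids = [f"F{i:03d}" for i in range(n_feat)]
    iids = [f"I{j:03d}" for j in range(n_inj)]
    features = pd.DataFrame({
        "column": column,
        "mz": mz if mz is not None else np.linspace(100, 500, n_feat),
        "rt": rt if rt is not None else np.linspace(20, 200, n_feat),
    }, index=pd.Index(fids, name="feature_id"))
    injections = pd.DataFrame({
        "subject_id": subject_of if subject_of is not None else [f"S{j}" for j in range(n_inj)],
        "role": role_of if role_of is not None else ["study"] * n_inj,
        "replicate_index": replicate_of if replicate_of is not None else [0] * n_inj,
        "batch": batch_of if batch_of is not None else [0] * n_inj,
        "run": run_of if run_of is not None else [1] * n_inj,
        "order": list(range(n_inj)),
    }, index=pd.Index(iids, name="injection_id"))
    return FeatureTable(features=features, injections=injections,
                        intensity=pd.DataFrame(intensity, index=fids, columns=iids))
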