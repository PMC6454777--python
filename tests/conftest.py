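import numpy as np
import pandas as pd
import pytest

from methmirnet.containers import OmicsMatrix
from methmirnet.pipeline import PipelineConfig, run_pipeline
from methmirnet.synthetic import CohortConfig, generate_cohort, write_cohort


def make_matrix(values, layer="mRNA", conditions=None, datasets=None, patients=None,
                features=None, samples=None):
    """Build a small OmicsMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    n_feat, n_samp = values.shape
    features = features or [f"g{i}" for i in range(1, n_feat + 1)]
    samples = samples or [f"s{i}" for i in range(1, n_samp + 1)]
    conditions = conditions or ["tumor"] * (n_samp // 2) + ["normal"] * (n_samp - n_samp // 2)
    datasets = datasets or ["DS1"] * n_samp
    idx = pd.Index(samples)
    return OmicsMatrix(
        layer=layer,
        values=pd.DataFrame(values, index=pd.Index(features, name="feature_id"), columns=idx),
        condition=pd.Series(conditions, index=idx),
        dataset_id=pd.Series(datasets, index=idx),
        patient_id=pd.Series(patients, index=idx) if patients else None,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort with planted structure, shared across unit tests."""
    cfg = CohortConfig(
        n_tumor=80, n_normal=40, n_genes=500, n_mirnas=60,
        n_planted_ts=40, n_planted_og=40, targets_per_mirna=8,
        n_decoy_edges=120, n_background_meth=20, seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline execution at the reference study conditions."""
    base = tmp_path_factory.mktemp("default_run")
    cohort = generate_cohort(CohortConfig(seed=101))
    write_cohort(cohort, base / "cohort")
    config = PipelineConfig(
        input_dir=str(base / "cohort"), output_dir=str(base / "out"),
        n_perm=99, seed=7,
    )
    return run_pipeline(config)
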