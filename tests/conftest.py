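import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from zdosage.expr_io import ExpressionMatrix, SampleMeta
from zdosage import synthetic_data as sd

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


def make_matrix(values, unit="raw_counts", gene_ids=None, metas=None, lengths=None):
    """Build a small ExpressionMatrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i+1}" for i in range(values.shape[0])]
    if metas is None:
        metas = [SampleMeta(f"s{j+1}", "none", "x", 1) for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=gene_ids, columns=[m.sample_id for m in metas])
    lseries = (
        pd.Series(lengths, index=gene_ids) if lengths is not None else None
    )
    return ExpressionMatrix(df, unit, metas, lseries)


@pytest.fixture
def tiny_counts():
    """3 genes x 4 samples of one stage: 2 male + 2 female technical replicates."""
    metas = [
        SampleMeta("m1", "male", "96h", 1),
        SampleMeta("m2", "male", "96h", 2),
        SampleMeta("f1", "female", "96h", 1),
        SampleMeta("f2", "female", "96h", 2),
    ]
    return make_matrix(
        [[4, 4, 4, 4], [3, 10, 10, 10], [0, 0, 0, 0]],
        metas=metas,
        lengths=[1000, 2000, 500],
    )


@pytest.fixture(scope="session")
def head_dataset():
    """Small compensated-head simulation shared across tests (fast plumbing checks)."""
    params = sd.scenario_presets("compensated_head", n_z=80, n_autosomal=400, seed=3)
    return sd.generate_dataset(params)
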