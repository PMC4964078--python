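import numpy as np
import pandas as pd
import pytest

from nodesig.cohort_data import CohortTable, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_matrix(values, gene_ids=None, sample_ids=None, scale="log2"):
    values = np.asarray(values, float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids), scale=scale
    )


def make_cohort(times, events, ln=None, er=None, her2=None, ids=None):
    n = len(times)
    ids = ids or [f"s{j}" for j in range(n)]
    return CohortTable(
        pd.DataFrame(
            {
                "sample_id": ids,
                "er_status": er or ["positive"] * n,
                "her2_status": her2 or ["negative"] * n,
                "ln_status": ln or ["negative"] * n,
                "dmfs_time": list(times),
                "dmfs_event": list(events),
            }
        )
    )


@pytest.fixture
def toy_matrix():
    return make_matrix([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0], [2.0, 4.0, 9.0]])
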