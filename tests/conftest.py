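import numpy as np
import pandas as pd
import pytest

from pcpgx import ExpressionMatrix, SyntheticCohortSpec, simulate_expression_cohort

#: Reduced-scale study conditions used by fast unit tests (the acceptance
#: suite runs the full 173-sample / 3000-gene conditions).
SMALL = dict(n_genes=600, cluster_sizes=(16, 14, 12, 8), markers_per_cluster=10)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_expression_cohort(SyntheticCohortSpec(seed=1, **SMALL))


@pytest.fixture()
def random_matrix():
    rng = np.random.default_rng(42)
    df = pd.DataFrame(
        rng.uniform(0, 100, size=(50, 10)),
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{i}" for i in range(10)],
    )
    return ExpressionMatrix(df, state="raw")
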