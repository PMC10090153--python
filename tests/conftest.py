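import numpy as np
import pandas as pd
import pytest

import bulkpurity as bp


@pytest.fixture(scope="session")
def small_cohort():
    """A compact multi-type cohort for unit tests (4 types, 120 genes)."""
    return bp.make_cohort(
        n_groups=4, samples_per_group=100, n_genes=120, n_informative=12, seed=101
    )


@pytest.fixture(scope="session")
def small_ranks(small_cohort):
    universe = bp.filter_genes(small_cohort.expr, small_cohort.groups)
    return bp.rank_percentile(small_cohort.expr, universe)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def toy_expr(values, sample="s1", genes=None):
    """One-sample expression matrix from a plain list."""
    genes = genes or [f"g{i}" for i in range(len(values))]
    return pd.DataFrame([values], index=[sample], columns=genes)
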