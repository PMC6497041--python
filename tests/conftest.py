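import warnings

import numpy as np
import pandas as pd
import pytest

from cernakit.data_model import ExpressionMatrix, SampleTable
from cernakit.synthetic import SimulationConfig, simulate_cohort

# lifelines emits approximation warnings on tied day-resolution data
warnings.filterwarnings("ignore", module="lifelines")


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort, seed 1 (8 planted triplets)."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def survival_cohort():
    """Cohort with ~300 tumor samples for survival power checks, seed 2."""
    cfg = SimulationConfig(seed=2, n_normal=30, n_t1=96, n_t2=158, n_t3=27, n_t4=19)
    return simulate_cohort(cfg)


def make_expression(values, gene_ids=None, sample_ids=None, gene_class="mRNA", unit="counts"):
    arr = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=gene_ids, columns=sample_ids), gene_class, unit)


def make_two_group_samples(n_normal, n_tumor, stage="T1"):
    """Sample table whose ids line up with make_expression defaults (S0, S1, ...)."""
    ids = [f"S{i}" for i in range(n_normal + n_tumor)]
    return SampleTable(
        pd.DataFrame(
            {
                "condition": ["normal"] * n_normal + ["tumor"] * n_tumor,
                "stage": [np.nan] * n_normal + [stage] * n_tumor,
                "os_time": np.nan,
                "os_event": np.nan,
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )
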