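import numpy as np
import pandas as pd
import pytest

from emphymir import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort reused across module tests (read-only)."""
    cfg = CohortConfig(n_mirna=60, n_gene=400, hub_targets=30,
                       frac_lm_mirna=0.2, seed=11)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def metadata64():
    """Plain 8-patient x 8-slice metadata frame for direct LMM tests."""
    cfg = CohortConfig(n_mirna=1, n_gene=2, frac_lm_mirna=0.0,
                       frac_slice_mirna=0.0, targets_per_mirna=1,
                       hub_targets=1, seed=0)
    return generate_cohort(cfg).metadata


def random_grouped_instance(rng, n_groups=5, per_group=6, n_cov=2):
    """A small random mixed-model instance for oracle comparisons."""
    n = n_groups * per_group
    codes = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(n_cov)])
    beta = rng.normal(size=n_cov + 1)
    sb, se = rng.uniform(0.2, 1.5), rng.uniform(0.3, 1.2)
    y = X @ beta + rng.normal(0, sb, n_groups)[codes] + rng.normal(0, se, n)
    return y, X, codes
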