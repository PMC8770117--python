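import numpy as np
import pandas as pd
import pytest

from cfrnakit.simulate import (DEFAULT_GA_WINDOWS, LongitudinalSpec, SimConfig,
                               simulate_cohorts, simulate_longitudinal)


def small_config(**overrides) -> SimConfig:
    """Desk-scale-down config used by most tests: 3 cohorts x 60 samples,
    300 genes, defaults otherwise."""
    base = dict(
        n_cohorts=3,
        samples_per_cohort=[60, 60, 60],
        ga_window_per_cohort=DEFAULT_GA_WINDOWS[:3],
        n_genes=300,
        n_gene_sets=10,
        gene_set_size_range=(5, 15),
        seed=11,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_cohorts(small_config())


@pytest.fixture(scope="session")
def longitudinal_dataset():
    cfg = small_config(longitudinal_cohort=LongitudinalSpec(n_subjects=93))
    return simulate_longitudinal(cfg)
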