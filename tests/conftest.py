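import numpy as np
import pytest

from neurotype.synthetic import (
    SyntheticConfig,
    block_informative_sets,
    generate_cohort,
)


@pytest.fixture(scope="session")
def binary_cohort():
    """Small two-domain, two-class cohort without shift (separable)."""
    info = block_informative_sets(["excitatory", "inhibitory"], 20, 4)
    cfg = SyntheticConfig(
        n_per_class_per_domain={
            ("mouse", "excitatory"): 120,
            ("mouse", "inhibitory"): 120,
            ("human", "excitatory"): 60,
            ("human", "inhibitory"): 60,
        },
        d_features=20,
        informative_sets=info,
        class_effect_size=3.0,
        seed=42,
    )
    table, truth = generate_cohort(cfg)
    return cfg, table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
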