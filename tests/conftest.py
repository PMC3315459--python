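import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from recimprint.simulate import SyntheticConfig, generate

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_dataset():
    """A modest noisy dataset with imprinted genes, shared across tests."""
    cfg = SyntheticConfig(
        n_genes=120,
        frac_imprinted=0.15,
        depth_median=80.0,
        depth_log_sd=0.6,
        strain_effect_sd=0.3,
        bio_sd=0.1,
        rho=0.002,
        seed=421,
    )
    counts, snps, models, truth = generate(cfg)
    return {
        "config": cfg,
        "counts": counts,
        "snps": snps,
        "models": models,
        "truth": truth,
        "samples": cfg.samples_frame(),
    }


@pytest.fixture
def count_table():
    return pd.DataFrame(
        {
            "snp_id": ["snp1", "snp2", "snp1", "snp2"],
            "sample_id": ["A", "A", "B", "B"],
            "count_B": [30, 10, 5, 40],
            "count_C": [70, 20, 15, 10],
        }
    )


@pytest.fixture
def sample_table():
    return pd.DataFrame(
        {
            "sample_id": ["A", "B"],
            "cross": ["BxC", "CxB"],
            "sex": ["M", "M"],
            "tissue": ["brain", "brain"],
            "replicate": [1, 1],
        }
    )
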