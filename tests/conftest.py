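import numpy as np
import pandas as pd
import pytest

from cfomics import synth


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but fully populated cohort used across modules."""
    spec = synth.CohortSpec(n_lc=40, n_bln=30, seed=11)
    return synth.generate_cohort(spec)


@pytest.fixture(scope="session")
def methyl_data():
    """Tissue + plasma methylation with planted DMRs for 60 samples."""
    samples = pd.DataFrame({
        "sample_id": [f"LC{i:03d}" for i in range(30)]
        + [f"BLN{i:03d}" for i in range(30)],
        "label": ["LC"] * 30 + ["BLN"] * 30,
    })
    spec = synth.MethylSpec(n_regions=80, n_hyper=12, n_hypo=2,
                            n_pairs=15, seed=7)
    return synth.generate_methylation(spec, samples), samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
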