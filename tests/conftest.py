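import numpy as np
import pytest

from ithkit.simdata import SimConfig, make_annotation, normal_beta_profile


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale study conditions: 4,000 probes, shorter segments in
    proportion, default assay noise and purity."""
    return SimConfig(
        n_probes=4000,
        seg_len_min=150,
        seg_len_max=450,
        founder_scna_events=4,
        branch_scna_rate=2.0,
        founder_meth_events=5,
        branch_meth_rate=3.0,
        meth_event_len=30,
        seed=11,
    )


@pytest.fixture(scope="session")
def annotation(small_config):
    return make_annotation(small_config)


@pytest.fixture(scope="session")
def beta_normal(small_config, annotation):
    return normal_beta_profile(annotation, small_config.seed + 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
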