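import numpy as np
import pytest

from regiongsea import Injection, SimConfig, generate_dataset
from regiongsea.expression import collapse_probes_by_cv


@pytest.fixture(scope="session")
def injected_study():
    """A small 4-group x 3-region study with one set shifted in D:WM."""
    cfg = SimConfig(
        n_genes=600, n_sets=6, set_size=25, n_per_cell=6, seed=11,
        injections=(Injection(set_index=0, group="D", region="WM", delta=2.0),),
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def injected_matrix(injected_study):
    return collapse_probes_by_cv(injected_study.probes, injected_study.probe_map)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
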