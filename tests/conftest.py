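import numpy as np
import pandas as pd
import pytest

import salinet as sn


@pytest.fixture(scope="session")
def default_sim() -> sn.SimOutput:
    """Default two-group fixture (300 genes, 72/96 samples), seed 1."""
    return sn.simulate_two_group_expression(sn.SimConfig(seed=1))


@pytest.fixture(scope="session")
def annotated_sim() -> sn.SimOutput:
    """Default fixture with probe/outlier corruption and annotations."""
    cfg = sn.SimConfig(seed=1)
    sim = sn.simulate_two_group_expression(cfg)
    sim = sn.corrupt_with_probes_and_outliers(sim, cfg)
    sn.generate_fixture_annotations(sim, seed=1)
    return sim


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_expression(rng, n_genes=10, n_samples=8, group="sensitive"):
    data = pd.DataFrame(
        rng.uniform(1.0, 100.0, size=(n_genes, n_samples)),
        index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return sn.ExpressionMatrix(data, group)
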