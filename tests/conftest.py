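import numpy as np
import pytest

import cooccurnet as cn


@pytest.fixture(scope="session")
def default_design():
    return cn.CommunityDesign(seed=42)


@pytest.fixture(scope="session")
def planted(default_design):
    """One generated dataset plus its inferred network, shared across tests."""
    table, truth = cn.generate_counts(default_design)
    edges = cn.ensemble_network(table, cn.AssociationConfig(seed=42))
    return {"design": default_design, "table": table, "truth": truth, "edges": edges}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
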