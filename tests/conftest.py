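import numpy as np
import pytest

import connleak as cl


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def parc10():
    """10-network parcellation on 40 nodes (4 nodes per network)."""
    return cl.Parcellation(node_network=np.repeat(np.arange(10), 4))


@pytest.fixture
def tiny_dataset():
    """Small signal-free dataset with covariates, 2 sites and some families."""
    rng = np.random.default_rng(0)
    n, p = 40, 60
    fam = np.array([f"f{i // 2}" for i in range(20)] + [f"s{i}" for i in range(20)])
    return cl.ConnectomeDataset(
        subject_ids=np.array([f"sub{i}" for i in range(n)]),
        X=rng.standard_normal((n, p)),
        y=rng.standard_normal(n),
        covariates={
            "age": rng.uniform(8, 22, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "motion": rng.uniform(0.02, 0.3, n),
        },
        site=np.array(["A", "B"] * (n // 2)),
        family_id=fam,
    )


@pytest.fixture(scope="session")
def moderate_dataset():
    """Moderate-signal synthetic cohort reused across slow tests."""
    cfg = cl.SyntheticConfig(n_subjects=120, n_nodes=40, effect_size=0.3, seed=99)
    return cl.generate_dataset(cfg)
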