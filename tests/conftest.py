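import numpy as np
import pytest

from r2snet import (CohortSpec, ModelConfig, RadiomicTable,
                    generate_cohort, load_atlas, prepare_graphs)


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_table(rng, n_features=10, subject_id="s0", label=None):
    values = rng.normal(size=(96, n_features))
    names = [f"f{k:02d}" for k in range(n_features)]
    return RadiomicTable(subject_id, values, names, label)


@pytest.fixture()
def table(rng):
    return random_table(rng)


def tiny_model_config(**kw):
    """A 6-node toy configuration used by oracle and gradient tests."""
    defaults = dict(n_nodes=6, d_model=5, n_layers=2, n_heads=2, d_k=3,
                    d_v=4, d_ffn=7, head_dims=(8, 4, 3), topk_neighbors=3,
                    projection_dims=(6, 4), seed=7)
    defaults.update(kw)
    return ModelConfig(**defaults)


def random_graph_arrays(rng, n=6, d=5, batch=1):
    """Random valid (X, W) pair: W symmetric in [0,1], unit diagonal."""
    X = rng.normal(size=(batch, n, d))
    r = rng.uniform(-1, 1, size=(batch, n, n))
    W = (r + r.transpose(0, 2, 1)) / 2
    W = (W + 1) / 2
    for b in range(batch):
        np.fill_diagonal(W[b], 1.0)
    return X, W


@pytest.fixture(scope="session")
def small_cohort_graphs():
    """A small planted cohort run through the full graph pipeline once."""
    spec = CohortSpec(n_per_class=8, seed=42)
    cohort = generate_cohort(spec)
    graphs, selection = prepare_graphs(cohort.tables)
    return cohort, graphs, selection
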