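import numpy as np
import pytest

from siamcell import (
    NetworkSpec,
    TrainConfig,
    SimConfig,
    TypeSpec,
    build_network,
    make_pairs,
    max_scale,
    sample_reference,
    simulate_counts,
    train,
)


@pytest.fixture(scope="session")
def tiny_sim():
    """Compact 3-type dataset used across the unit tests."""
    cfg = SimConfig(
        n_genes=100,
        types=(
            TypeSpec("A", n_cells=40, n_markers=8),
            TypeSpec("B", n_cells=40, n_markers=8),
            TypeSpec("C", n_cells=40, n_markers=8),
        ),
        seed=7,
    )
    m, labels, truth = simulate_counts(cfg)
    return m, labels, truth


@pytest.fixture(scope="session")
def tiny_trained(tiny_sim):
    """A small network trained briefly on the tiny dataset.

    Deliberately modest (one 64-wide hidden layer, 8-d embedding, 15
    epochs): enough structure for the annotation/benchmark tests without
    noticeable runtime.
    """
    m, labels, _ = tiny_sim
    x = max_scale(m)
    panel = sample_reference(m, labels, seed=3)
    train_pairs = make_pairs(panel, "train", seed=3)
    val_pairs = make_pairs(panel, "val", seed=4)
    spec = NetworkSpec(
        input_dim=m.n_genes, hidden_widths=(64,), embedding_dim=8, dropout_rate=0.3
    )
    model = build_network(spec, seed=3)
    model.gene_space = tuple(m.gene_ids)
    model = train(
        model, x, train_pairs, val_pairs, TrainConfig(epochs=15, batch_size=64, seed=3)
    )
    return model, x, panel, labels
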