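import numpy as np
import pytest

import pairgrn as pg
from pairgrn.matrix import log_transform, normalize_per_million


@pytest.fixture(scope="session")
def small_sim():
    """A small but signal-bearing paired dataset, normalized and aligned."""
    cfg = pg.SimulationConfig(
        n_tfs=8, targets_per_tf=3, n_decoys=40,
        n_bulk_samples=60, n_cells=120, seed=11,
    )
    bulk, sc, pairs = pg.simulate_paired_dataset(cfg)
    bulk = log_transform(normalize_per_million(bulk))
    sc = log_transform(normalize_per_million(sc))
    bulk, sc, shared = pg.align_gene_universe(bulk, sc)
    return bulk, sc, pairs, shared


@pytest.fixture(scope="session")
def tiny_model_config():
    """A minimal architecture for fast training in unit tests."""
    return pg.ModelConfig(
        input_shape=(32, 16),
        conv_filters=(4, 4, 8, 8, 8, 8),
        dense_widths=(16, 8),
        max_epochs=4,
        early_stop_patience=2,
        seed=5,
    )


@pytest.fixture(scope="session")
def small_corpus(small_sim):
    bulk, sc, pairs, _ = small_sim
    hc = pg.HistogramConfig(bins=16)
    images, n_skipped = pg.build_image_corpus(pairs, bulk, sc, hc)
    assert n_skipped == 0
    return images, pairs.labels
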