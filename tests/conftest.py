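"""Shared fixtures.

`synthetic_study` is the expensive one: it simulates the planted-motif
dataset, trains the full model and its non-recurrent ablation once per
session, and is shared by the acceptance tests and the
interpretation-recovery tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from apanet.estimator import APAUsageRegressor
from apanet.synthetic import GeneratorConfig, simulate_allele_pair, simulate_dataset

STUDY_SEED = 11
STUDY_W = 201


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_dataset():
    """30 genes at W=101: cheap input for data/metric plumbing tests."""
    cfg = GeneratorConfig(n_genes=30, W=101, seed=7)
    return simulate_dataset(cfg)


def random_windows(rng, n, W):
    return ["".join(rng.choice(list("ACGT"), W)) for _ in range(n)]


@pytest.fixture(scope="session")
def synthetic_study():
    """Planted-motif recovery study: 400 training / 100 held-out genes.

    Trains the convolutional model with the BiLSTM interaction and the
    same architecture with the non-recurrent (dense-only) interaction,
    identically configured, on the same data.
    """
    cfg = GeneratorConfig(n_genes=500, W=STUDY_W, seed=STUDY_SEED)
    dataset, truth = simulate_dataset(cfg)
    genes = dataset.multi_pas()
    train, test = genes[:400], genes[400:500]

    models = {}
    for interaction in ("bilstm", "dense_only"):
        est = APAUsageRegressor(base_net="multi_conv", interaction=interaction,
                                max_epochs=30, patience=5, batch_genes=16,
                                random_state=0)
        est.fit(train)
        models[interaction] = est

    pair_cfg = GeneratorConfig(n_genes=80, W=STUDY_W, seed=99)
    ds_a, ds_b, pair_truth = simulate_allele_pair(pair_cfg, n_variants=60)

    return {
        "config": cfg,
        "train": train,
        "test": test,
        "truth": truth,
        "bilstm": models["bilstm"],
        "dense_only": models["dense_only"],
        "allele_pairs": list(zip(ds_a.genes, ds_b.genes)),
        "pair_truth": pair_truth,
    }
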