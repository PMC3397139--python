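"""Shared fixtures: synthetic study data and trained network families.

The heavier fixtures are session-scoped so the motif-recovery pipeline
(500 implanted sites, 30-network family) is trained once and shared between
the module tests and the end-to-end checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from ptmstar import dataset, encoding, indices, mlp, synthetic
from ptmstar.mlp import MLPModel


# --- study conditions: strength-0.9 motif, 500 implanted sites -------------

RECOVERY_SEEDS = {"proteome": 11, "indices": 12, "split": 13, "train": 13}
NULL_SEEDS = {"proteome": 21, "split": 22, "train": 23}
# epochs are a free hyperparameter (library default is 1000); the suite uses
# a short schedule that already separates the classes cleanly
FAST_TRAIN = dict(epochs=60, checkpoint_every=20)
NULL_TRAIN = dict(epochs=40, checkpoint_every=20)


@pytest.fixture(scope="session")
def index_collection():
    """A clustered synthetic index collection: 8 clusters x 5 members."""
    return synthetic.generate_index_collection(
        n_clusters=8, members_per_cluster=5, spread=0.5,
        seed=RECOVERY_SEEDS["indices"],
    )


@pytest.fixture(scope="session")
def hqi_sets(index_collection):
    """The three HQI tiers selected from the synthetic collection."""
    collection, clusters = index_collection
    return {
        tier: indices.select_hqi(collection, clusters, tier)
        for tier in (1, 3, 5)
    }


@pytest.fixture(scope="session")
def recovery_data():
    """Labelled windows and split for the strength-0.9 implanted proteome."""
    config = synthetic.SynthConfig(
        n_proteins=100, mean_length=300, n_sites=500,
        motif=synthetic.kinase_like_motif(0.9),
        seed=RECOVERY_SEEDS["proteome"],
    )
    proteins, annotations = synthetic.generate_proteome(config)
    positives, pool = dataset.build_labeled_windows(
        proteins, annotations, config.ptm_type
    )
    split = dataset.split_dataset(
        positives, pool, seed=RECOVERY_SEEDS["split"]
    )
    return {
        "config": config, "proteins": proteins, "annotations": annotations,
        "positives": positives, "pool": pool, "split": split,
    }


@pytest.fixture(scope="session")
def recovery_family(recovery_data, hqi_sets):
    """A 30-network HQI-8 family trained on the recovery proteome."""
    hqi8 = hqi_sets[1]
    split = recovery_data["split"]
    train_x, train_y = encoding.encode_dataset(split.train, hqi8)
    test_x, test_y = encoding.encode_dataset(split.test, hqi8)
    family = mlp.train_family(
        train_x, train_y, test_x, test_y,
        mlp.TrainConfig(seed=RECOVERY_SEEDS["train"], **FAST_TRAIN),
        feature_set_id=hqi8.name,
    )
    return {
        "family": family, "index_set": hqi8,
        "train": (train_x, train_y), "test": (test_x, test_y),
    }


@pytest.fixture(scope="session")
def null_family(hqi_sets):
    """A family trained on a strength-0 (pure background) proteome."""
    hqi8 = hqi_sets[1]
    config = synthetic.SynthConfig(
        n_proteins=100, mean_length=300, n_sites=500,
        motif=synthetic.kinase_like_motif(0.0),
        seed=NULL_SEEDS["proteome"],
    )
    proteins, annotations = synthetic.generate_proteome(config)
    positives, pool = dataset.build_labeled_windows(
        proteins, annotations, config.ptm_type
    )
    split = dataset.split_dataset(positives, pool, seed=NULL_SEEDS["split"])
    train_x, train_y = encoding.encode_dataset(split.train, hqi8)
    test_x, test_y = encoding.encode_dataset(split.test, hqi8)
    family = mlp.train_family(
        train_x, train_y, test_x, test_y,
        mlp.TrainConfig(seed=NULL_SEEDS["train"], **NULL_TRAIN),
        feature_set_id=hqi8.name,
    )
    return {"family": family, "test": (test_x, test_y)}


@pytest.fixture(scope="session")
def tiny_families():
    """Fast throwaway families for four feature sets (cardinality tests).

    Trained on small random data; only the family structure matters.
    """
    rng = np.random.default_rng(7)
    families, eval_data = {}, {}
    for i, fs in enumerate(["HQI-8", "HQI-24", "HQI-40", "LEGACY-10"]):
        x = rng.normal(size=(40, 6))
        y = np.array([0, 1] * 20)
        x[y == 1] += 1.0
        cfg = mlp.TrainConfig(epochs=4, checkpoint_every=2, seed=100 + i)
        families[fs] = mlp.train_family(x, y, x, y, cfg, feature_set_id=fs)
        eval_data[fs] = (x, y)
    return families, eval_data


def make_constant_model(
    vote: bool, input_dim: int = 9, feature_set_id: str | None = None,
    hidden_k: int = 1, objective_tag: str | None = None,
) -> MLPModel:
    """A degenerate network that always votes the same way
    (output sigmoid(+-2) ~ 0.88 / 0.12 regardless of input)."""
    return MLPModel(
        w1=np.zeros((hidden_k, input_dim)),
        b1=np.zeros(hidden_k),
        w2=np.zeros(hidden_k),
        b2=2.0 if vote else -2.0,
        feature_set_id=feature_set_id,
        objective_tag=objective_tag,
    )
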