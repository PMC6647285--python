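from __future__ import annotations

import numpy as np
import pytest

from cidrex.intra import BagData, init_intra_params
from cidrex.inter import PairData, init_inter_params
from cidrex.simulate import SynthConfig, generate_collection


@pytest.fixture(scope="session")
def small_collection():
    """A compact synthetic collection shared by alignment and generator tests."""
    return generate_collection(SynthConfig(n_docs=40, seed=11))


@pytest.fixture(scope="session")
def experiment():
    """Full pipeline run at the reference study conditions (200 docs, noise 0.3)."""
    from cidrex.pipeline import run_synthetic_experiment

    return run_synthetic_experiment(seed=0)


def tiny_intra_params(rng: np.random.Generator, n_words: int = 7, n_concepts: int = 4,
                      hidden_dim: int = 3, randomize_all: bool = False):
    params = init_intra_params(
        rng, n_words=n_words, n_concepts=n_concepts, word_dim=3, position_dim=2,
        identifier_dim=3, hyponym_dim=2, location_dim=2, hidden_dim=hidden_dim,
        attention_dim=3, hidden_nodes=4, max_dist=3,
    )
    if randomize_all:  # give every group (biases included) non-negligible gradients
        for k in params:
            params[k] = rng.normal(0.0, 0.4, size=params[k].shape)
    return params


def tiny_inter_params(rng: np.random.Generator, n_words: int = 6, n_concepts: int = 4,
                      randomize_all: bool = False):
    params = init_inter_params(
        rng, n_words=n_words, n_concepts=n_concepts, word_dim=3, identifier_dim=2,
        hyponym_dim=2, frequency_dim=2, encoder_nodes=4, decoder_nodes=3,
    )
    if randomize_all:
        for k in params:
            params[k] = rng.normal(0.0, 0.4, size=params[k].shape)
    return params


def random_bag(rng: np.random.Generator, label: int = 1, n_inst: int = 2,
               n_words: int = 7, n_concepts: int = 4, max_tokens: int = 4) -> BagData:
    insts = []
    for _ in range(n_inst):
        n = int(rng.integers(2, max_tokens + 1))
        insts.append(
            (
                rng.integers(0, n_words, n),
                rng.integers(0, 7, n),
                rng.integers(0, 7, n),
                int(rng.integers(0, 4)),
            )
        )
    return BagData(
        insts,
        int(rng.integers(0, n_concepts)),
        int(rng.integers(0, 2)),
        int(rng.integers(0, n_concepts)),
        int(rng.integers(0, 2)),
        label,
    )


def random_pair(rng: np.random.Generator, label: int = 1, n_words: int = 6,
                n_concepts: int = 4) -> PairData:
    return PairData(
        rng.integers(0, n_words, int(rng.integers(1, 4))),
        rng.integers(0, n_words, int(rng.integers(1, 4))),
        int(rng.integers(0, n_concepts)),
        int(rng.integers(0, n_concepts)),
        int(rng.integers(0, 2)),
        int(rng.integers(0, 2)),
        int(rng.integers(0, 8)),
        int(rng.integers(0, 8)),
        label,
    )
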