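"""Shared fixtures.

Two tiers: quick throwaway models for unit tests, and one session-scoped
trained fixture (default study conditions) shared by the end-to-end and
acceptance tests so the multi-minute training cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from factedit import editor, metrics, pipeline, synthetic_world as sw
from factedit.io import RunConfig
from factedit.tiny_lm import ModelConfig, ModelHandle, Tokenizer, train

SEED = 1


@pytest.fixture(scope="session")
def mini_world():
    return sw.generate_world(sw.WorldSpec(n_subjects=6, n_relations=2, n_objects=3,
                                          seed=11))


@pytest.fixture(scope="session")
def mini_model(mini_world):
    """A small model trained on a small world — enough to memorize facts."""
    corpus = sw.render_corpus(mini_world, repetitions=12, seed=3)
    tok = Tokenizer(sw.vocabulary(mini_world))
    cfg = ModelConfig(n_layers=2, d_model=32, n_heads=4, d_ff=64,
                      vocab_size=len(tok), max_seq_len=32, seed=5)
    model = ModelHandle.init_model(cfg, tok)
    train(model, corpus, epochs=60, batch_size=32, lr=3e-3, seed=5,
          holdout_fraction=0.0)
    return model


@pytest.fixture(scope="session")
def mini_corpus(mini_world):
    return sw.render_corpus(mini_world, repetitions=12, seed=3)


@pytest.fixture(scope="session")
def mini_entries(mini_world):
    return sw.make_attack_dataset(mini_world, 4, seed=2)


@pytest.fixture
def untrained_model():
    tok = Tokenizer([f"w{i}" for i in range(8)])
    cfg = ModelConfig(n_layers=2, d_model=8, n_heads=2, d_ff=16,
                      vocab_size=len(tok), max_seq_len=12, seed=3)
    return ModelHandle.init_model(cfg, tok)


# ---------------------------------------------------------------------------
# Session-scoped trained fixture under the default study conditions
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=SEED, n_entries=10)


@pytest.fixture(scope="session")
def fixture(run_config):
    fx = pipeline.build_fixture(run_config)
    assert fx.memorization >= 0.95, "fixture failed to memorize its facts"
    return fx


@pytest.fixture(scope="session")
def attack_entries(fixture, run_config):
    return sw.make_attack_dataset(fixture.world, run_config.n_entries,
                                  seed=pipeline.child_seed(SEED, 5))


@pytest.fixture(scope="session")
def key_stats(fixture):
    return editor.estimate_key_stats(
        fixture.model, "\n".join(fixture.corpus_lines), fixture.edit_layer)


@pytest.fixture(scope="session")
def attack_runs(fixture, attack_entries, run_config, key_stats):
    """10 R1 attacks plus FT / FT-attn baselines on the same entries."""
    return pipeline.run_attacks(fixture, attack_entries, run_config,
                                stats=key_stats)
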