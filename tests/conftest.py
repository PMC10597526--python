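"""Shared fixtures: small synthetic worlds and session-scoped trained toy models.

Model training is expensive relative to everything else in the suite, so the
toy models used by several tests (and by the qualitative acceptance checks)
are trained once per session and shared. The worlds are deliberately
scaled down (short transcripts, small hidden dimension) to fit a single-CPU
time budget; the generator's scientific defaults live in
:class:`rnacoding.simulate.GeneratorParams` and are exercised separately.
"""

from __future__ import annotations

import numpy as np
import pytest

from rnacoding.inference import classify_batch, confusion_metrics
from rnacoding.model import ModelConfig
from rnacoding.simulate import GeneratorParams, generate_dataset
from rnacoding.training import BatchPlan, ObjectiveConfig, TrainConfig, train

TOY_MODEL_CONFIG = ModelConfig(
    window_length=18, hidden_dim=32, n_heads=4, n_encoder_layers=1, n_decoder_layers=1
)
TOY_PLAN = BatchPlan(max_tokens_per_batch=12000, gradient_accumulation_steps=1)
SEEDS = (0, 1, 2)


def _split_sets(transcripts, split):
    by_id = {t.id: t for t in transcripts}
    return (
        [by_id[i] for i in split.train],
        [by_id[i] for i in split.validation],
        [by_id[i] for i in split.test],
    )


@pytest.fixture(scope="session")
def hard_world():
    """Hard-mode toy transcriptome: lncRNAs carry long unbiased ORFs."""
    params = GeneratorParams(n_per_class=500, length_range=(80, 240), seed=1, hard=True)
    transcripts, split = generate_dataset(params)
    return {"params": params, "transcripts": transcripts, "split": split,
            "sets": _split_sets(transcripts, split)}


def _train_one(world, task: str, seed: int, epochs: int):
    train_set, val_set, _ = world["sets"]
    objective = ObjectiveConfig(task=task, lam=0.1, max_protein_len=20)
    return train(
        train_set,
        objective,
        TOY_MODEL_CONFIG,
        TOY_PLAN,
        TrainConfig(epochs=epochs, learning_rate=3e-3, seed=seed, eval_every=2),
        validation=val_set,
    )


@pytest.fixture(scope="session")
def hard_models(hard_world):
    """Per-seed class- and seq_wt-task models on the hard-mode world."""
    out = {}
    for seed in SEEDS:
        out[seed] = {
            "class": _train_one(hard_world, "class", seed, epochs=20),
            "seq_wt": _train_one(hard_world, "seq_wt", seed, epochs=35),
        }
    return out


def f1_on_test_set(result, world) -> float:
    _, _, test_set = world["sets"]
    preds = classify_batch(result.params, result.config, test_set)
    return confusion_metrics([p.label for p in preds], [t.label for t in test_set])["F1"]
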