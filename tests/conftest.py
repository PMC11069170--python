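"""Shared fixtures: small synthetic corpora and trained demo models.

Training fixtures are session-scoped because two-stage optimization on a
pure-numpy network is the expensive part of the suite; every test that
needs a fitted model shares these.
"""

from __future__ import annotations

import numpy as np
import pytest

from freeprotmap.network import build_variant
from freeprotmap.synthetic import SyntheticSpec, make_dataset, sampled_inputs
from freeprotmap.training import (
    TrainConfig,
    constant_baseline_mae,
    heldout_masked_mae,
    train_stage1,
    train_stage2,
)


@pytest.fixture(scope="session")
def demo_dataset():
    """24 + 8 synthetic proteins, lengths 16..32, default generator noise."""
    spec = SyntheticSpec(length_range=(16, 32))
    return make_dataset(spec, n_train=24, n_val=8, seed=3)


@pytest.fixture(scope="session")
def trained_demo(demo_dataset):
    """Full-architecture model trained with the complete two-stage schedule
    (Adam, weight decay 0.01, lr 1e-3, batch 1, 30 + 5 epochs)."""
    data = demo_dataset
    model = build_variant("freeprotmap", seed=0)
    cfg = TrainConfig(epochs_stage1=30, epochs_stage2=5, seed=0)
    history1 = train_stage1(model, data.train, cfg, val_items=data.val)
    stage1_state = model.state_dict()
    history2 = train_stage2(model, data.train, cfg, val_items=data.val)
    return {
        "model": model,
        "data": data,
        "config": cfg,
        "history1": history1,
        "history2": history2,
        "stage1_state": stage1_state,
        "baseline_mae": constant_baseline_mae(data.train, data.val),
        "heldout_mae": heldout_masked_mae(model, data.val),
    }


@pytest.fixture(scope="session")
def ablation_runs():
    """Group pooling ('p') vs random sampling ('baseline') held-out MAEs,
    identical data and seeds, three independent seeds."""
    results = {"p": [], "baseline": []}
    for seed in (0, 1, 2):
        spec = SyntheticSpec(length_range=(16, 32))
        data = make_dataset(spec, n_train=20, n_val=8, seed=seed,
                            keep_stacks=True)
        s_train, s_val = sampled_inputs(data, seed=seed)
        for name, (train, val) in (("p", (data.train, data.val)),
                                   ("baseline", (s_train, s_val))):
            model = build_variant(name, seed=seed)
            train_stage1(model, train, TrainConfig(seed=seed))
            results[name].append(heldout_masked_mae(model, val))
    return {k: np.asarray(v) for k, v in results.items()}
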