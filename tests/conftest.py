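"""Shared fixtures: a synthetic two-state expression study and a trained
small-profile diffusion model reused across the model-dependent tests."""

from __future__ import annotations

import numpy as np
import pytest

from gembridge.model import ExpressionDiffusion
from gembridge.preprocess import ScalerParams, apply_scaler, fit_scaler, log2p1
from gembridge.profiles import SMALL_PROFILE
from gembridge.synthetic import SyntheticSpec, generate_two_state_gem


@pytest.fixture(scope="session")
def toy_study():
    """A planted-signal study: 400 training + 200 held-out samples, 16 genes.

    Generated as one 600-sample draw so the per-gene baselines are shared,
    then split 200/100 per class into train/test.  Scaler fitted on train.
    """
    gem, signal = generate_two_state_gem(
        SyntheticSpec(
            n_per_class=300, n_genes=16, n_signal=4, effect_size=3.0, seed=7
        )
    )
    n = 300
    train_idx = list(range(0, 200)) + list(range(n, n + 200))
    test_idx = list(range(200, n)) + list(range(n + 200, 2 * n))
    train = gem.subset_samples(train_idx)
    test = gem.subset_samples(test_idx)
    scaler = fit_scaler(log2p1(train))
    return {
        "gem": gem,
        "train": train,
        "test": test,
        "scaler": scaler,
        "X_train": apply_scaler(log2p1(train), scaler).values,
        "y_train": np.asarray(train.labels),
        "X_test": apply_scaler(log2p1(test), scaler).values,
        "y_test": np.asarray(test.labels),
        "signal_genes": signal,
        "gene_ids": list(gem.gene_ids),
    }


@pytest.fixture(scope="session")
def toy_model(toy_study) -> ExpressionDiffusion:
    """Small-profile conditional diffusion model trained on the 400-row split."""
    model = ExpressionDiffusion(**SMALL_PROFILE, random_state=0)
    model.fit(toy_study["X_train"], toy_study["y_train"])
    return model
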