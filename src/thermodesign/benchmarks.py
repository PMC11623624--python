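"""Desk-scale study conditions reused by the test suite and the acceptance
script.

The memorization benchmark is the standard overfit sanity check for an
autoregressive inverse-folding model: five geometrically distinct synthetic
chains (the secondary-structure types at five different lengths, so that no
two backbones are congruent) are treated as five single-member clusters and
trained to convergence. A model that cannot drive training perplexity to
~1 on five structures has a defect in featurization, message passing or the
decoding mask. Training uses full neighbourhoods (k >= n-1 at these sizes),
no backbone noise and no dropout — memorization probes the machinery, not
regularisation.
"""

from __future__ import annotations

import numpy as np

from thermodesign.fixtures import FixtureSpec, build_chain
from thermodesign.mpnn_core import TrainConfig
from thermodesign.structio import BackboneStructure

MEMORIZATION_SPECS = [
    ("helix", 10), ("strand", 11), ("coil", 12), ("helix", 13), ("strand", 14),
]


def memorization_structures() -> list[BackboneStructure]:
    return [build_chain(FixtureSpec(n_res=n, secondary=sec, seed=i),
                        id=f"memo-{sec}-{n}")
            for i, (sec, n) in enumerate(MEMORIZATION_SPECS)]


def memorization_config(seed: int, epochs: int = 200) -> TrainConfig:
    return TrainConfig(
        backbone_noise_sd=0.0, dropout=0.0, epochs=epochs,
        batch_tokens=15, examples_per_epoch=5, k_neighbors=13,
        hidden_dim=64, seed=seed, lr_schedule="cosine", learning_rate=3e-3)


def run_memorization(seed: int, epochs: int = 200):
    """Train the benchmark and return (weights, log, structures)."""
    from thermodesign.mpnn_core import train

    structures = memorization_structures()
    clusters = {s.id: [s] for s in structures}
    weights, log = train(clusters, memorization_config(seed, epochs))
    return weights, log, structures


def best_epoch_metrics(log: list[dict]) -> dict:
    """Best simultaneous (perplexity, accuracy) training epoch, judged by
    loss."""
    train_log = [e for e in log if e["split"] == "train"]
    return min(train_log, key=lambda e: e["loss"])


def moving_average(values, window: int = 20) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if len(values) < window:
        raise ValueError("fewer values than the window")
    return np.convolve(values, np.ones(window) / window, mode="valid")
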