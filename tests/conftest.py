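"""Shared fixtures.

The expensive fixture is ``trained_pipeline``: a reduced-width network
trained once per session on the synthetic shape dataset and reused by the
end-to-end classification, localisation, retrieval and saliency-sign
tests.  Everything else is cheap and deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import sononet as sn
from sononet.training import LabelledDataset, train


def make_tiny_net(seed: int, num_classes: int = 3, base_width: int = 2,
                  batch_norm: bool | None = None) -> sn.Network:
    """A small random network for saliency/backward tests."""
    cfg = sn.NetworkConfig("sononet", base_width, num_classes,
                           batch_norm=batch_norm)
    return sn.build_network(cfg, np.random.default_rng(seed))


@pytest.fixture
def tiny_net():
    return make_tiny_net(0)


@pytest.fixture(scope="session")
def desk_spec() -> sn.SyntheticSpec:
    """Desk-scale synthetic conditions: 64x64 frames, three shape classes."""
    return sn.SyntheticSpec(num_foreground_classes=3, height=64, width=64)


@pytest.fixture(scope="session")
def trained_pipeline(desk_spec):
    """Train a base-width-8 network on the synthetic dataset (fixed seed).

    Returns (net, taxonomy, held-out test samples).  Training conditions:
    120 frames per foreground class plus 240 background frames, balanced
    batches, the standard warm-up/decay schedule, scale/flip/rotation
    augmentation, 1000 iterations.
    """
    tax = sn.synthetic_taxonomy(desk_spec)
    samples = sn.generate_dataset(desk_spec, n_per_class=120,
                                  n_background=240,
                                  rng=np.random.default_rng(42))
    data = LabelledDataset([(s.frame, s.label) for s in samples], tax)
    net = sn.build_network(
        sn.NetworkConfig("sononet", 8, tax.num_classes),
        np.random.default_rng(7))
    net, _ = train(net, data, rng=np.random.default_rng(1),
                   n_iterations=1000, val_every=50)
    test = sn.generate_dataset(desk_spec, n_per_class=50, n_background=100,
                               rng=np.random.default_rng(4242))
    return net, tax, test
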