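"""Shared fixtures: toy structures built once per session."""

import numpy as np
import pytest

from tracefold.synthetic import (
    TopologySpec,
    build_helix,
    build_stemloop,
    build_topology,
    synth_predictions,
)


@pytest.fixture(scope="session")
def helix6():
    chain, pairs = build_helix(6)
    return chain, pairs


@pytest.fixture(scope="session")
def stemloop():
    return build_stemloop(6, 4)


@pytest.fixture(scope="session")
def y_linked():
    """Y topology with a planted distal loop-loop cross-link."""
    spec = TopologySpec("Y", (4, 6, 6), (4, 4), cross_links=((0, 1),))
    return build_topology(spec)


@pytest.fixture(scope="session")
def y_predictions(y_linked):
    """Ten ranked predictions: the cross-link first, then nine base pairs."""
    preds, labels = synth_predictions(
        y_linked, n_true_nonlocal=1, n_false=0, n_local=9, seed=11
    )
    return preds, labels


@pytest.fixture(scope="session")
def cruciform():
    return build_topology(TopologySpec("cruciform", (5, 5, 5, 5), (4, 4, 4, 4)))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
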