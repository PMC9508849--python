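"""Shared fixtures: synthetic cells are generated once per session and
reused — generation is deterministic, so sharing does not couple tests."""

from __future__ import annotations

import numpy as np
import pytest

from exepi.fixtures import dense_cell, sparse_cell, spots_from_truth
from exepi.segmentation import segment_nuclei
from exepi.simulate import DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def geometry():
    return DEFAULT_GEOMETRY


@pytest.fixture(scope="session")
def dense_null():
    """Dense default cell, no planted co-localization, with its nucleus."""
    stack, truth = dense_cell(seed=11)
    region = segment_nuclei(stack.channel("dapi"), stack.geometry)[0]
    return stack, truth, region


@pytest.fixture(scope="session")
def sparse_planted():
    """Sparse-loci cell with half the emitters on enriched loci."""
    stack, truth = sparse_cell(seed=11, coloc_fraction=0.5, enrichment=10.0)
    region = segment_nuclei(stack.channel("dapi"), stack.geometry)[0]
    return stack, truth, region


@pytest.fixture()
def truth_spots():
    return spots_from_truth
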