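"""Shared phantom fixtures.

The heavy end-to-end traces (straight tube, Y-bifurcation) are
session-scoped so the tracer tests and the acceptance tests reuse one run.
"""

from __future__ import annotations

import numpy as np
import pytest

from seqseg import (
    OracleSegmenter,
    PhantomConfig,
    TracerConfig,
    generate_tree,
    run_trace,
    voxelize,
)


@pytest.fixture(scope="session")
def tube_phantom():
    """Noise-free straight tube (128 mm, radius 4 mm) spanning the volume."""
    tree = generate_tree(
        "tube", start=(0, 64, 64), direction=(1, 0, 0), length=127, radius=4, rng=0
    )
    image, label, centerline = voxelize(
        tree, PhantomConfig(grid_shape=(128, 128, 128), noise_sd=0), allow_exit=True
    )
    return image, label, centerline


@pytest.fixture(scope="session")
def tube_trace(tube_phantom):
    """Oracle-backend trace of the straight tube, seeded near one end."""
    image, label, _ = tube_phantom
    result = run_trace(
        image, ((10, 64, 64), (1, 0, 0), 4.0), OracleSegmenter(label), TracerConfig()
    )
    return result


@pytest.fixture(scope="session")
def y_phantom():
    """Noise-free Y bifurcation: parent radius 4 mm, children 2.8 mm."""
    tree = generate_tree(
        "y_bifurcation",
        start=(12, 64, 64),
        direction=(1, 0, 0),
        length=50,
        radius=4,
        child_ratio=0.7,
        length_ratio=0.8,
        branch_angle_deg=(35, 40),
        rng=1,
    )
    image, label, centerline = voxelize(
        tree, PhantomConfig(grid_shape=(128, 128, 128), noise_sd=0)
    )
    return image, label, centerline


@pytest.fixture(scope="session")
def y_trace(y_phantom):
    image, label, _ = y_phantom
    result = run_trace(
        image, ((12, 64, 64), (1, 0, 0), 4.0), OracleSegmenter(label), TracerConfig()
    )
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
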