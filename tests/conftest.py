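"""Shared fixtures: synthetic channels, datasets and trained models.

Expensive objects (solved fields, long recordings, trained models) are
session-scoped so the unit suite and the acceptance checks share them.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import flowbasis as fb

# scaled-down study conditions used throughout the suite: obstacle-free slit
# recordings of 50 cells x 400 snapshots; slit-channel training recording of
# 100 cells x 1500 snapshots with held-out / geometry-variant recordings of
# 50 cells x 300 snapshots.
PLANE_TRAIN_SEED, PLANE_TEST_SEED = 11, 99
SLIT_TRAIN_SEED, SLIT_HELDOUT_SEED, SLIT_VARIANT_SEED = 21, 77, 78
TRAIN_SEEDS = (1, 2, 3)


def naive_predict(positions, velocities, k, x):
    """Independent direct-summation prediction (Gaussian similarity weights).

    Deliberately naive scalar Python, kept separate from the library path.
    """
    sims = []
    for a in positions:
        d2 = sum((float(xc) - float(ac)) ** 2 for xc, ac in zip(x, a))
        sims.append(math.exp(-k * d2))
    total = sum(sims)
    out = [0.0, 0.0, 0.0]
    for s, b in zip(sims, velocities):
        for c in range(3):
            out[c] += (s / total) * float(b[c])
    return np.asarray(out)


@pytest.fixture(scope="session")
def plane_field():
    return fb.plane_poiseuille_field(fb.plane_slit_spec())


@pytest.fixture(scope="session")
def plane_train_ds(plane_field):
    spec = fb.plane_slit_spec(n_cells=50, n_snapshots=400, seed=PLANE_TRAIN_SEED)
    return fb.generate_trajectories(plane_field, spec)


@pytest.fixture(scope="session")
def plane_test_ds(plane_field):
    spec = fb.plane_slit_spec(n_cells=50, n_snapshots=400, seed=PLANE_TEST_SEED)
    return fb.generate_trajectories(plane_field, spec)


@pytest.fixture(scope="session")
def plane_models(plane_train_ds):
    """Basis systems trained on the obstacle-free slit recording, three seeds."""
    pairs = fb.assemble_training_vectors(plane_train_ds)
    return {
        seed: fb.train(pairs, 256, 1.0, 0.1, 200_000, seed=seed, source="planeA")
        for seed in TRAIN_SEEDS
    }


@pytest.fixture(scope="session")
def slit_field():
    return fb.slit_obstacle_field(fb.channel_a_spec())


@pytest.fixture(scope="session")
def slit_train_ds(slit_field):
    spec = fb.channel_a_spec(n_cells=100, n_snapshots=1500, seed=SLIT_TRAIN_SEED)
    return fb.generate_trajectories(slit_field, spec)


@pytest.fixture(scope="session")
def slit_heldout_ds(slit_field):
    spec = fb.channel_a_spec(n_cells=50, n_snapshots=300, seed=SLIT_HELDOUT_SEED)
    return fb.generate_trajectories(slit_field, spec)


@pytest.fixture(scope="session")
def variant_field():
    return fb.slit_obstacle_field(
        fb.remove_middle_obstacle(fb.channel_a_spec())
    )


@pytest.fixture(scope="session")
def variant_ds(variant_field):
    spec = fb.remove_middle_obstacle(
        fb.channel_a_spec(n_cells=50, n_snapshots=300, seed=SLIT_VARIANT_SEED)
    )
    return fb.generate_trajectories(variant_field, spec)


@pytest.fixture(scope="session")
def slit_models(slit_train_ds):
    """Basis systems trained on the slit-channel recording, three seeds."""
    pairs = fb.assemble_training_vectors(slit_train_ds)
    return {
        seed: fb.train(pairs, 1024, 10.0, 0.1, 200_000, seed=seed, source="slitA")
        for seed in TRAIN_SEEDS
    }


@pytest.fixture
def small_dataset():
    """Tiny hand-made dataset: 2 cells x 3 snapshots."""
    return fb.TrajectoryDataset(
        cell_ids=np.array(["a", "a", "a", "b", "b", "b"], dtype=object),
        steps=np.array([0, 1, 2, 0, 1, 2]),
        positions=np.array([
            [0.0, 0.0, 1.0], [0.5, 0.0, 1.0], [1.0, 0.0, 1.0],
            [0.0, 1.0, 2.0], [0.25, 1.0, 2.0], [0.5, 1.0, 2.0],
        ]),
        velocities=np.array([
            [0.5, 0.0, 0.0], [0.5, 0.0, 0.0], [0.5, 0.0, 0.0],
            [0.25, 0.0, 0.0], [0.25, 0.0, 0.0], [0.25, 0.0, 0.0],
        ]),
        channel_id="toy",
    )
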