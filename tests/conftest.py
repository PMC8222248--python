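"""Shared fixtures: small deterministic synthetic structures and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from distfold.fixtures import FixtureSpec, make_structure
from distfold.metrics import kabsch_rmsd, tm_score
from distfold.structio import Structure


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix (test helper, independent of the package)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0.0, -axis[2], axis[1]],
        [axis[2], 0.0, -axis[0]],
        [-axis[1], axis[0], 0.0],
    ])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def best_enantiomer_tm(model_pair, native: Structure) -> float:
    """TM-score of the better of a fold's two mirror images."""
    return max(tm_score(model_pair.model, native).tm_score,
               tm_score(model_pair.mirror_model, native).tm_score)


def best_enantiomer_rmsd(model_pair, native: Structure) -> float:
    return min(kabsch_rmsd(model_pair.model, native)[0],
               kabsch_rmsd(model_pair.mirror_model, native)[0])


@pytest.fixture(scope="session")
def bundle40() -> Structure:
    return make_structure(FixtureSpec(L=40, topology="helix_bundle", seed=1))


@pytest.fixture(scope="session")
def coil20() -> Structure:
    return make_structure(FixtureSpec(L=20, topology="random_coil", seed=2))


@pytest.fixture(scope="session")
def helix30() -> Structure:
    return make_structure(FixtureSpec(L=30, topology="ideal_helix", seed=0))
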