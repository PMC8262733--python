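"""Shared synthetic fixtures.

Expensive objects (planted library, full prediction run) are session-scoped
and reused across test modules.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from heterodock import synth
from heterodock.assemble import ComplexModel
from heterodock.pipeline import predict_complex


def random_rigid(seed: int):
    """A reproducible proper rotation + translation."""
    R = Rotation.random(random_state=seed).as_matrix()
    t = np.random.default_rng(seed).uniform(-20, 20, size=3)
    return R, t


@pytest.fixture(scope="session")
def helix40():
    return synth.make_helix(40, chain_id="A")


@pytest.fixture(scope="session")
def target_dimer():
    """The canonical study-condition target: two 40-residue bundles docked
    side-by-side at a 4.2 Å gap, validated against the physical filters."""
    return synth.make_target_dimer(40, seed=10)


@pytest.fixture(scope="session")
def native_model(target_dimer):
    return ComplexModel(chain_a=target_dimer.chains[0],
                        chain_b=target_dimer.chains[1])


@pytest.fixture(scope="session")
def planted_lib(target_dimer):
    return synth.make_planted_library(target_dimer, n_decoys=3, seed=99)


@pytest.fixture(scope="session")
def prediction(target_dimer, planted_lib):
    return predict_complex(target_dimer.chains[0], target_dimer.chains[1],
                           het_lib=planted_lib)
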