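"""Shared fixtures: small molecules, synthetic hypotheses and the
multi-hypothesis ensemble dataset used by the regression-stage tests."""

from __future__ import annotations

import numpy as np
import pytest

from phesvm.conformers import conformer_contract
from phesvm.ensemble import build_descriptors
from phesvm.synthetic import make_ensemble_dataset, make_hypothesis


@pytest.fixture(scope="session")
def ethanol():
    mol, cs = conformer_contract("CCO", seed=7, compound_id="ethanol")
    return mol, cs


@pytest.fixture(scope="session")
def benzene():
    mol, cs = conformer_contract("c1ccccc1", seed=7, compound_id="benzene")
    return mol, cs


@pytest.fixture(scope="session")
def ensemble_hypotheses():
    """Three hypotheses with the donor/acceptor/hydrophobe compositions of a
    promiscuous-target ensemble (1 HBD + 4 HP; 1 HBA + 1 HBD + 2 HP;
    1 HBD + 3 HP)."""
    kinds = [
        ["HBD", "HP", "HP", "HP", "HP"],
        ["HBA", "HBD", "HP", "HP"],
        ["HBD", "HP", "HP", "HP"],
    ]
    return [make_hypothesis(11 + i, len(k), k) for i, k in enumerate(kinds)]


@pytest.fixture(scope="session")
def ensemble_dataset(ensemble_hypotheses):
    """130 synthetic ligands (31 train / 88 test / 11 outlier shaped),
    activities a linear mix of per-hypothesis fits plus N(0, 0.2) noise,
    with the precomputed descriptor matrix."""
    ligs = make_ensemble_dataset(
        ensemble_hypotheses, n=130, jitter_sd=0.3, noise_sd=0.2, seed=5
    )
    y = np.array([l.pec50_true for l in ligs])
    X, flags = build_descriptors(
        [[l.features] for l in ligs], ensemble_hypotheses, max_misses=1
    )
    idx_train = np.arange(0, 31)
    idx_test = np.arange(31, 119)
    idx_outlier = np.arange(119, 130)
    return {
        "ligands": ligs,
        "y": y,
        "X": X,
        "flags": flags,
        "train": idx_train,
        "test": idx_test,
        "outlier": idx_outlier,
    }
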