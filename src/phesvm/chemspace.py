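"""Chemical-space PCA and a simple applicability-domain flag.

Compounds are summarized by eight physicochemical descriptors (molecular
weight, Crippen logP, topological polar surface area, H-bond donor and
acceptor counts, rotatable bonds, ring count, heavy-atom count), projected
by PCA of the column-standardized matrix, and flagged out-of-domain when
their Mahalanobis-style distance in the leading three components exceeds a
quantile of the training distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import PhesvmError

logger = logging.getLogger(__name__)

DESCRIPTOR_COLUMNS = (
    "mol_weight",
    "logp",
    "tpsa",
    "hbd_count",
    "hba_count",
    "rotatable_bonds",
    "ring_count",
    "heavy_atoms",
)


def descriptor_table(smiles_list: Sequence[str], ids: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Physicochemical descriptor matrix, one row per SMILES."""
    from rdkit import Chem
    from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

    rows = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES {smi!r}")
        rows.append(
            [
                Descriptors.MolWt(mol),
                Crippen.MolLogP(mol),
                rdMolDescriptors.CalcTPSA(mol),
                Lipinski.NumHDonors(mol),
                Lipinski.NumHAcceptors(mol),
                rdMolDescriptors.CalcNumRotatableBonds(mol),
                rdMolDescriptors.CalcNumRings(mol),
                mol.GetNumHeavyAtoms(),
            ]
        )
    idx = list(ids) if ids is not None else list(range(len(rows)))
    return pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS), index=idx)


@dataclass
class ChemSpace:
    """Fitted PCA state on a standardized descriptor matrix."""

    columns: list
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # descriptor x component
    explained: np.ndarray  # variance fractions, non-increasing
    scores: np.ndarray  # training compounds x component


def pca_fit(X) -> ChemSpace:
    """PCA of the centred, unit-variance-scaled matrix via SVD.

    Constant columns are dropped with a warning; loading signs are fixed by
    making each column's largest-magnitude entry positive.
    """
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        M = X.to_numpy(dtype=float)
    else:
        M = np.asarray(X, dtype=float)
        columns = list(range(M.shape[1]))
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need a 2-D matrix with n >= 2")
    sd = M.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise PhesvmError("all descriptor columns are constant")
    if not keep.all():
        dropped = [c for c, k in zip(columns, keep) if not k]
        logger.warning("dropping constant descriptor columns: %s", dropped)
    columns = [c for c, k in zip(columns, keep) if k]
    M = M[:, keep]
    center = M.mean(axis=0)
    scale = M.std(axis=0)
    Z = (M - center) / scale
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    loadings = Vt.T
    # sign convention: largest-magnitude loading entry positive per component
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            U[:, j] *= -1
    scores = U * S
    explained = (S**2) / np.sum(S**2)
    return ChemSpace(
        columns=columns,
        center=center,
        scale=scale,
        loadings=loadings,
        explained=explained,
        scores=scores,
    )


def pca_project(space: ChemSpace, X_new) -> np.ndarray:
    """Project new compounds into a fitted chemical space."""
    if isinstance(X_new, pd.DataFrame):
        X_new = X_new[space.columns].to_numpy(dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    Z = (X_new - space.center) / space.scale
    return Z @ space.loadings


def ad_flag(
    space: ChemSpace,
    scores_new: np.ndarray,
    training_scores: Optional[np.ndarray] = None,
    alpha: float = 0.99,
    n_components: int = 3,
):
    """Applicability-domain flag in the leading components.

    Distance is the per-component standardized Euclidean norm (a diagonal
    Mahalanobis distance) over the first ``n_components`` scores; a
    compound is out-of-domain when its distance exceeds the ``alpha``
    quantile of the training distances.  Returns ``(out_of_domain, dist)``.
    """
    if training_scores is None:
        training_scores = space.scores
    nc = min(n_components, training_scores.shape[1])
    T = np.asarray(training_scores, dtype=float)[:, :nc]
    sd = T.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    d_train = np.sqrt(np.sum((T / sd) ** 2, axis=1))
    thresh = float(np.quantile(d_train, alpha))
    S = np.atleast_2d(np.asarray(scores_new, dtype=float))[:, :nc]
    d_new = np.sqrt(np.sum((S / sd) ** 2, axis=1))
    return d_new > thresh, d_new
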