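"""Conformer-ensemble generation contract.

The downstream pharmacophore machinery only consumes conformer ensembles,
so generation is a pluggable contract: the default backend embeds with
RDKit's ETKDG distance geometry, minimizes with MMFF94, keeps conformers
within an energy window above the minimum (default 83.7 kJ/mol, i.e.
20 kcal/mol), deduplicates by heavy-atom RMSD and caps the ensemble size
(default 255).
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .types import ConformerSet, PhesvmError

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184

DEFAULT_MAX_CONFORMERS = 255
DEFAULT_ENERGY_WINDOW_KJ = 83.7  # = 20 kcal/mol
DEFAULT_DEDUP_RMSD = 0.5  # Angstrom, heavy atoms


class EmbeddingError(PhesvmError):
    """Raised when 3D embedding fails for a compound."""


def mol_from_smiles(smiles: str, compound_id: str = ""):
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise EmbeddingError(f"unparsable SMILES for compound {compound_id!r}: {smiles!r}")
    return mol


def conformer_contract(
    mol,
    max_conformers: int = DEFAULT_MAX_CONFORMERS,
    energy_window: float = DEFAULT_ENERGY_WINDOW_KJ,
    seed: int = 0,
    compound_id: str = "",
    dedup_rmsd: float = DEFAULT_DEDUP_RMSD,
    n_embed: Optional[int] = None,
):
    """Generate a low-energy conformer ensemble for one molecule.

    ``mol`` is a SMILES string or an RDKit Mol.  Returns ``(mol_with_hs,
    ConformerSet)`` where the ConformerSet coordinates are ordered by
    relative energy (kJ/mol above the minimum), filtered to the energy
    window, deduplicated at ``dedup_rmsd`` heavy-atom RMSD and capped at
    ``max_conformers``.  Deterministic for a fixed seed.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    if max_conformers < 1:
        raise ValueError("max_conformers must be >= 1")
    if isinstance(mol, str):
        mol = mol_from_smiles(mol, compound_id)
    mol = Chem.AddHs(mol)

    if n_embed is None:
        # scale the embedding attempts with flexibility, bounded by the cap
        n_rot = AllChem.CalcNumRotatableBonds(mol)
        n_embed = int(min(max_conformers, max(1, 10 + 10 * n_rot)))

    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    params.pruneRmsThresh = -1.0
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_embed, params=params)
    if len(ids) == 0:
        raise EmbeddingError(f"embedding failed for compound {compound_id!r}")

    energies = []
    props = AllChem.MMFFGetMoleculeProperties(mol)
    for cid in ids:
        if props is not None:
            ff = AllChem.MMFFGetMoleculeForceField(mol, props, confId=cid)
        else:
            ff = AllChem.UFFGetMoleculeForceField(mol, confId=cid)
        if ff is None:
            energies.append(0.0)
            continue
        ff.Minimize(maxIts=500)
        energies.append(ff.CalcEnergy() * KCAL_TO_KJ)

    order = sorted(range(len(ids)), key=lambda i: (energies[i], i))
    e_min = energies[order[0]]

    heavy = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() > 1]
    kept_ids: list = []
    kept_coords: list = []
    kept_rel: list = []
    for i in order:
        rel = energies[i] - e_min
        if rel > energy_window + 1e-9:
            continue
        conf = mol.GetConformer(int(ids[i]))
        xyz = np.array(conf.GetPositions(), dtype=float)
        if _is_duplicate(xyz[heavy], [c[heavy] for c in kept_coords], dedup_rmsd):
            continue
        kept_ids.append(int(ids[i]))
        kept_coords.append(xyz)
        kept_rel.append(rel)
        if len(kept_ids) >= max_conformers:
            break
    if not kept_ids:
        raise EmbeddingError(f"no conformers within the energy window for {compound_id!r}")

    # drop un-kept conformers from the molecule so conformer indices align
    for cid in list(c.GetId() for c in mol.GetConformers()):
        if cid not in kept_ids:
            mol.RemoveConformer(cid)
    # reorder molecule conformer ids to match the kept (energy) order
    id_to_pos = {cid: pos for pos, cid in enumerate(kept_ids)}
    for conf in mol.GetConformers():
        conf.SetId(id_to_pos[conf.GetId()])

    cs = ConformerSet(compound_id=compound_id, coords=kept_coords, rel_energy=np.array(kept_rel))
    cs.validate(max_conformers=max_conformers, energy_window=energy_window)
    return mol, cs


def _is_duplicate(xyz_heavy, kept_heavy, threshold: float) -> bool:
    """Heavy-atom RMSD duplicate check after optimal superposition."""
    from .fit import superpose

    for ref in kept_heavy:
        try:
            _, _, rmsd = superpose(xyz_heavy, ref)
        except (PhesvmError, ValueError):
            # tiny or degenerate (e.g. linear) heavy-atom skeleton: raw RMSD
            rmsd = float(np.sqrt(np.mean(np.sum((xyz_heavy - ref) ** 2, axis=1))))
        if rmsd < threshold:
            return True
    return False
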