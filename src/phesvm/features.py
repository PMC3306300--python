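"""Ligand-side pharmacophore feature perception.

Detects hydrogen-bond donors (HBD), hydrogen-bond acceptors (HBA) and
hydrophobes (HP) on a 3D conformer and returns their centres:

* HBD — N/O/S bearing at least one hydrogen, anchored on the heavy atom;
* HBA — N or O with an available lone pair; amide and aniline-type
  nitrogens and nitro oxygens are excluded;
* HP — the centroid of each all-carbon ring, each carbon bearing a halogen,
  and each maximal connected group of >= 3 non-aromatic carbons none of
  which touches a heteroatom.

The SMARTS-expressible part of the dictionary ships as an editable text
config (``data/feature_patterns.txt``); ring/cluster hydrophobes need
connected-component logic and are procedural.  Ring-aromatic is
deliberately not a separate kind: aromatic rings are perceived as
hydrophobes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import List, Optional

import numpy as np

from .types import LigandFeature, check_kind

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeaturePattern:
    label: str
    kind: str
    smarts: str


def load_patterns(path: Optional[str] = None) -> list:
    """Load the feature-pattern dictionary (default: the packaged config)."""
    if path is None:
        text = resources.files("phesvm").joinpath("data/feature_patterns.txt").read_text()
    else:
        text = Path(path).read_text()
    patterns = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"bad pattern line: {raw!r}")
        label, kind, smarts = parts
        patterns.append(FeaturePattern(label, check_kind(kind), smarts))
    return patterns


_DEFAULT_PATTERNS: Optional[list] = None


def _default_patterns() -> list:
    global _DEFAULT_PATTERNS
    if _DEFAULT_PATTERNS is None:
        _DEFAULT_PATTERNS = load_patterns()
    return _DEFAULT_PATTERNS


def perceive_features(
    mol,
    conf_id: int = 0,
    patterns: Optional[list] = None,
    coords: Optional[np.ndarray] = None,
) -> List[LigandFeature]:
    """Perceive HBD/HBA/HP features on one conformer of an RDKit Mol.

    ``coords`` overrides the conformer coordinates (same atom order);
    otherwise conformer ``conf_id`` must exist.  Deterministic for a fixed
    pattern set; feature order is (pattern order, match order), then the
    procedural hydrophobes.
    """
    from rdkit import Chem

    if patterns is None:
        patterns = _default_patterns()
    if coords is None:
        if mol.GetNumConformers() == 0:
            raise ValueError("molecule has no 3D coordinates")
        coords = np.array(mol.GetConformer(conf_id).GetPositions(), dtype=float)
    else:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (mol.GetNumAtoms(), 3):
            raise ValueError("coords shape does not match atom count")

    features: List[LigandFeature] = []
    seen: set = set()

    def add(kind: str, atom_ids: tuple, label: str) -> None:
        key = (kind, tuple(sorted(atom_ids)))
        if key in seen:
            return
        seen.add(key)
        pos = coords[list(atom_ids)].mean(axis=0)
        features.append(LigandFeature(kind, pos, tuple(atom_ids), label))

    for pat in patterns:
        q = Chem.MolFromSmarts(pat.smarts)
        if q is None:
            logger.warning("skipping unparsable SMARTS pattern %s", pat.label)
            continue
        for match in mol.GetSubstructMatches(q):
            # anchor on the first matched atom (the donor/acceptor heavy atom
            # or the halogenated carbon)
            add(pat.kind, (match[0],), pat.label)

    features.extend(_procedural_hydrophobes(mol, coords, seen))
    return features


def _procedural_hydrophobes(mol, coords, seen) -> List[LigandFeature]:
    """All-carbon rings and >= 3-carbon heteroatom-free aliphatic clusters."""
    out: List[LigandFeature] = []

    ring_info = mol.GetRingInfo()
    ring_atoms: set = set()
    for ring in ring_info.AtomRings():
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if all(a.GetAtomicNum() == 6 for a in atoms):
            key = ("HP", tuple(sorted(ring)))
            if key not in seen:
                seen.add(key)
                pos = coords[list(ring)].mean(axis=0)
                out.append(LigandFeature("HP", pos, tuple(ring), "hp_ring"))
        ring_atoms.update(ring)

    # aliphatic clusters: non-ring, non-aromatic carbons with no heteroatom
    # neighbours, in maximal connected components of size >= 3
    ok = []
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic() or atom.GetIdx() in ring_atoms:
            continue
        if any(n.GetAtomicNum() not in (1, 6) for n in atom.GetNeighbors()):
            continue
        ok.append(atom.GetIdx())
    ok_set = set(ok)
    visited: set = set()
    for start in ok:
        if start in visited:
            continue
        comp = []
        stack = [start]
        visited.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for n in mol.GetAtomWithIdx(i).GetNeighbors():
                j = n.GetIdx()
                if j in ok_set and j not in visited:
                    visited.add(j)
                    stack.append(j)
        if len(comp) >= 3:
            comp = tuple(sorted(comp))
            key = ("HP", comp)
            if key not in seen:
                seen.add(key)
                pos = coords[list(comp)].mean(axis=0)
                out.append(LigandFeature("HP", pos, comp, "hp_aliphatic"))
    return out


def feature_histogram(features) -> dict:
    """Counts by feature kind; always contains all three kinds."""
    counts = {"HBD": 0, "HBA": 0, "HP": 0}
    for f in features:
        counts[f.kind] += 1
    return counts
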