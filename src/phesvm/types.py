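"""Core domain types shared across the package.

The modelling vocabulary:

* a *compound record* ties an identifier/SMILES to an observed potency
  (pEC50 = -log10 EC50 in molar) and a train/test/outlier partition label;
* a *conformer set* is the low-energy 3D ensemble of one compound;
* a *pharmacophore hypothesis* is a small set of typed feature spheres
  (donor / acceptor / hydrophobe) in 3D, each with a tolerance radius and a
  weight, plus a linear map from fit value to predicted pEC50;
* a *fit result* records how a conformer ensemble best superposes onto a
  hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Closed set of pharmacophore feature kinds: hydrogen-bond donor,
#: hydrogen-bond acceptor, hydrophobe.
FEATURE_KINDS = ("HBD", "HBA", "HP")

#: Closed set of dataset partition labels.
PARTITIONS = ("train", "test", "outlier", "unassigned")


class PhesvmError(Exception):
    """Base class for package errors."""


class DegenerateGeometryError(PhesvmError):
    """Raised when point geometry is too degenerate for superposition."""


def check_kind(kind: str) -> str:
    if kind not in FEATURE_KINDS:
        raise ValueError(f"unknown feature kind {kind!r}; expected one of {FEATURE_KINDS}")
    return kind


@dataclass
class CompoundRecord:
    """One compound: identity, structure, observed potency, partition."""

    id: str
    name: str = ""
    smiles: str = ""
    pec50_obs: Optional[float] = None
    partition: str = "unassigned"
    source: str = ""

    def __post_init__(self) -> None:
        if self.partition not in PARTITIONS:
            raise ValueError(
                f"partition {self.partition!r} not in {PARTITIONS} (compound {self.id})"
            )
        if self.pec50_obs is not None and not np.isfinite(self.pec50_obs):
            raise ValueError(f"non-finite pEC50 for compound {self.id}")


@dataclass
class ConformerSet:
    """Low-energy conformer ensemble of one compound.

    ``coords`` holds one (n_atoms, 3) array per conformation, in Angstrom;
    ``rel_energy`` is each conformation's energy above the ensemble minimum
    in kJ/mol, sorted non-decreasing.
    """

    compound_id: str
    coords: list  # list of (n_atoms, 3) float arrays
    rel_energy: np.ndarray

    def __post_init__(self) -> None:
        self.rel_energy = np.asarray(self.rel_energy, dtype=float)
        if len(self.coords) != len(self.rel_energy):
            raise ValueError("coords / rel_energy length mismatch")

    def validate(self, max_conformers: int = 255, energy_window: float = 83.7) -> None:
        if len(self.coords) == 0:
            raise ValueError(f"empty conformer set for {self.compound_id}")
        if len(self.coords) > max_conformers:
            raise ValueError(
                f"{len(self.coords)} conformers exceeds cap {max_conformers}"
            )
        if np.any(np.diff(self.rel_energy) < 0):
            raise ValueError("rel_energy not sorted non-decreasing")
        if self.rel_energy[0] < -1e-9:
            raise ValueError("rel_energy must be relative to the minimum (>= 0)")
        if np.any(self.rel_energy > energy_window + 1e-9):
            raise ValueError(f"rel_energy exceeds window {energy_window} kJ/mol")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class PharmacophorePoint:
    """A typed feature sphere: position, tolerance radius, weight."""

    kind: str
    position: np.ndarray  # (3,), Angstrom
    tolerance: float = 1.6
    weight: float = 1.0

    def __post_init__(self) -> None:
        check_kind(self.kind)
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not self.tolerance > 0:
            raise ValueError(f"tolerance must be > 0, got {self.tolerance}")
        if self.weight < 0:
            raise ValueError(f"weight must be >= 0, got {self.weight}")


@dataclass
class Hypothesis:
    """A 3D pharmacophore: 3-10 typed points plus a fit -> pEC50 linear map.

    ``activity_map`` is (alpha, beta): predicted pEC50 = alpha + beta * fit.
    """

    id: str
    points: list  # list[PharmacophorePoint]
    activity_map: tuple = (0.0, 1.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        if not 3 <= len(self.points) <= 10:
            raise ValueError(
                f"hypothesis {self.id}: point count {len(self.points)} outside [3, 10]"
            )
        a, b = self.activity_map
        if not (np.isfinite(a) and np.isfinite(b)):
            raise ValueError(f"hypothesis {self.id}: non-finite activity map")
        self.activity_map = (float(a), float(b))

    @property
    def kinds(self) -> list:
        return [p.kind for p in self.points]

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points])

    @property
    def max_fit(self) -> float:
        """Upper bound on the fit value: the sum of point weights."""
        return float(sum(p.weight for p in self.points))

    def interfeature_distances(self) -> np.ndarray:
        """Condensed pairwise distance vector (rigid-motion invariant)."""
        P = self.positions
        d = P[:, None, :] - P[None, :, :]
        m = np.linalg.norm(d, axis=-1)
        iu = np.triu_indices(len(self.points), k=1)
        return m[iu]


@dataclass
class LigandFeature:
    """A perceived ligand-side feature: kind, 3D centre, defining atoms."""

    kind: str
    position: np.ndarray
    atom_ids: tuple = ()
    label: str = ""

    def __post_init__(self) -> None:
        check_kind(self.kind)
        self.position = np.asarray(self.position, dtype=float).reshape(3)


@dataclass
class FeatureMapping:
    """Injective, kind-compatible pairing of hypothesis points to ligand features."""

    pairs: tuple  # tuple of (hypothesis point index, ligand feature index)
    misses: tuple  # hypothesis point indices left unmapped

    def __post_init__(self) -> None:
        self.pairs = tuple((int(h), int(f)) for h, f in self.pairs)
        self.misses = tuple(int(m) for m in self.misses)

    @property
    def n_mapped(self) -> int:
        return len(self.pairs)


@dataclass
class FitResult:
    """Best alignment of a conformer ensemble onto a hypothesis."""

    mapping: FeatureMapping
    rotation: np.ndarray  # 3x3 proper rotation applied to the ligand
    translation: np.ndarray  # (3,)
    displacements: np.ndarray  # per hypothesis point; NaN where missed
    fit: float
    pec50_pred: Optional[float] = None
    conformer_index: int = 0
    no_fit: bool = False


@dataclass
class DatasetDesignReport:
    """Training-set design diagnostics (size, activity span, bin occupancy)."""

    n: int
    activity_span: float
    per_order_counts: dict  # integer pEC50 bin -> count
    warnings: list = field(default_factory=list)
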