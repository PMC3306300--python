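"""Rigid alignment of ligand features onto a pharmacophore and fit scoring.

A *mapping* is an injective, kind-compatible assignment of hypothesis
points to ligand features (some hypothesis points may be left unmapped,
up to ``max_misses``).  For each mapping the mapped ligand features are
rigidly superposed onto the hypothesis points (Kabsch, proper rotations
only) and the fit value is the weighted, tolerance-gated score

    fit = sum over mapped points of  w_i * max(0, 1 - (d_i / tol_i)^2)

where d_i is the residual displacement after superposition.  Missed points
contribute zero, so 0 <= fit <= sum of weights.  ``best_fit`` maximizes the
fit over all conformers and mappings; a per-hypothesis linear activity map
turns the winning fit into a predicted pEC50.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Iterator, List, Optional, Sequence

import numpy as np

from .types import (
    DegenerateGeometryError,
    FeatureMapping,
    FitResult,
    Hypothesis,
    LigandFeature,
)

#: Default number of hypothesis points that may be left unmapped.
DEFAULT_MAX_MISSES = 1

#: Cap on mappings enumerated per conformer before greedy feature pruning.
DEFAULT_MAPPING_CAP = 100_000


def superpose(A, B):
    """Least-squares rigid superposition of point set A onto B (Kabsch).

    Returns ``(rotation, translation, rmsd)`` with ``rotation`` a proper
    rotation (det = +1) such that ``rotation @ a + translation`` best
    approximates ``b`` pairwise.  Requires n >= 3 non-collinear points in A.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("A and B must be matching (n, 3) arrays")
    n = A.shape[0]
    if n < 3:
        raise ValueError(f"superposition needs at least 3 points, got {n}")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    sv = np.linalg.svd(A0, compute_uv=False)
    if sv[1] <= 1e-8 * max(1.0, sv[0]):
        raise DegenerateGeometryError("points of A are collinear (or coincident)")
    H = A0.T @ B0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A @ R.T + t) - B
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def enumerate_mappings(
    features: Sequence[LigandFeature],
    h: Hypothesis,
    max_misses: int = DEFAULT_MAX_MISSES,
    compat: Optional[list] = None,
) -> Iterator[FeatureMapping]:
    """Yield every kind-compatible injective mapping with <= max_misses
    unmapped hypothesis points and >= 3 mapped pairs.

    Deterministic order: depth-first by hypothesis point index, ligand
    feature index ascending, with the miss option sorting last.
    """
    if max_misses < 0:
        raise ValueError("max_misses must be >= 0")
    m = len(h.points)
    if compat is None:
        compat = [
            [j for j, f in enumerate(features) if f.kind == p.kind] for p in h.points
        ]

    def rec(idx: int, used: set, pairs: list, misses: list) -> Iterator[FeatureMapping]:
        remaining = m - idx
        # prune: cannot reach 3 pairs or stay within the miss budget
        if len(pairs) + remaining < 3 or len(misses) > max_misses:
            return
        if idx == m:
            yield FeatureMapping(tuple(pairs), tuple(misses))
            return
        for j in compat[idx]:
            if j in used:
                continue
            used.add(j)
            pairs.append((idx, j))
            yield from rec(idx + 1, used, pairs, misses)
            pairs.pop()
            used.remove(j)
        if len(misses) < max_misses:
            misses.append(idx)
            yield from rec(idx + 1, used, pairs, misses)
            misses.pop()

    yield from rec(0, set(), [], [])


def fit_score(h: Hypothesis, displacements) -> float:
    """Weighted tolerance-gated fit from per-point displacements.

    ``displacements`` has one entry per hypothesis point: a distance in
    Angstrom for mapped points, NaN (or None) for missed points.
    """
    disp = [np.nan if d is None else float(d) for d in displacements]
    if len(disp) != len(h.points):
        raise ValueError("displacements length must equal hypothesis point count")
    total = 0.0
    for p, d in zip(h.points, disp):
        if math.isnan(d):
            continue
        if d < 0:
            raise ValueError(f"negative displacement {d}")
        total += p.weight * max(0.0, 1.0 - (d / p.tolerance) ** 2)
    return total


def estimate_activity(fit: float, activity_map) -> float:
    """Linear fit -> pEC50 map: alpha + beta * fit."""
    alpha, beta = activity_map
    if not (np.isfinite(alpha) and np.isfinite(beta)):
        raise ValueError("activity map must be finite")
    return float(alpha + beta * fit)


def _no_fit_result(h: Hypothesis) -> FitResult:
    return FitResult(
        mapping=FeatureMapping((), tuple(range(len(h.points)))),
        rotation=np.eye(3),
        translation=np.zeros(3),
        displacements=np.full(len(h.points), np.nan),
        fit=0.0,
        pec50_pred=estimate_activity(0.0, h.activity_map),
        conformer_index=0,
        no_fit=True,
    )


def _mapping_count_bound(compat: list, max_misses: int) -> float:
    """Cheap upper bound on the number of mappings (for cap pruning)."""
    bound = 1.0
    for options in compat:
        bound *= len(options) + 1  # +1 for the miss option
        if bound > 1e15:
            return bound
    return bound


def _prune_features(
    features: Sequence[LigandFeature], h: Hypothesis, cap: int, max_misses: int
):
    """Greedily drop trailing features of the most numerous kind until the
    mapping-count bound fits under the cap."""
    keep = list(range(len(features)))
    by_kind: dict = {}
    for i, f in enumerate(features):
        by_kind.setdefault(f.kind, []).append(i)
    need = {p.kind: 0 for p in h.points}
    for p in h.points:
        need[p.kind] += 1

    def bound(idx_set):
        compat = [
            [j for j in idx_set if features[j].kind == p.kind] for p in h.points
        ]
        return _mapping_count_bound(compat, max_misses)

    keep_set = set(keep)
    while bound(keep_set) > cap:
        kind = max(
            by_kind,
            key=lambda k: len([j for j in by_kind[k] if j in keep_set]),
        )
        avail = [j for j in by_kind[kind] if j in keep_set]
        if len(avail) <= need.get(kind, 0) + 1:
            break  # cannot prune further without starving the hypothesis
        keep_set.discard(avail[-1])
    return sorted(keep_set)


def best_fit(
    conformer_features: Sequence[Sequence[LigandFeature]],
    h: Hypothesis,
    max_misses: int = DEFAULT_MAX_MISSES,
    mapping_cap: int = DEFAULT_MAPPING_CAP,
) -> FitResult:
    """Best alignment of a conformer ensemble onto a hypothesis.

    ``conformer_features`` is one perceived feature list per conformer
    (a single-element sequence for rigid/synthetic ligands).  Over all
    conformers and mappings the maximum-fit superposition wins; ties break
    by lower mapped-point RMSD, then lower conformer index, then
    lexicographic mapping.  If no mapping with >= 3 kind-compatible pairs
    superposes on any conformer, a zero-fit result flagged ``no_fit`` is
    returned.
    """
    if len(conformer_features) == 0:
        raise ValueError("empty conformer ensemble")
    best: Optional[FitResult] = None
    best_key = None
    m = len(h.points)
    hpos = h.positions
    for ci, features in enumerate(conformer_features):
        features = list(features)
        keep = _prune_features(features, h, mapping_cap, max_misses)
        if len(keep) < len(features):
            features = [features[j] for j in keep]
        compat = [
            [j for j, f in enumerate(features) if f.kind == p.kind] for p in h.points
        ]
        for mapping in enumerate_mappings(features, h, max_misses, compat=compat):
            hidx = [p for p, _ in mapping.pairs]
            fidx = [f for _, f in mapping.pairs]
            L = np.array([features[j].position for j in fidx])
            try:
                R, t, rmsd = superpose(L, hpos[hidx])
            except DegenerateGeometryError:
                continue
            moved = L @ R.T + t
            disp = np.full(m, np.nan)
            disp[hidx] = np.linalg.norm(moved - hpos[hidx], axis=1)
            fit = fit_score(h, disp)
            key = (-fit, rmsd, ci, mapping.pairs)
            if best_key is None or key < best_key:
                best_key = key
                best = FitResult(
                    mapping=mapping,
                    rotation=R,
                    translation=t,
                    displacements=disp,
                    fit=fit,
                    pec50_pred=estimate_activity(fit, h.activity_map),
                    conformer_index=ci,
                    no_fit=False,
                )
    if best is None:
        return _no_fit_result(h)
    return best
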