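"""Synthetic ligand/hypothesis generators and brute-force alignment oracle.

Synthetic ligands are bare 3D feature-point sets (no underlying molecule):
this isolates the alignment, ensemble and regression machinery from
perception chemistry, which has its own molecule-level tests.  Generators
are pure functions of their seed and parameters.

``brute_force_align`` is an exhaustive, transform-free re-derivation of the
best-fit search built on ``itertools`` and SciPy's ``align_vectors`` — an
independent oracle for ``phesvm.fit.best_fit``, kept deliberately separate
from that code path.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .types import FeatureMapping, FitResult, Hypothesis, LigandFeature, PharmacophorePoint

DEFAULT_BOX = 10.0  # Angstrom edge of the generation cube
MIN_POINT_SEPARATION = 2.0  # Angstrom


@dataclass
class SyntheticLigand:
    """A generated feature-point ligand with its planted ground truth."""

    id: str
    features: list  # list[LigandFeature]
    true_fit: float = 0.0
    pec50_true: float = 0.0
    is_decoy: bool = False


def make_hypothesis(
    seed: int,
    n_points: int = 4,
    kinds: Optional[Sequence[str]] = None,
    box: float = DEFAULT_BOX,
    tolerance: float = 1.6,
    weight: float = 1.0,
) -> Hypothesis:
    """Random hypothesis: points uniform in a box, pairwise >= 2 Angstrom apart.

    Default composition mirrors a donor plus hydrophobes arrangement
    (1 HBD + (n-1) HP) when ``kinds`` is not given.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    if kinds is None:
        kinds = ["HBD"] + ["HP"] * (n_points - 1)
    if len(kinds) != n_points:
        raise ValueError("kinds length must equal n_points")
    rng = np.random.default_rng(seed)
    pts: List[np.ndarray] = []
    tries = 0
    while len(pts) < n_points:
        cand = rng.uniform(0.0, box, size=3)
        if all(np.linalg.norm(cand - p) >= MIN_POINT_SEPARATION for p in pts):
            pts.append(cand)
        tries += 1
        if tries > 10_000:
            raise RuntimeError("failed to place well-separated points; enlarge box")
    points = [PharmacophorePoint(k, p, tolerance, weight) for k, p in zip(kinds, pts)]
    return Hypothesis(id=f"synth-{seed}", points=points, provenance="synthetic generator")


def random_rotation(rng) -> np.ndarray:
    """Uniform random proper rotation (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def make_ligand_set(
    h: Hypothesis,
    n: int,
    jitter_sd: float = 0.3,
    decoy_fraction: float = 0.2,
    noise_sd: float = 0.2,
    alpha: float = 4.0,
    beta: float = 1.0,
    seed: int = 0,
    max_misses: int = 0,
    box: float = DEFAULT_BOX,
) -> List[SyntheticLigand]:
    """Generate ligands matching (or decoying) a hypothesis.

    Matching ligands are the hypothesis feature points jittered by an
    isotropic Gaussian, placed under a random rigid transform, with 0-3
    distractor features added.  Decoys are fully random feature sets.
    Activities are pec50_true = alpha + beta * true_fit + N(0, noise_sd)
    where true_fit comes from :func:`brute_force_align`.
    """
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if not 0 <= decoy_fraction <= 1:
        raise ValueError("decoy_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: List[SyntheticLigand] = []
    all_kinds = ("HBD", "HBA", "HP")
    for i in range(n):
        is_decoy = bool(rng.random() < decoy_fraction)
        feats: List[LigandFeature] = []
        if is_decoy:
            n_feat = int(rng.integers(3, 7))
            for j in range(n_feat):
                feats.append(
                    LigandFeature(
                        all_kinds[int(rng.integers(0, 3))],
                        rng.uniform(0.0, box, size=3),
                        (j,),
                        "decoy",
                    )
                )
        else:
            R = random_rotation(rng)
            t = rng.uniform(-5.0, 5.0, size=3)
            for j, p in enumerate(h.points):
                pos = R @ (p.position + rng.normal(0.0, jitter_sd, size=3)) + t
                feats.append(LigandFeature(p.kind, pos, (j,), "planted"))
            for j in range(int(rng.integers(0, 4))):
                feats.append(
                    LigandFeature(
                        all_kinds[int(rng.integers(0, 3))],
                        rng.uniform(0.0, box, size=3) @ R.T + t,
                        (len(h.points) + j,),
                        "distractor",
                    )
                )
        res = brute_force_align(feats, h, max_misses=max_misses)
        true_fit = res.fit
        pec50 = alpha + beta * true_fit + rng.normal(0.0, noise_sd)
        out.append(
            SyntheticLigand(
                id=f"L{i:03d}",
                features=feats,
                true_fit=true_fit,
                pec50_true=float(pec50),
                is_decoy=is_decoy,
            )
        )
    return out


def make_ensemble_dataset(
    hypotheses: Sequence[Hypothesis],
    n: int,
    jitter_sd: float = 0.3,
    noise_sd: float = 0.2,
    mix_alpha: float = 2.0,
    mix_weights: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> List[SyntheticLigand]:
    """Multi-hypothesis dataset: each ligand is planted on one hypothesis
    (round-robin) and its activity is a linear mix of its true fits to all
    hypotheses plus Gaussian noise — the generative model the ensemble/SVR
    stage is meant to invert.
    """
    k = len(hypotheses)
    if mix_weights is None:
        mix_weights = [1.0] * k
    rng = np.random.default_rng(seed)
    out: List[SyntheticLigand] = []
    for i in range(n):
        h = hypotheses[i % k]
        sub = make_ligand_set(
            h,
            1,
            jitter_sd=jitter_sd,
            decoy_fraction=0.0,
            noise_sd=0.0,
            alpha=0.0,
            beta=1.0,
            seed=int(rng.integers(0, 2**31 - 1)),
        )[0]
        fits = [brute_force_align(sub.features, hj, max_misses=1).fit for hj in hypotheses]
        pec50 = mix_alpha + float(np.dot(mix_weights, fits)) + rng.normal(0.0, noise_sd)
        out.append(
            SyntheticLigand(
                id=f"E{i:03d}",
                features=sub.features,
                true_fit=fits[i % k],
                pec50_true=float(pec50),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Brute-force alignment oracle
# ---------------------------------------------------------------------------

def _scipy_superpose(L: np.ndarray, H: np.ndarray):
    """Proper-rotation Kabsch via scipy (independent of phesvm.fit)."""
    from scipy.spatial.transform import Rotation

    cl, ch = L.mean(axis=0), H.mean(axis=0)
    rot, _ = Rotation.align_vectors(H - ch, L - cl)
    R = rot.as_matrix()
    t = ch - R @ cl
    return R, t


def brute_force_align(
    features: Sequence[LigandFeature],
    h: Hypothesis,
    max_misses: int = 1,
) -> FitResult:
    """Exhaustive alignment oracle (factorial cost; keep <= ~6 features/side).

    Enumerates every subset of hypothesis points of size >= 3 within the
    miss budget and every kind-compatible ordered choice of ligand features
    via itertools, superposes with SciPy and scores with the tolerance-gated
    fit formula.  Tie-breaking contract matches ``best_fit``: higher fit,
    then lower mapped RMSD, then lexicographic mapping.
    """
    m = len(h.points)
    feats = list(features)
    best = None
    best_key = None
    for n_miss in range(0, max_misses + 1):
        if m - n_miss < 3:
            break
        for missed in itertools.combinations(range(m), n_miss):
            mapped_h = [i for i in range(m) if i not in missed]
            # ordered choices of distinct ligand features, kind-compatible
            cand_lists = [
                [j for j, f in enumerate(feats) if f.kind == h.points[i].kind]
                for i in mapped_h
            ]
            for choice in itertools.product(*cand_lists):
                if len(set(choice)) != len(choice):
                    continue
                L = np.array([feats[j].position for j in choice])
                H = h.positions[mapped_h]
                centered = L - L.mean(axis=0)
                sv = np.linalg.svd(centered, compute_uv=False)
                if sv[1] <= 1e-8 * max(1.0, sv[0]):
                    continue  # collinear: no well-defined superposition
                R, t = _scipy_superpose(L, H)
                moved = L @ R.T + t
                d = np.linalg.norm(moved - H, axis=1)
                rmsd = float(np.sqrt(np.mean(d * d)))
                fit = 0.0
                for i, di in zip(mapped_h, d):
                    p = h.points[i]
                    fit += p.weight * max(0.0, 1.0 - (di / p.tolerance) ** 2)
                pairs = tuple(zip(mapped_h, choice))
                key = (-fit, rmsd, 0, pairs)
                if best_key is None or key < best_key:
                    best_key = key
                    disp = np.full(m, np.nan)
                    disp[list(mapped_h)] = d
                    best = FitResult(
                        mapping=FeatureMapping(pairs, tuple(missed)),
                        rotation=R,
                        translation=t,
                        displacements=disp,
                        fit=fit,
                        pec50_pred=h.activity_map[0] + h.activity_map[1] * fit,
                        conformer_index=0,
                        no_fit=False,
                    )
    if best is None:
        from .fit import _no_fit_result

        return _no_fit_result(h)
    return best
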