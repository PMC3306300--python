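"""Simplified construct / subtract / optimize induction of hypotheses.

A deliberately transparent three-phase generator of candidate
pharmacophores from a training set:

* **construct** — candidate 3-5 point arrangements are taken from the
  feature sets of the most active compounds and retained when every other
  top-active compound can realize the arrangement (kind-matching features
  whose pairwise distances agree within ``eps_d``) on some conformer;
* **subtract** — candidates that the least-active compounds also fit well
  (fit fraction >= 0.5 on at least half of them) are discarded;
* **optimize** — simulated annealing over point positions, tolerances and
  weights maximizes the training r^2 between estimated and observed pEC50,
  re-calibrating the linear activity map at every evaluation and keeping
  the best state seen.

``calibrate`` fits the per-hypothesis (alpha, beta) activity map by
ordinary least squares of observed pEC50 on best-fit values.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .fit import best_fit, estimate_activity
from .types import Hypothesis, PharmacophorePoint, PhesvmError

logger = logging.getLogger(__name__)

DEFAULT_TOLERANCE = 1.6  # Angstrom, induced-point radius
TOLERANCE_BOUNDS = (1.0, 3.0)  # annealing bounds, Angstrom
WEIGHT_BOUNDS = (0.0, 3.0)


@dataclass
class TrainingCompound:
    """One training compound ready for induction: activity + per-conformer
    feature lists (as produced by perception, or synthetic)."""

    id: str
    pec50_obs: float
    conformer_features: list  # list over conformers of list[LigandFeature]


@dataclass
class InductionConfig:
    feature_menu: tuple = ("HBD", "HBA", "HP")
    min_points: int = 3
    max_points: int = 5
    n_top_active: Optional[int] = None  # default: top quartile
    n_inactive: Optional[int] = None  # default: bottom quartile
    candidate_cap: int = 50
    eps_d: float = 1.5  # Angstrom, pairwise-distance match tolerance
    anneal_steps: int = 60
    anneal_step_size: float = 0.5  # Angstrom, initial perturbation scale
    anneal_cooling: float = 0.95
    seed: int = 0
    max_misses: int = 1

    def __post_init__(self) -> None:
        if self.candidate_cap < 1:
            raise ValueError("candidate_cap must be >= 1")
        if not 3 <= self.min_points <= self.max_points:
            raise ValueError("point-count window must sit inside [3, ...]")


def _split_actives(training: Sequence[TrainingCompound], cfg: InductionConfig):
    ordered = sorted(training, key=lambda c: -c.pec50_obs)
    n_top = cfg.n_top_active if cfg.n_top_active is not None else max(2, len(ordered) // 4)
    n_in = cfg.n_inactive if cfg.n_inactive is not None else max(1, len(ordered) // 4)
    return ordered[:n_top], ordered[-n_in:] if n_in else []


def _pairwise(P: np.ndarray) -> np.ndarray:
    d = P[:, None, :] - P[None, :, :]
    return np.linalg.norm(d, axis=-1)


def _matches_arrangement(
    compound: TrainingCompound, kinds: Sequence[str], D: np.ndarray, eps_d: float
) -> bool:
    """Does some conformer have kind-matching features whose pairwise
    distances agree with D within eps_d (injective assignment)?"""
    s = len(kinds)
    for feats in compound.conformer_features:
        cand = [
            [j for j, f in enumerate(feats) if f.kind == kinds[i]] for i in range(s)
        ]
        if any(len(c) == 0 for c in cand):
            continue
        pos = [f.position for f in feats]

        def rec(i: int, chosen: list) -> bool:
            if i == s:
                return True
            for j in cand[i]:
                if j in chosen:
                    continue
                ok = True
                for ii, jj in enumerate(chosen):
                    if abs(np.linalg.norm(pos[j] - pos[jj]) - D[i, ii]) > eps_d:
                        ok = False
                        break
                if ok and rec(i + 1, chosen + [j]):
                    return True
            return False

        if rec(0, []):
            return True
    return False


def construct(
    training: Sequence[TrainingCompound], cfg: InductionConfig = InductionConfig()
) -> List[Hypothesis]:
    """Construction phase: arrangements common to the most active compounds."""
    actives, _ = _split_actives(training, cfg)
    if len(actives) < 2:
        raise ValueError("construction needs at least 2 top-active compounds")
    seed_cpd, rest = actives[0], actives[1:]
    candidates: List[Hypothesis] = []
    seen_dists: List[np.ndarray] = []
    for ci, feats in enumerate(seed_cpd.conformer_features):
        idx_ok = [j for j, f in enumerate(feats) if f.kind in cfg.feature_menu]
        for size in range(cfg.min_points, cfg.max_points + 1):
            for combo in itertools.combinations(idx_ok, size):
                P = np.array([feats[j].position for j in combo])
                kinds = [feats[j].kind for j in combo]
                if np.min(_pairwise(P) + np.eye(size) * 1e9) < 1.0:
                    continue  # overlapping feature centres: degenerate seed
                sv = np.linalg.svd(P - P.mean(axis=0), compute_uv=False)
                if sv[1] <= 1e-6:
                    continue  # collinear arrangement cannot anchor a 3D model
                D = _pairwise(P)
                key = np.sort(D[np.triu_indices(size, k=1)])
                if any(
                    len(k0) == len(key) and np.all(np.abs(k0 - key) < cfg.eps_d / 2)
                    for k0 in seen_dists
                ):
                    continue  # near-duplicate of an existing candidate
                if all(_matches_arrangement(c, kinds, D, cfg.eps_d) for c in rest):
                    pts = [
                        PharmacophorePoint(k, p - P.mean(axis=0), DEFAULT_TOLERANCE, 1.0)
                        for k, p in zip(kinds, P)
                    ]
                    candidates.append(
                        Hypothesis(
                            id=f"cand-{len(candidates):03d}",
                            points=pts,
                            provenance=f"construct from {seed_cpd.id} conformer {ci}",
                        )
                    )
                    seen_dists.append(key)
                if len(candidates) >= cfg.candidate_cap:
                    return candidates
    if not candidates:
        logger.info("construction found no common arrangement")
    return candidates


def subtract(
    candidates: Sequence[Hypothesis],
    training: Sequence[TrainingCompound],
    cfg: InductionConfig = InductionConfig(),
) -> List[Hypothesis]:
    """Subtraction phase: drop candidates the inactives also fit well."""
    _, inactives = _split_actives(training, cfg)
    if not inactives:
        return list(candidates)
    kept = []
    for h in candidates:
        max_fit = h.max_fit
        n_hit = 0
        for c in inactives:
            res = best_fit(c.conformer_features, h, max_misses=cfg.max_misses)
            if max_fit > 0 and res.fit / max_fit >= 0.5:
                n_hit += 1
        if n_hit >= 0.5 * len(inactives):
            logger.info("subtracting %s (fits %d/%d inactives)", h.id, n_hit, len(inactives))
            continue
        kept.append(h)
    return kept


def calibrate(
    h: Hypothesis, training: Sequence[TrainingCompound], max_misses: int = 1
) -> Hypothesis:
    """OLS of observed pEC50 on best-fit values -> (alpha, beta) activity map.

    beta is clipped at zero (with a warning) so the map never inverts the
    fit ordering; a hypothesis with zero fit variance is uninformative.
    """
    if len(training) < 3:
        raise ValueError("calibration needs >= 3 training compounds")
    fits = np.array(
        [best_fit(c.conformer_features, h, max_misses=max_misses).fit for c in training]
    )
    y = np.array([c.pec50_obs for c in training])
    if np.var(fits) <= 1e-12:
        raise PhesvmError(f"uninformative hypothesis {h.id}: zero fit variance")
    beta, alpha = np.polyfit(fits, y, 1)
    if beta < 0:
        logger.warning("hypothesis %s: negative slope %.3f clipped to 0", h.id, beta)
        beta, alpha = 0.0, float(np.mean(y))
    return Hypothesis(h.id, h.points, (float(alpha), float(beta)), h.provenance)


def _training_r2(
    h: Hypothesis, training: Sequence[TrainingCompound], max_misses: int
) -> float:
    """Calibrated training r^2 (squared Pearson of estimates vs observed)."""
    fits = np.array(
        [best_fit(c.conformer_features, h, max_misses=max_misses).fit for c in training]
    )
    y = np.array([c.pec50_obs for c in training])
    if np.var(fits) <= 1e-12 or np.var(y) <= 1e-12:
        return 0.0
    r = np.corrcoef(fits, y)[0, 1]
    return float(r * r)


def optimize(
    candidates: Sequence[Hypothesis],
    training: Sequence[TrainingCompound],
    cfg: InductionConfig = InductionConfig(),
) -> List[Hypothesis]:
    """Simulated-annealing refinement of each candidate (best-so-far kept).

    Perturbs one random point per step — its position (Gaussian, scale
    cooled geometrically), tolerance (within 1.0-3.0 Angstrom) or weight
    (within 0-3) — and accepts by the Metropolis rule on training r^2.
    Deterministic for a fixed config seed; the returned hypothesis is never
    worse than the input on the annealing objective.
    """
    if cfg.anneal_steps < 0:
        raise ValueError("anneal_steps must be >= 0")
    if cfg.anneal_steps == 0:
        return list(candidates)
    out = []
    for hi, h in enumerate(candidates):
        rng = np.random.default_rng((cfg.seed, hi))
        cur = h
        cur_obj = _training_r2(h, training, cfg.max_misses)
        best_h, best_obj = cur, cur_obj
        step = cfg.anneal_step_size
        temp = 0.1
        for _ in range(cfg.anneal_steps):
            cand = _perturb(cur, rng, step)
            obj = _training_r2(cand, training, cfg.max_misses)
            if obj > cur_obj or rng.random() < math.exp((obj - cur_obj) / max(temp, 1e-9)):
                cur, cur_obj = cand, obj
                if obj > best_obj:
                    best_h, best_obj = cand, obj
            step *= cfg.anneal_cooling
            temp *= cfg.anneal_cooling
        out.append(
            Hypothesis(best_h.id, best_h.points, best_h.activity_map, best_h.provenance)
        )
    return out


def _perturb(h: Hypothesis, rng, step: float) -> Hypothesis:
    pts = [PharmacophorePoint(p.kind, p.position.copy(), p.tolerance, p.weight) for p in h.points]
    i = int(rng.integers(0, len(pts)))
    mode = int(rng.integers(0, 3))
    p = pts[i]
    if mode == 0:
        p.position = p.position + rng.normal(0.0, step, size=3)
    elif mode == 1:
        p.tolerance = float(
            np.clip(p.tolerance + rng.normal(0.0, 0.2), *TOLERANCE_BOUNDS)
        )
    else:
        p.weight = float(np.clip(p.weight + rng.normal(0.0, 0.2), *WEIGHT_BOUNDS))
    return Hypothesis(h.id, pts, h.activity_map, h.provenance)


def induce(
    training: Sequence[TrainingCompound], cfg: InductionConfig = InductionConfig()
) -> List[Hypothesis]:
    """Full pipeline: construct -> subtract -> optimize -> calibrate,
    returning candidates ranked by training r^2 (best first)."""
    cands = construct(training, cfg)
    cands = subtract(cands, training, cfg)
    cands = optimize(cands, training, cfg)
    calibrated = []
    for h in cands:
        try:
            calibrated.append(calibrate(h, training, cfg.max_misses))
        except PhesvmError as exc:
            logger.info("dropping candidate: %s", exc)
    calibrated.sort(
        key=lambda h: -_training_r2(h, training, cfg.max_misses)
    )
    return calibrated
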