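"""Pharmacophore ensemble + support-vector regression (the PhE/SVM stage).

Each hypothesis in the ensemble emits its own pEC50 estimate for a
molecule; those estimates form the descriptor vector (the SVM input
dimensionality equals the ensemble size).  An epsilon- or nu-SVR with an
RBF kernel is trained on the descriptor matrix; hyperparameters come from
an exhaustive grid search under k-fold cross-validation, and the
cross-validation coefficient q^2 = 1 - PRESS/SS is the internal-validation
statistic.

Descriptor columns are standardized (mean 0, sd 1) before the kernel;
predictions are returned in pEC50 units.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .fit import best_fit, estimate_activity
from .types import Hypothesis, PhesvmError

logger = logging.getLogger(__name__)

#: Default fold-assignment seed for cross-validation splits.
DEFAULT_CV_SEED = 20120316

#: Default hyperparameter grids (powers of two for C and gamma).
DEFAULT_C_GRID = tuple(2.0**k for k in range(-4, 9))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-10, 3))
DEFAULT_EPSILON_GRID = (0.001, 0.01, 0.1)
DEFAULT_NU_GRID = (0.2, 0.4, 0.6, 0.8)


@dataclass
class SVRParams:
    """SVR hyperparameters (RBF kernel only)."""

    mode: str = "eps-SVR"  # or "nu-SVR"
    C: float = 4.0
    gamma: float = 0.008
    epsilon: float = 0.001
    nu: float = 0.5

    def __post_init__(self) -> None:
        if self.mode not in ("eps-SVR", "nu-SVR"):
            raise ValueError(f"unknown SVR mode {self.mode!r}")
        if not self.C > 0:
            raise ValueError("C must be > 0")
        if not self.gamma > 0:
            raise ValueError("gamma must be > 0")
        if self.mode == "eps-SVR" and self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.mode == "nu-SVR" and not 0 < self.nu <= 1:
            raise ValueError("nu must be in (0, 1]")


@dataclass
class TrainedSVR:
    """Trained SVR state: column scaling + fitted libsvm estimator."""

    params: SVRParams
    center: np.ndarray
    scale: np.ndarray
    estimator: object

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(self.transform(X)), dtype=float)


def train_svr(X, y, p: SVRParams = SVRParams()) -> TrainedSVR:
    """Fit an RBF-kernel epsilon- or nu-SVR on a descriptor matrix.

    Columns are standardized internally (constant columns are centred and
    left at zero).  Training is deterministic: identical inputs and
    parameters reproduce identical predictions.
    """
    from sklearn.svm import SVR, NuSVR

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per y entry")
    if len(y) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    center = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = (X - center) / scale
    if p.mode == "eps-SVR":
        est = SVR(kernel="rbf", C=p.C, gamma=p.gamma, epsilon=p.epsilon)
    else:
        est = NuSVR(kernel="rbf", C=p.C, gamma=p.gamma, nu=p.nu)
    est.fit(Xs, y)
    return TrainedSVR(params=p, center=center, scale=scale, estimator=est)


def activity_folds(y, folds: int, seed: int = DEFAULT_CV_SEED) -> np.ndarray:
    """Fold assignment stratified by activity decile.

    Samples are ranked by activity, cut into deciles, shuffled within each
    stratum with the seeded RNG and dealt round-robin across folds, so every
    fold spans the activity range.  Returns an integer fold id per sample.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if n < folds:
        raise ValueError(f"n = {n} < folds = {folds}")
    rng = np.random.default_rng(seed)
    order = np.argsort(y, kind="stable")
    n_strata = min(10, n)
    strata = np.array_split(order, n_strata)
    assign = np.empty(n, dtype=int)
    pos = 0
    for s in strata:
        s = s.copy()
        rng.shuffle(s)
        for i in s:
            assign[i] = pos % folds
            pos += 1
    return assign


def kfold_q2(
    X, y, p: SVRParams = SVRParams(), folds: int = 10, seed: int = DEFAULT_CV_SEED
) -> float:
    """Cross-validation coefficient q^2 = 1 - PRESS / SS.

    Out-of-fold predictions from refitting on each training split; folds
    stratified by activity decile; deterministic per seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.var(y) <= 0:
        raise PhesvmError("zero activity variance: q^2 undefined")
    assign = activity_folds(y, folds, seed)
    yhat = np.empty_like(y)
    for f in range(folds):
        mask = assign == f
        model = train_svr(X[~mask], y[~mask], p)
        yhat[mask] = model.predict(X[mask])
    press = float(np.sum((y - yhat) ** 2))
    ss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - press / ss


def cv_rmse(X, y, p: SVRParams, assign: np.ndarray) -> float:
    """Out-of-fold RMSE for a fixed fold assignment."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    yhat = np.empty_like(y)
    for f in np.unique(assign):
        mask = assign == f
        model = train_svr(X[~mask], y[~mask], p)
        yhat[mask] = model.predict(X[mask])
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def grid_search(
    X,
    y,
    mode: str = "eps-SVR",
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    eps_or_nu_grid: Optional[Sequence[float]] = None,
    folds: int = 10,
    seed: int = DEFAULT_CV_SEED,
):
    """Exhaustive grid search by k-fold CV RMSE.

    Returns ``(best SVRParams, table)`` where the table lists every grid
    point and its CV RMSE.  Ties break toward smaller C, larger
    epsilon (or nu), then smaller gamma.  Deterministic per seed.
    """
    if eps_or_nu_grid is None:
        eps_or_nu_grid = DEFAULT_EPSILON_GRID if mode == "eps-SVR" else DEFAULT_NU_GRID
    if not (len(c_grid) and len(gamma_grid) and len(eps_or_nu_grid)):
        raise ValueError("grids must be non-empty")
    y = np.asarray(y, dtype=float)
    if len(y) < folds:
        raise ValueError(f"n = {len(y)} < folds = {folds}")
    assign = activity_folds(y, folds, seed)
    rows = []
    for C, gamma, e in itertools.product(c_grid, gamma_grid, eps_or_nu_grid):
        if mode == "eps-SVR":
            p = SVRParams(mode=mode, C=C, gamma=gamma, epsilon=e)
        else:
            p = SVRParams(mode=mode, C=C, gamma=gamma, nu=e)
        rows.append((C, gamma, e, cv_rmse(X, y, p, assign)))
    table = pd.DataFrame(rows, columns=["C", "gamma", "eps_or_nu", "cv_rmse"])
    best_row = min(rows, key=lambda r: (r[3], r[0], -r[2], r[1]))
    C, gamma, e, _ = best_row
    if mode == "eps-SVR":
        best = SVRParams(mode=mode, C=C, gamma=gamma, epsilon=e)
    else:
        best = SVRParams(mode=mode, C=C, gamma=gamma, nu=e)
    return best, table


# ---------------------------------------------------------------------------
# Descriptor construction and ensemble assembly
# ---------------------------------------------------------------------------

def build_descriptors(
    conformer_features_per_compound: Sequence,
    hypotheses: Sequence[Hypothesis],
    max_misses: int = 1,
):
    """n x k matrix of per-hypothesis pEC50 estimates.

    Entry (i, j) is the activity estimate of compound i's best fit onto
    hypothesis j.  A no-fit entry falls back to the hypothesis intercept
    (fit = 0) and is flagged in the returned boolean matrix.
    """
    if len(hypotheses) == 0:
        raise ValueError("empty hypothesis ensemble")
    n, k = len(conformer_features_per_compound), len(hypotheses)
    X = np.empty((n, k))
    flags = np.zeros((n, k), dtype=bool)
    for i, confs in enumerate(conformer_features_per_compound):
        for j, h in enumerate(hypotheses):
            res = best_fit(confs, h, max_misses=max_misses)
            X[i, j] = res.pec50_pred
            flags[i, j] = res.no_fit
    return X, flags


def select_ensemble(
    candidates: Sequence[Hypothesis],
    train_conformer_features: Sequence,
    y_train,
    k: int = 3,
    test_conformer_features: Optional[Sequence] = None,
    max_misses: int = 1,
    redundancy_r: float = 0.95,
) -> List[Hypothesis]:
    """Greedy ensemble assembly by training r^2 with a redundancy filter.

    Candidates are ranked by the squared Pearson correlation of their
    training predictions with the observed activities; the top k are taken,
    skipping any candidate whose training predictions correlate above
    ``redundancy_r`` with an already-selected member.  The optional test
    features are accepted for reporting parity but do not drive selection.
    """
    if len(candidates) < k:
        raise ValueError(f"need >= {k} candidates, got {len(candidates)}")
    y = np.asarray(y_train, dtype=float)
    preds = []
    for h in candidates:
        col = np.array(
            [best_fit(c, h, max_misses=max_misses).pec50_pred for c in train_conformer_features]
        )
        preds.append(col)
    r2s = []
    for col in preds:
        if np.std(col) <= 1e-12:
            r2s.append(-np.inf)
        else:
            r = np.corrcoef(col, y)[0, 1]
            r2s.append(r * r)
    order = sorted(range(len(candidates)), key=lambda i: (-r2s[i], i))
    chosen: List[int] = []
    for i in order:
        if len(chosen) == k:
            break
        redundant = False
        for j in chosen:
            if np.std(preds[i]) <= 1e-12 or np.std(preds[j]) <= 1e-12:
                redundant = np.allclose(preds[i], preds[j])
            else:
                redundant = abs(np.corrcoef(preds[i], preds[j])[0, 1]) > redundancy_r
            if redundant:
                break
        if not redundant:
            chosen.append(i)
    if len(chosen) < k:
        survivors = [candidates[i].id for i in chosen]
        raise PhesvmError(
            f"only {len(chosen)} candidates survive the redundancy filter: {survivors}"
        )
    return [candidates[i] for i in chosen]


@dataclass
class PhEModel:
    """The pharmacophore ensemble plus its trained SVR."""

    hypotheses: list  # list[Hypothesis], fixed order
    svr: TrainedSVR
    max_misses: int = 1

    @property
    def k(self) -> int:
        return len(self.hypotheses)

    def predict_features(self, conformer_features: Sequence) -> tuple:
        """Predict from perceived (or synthetic) per-conformer feature lists.

        Returns ``(pec50, breakdown, any_no_fit)`` where breakdown is the
        k-vector of raw per-hypothesis estimates.
        """
        X, flags = build_descriptors([conformer_features], self.hypotheses, self.max_misses)
        pred = float(self.svr.predict(X)[0])
        return pred, X[0], bool(flags[0].any())

    def predict_batch(self, conformer_features_per_compound: Sequence) -> np.ndarray:
        X, _ = build_descriptors(
            conformer_features_per_compound, self.hypotheses, self.max_misses
        )
        return self.svr.predict(X)


def train_phe_model(
    hypotheses: Sequence[Hypothesis],
    train_conformer_features: Sequence,
    y_train,
    params: SVRParams = SVRParams(),
    max_misses: int = 1,
) -> PhEModel:
    """Assemble descriptors for the ensemble and train the SVR stage."""
    X, _ = build_descriptors(train_conformer_features, hypotheses, max_misses)
    svr = train_svr(X, np.asarray(y_train, dtype=float), params)
    return PhEModel(hypotheses=list(hypotheses), svr=svr, max_misses=max_misses)
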