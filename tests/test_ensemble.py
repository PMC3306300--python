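"""Descriptor assembly, SVR training, grid search and cross-validation."""

import itertools

import numpy as np
import pytest

from phesvm import (
    LigandFeature,
    PhesvmError,
    SVRParams,
    build_descriptors,
    kfold_q2,
    select_ensemble,
    train_svr,
)
from phesvm.ensemble import activity_folds, cv_rmse, grid_search, train_phe_model
from phesvm.synthetic import make_hypothesis


class TestSVRParams:
    def test_defaults_match_reference_optimum(self):
        p = SVRParams()
        assert (p.mode, p.gamma, p.C, p.epsilon) == ("eps-SVR", 0.008, 4.0, 0.001)

    @pytest.mark.parametrize(
        "kwargs", [{"C": 0}, {"gamma": -1}, {"mode": "linear"}, {"mode": "nu-SVR", "nu": 0}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SVRParams(**kwargs)


class TestBuildDescriptors:
    def test_column_per_hypothesis(self, ensemble_dataset, ensemble_hypotheses):
        X = ensemble_dataset["X"]
        assert X.shape == (130, 3)

    def test_no_fit_rows_fall_back_to_intercept(self, ensemble_hypotheses):
        h = ensemble_hypotheses[0]
        lonely = [[LigandFeature("HBA", [0, 0, 0])]]  # nothing kind-compatible
        X, flags = build_descriptors([lonely], [h])
        assert flags[0, 0]
        assert X[0, 0] == pytest.approx(h.activity_map[0])

    def test_deterministic_recomputation(self, ensemble_dataset, ensemble_hypotheses):
        ligs = ensemble_dataset["ligands"][:5]
        X1, _ = build_descriptors([[l.features] for l in ligs], ensemble_hypotheses)
        X2, _ = build_descriptors([[l.features] for l in ligs], ensemble_hypotheses)
        np.testing.assert_array_equal(X1, X2)

    def test_empty_ensemble_rejected(self, ensemble_dataset):
        with pytest.raises(ValueError):
            build_descriptors([[]], [])


class TestTrainSVR:
    def test_duplicated_rows_interpolated_within_epsilon(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0]])
        y = np.array([5.0, 5.0])
        p = SVRParams(C=100.0, gamma=1.0, epsilon=0.01)
        m = train_svr(X, y, p)
        assert np.abs(m.predict(X) - y).max() <= p.epsilon + 1e-9

    def test_rbf_representable_function_fit_to_epsilon(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 2))
        centre = np.array([0.3, -0.2])
        gamma = 0.5
        y = 2.0 * np.exp(-gamma * np.sum((X - centre) ** 2, axis=1))
        p = SVRParams(C=1e4, gamma=gamma, epsilon=0.001)
        m = train_svr(X, y, p)
        rmse = np.sqrt(np.mean((m.predict(X) - y) ** 2))
        assert rmse < p.epsilon + 1e-3

    def test_bit_reproducible_retraining(self, ensemble_dataset):
        d = ensemble_dataset
        tr = d["train"]
        m1 = train_svr(d["X"][tr], d["y"][tr])
        m2 = train_svr(d["X"][tr], d["y"][tr])
        np.testing.assert_array_equal(m1.predict(d["X"]), m2.predict(d["X"]))

    def test_predictions_in_pec50_units_despite_scaling(self):
        # scaling a descriptor column must not change predictions
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        y = X @ np.array([1.0, -0.5]) + 6.0
        p = SVRParams(C=100, gamma=0.1, epsilon=0.01)
        base = train_svr(X, y, p).predict(X)
        X2 = X * np.array([1000.0, 1.0])  # same information, different units
        rescaled = train_svr(X2, y, p).predict(X2)
        np.testing.assert_allclose(base, rescaled, atol=1e-8)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            train_svr(np.array([[np.nan], [1.0]]), np.array([1.0, 2.0]))


class TestGridSearch:
    def test_single_point_grid_returned(self, ensemble_dataset):
        d = ensemble_dataset
        tr = d["train"]
        best, table = grid_search(
            d["X"][tr], d["y"][tr], c_grid=[4.0], gamma_grid=[0.008],
            eps_or_nu_grid=[0.001], folds=5, seed=1,
        )
        assert (best.C, best.gamma, best.epsilon) == (4.0, 0.008, 0.001)
        assert len(table) == 1

    def test_matches_independent_reevaluation(self, ensemble_dataset):
        d = ensemble_dataset
        tr = d["train"]
        X, y = d["X"][tr], d["y"][tr]
        cg, gg, eg = [1.0, 16.0, 256.0], [0.01, 0.1, 1.0], [0.001, 0.01, 0.1]
        best, table = grid_search(X, y, c_grid=cg, gamma_grid=gg, eps_or_nu_grid=eg,
                                  folds=5, seed=3)
        assign = activity_folds(y, 5, 3)
        recomputed = {}
        for C, gamma, e in itertools.product(cg, gg, eg):
            p = SVRParams(C=C, gamma=gamma, epsilon=e)
            recomputed[(C, gamma, e)] = cv_rmse(X, y, p, assign)
        for _, row in table.iterrows():
            key = (row["C"], row["gamma"], row["eps_or_nu"])
            assert row["cv_rmse"] == pytest.approx(recomputed[key], abs=1e-12)
        best_key = min(recomputed, key=lambda k: (recomputed[k], k[0], -k[2], k[1]))
        assert (best.C, best.gamma, best.epsilon) == best_key

    def test_grid_coverage_identical_across_seeds(self, ensemble_dataset):
        d = ensemble_dataset
        tr = d["train"]
        cg, gg, eg = [1.0, 4.0], [0.01, 0.1], [0.001]
        _, t1 = grid_search(d["X"][tr], d["y"][tr], c_grid=cg, gamma_grid=gg,
                            eps_or_nu_grid=eg, folds=5, seed=1)
        _, t2 = grid_search(d["X"][tr], d["y"][tr], c_grid=cg, gamma_grid=gg,
                            eps_or_nu_grid=eg, folds=5, seed=2)
        pts1 = set(map(tuple, t1[["C", "gamma", "eps_or_nu"]].to_numpy()))
        pts2 = set(map(tuple, t2[["C", "gamma", "eps_or_nu"]].to_numpy()))
        assert pts1 == pts2 == set(itertools.product(cg, gg, eg))


class TestKfoldQ2:
    def test_stratified_folds_partition_everything(self):
        y = np.linspace(4, 10, 31)
        assign = activity_folds(y, 10, seed=0)
        assert len(np.unique(assign)) == 10
        sizes = np.bincount(assign)
        assert sizes.max() - sizes.min() <= 1

    def test_q2_upper_bound_and_null_model(self, ensemble_dataset):
        d = ensemble_dataset
        tr = d["train"]
        q2 = kfold_q2(d["X"][tr], d["y"][tr], folds=10, seed=1)
        assert q2 <= 1.0
        # a constant-only model (gamma tiny, C tiny) predicts near the mean:
        # q2 collapses toward zero or below
        p_null = SVRParams(C=1e-6, gamma=1e-6, epsilon=0.001)
        q2_null = kfold_q2(d["X"][tr], d["y"][tr], p_null, folds=10, seed=1)
        assert q2_null < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(PhesvmError):
            kfold_q2(np.zeros((12, 2)), np.full(12, 5.0), folds=3)


class TestSelectEnsemble:
    def _candidates_and_training(self):
        rng = np.random.default_rng(6)
        hyps = [make_hypothesis(100 + i, 4) for i in range(6)]
        # single-conformer ligands with activities tied to hypothesis 0
        from phesvm.synthetic import make_ligand_set

        ligs = make_ligand_set(hyps[0], 20, jitter_sd=0.4, decoy_fraction=0.2,
                               noise_sd=0.15, seed=8)
        train_feats = [[l.features] for l in ligs]
        y = np.array([l.pec50_true for l in ligs])
        return hyps, train_feats, y

    def test_matches_brute_force_subset_search(self):
        hyps, train_feats, y = self._candidates_and_training()
        k = 3
        chosen = select_ensemble(hyps, train_feats, y, k=k)
        # oracle: score all candidates once, then replay the greedy contract
        from phesvm.fit import best_fit

        preds = [
            np.array([best_fit(c, h, 1).pec50_pred for c in train_feats]) for h in hyps
        ]
        r2 = []
        for col in preds:
            r2.append(np.corrcoef(col, y)[0, 1] ** 2 if np.std(col) > 0 else -np.inf)
        order = sorted(range(len(hyps)), key=lambda i: (-r2[i], i))
        picked = []
        for i in order:
            if len(picked) == k:
                break
            if all(abs(np.corrcoef(preds[i], preds[j])[0, 1]) <= 0.95 for j in picked):
                picked.append(i)
        assert [h.id for h in chosen] == [hyps[i].id for i in picked]

    def test_duplicate_candidates_collapse(self):
        hyps, train_feats, y = self._candidates_and_training()
        doubled = [hyps[0], hyps[0]] + hyps[1:]
        chosen = select_ensemble(doubled, train_feats, y, k=3)
        ids = [id(h) for h in chosen]
        assert len(set(ids)) == 3  # distinct objects survive the filter

    def test_too_few_survivors_error(self):
        hyps, train_feats, y = self._candidates_and_training()
        with pytest.raises(PhesvmError, match="survive"):
            select_ensemble([hyps[0]] * 5, train_feats, y, k=3)


class TestPhEModel:
    def test_prediction_order_invariant(self, ensemble_dataset, ensemble_hypotheses):
        d = ensemble_dataset
        model = train_phe_model(
            ensemble_hypotheses,
            [[l.features] for l in d["ligands"][:31]],
            d["y"][:31],
        )
        batch = [[l.features] for l in d["ligands"][31:41]]
        fwd = model.predict_batch(batch)
        rev = model.predict_batch(batch[::-1])
        np.testing.assert_allclose(fwd, rev[::-1], atol=1e-12)

    def test_breakdown_has_k_entries(self, ensemble_dataset, ensemble_hypotheses):
        d = ensemble_dataset
        model = train_phe_model(
            ensemble_hypotheses,
            [[l.features] for l in d["ligands"][:31]],
            d["y"][:31],
        )
        pred, breakdown, flagged = model.predict_features([d["ligands"][40].features])
        assert len(breakdown) == model.k == 3
        assert np.isfinite(pred)
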