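"""Superposition, mapping enumeration, fit scoring and best-fit search."""

import itertools
import math

import numpy as np
import pytest

from phesvm import (
    DegenerateGeometryError,
    Hypothesis,
    LigandFeature,
    PharmacophorePoint,
    best_fit,
    enumerate_mappings,
    estimate_activity,
    fit_score,
    superpose,
)
from phesvm.synthetic import make_hypothesis, random_rotation


def _hp(pos, tol=1.0, w=1.0, kind="HP"):
    return PharmacophorePoint(kind, pos, tol, w)


@pytest.fixture
def tri_hypo():
    pts = [_hp([0, 0, 0], kind="HBD"), _hp([3, 0, 0]), _hp([0, 3, 0])]
    return Hypothesis("tri", pts)


class TestSuperpose:
    def test_identity_case(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
        R, t, rmsd = superpose(A, A)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0, atol=1e-9)
        assert rmsd == pytest.approx(0, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_recovers_known_rigid_transform(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(6, 3))
        R = random_rotation(rng)
        t = rng.normal(size=3)
        B = A @ R.T + t
        R2, t2, rmsd = superpose(A, B)
        assert np.abs(R2 - R).max() < 1e-6
        assert rmsd < 1e-6
        assert np.linalg.det(R2) == pytest.approx(1.0, abs=1e-9)

    def test_mirror_image_not_matched(self):
        # chiral 4-point set; reflection cannot be reached by proper rotation
        A = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 2]], dtype=float)
        B = A * np.array([-1, 1, 1])
        _, _, rmsd = superpose(A, B)
        assert rmsd > 0.1

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_rejected(self):
        A = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            superpose(A, A + 1.0)


class TestEnumerateMappings:
    def test_no_kind_compatible_pair(self):
        h = Hypothesis("h", [_hp([0, 0, 0], kind="HBD"), _hp([3, 0, 0], kind="HBD"), _hp([0, 3, 0], kind="HBD")])
        feats = [LigandFeature("HBA", [0, 0, 0])]
        assert list(enumerate_mappings(feats, h, 0)) == []

    def test_hand_counted_permutation(self, tri_hypo):
        feats = [
            LigandFeature("HBD", [0, 0, 0]),
            LigandFeature("HP", [3, 0, 0]),
            LigandFeature("HP", [0, 3, 0]),
        ]
        maps = list(enumerate_mappings(feats, tri_hypo, 0))
        assert len(maps) == 2  # the two HP pairings permute
        for m in maps:
            assert m.n_mapped == 3 and not m.misses

    def test_mapping_invariants(self, tri_hypo):
        feats = [
            LigandFeature("HBD", [0, 0, 0]),
            LigandFeature("HP", [1, 0, 0]),
            LigandFeature("HP", [0, 1, 0]),
            LigandFeature("HP", [1, 1, 0]),
        ]
        for m in enumerate_mappings(feats, tri_hypo, 1):
            hs = [p for p, _ in m.pairs]
            fs = [f for _, f in m.pairs]
            assert len(set(hs)) == len(hs) and len(set(fs)) == len(fs)
            assert len(m.pairs) + len(m.misses) == 3
            for hp_i, f_i in m.pairs:
                assert tri_hypo.points[hp_i].kind == feats[f_i].kind

    @pytest.mark.parametrize("seed", range(10))
    def test_count_matches_combinatorial_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kinds = ["HBD", "HBA", "HP"]
        n_h = int(rng.integers(3, 6))
        n_f = int(rng.integers(3, 7))
        max_misses = int(rng.integers(0, 3))
        h = Hypothesis(
            "h",
            [_hp(rng.normal(size=3) * 5, kind=kinds[rng.integers(0, 3)]) for _ in range(n_h)],
        )
        feats = [
            LigandFeature(kinds[rng.integers(0, 3)], rng.normal(size=3) * 5)
            for _ in range(n_f)
        ]
        got = len(list(enumerate_mappings(feats, h, max_misses)))
        # oracle: enumerate all injective partial functions via brute force
        expected = 0
        for mapped in itertools.chain.from_iterable(
            itertools.combinations(range(n_h), r)
            for r in range(3, n_h + 1)
        ):
            if n_h - len(mapped) > max_misses:
                continue
            for perm in itertools.permutations(range(n_f), len(mapped)):
                if all(
                    h.points[i].kind == feats[j].kind for i, j in zip(mapped, perm)
                ):
                    expected += 1
        assert got == expected


class TestFitScore:
    def test_zero_displacement_full_weight(self):
        h = Hypothesis("h", [_hp([0, 0, 0]), _hp([3, 0, 0]), _hp([0, 3, 0]), _hp([3, 3, 0])])
        assert fit_score(h, [0, 0, 0, 0]) == pytest.approx(4.0)

    def test_tolerance_boundary_contributes_zero(self):
        h = Hypothesis("h", [_hp([0, 0, 0], tol=2.0), _hp([3, 0, 0]), _hp([0, 3, 0])])
        full = fit_score(h, [0, 0, 0])
        at_edge = fit_score(h, [2.0, 0, 0])
        assert full - at_edge == pytest.approx(1.0)

    def test_quadratic_falloff_hand_values(self):
        h = Hypothesis("h", [_hp([0, 0, 0]), _hp([3, 0, 0]), _hp([0, 3, 0])])
        assert fit_score(h, [0.0, 0.5, 1.0]) == pytest.approx(1.75)

    def test_negative_displacement_rejected(self):
        h = Hypothesis("h", [_hp([0, 0, 0]), _hp([3, 0, 0]), _hp([0, 3, 0])])
        with pytest.raises(ValueError):
            fit_score(h, [-0.1, 0, 0])

    def test_missed_points_contribute_zero(self):
        h = Hypothesis("h", [_hp([0, 0, 0]), _hp([3, 0, 0]), _hp([0, 3, 0]), _hp([3, 3, 0])])
        assert fit_score(h, [0, 0, 0, None]) == pytest.approx(3.0)


class TestEstimateActivity:
    def test_identity_map(self):
        assert estimate_activity(3.0, (0.0, 1.0)) == pytest.approx(3.0)

    def test_degenerate_constant_predictor(self):
        assert estimate_activity(0.0, (5.5, 0.0)) == estimate_activity(99.0, (5.5, 0.0))


class TestBestFit:
    def test_exact_coincidence_reaches_weight_sum(self):
        h = make_hypothesis(3, 4)
        feats = [LigandFeature(p.kind, p.position.copy()) for p in h.points]
        res = best_fit([feats], h, max_misses=0)
        assert res.fit == pytest.approx(h.max_fit, abs=1e-9)
        assert np.nanmax(res.displacements) < 1e-9
        assert not res.no_fit

    def test_no_fit_flagged(self, tri_hypo):
        feats = [LigandFeature("HBA", [0, 0, 0])]
        res = best_fit([feats], tri_hypo, max_misses=0)
        assert res.no_fit and res.fit == 0.0 and res.mapping.n_mapped == 0
        assert res.pec50_pred == pytest.approx(tri_hypo.activity_map[0])

    def test_rotation_is_proper(self):
        h = make_hypothesis(5, 4)
        rng = np.random.default_rng(0)
        feats = [
            LigandFeature(p.kind, p.position + rng.normal(0, 0.3, 3)) for p in h.points
        ]
        res = best_fit([feats], h, max_misses=1)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        assert 0 <= res.fit <= h.max_fit + 1e-12

    def test_fit_invariant_under_common_rigid_transform(self):
        h = make_hypothesis(9, 4)
        rng = np.random.default_rng(1)
        feats = [
            LigandFeature(p.kind, p.position + rng.normal(0, 0.4, 3)) for p in h.points
        ]
        base = best_fit([feats], h, max_misses=0).fit
        R = random_rotation(rng)
        t = rng.normal(size=3)
        feats2 = [LigandFeature(f.kind, R @ f.position + t) for f in feats]
        pts2 = [
            PharmacophorePoint(p.kind, R @ p.position + t, p.tolerance, p.weight)
            for p in h.points
        ]
        h2 = Hypothesis(h.id, pts2, h.activity_map)
        assert best_fit([feats2], h2, max_misses=0).fit == pytest.approx(base, abs=1e-9)

    def test_fit_nonincreasing_as_tolerance_shrinks(self):
        h = make_hypothesis(13, 4)
        rng = np.random.default_rng(2)
        feats = [
            LigandFeature(p.kind, p.position + rng.normal(0, 0.5, 3)) for p in h.points
        ]
        fits = []
        for tol in (2.0, 1.5, 1.0, 0.6):
            pts = [
                PharmacophorePoint(p.kind, p.position, tol, p.weight) for p in h.points
            ]
            fits.append(best_fit([feats], Hypothesis(h.id, pts), max_misses=0).fit)
        assert all(a >= b - 1e-12 for a, b in zip(fits, fits[1:]))

    def test_more_misses_never_decrease_fit(self):
        h = make_hypothesis(17, 5)
        rng = np.random.default_rng(3)
        feats = [
            LigandFeature(p.kind, p.position + rng.normal(0, 0.8, 3))
            for p in h.points[:4]
        ]
        fits = [best_fit([feats], h, max_misses=m).fit for m in (1, 2)]
        assert fits[1] >= fits[0] - 1e-12

    def test_best_fit_dominates_hand_mapping(self):
        h = make_hypothesis(19, 4)
        rng = np.random.default_rng(5)
        feats = [
            LigandFeature(p.kind, p.position + rng.normal(0, 0.3, 3)) for p in h.points
        ]
        res = best_fit([feats], h, max_misses=0)
        # hand mapping: reversed pairing of the HP block, superposed separately
        from phesvm.fit import fit_score as fs, superpose as sp

        idx = [0, 1, 2, 3]
        L = np.array([feats[j].position for j in idx])
        # any alternative kind-compatible assignment cannot beat the winner
        for perm in itertools.permutations(range(4)):
            if any(h.points[i].kind != feats[j].kind for i, j in zip(idx, perm)):
                continue
            Lp = np.array([feats[j].position for j in perm])
            R, t, _ = sp(Lp, h.positions)
            d = np.linalg.norm(Lp @ R.T + t - h.positions, axis=1)
            assert res.fit >= fs(h, d) - 1e-9

    def test_different_hypotheses_select_different_conformers(self):
        hA = make_hypothesis(23, 4, ["HBD", "HP", "HP", "HP"])
        hB = make_hypothesis(29, 4, ["HBD", "HP", "HP", "HP"])
        conf0 = [LigandFeature(p.kind, p.position.copy()) for p in hA.points]
        conf1 = [LigandFeature(p.kind, p.position.copy()) for p in hB.points]
        confs = [conf0, conf1]
        assert best_fit(confs, hA, 0).conformer_index == 0
        assert best_fit(confs, hB, 0).conformer_index == 1
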